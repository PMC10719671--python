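"""Maximum-likelihood tetrachoric correlations from cross-twin 2x2 tables.

Under the liability-threshold model a binary trait reflects a latent
standard-normal liability dichotomized at a threshold; the tetrachoric
correlation of a 2x2 cross-twin table is the ML estimate of the correlation
of the two latent liabilities.  Tables are double-entered (each pair counted
in both twin orders), the convention in twin analysis; confidence intervals
are computed on the raw pair count so double entry does not shrink them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from scipy.special import ndtr

from ._normal import bvn_cdf, norm_ppf, same_trait_cell_probs
from .definitions import CRITERIA

__all__ = [
    "PairTable",
    "TetrachoricEstimate",
    "EstimationError",
    "table_from_pairs",
    "build_pair_tables",
    "tetrachoric_mle",
    "correlations_frame",
]

_CHI2_95 = 3.841458820694124  # qchisq(0.95, df=1)
_RHO_EDGE = 1.0 - 1e-7


class EstimationError(ValueError):
    """Raised when a contingency table does not admit estimation."""


@dataclass
class PairTable:
    """Cross-twin 2x2 counts for one criterion/measure/zygosity cell.

    Counts follow (row = twin 1, column = twin 2) with 1 = positive:
    ``n11, n10, n01, n00``.  ``n_pairs_raw`` is the number of distinct pairs
    before double entry; likelihood-based inference is scaled to this count.
    ``n_single_pos``/``n_single_neg`` count twins whose co-twin is missing;
    they contribute Bernoulli margin terms (threshold information) only.
    """

    n11: float
    n10: float
    n01: float
    n00: float
    n_pairs_raw: int
    criterion: str = ""
    measure_pair: str = ""
    zygosity: str = ""
    n_single_pos: int = 0
    n_single_neg: int = 0

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n_pairs_raw <= 0:
            raise ValueError("n_pairs_raw must be positive")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n11, self.n10, self.n01, self.n00], dtype=float)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def loglik_scale(self) -> float:
        """Per-pair scale: 0.5 for double-entered tables, 1 otherwise."""
        return self.n_pairs_raw / self.total

    def transpose(self) -> "PairTable":
        return PairTable(
            self.n11, self.n01, self.n10, self.n00, self.n_pairs_raw,
            self.criterion, self.measure_pair, self.zygosity,
            self.n_single_pos, self.n_single_neg,
        )


@dataclass
class TetrachoricEstimate:
    rho: float
    tau_row: float
    tau_col: float
    ci_low: float
    ci_high: float
    loglik: float
    n: int
    boundary: bool = False


def table_from_pairs(
    x1: np.ndarray,
    x2: np.ndarray,
    double_entry: bool = True,
    **meta,
) -> PairTable:
    """Build a cross-twin table from per-pair binary outcome vectors."""
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have the same length")
    n11 = float(np.sum((x1 == 1) & (x2 == 1)))
    n10 = float(np.sum((x1 == 1) & (x2 == 0)))
    n01 = float(np.sum((x1 == 0) & (x2 == 1)))
    n00 = float(np.sum((x1 == 0) & (x2 == 0)))
    n_raw = len(x1)
    if double_entry:
        n11, n00 = 2 * n11, 2 * n00
        n10 = n01 = n10 + n01
    return PairTable(n11, n10, n01, n00, n_pairs_raw=n_raw, **meta)


def _wide_pairs(profiles: pd.DataFrame, zygosity: str, pool_os: bool) -> pd.DataFrame:
    groups = {"MZ": ["MZ-ss"], "DZ": ["DZ-ss"] + (["OS"] if pool_os else [])}[zygosity]
    sub = profiles[profiles["zygosity_group"].isin(groups)]
    t1 = sub[sub["twin_order"] == 1].set_index("pair_id")
    t2 = sub[sub["twin_order"] == 2].set_index("pair_id")
    common = t1.index.intersection(t2.index)
    return t1.loc[common], t2.loc[common], sub


def build_pair_tables(
    profiles: pd.DataFrame,
    measure_pair: str,
    zygosity: str,
    pool_os: bool = True,
) -> dict[str, PairTable]:
    """Cross-twin tables per criterion from a long-format profile frame.

    ``measure_pair`` is ``in-in``, ``out-out`` or ``in-out``.  Same-trait
    tables are double-entered symmetrically; in-out cross tables are
    double-entered as (twin1-IN x twin2-OUT) plus (twin2-IN x twin1-OUT).
    Pairs with an unknown status on either member are excluded from that
    criterion's joint cells; twins without a co-twin contribute margin
    counts only.
    """
    if measure_pair not in ("in-in", "out-out", "in-out"):
        raise ValueError(f"unknown measure_pair {measure_pair!r}")
    t1, t2, sub = _wide_pairs(profiles, zygosity, pool_os)
    paired_ids = set(t1.index)
    singles = sub[~sub["pair_id"].isin(paired_ids)]

    tables = {}
    for crit in CRITERIA:
        col_row = f"in_{crit}" if measure_pair.startswith("in") else f"out_{crit}"
        col_col = f"out_{crit}" if measure_pair.endswith("out") else f"in_{crit}"
        a1 = t1[col_row]
        b2 = t2[col_col]
        if measure_pair == "in-out":
            a2 = t2[col_row]
            b1 = t1[col_col]
            ok_f = a1.notna() & b2.notna()
            ok_r = a2.notna() & b1.notna()
            xs = np.concatenate([a1[ok_f].to_numpy(int), a2[ok_r].to_numpy(int)])
            ys = np.concatenate([b2[ok_f].to_numpy(int), b1[ok_r].to_numpy(int)])
            n_raw = int(max(ok_f.sum(), ok_r.sum()))
            if n_raw == 0:
                raise EstimationError(f"no complete pairs for criterion {crit!r}")
            tab = table_from_pairs(
                xs, ys, double_entry=False,
                criterion=crit, measure_pair=measure_pair, zygosity=zygosity,
            )
            tab = PairTable(
                tab.n11, tab.n10, tab.n01, tab.n00, n_pairs_raw=n_raw,
                criterion=crit, measure_pair=measure_pair, zygosity=zygosity,
            )
        else:
            ok = a1.notna() & b2.notna()
            if int(ok.sum()) == 0:
                raise EstimationError(f"no complete pairs for criterion {crit!r}")
            tab = table_from_pairs(
                a1[ok].to_numpy(int), b2[ok].to_numpy(int), double_entry=True,
                criterion=crit, measure_pair=measure_pair, zygosity=zygosity,
            )
        s = singles[col_row].dropna()
        tab.n_single_pos = int((s == 1).sum())
        tab.n_single_neg = int((s == 0).sum())
        tables[crit] = tab
    return tables


def _loglik(rho: float, tau_r: float, tau_c: float, table: PairTable) -> float:
    """Per-pair-scaled log-likelihood (raw pair count scale)."""
    if not -1.0 < rho < 1.0 or not np.isfinite(tau_r) or not np.isfinite(tau_c):
        return -np.inf
    probs = same_trait_cell_probs(rho, tau_r, tau_c)
    probs = np.clip(probs, 1e-300, 1.0)
    ll = table.loglik_scale * float(table.counts @ np.log(probs))
    if table.n_single_pos or table.n_single_neg:
        p_neg = float(np.clip(ndtr(tau_r), 1e-300, 1 - 1e-16))
        ll += table.n_single_neg * np.log(p_neg) + table.n_single_pos * np.log1p(-p_neg)
    return ll


def _margin_taus(table: PairTable) -> tuple[float, float]:
    c = table.counts
    tot = c.sum()
    p_row = (c[0] + c[1]) / tot
    p_col = (c[0] + c[2]) / tot
    if p_row in (0.0, 1.0) or p_col in (0.0, 1.0):
        raise EstimationError("undefined threshold: empty margin")
    return float(norm_ppf(1 - p_row)), float(norm_ppf(1 - p_col))


def _profile_loglik(rho: float, table: PairTable, tau0: tuple[float, float]) -> float:
    """Max over thresholds of the scaled log-likelihood at fixed rho."""
    res = minimize(
        lambda t: -_loglik(rho, t[0], t[1], table),
        x0=np.array(tau0),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 400},
    )
    return -res.fun


def _bisect_ci(
    table: PairTable, rho_hat: float, llmax: float, tau0, side: int
) -> float:
    """Profile-likelihood CI endpoint (side = +1 upper, -1 lower)."""
    target = llmax - _CHI2_95 / 2.0
    edge = side * _RHO_EDGE
    if _profile_loglik(edge, table, tau0) >= target:
        return side * 1.0
    lo, hi = rho_hat, edge  # f(lo) >= target > f(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _profile_loglik(mid, table, tau0) >= target:
            lo = mid
        else:
            hi = mid
        if abs(hi - lo) < 1e-6:
            break
    return 0.5 * (lo + hi)


def tetrachoric_mle(table: PairTable, compute_ci: bool = True) -> TetrachoricEstimate:
    """ML tetrachoric correlation with profile-likelihood 95% CI.

    The multinomial likelihood over the four cells is maximized jointly in
    (rho, tau_row, tau_col) by Nelder-Mead simplex from three starting
    correlations; ties are broken toward the smallest ``|rho|``.  Perfectly
    concordant (or discordant) tables give a boundary estimate of +1 (-1)
    with a one-sided CI.
    """
    c = table.counts
    if int(np.count_nonzero(c)) < 2:
        raise EstimationError("degenerate table: fewer than 2 non-empty cells")
    tau0 = _margin_taus(table)

    # perfect association boundaries
    if c[1] == 0 and c[2] == 0:
        rho, boundary = 1.0, True
    elif c[0] == 0 and c[3] == 0:
        rho, boundary = -1.0, True
    else:
        boundary = False
        best = None
        for start in (-0.5, 0.0, 0.5):
            res = minimize(
                lambda x: -_loglik(np.clip(x[0], -_RHO_EDGE, _RHO_EDGE), x[1], x[2], table),
                x0=np.array([start, tau0[0], tau0[1]]),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
            )
            cand = (float(-res.fun), float(np.clip(res.x[0], -_RHO_EDGE, _RHO_EDGE)),
                    float(res.x[1]), float(res.x[2]))
            if best is None or cand[0] > best[0] + 1e-8 or (
                abs(cand[0] - best[0]) <= 1e-8 and abs(cand[1]) < abs(best[1])
            ):
                best = cand
        _, rho, tau_r, tau_c = best
        if abs(rho) >= _RHO_EDGE - 1e-9:
            rho, boundary = float(np.sign(rho)), True

    if boundary:
        tau_r, tau_c = tau0
        llmax = _profile_loglik(np.sign(rho) * _RHO_EDGE, table, tau0)
    else:
        llmax = _loglik(rho, tau_r, tau_c, table)

    ci_low = ci_high = np.nan
    if compute_ci:
        ci_low = rho if (boundary and rho < 0) else _bisect_ci(table, rho, llmax, tau0, -1)
        ci_high = rho if (boundary and rho > 0) else _bisect_ci(table, rho, llmax, tau0, +1)

    return TetrachoricEstimate(
        rho=float(rho),
        tau_row=float(tau_r),
        tau_col=float(tau_c),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        loglik=float(llmax),
        n=int(table.n_pairs_raw),
        boundary=boundary,
    )


def correlations_frame(
    estimates: dict[tuple[str, str, str], TetrachoricEstimate]
) -> pd.DataFrame:
    """Tidy frame of estimates keyed by (criterion, measure_pair, zygosity)."""
    rows = [
        {
            "criterion": crit,
            "measure_pair": mp,
            "zygosity": zyg,
            "rho": e.rho,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n_pairs": e.n,
        }
        for (crit, mp, zyg), e in estimates.items()
    ]
    df = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(CRITERIA)}
    return df.sort_values(
        ["measure_pair", "zygosity", "criterion"],
        key=lambda s: s.map(order) if s.name == "criterion" else s,
        kind="stable",
    ).reset_index(drop=True)
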