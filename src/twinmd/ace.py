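"""Univariate and bivariate liability-threshold ACE twin models.

The ACE decomposition attributes liability variance to additive genetics
(A, shared with coefficient 1 by MZ and 0.5 by DZ co-twins), common
environment (C, fully shared within a pair), and unique environment (E,
uncorrelated across twins).  For a binary criterion the model implies
cross-twin liability correlations r_MZ = a2 + c2 and r_DZ = 0.5 a2 + c2,
and cell probabilities of the cross-twin contingency table follow from the
bivariate (univariate model) or 4-variate (bivariate IN/OUT model) normal
with those correlations.

Estimation maximizes the per-pair multinomial likelihood of the observed
cell counts, with thresholds equated across twin order and zygosity within
a trait.  In the full ACE model the variance components are left unbounded
(they may go negative), which avoids the bias that implicit non-negativity
bounds induce near the boundary; standardized proportions are reported at
the solution.  Model selection among ACE/AE/CE/E uses AIC; interval
estimates are profile-likelihood based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from ._normal import joint_cell_probs, norm_ppf, same_trait_cell_probs, mvn_orthant
from .definitions import CRITERIA
from .tetrachoric import EstimationError, PairTable

__all__ = [
    "JointPairTable",
    "UnivariateACEFit",
    "BivariateACEFit",
    "build_joint_tables",
    "univariate_loglik",
    "fit_univariate",
    "fit_bivariate",
    "aic_select",
    "mvn_orthant",
    "univariate_fits_frame",
    "bivariate_fits_frame",
]

_CHI2_95 = 3.841458820694124
_MODEL_ORDER = {"ACE": 0, "AE": 1, "CE": 2, "E": 3}
_PENALTY = -1e12


@dataclass
class JointPairTable:
    """16-cell cross-twin counts over (IN, OUT) for one criterion/zygosity.

    ``counts`` has shape (2, 2, 2, 2) indexed [in1, out1, in2, out2] with
    1 = positive; tables are double-entered (symmetric under twin swap) and
    ``n_pairs_raw`` preserves the raw pair count for likelihood scaling.
    """

    counts: np.ndarray
    n_pairs_raw: int
    criterion: str = ""
    zygosity: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2, 2, 2):
            raise ValueError("counts must have shape (2, 2, 2, 2)")
        if self.counts.min() < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n_pairs_raw <= 0:
            raise ValueError("n_pairs_raw must be positive")

    @property
    def loglik_scale(self) -> float:
        return self.n_pairs_raw / float(self.counts.sum())


def joint_table_from_pairs(x: np.ndarray, double_entry: bool = True, **meta) -> JointPairTable:
    """16-cell table from an (n_pairs, 4) binary array (IN1, OUT1, IN2, OUT2)."""
    x = np.asarray(x, dtype=int)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("x must have shape (n_pairs, 4)")
    counts = np.zeros((2, 2, 2, 2))
    np.add.at(counts, (x[:, 0], x[:, 1], x[:, 2], x[:, 3]), 1.0)
    if double_entry:
        np.add.at(counts, (x[:, 2], x[:, 3], x[:, 0], x[:, 1]), 1.0)
    return JointPairTable(counts, n_pairs_raw=x.shape[0], **meta)


def build_joint_tables(
    profiles: pd.DataFrame, zygosity: str, pool_os: bool = True
) -> dict[str, JointPairTable]:
    """Double-entered 16-cell IN/OUT tables per criterion from profiles."""
    from .tetrachoric import _wide_pairs

    t1, t2, _ = _wide_pairs(profiles, zygosity, pool_os)
    tables = {}
    for crit in CRITERIA:
        cols = [f"in_{crit}", f"out_{crit}"]
        a = t1[cols]
        b = t2[cols]
        ok = a.notna().all(axis=1) & b.notna().all(axis=1)
        if int(ok.sum()) == 0:
            raise EstimationError(f"no complete pairs for criterion {crit!r}")
        av = a[ok].to_numpy(int)
        bv = b[ok].to_numpy(int)
        counts = np.zeros((2, 2, 2, 2))
        np.add.at(counts, (av[:, 0], av[:, 1], bv[:, 0], bv[:, 1]), 1.0)
        np.add.at(counts, (bv[:, 0], bv[:, 1], av[:, 0], av[:, 1]), 1.0)
        tables[crit] = JointPairTable(
            counts, n_pairs_raw=int(ok.sum()), criterion=crit, zygosity=zygosity
        )
    return tables


# ---------------------------------------------------------------------------
# univariate model
# ---------------------------------------------------------------------------


@dataclass
class UnivariateACEFit:
    model: str
    va: float
    vc: float
    ve: float
    a2: float
    c2: float
    e2: float
    threshold: float
    loglik: float
    k: int
    aic: float
    ci: dict = field(default_factory=dict)  # component -> (low, high)
    converged: bool = True
    note: str = ""


def _implied_r(a2: float, c2: float) -> tuple[float, float]:
    return a2 + c2, 0.5 * a2 + c2


def _uni_ll(a2: float, c2: float, tau: float, tables: dict[str, PairTable]) -> float:
    """Scaled log-likelihood at standardized components (e2 = 1 - a2 - c2)."""
    if not np.isfinite(tau):
        return _PENALTY
    r_mz, r_dz = _implied_r(a2, c2)
    if not (-1.0 < r_mz < 1.0 and -1.0 < r_dz < 1.0):
        return _PENALTY
    ll = 0.0
    for zyg, r in (("MZ", r_mz), ("DZ", r_dz)):
        tab = tables.get(zyg)
        if tab is None:
            continue
        probs = np.clip(same_trait_cell_probs(r, tau, tau), 1e-300, 1.0)
        ll += tab.loglik_scale * float(tab.counts @ np.log(probs))
        if tab.n_single_pos or tab.n_single_neg:
            p_neg = float(np.clip(ndtr(tau), 1e-300, 1 - 1e-16))
            ll += tab.n_single_neg * np.log(p_neg) + tab.n_single_pos * np.log1p(-p_neg)
    return ll


def univariate_loglik(
    components: dict, threshold: float, tables: dict[str, PairTable]
) -> float:
    """Log-likelihood of raw variance components (normalized internally).

    ``components`` maps any subset of {"VA", "VC", "VE"} to raw values;
    omitted components are zero.  The total variance is normalized to 1, so
    only the proportions matter.  An implied cross-twin correlation outside
    (-1, 1) returns a large negative penalty rather than raising.
    """
    va = float(components.get("VA", 0.0))
    vc = float(components.get("VC", 0.0))
    ve = float(components.get("VE", 0.0))
    total = va + vc + ve
    if total <= 0:
        return _PENALTY
    return _uni_ll(va / total, vc / total, float(threshold), tables)


_FREE = {"ACE": ("a2", "c2"), "AE": ("a2",), "CE": ("c2",), "E": ()}


def _start_tau(tables: dict[str, PairTable]) -> float:
    num = den = 0.0
    for tab in tables.values():
        c = tab.counts
        num += c[0] + 0.5 * (c[1] + c[2])
        den += c.sum()
        num += tab.n_single_pos
        den += tab.n_single_pos + tab.n_single_neg
    p = min(max(num / den, 1e-6), 1 - 1e-6)
    return float(norm_ppf(1.0 - p))


def fit_univariate(
    tables: dict[str, PairTable],
    model: str = "ACE",
    compute_ci: bool = True,
) -> UnivariateACEFit:
    """ML fit of a univariate threshold model to MZ + DZ cross-twin tables.

    ``tables`` maps zygosity ("MZ", "DZ") to a :class:`PairTable`.  The free
    parameters are the standardized components named by ``model`` (unbounded
    in the full ACE model) plus the common threshold; ``e2`` absorbs the
    remainder.  95% CIs are profile-likelihood intervals on each
    standardized component.
    """
    if model not in _FREE:
        raise ValueError(f"unknown model {model!r}")
    if "MZ" not in tables or "DZ" not in tables:
        raise ValueError("both MZ and DZ tables are required")
    free = _FREE[model]
    tau0 = _start_tau(tables)

    def unpack(x):
        comp = dict(zip(free, x[:-1]))
        return comp.get("a2", 0.0), comp.get("c2", 0.0), x[-1]

    def nll(x):
        a2, c2, tau = unpack(x)
        return -_uni_ll(a2, c2, tau, tables)

    starts = {
        "ACE": [(0.3, 0.1), (0.5, 0.0), (0.1, 0.3), (0.0, 0.0), (0.7, 0.1)],
        "AE": [(0.3,), (0.6,), (0.05,), (0.45,), (0.8,)],
        "CE": [(0.2,), (0.4,), (0.05,), (0.6,), (0.8,)],
        "E": [()],
    }[model]
    best = None
    for s in starts:
        x0 = np.array(list(s) + [tau0])
        res = minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    a2, c2, tau = unpack(best.x)
    e2 = 1.0 - a2 - c2
    ll = float(-best.fun)
    k = len(free) + 1
    converged = bool(best.success) and ll > _PENALTY / 2
    note = "" if converged else f"optimizer did not converge: {best.message}"

    ci = {}
    if compute_ci and converged:
        target = ll - _CHI2_95 / 2.0

        def profile(comp: str, value: float) -> float:
            if comp == "a2":
                f = lambda y: -_uni_ll(value, y[0] if "c2" in free else 0.0, y[-1], tables)
                y0 = [c2, tau] if "c2" in free else [tau]
            elif comp == "c2":
                f = lambda y: -_uni_ll(y[0] if "a2" in free else 0.0, value, y[-1], tables)
                y0 = [a2, tau] if "a2" in free else [tau]
            else:  # e2: constrain a2 + c2 = 1 - value
                if model == "ACE":
                    f = lambda y: -_uni_ll(y[0], 1.0 - value - y[0], y[-1], tables)
                    y0 = [a2, tau]
                elif model == "AE":
                    f = lambda y: -_uni_ll(1.0 - value, 0.0, y[-1], tables)
                    y0 = [tau]
                elif model == "CE":
                    f = lambda y: -_uni_ll(0.0, 1.0 - value, y[-1], tables)
                    y0 = [tau]
                else:
                    return _PENALTY if abs(value - 1.0) > 1e-12 else ll
            res = minimize(
                f, np.array(y0), method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1500},
            )
            return float(-res.fun)

        def endpoint(comp: str, hat: float, side: int) -> float:
            edge = hat + side * 1.5
            if profile(comp, edge) >= target:
                return edge
            lo, hi = hat, edge
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if profile(comp, mid) >= target:
                    lo = mid
                else:
                    hi = mid
                if abs(hi - lo) < 1e-4:
                    break
            return 0.5 * (lo + hi)

        estimates = {"a2": a2, "c2": c2, "e2": e2}
        for comp in list(free) + ["e2"]:
            if model == "E" and comp == "e2":
                ci[comp] = (1.0, 1.0)
                continue
            hat = estimates[comp]
            ci[comp] = (endpoint(comp, hat, -1), endpoint(comp, hat, +1))

    return UnivariateACEFit(
        model=model,
        va=float(a2), vc=float(c2), ve=float(e2),
        a2=float(a2), c2=float(c2), e2=float(e2),
        threshold=float(tau),
        loglik=ll, k=k, aic=float(-2.0 * ll + 2.0 * k),
        ci=ci, converged=converged, note=note,
    )


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------


@dataclass
class BivariateACEFit:
    model: str
    A: np.ndarray | None
    C: np.ndarray | None
    E: np.ndarray
    rg: float | None
    rg_ci: tuple | None
    a2: tuple  # standardized (IN, OUT) additive proportions
    c2: tuple
    e2: tuple
    thresholds: tuple
    loglik: float
    k: int
    aic: float
    converged: bool = True
    note: str = ""


_BIV_FREE = {
    "ACE": ("A11", "A22", "A12", "C11", "C22", "C12", "E12", "tau_i", "tau_o"),
    "AE": ("A11", "A22", "A12", "E12", "tau_i", "tau_o"),
    "CE": ("C11", "C22", "C12", "E12", "tau_i", "tau_o"),
}


def _biv_blocks(p: dict) -> tuple[np.ndarray, dict[str, np.ndarray]] | None:
    """Within-twin covariance W and cross-twin blocks per zygosity.

    Returns None when the implied structure is invalid (non-PSD shared
    block, or a non-PD within-twin residual for either zygosity).
    """
    A11, A22, A12 = p.get("A11", 0.0), p.get("A22", 0.0), p.get("A12", 0.0)
    C11, C22, C12 = p.get("C11", 0.0), p.get("C22", 0.0), p.get("C12", 0.0)
    E12 = p.get("E12", 0.0)
    w12 = A12 + C12 + E12
    if not -1.0 < w12 < 1.0:
        return None
    W = np.array([[1.0, w12], [w12, 1.0]])
    blocks = {}
    for zyg, k in (("MZ", 1.0), ("DZ", 0.5)):
        B = np.array(
            [[k * A11 + C11, k * A12 + C12], [k * A12 + C12, k * A22 + C22]]
        )
        if np.linalg.eigvalsh(B).min() < -1e-10:
            return None
        R = W - B
        if np.diag(R).min() <= 1e-10:
            return None
        r = R[0, 1] / np.sqrt(R[0, 0] * R[1, 1])
        if abs(r) >= 1.0 - 1e-10:
            return None
        blocks[zyg] = B
    return W, blocks


def _biv_ll(p: dict, tables: dict[str, JointPairTable], n_nodes: int) -> float:
    wb = _biv_blocks(p)
    if wb is None:
        return _PENALTY
    W, blocks = wb
    tau = np.array([p["tau_i"], p["tau_o"]])
    ll = 0.0
    for zyg, tab in tables.items():
        probs = joint_cell_probs(W, blocks[zyg], tau, n_nodes=n_nodes)
        probs = np.clip(probs, 1e-300, 1.0)
        ll += tab.loglik_scale * float(np.sum(tab.counts * np.log(probs)))
    return ll


def _collapse_margin(tab: JointPairTable, which: int) -> PairTable:
    """Collapse a 16-cell joint table to the same-trait 4-cell table for one
    trait (0 = IN, 1 = OUT)."""
    c = tab.counts
    if which == 0:
        m = c.sum(axis=(1, 3))  # [in1, in2]
    else:
        m = c.sum(axis=(0, 2))  # [out1, out2]
    return PairTable(m[1, 1], m[1, 0], m[0, 1], m[0, 0], n_pairs_raw=tab.n_pairs_raw)


def _biv_starts(model: str, tau_i0: float, tau_o0: float) -> list[np.ndarray]:
    base = {
        "ACE": [
            (0.3, 0.15, 0.0, 0.05, 0.05, 0.0, 0.0),
            (0.2, 0.1, 0.05, 0.0, 0.0, 0.0, 0.1),
            (0.4, 0.2, -0.05, 0.1, 0.05, 0.02, 0.0),
        ],
        "AE": [
            (0.3, 0.15, 0.0, 0.0),
            (0.2, 0.1, 0.08, 0.05),
            (0.45, 0.25, -0.08, 0.0),
        ],
        "CE": [
            (0.2, 0.1, 0.0, 0.0),
            (0.3, 0.15, 0.05, 0.05),
            (0.1, 0.05, -0.03, 0.1),
        ],
    }[model]
    return [np.array(list(s) + [tau_i0, tau_o0]) for s in base]


def fit_bivariate(
    tables: dict[str, JointPairTable],
    model: str = "AE",
    compute_ci: bool = True,
    n_nodes: int = 24,
) -> BivariateACEFit:
    """ML fit of a bivariate IN/OUT variance-component model.

    ``tables`` maps zygosity to 16-cell joint tables for one criterion.
    Free parameters are the 2x2 component (co)variances named by ``model``
    (within-trait totals fixed at 1, so E diagonals absorb the remainder),
    the unique-environment cross-covariance, and the two thresholds.  The
    genetic correlation is rg = A12 / sqrt(A11 A22), reported as undefined
    when either within-trait additive variance estimate is non-positive;
    its 95% CI is profile-likelihood based.
    """
    if model not in _BIV_FREE:
        raise ValueError(f"unknown model {model!r}")
    if "MZ" not in tables or "DZ" not in tables:
        raise ValueError("both MZ and DZ tables are required")
    names = _BIV_FREE[model]

    c_any = next(iter(tables.values())).counts
    # margin starting thresholds from the pooled counts
    tot = sum(t.counts.sum() for t in tables.values())
    p_in = sum(t.counts[1, :, :, :].sum() for t in tables.values()) / tot
    p_out = sum(t.counts[:, 1, :, :].sum() for t in tables.values()) / tot
    tau_i0 = float(norm_ppf(1.0 - min(max(p_in, 1e-6), 1 - 1e-6)))
    tau_o0 = float(norm_ppf(1.0 - min(max(p_out, 1e-6), 1 - 1e-6)))

    def nll(x):
        return -_biv_ll(dict(zip(names, x)), tables, n_nodes)

    # data-driven starts: univariate fits on the collapsed same-trait margins
    starts = _biv_starts(model, tau_i0, tau_o0)
    try:
        uni_model = "CE" if model == "CE" else "AE"
        u_in = fit_univariate(
            {z: _collapse_margin(t, 0) for z, t in tables.items()},
            uni_model, compute_ci=False,
        )
        u_out = fit_univariate(
            {z: _collapse_margin(t, 1) for z, t in tables.items()},
            uni_model, compute_ci=False,
        )
        v_in = u_in.c2 if model == "CE" else u_in.a2
        v_out = u_out.c2 if model == "CE" else u_out.a2
        v_in, v_out = float(np.clip(v_in, 0.01, 0.9)), float(np.clip(v_out, 0.01, 0.9))
        x12 = 0.5 * np.sqrt(v_in * v_out)
        e12 = 0.5 * np.sqrt(max(1 - v_in, 0.05) * max(1 - v_out, 0.05))
        for cross, ecross in ((0.0, 0.0), (x12, e12)):
            p0 = {"tau_i": u_in.threshold, "tau_o": u_out.threshold, "E12": ecross}
            if model == "CE":
                p0.update(C11=v_in, C22=v_out, C12=cross)
            else:
                p0.update(A11=v_in, A22=v_out, A12=cross)
                if model == "ACE":
                    p0.update(C11=0.02, C22=0.02, C12=0.0)
            starts.append(np.array([p0.get(n, 0.0) for n in names]))
    except Exception:  # starts are best-effort; generic grid remains
        pass

    best = None
    for x0 in starts:
        res = minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 3000},
        )
        if best is None or res.fun < best.fun - 1e-8:
            best = res
    p = dict(zip(names, best.x))
    ll = float(-best.fun)
    k = len(names)
    converged = bool(best.success) and ll > _PENALTY / 2
    note = "" if converged else f"optimizer did not converge: {best.message}"

    A11, A22, A12 = p.get("A11", 0.0), p.get("A22", 0.0), p.get("A12", 0.0)
    C11, C22, C12 = p.get("C11", 0.0), p.get("C22", 0.0), p.get("C12", 0.0)
    E11, E22 = 1.0 - A11 - C11, 1.0 - A22 - C22
    A = np.array([[A11, A12], [A12, A22]]) if "A11" in p else None
    C = np.array([[C11, C12], [C12, C22]]) if "C11" in p else None
    E = np.array([[E11, p.get("E12", 0.0)], [p.get("E12", 0.0), E22]])

    rg = None
    rg_ci = None
    if A is not None:
        # additive variances on (or numerically at) the zero boundary make
        # the genetic-correlation ratio meaningless
        if A11 > 1e-6 and A22 > 1e-6:
            rg = float(A12 / np.sqrt(A11 * A22))
        else:
            note = (note + "; " if note else "") + (
                "rg undefined: within-trait additive variance estimate at or "
                f"below zero (A11={A11:.4g}, A22={A22:.4g})"
            )

    if compute_ci and rg is not None and converged:
        target = ll - _CHI2_95 / 2.0
        red_names = tuple(n for n in names if n != "A12")

        def profile_rg(r: float) -> float:
            def nll_red(y):
                q = dict(zip(red_names, y))
                a11, a22 = q.get("A11", 0.0), q.get("A22", 0.0)
                if a11 <= 0 or a22 <= 0:
                    return -_PENALTY
                q["A12"] = r * np.sqrt(a11 * a22)
                return -_biv_ll(q, tables, n_nodes)

            y0 = np.array([p[n] for n in red_names])
            res = minimize(
                nll_red, y0, method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 3000},
            )
            return float(-res.fun)

        def rg_endpoint(side: int) -> float:
            edge = side * (1.0 - 1e-6)
            if profile_rg(edge) >= target:
                return side * 1.0
            lo, hi = rg, edge
            for _ in range(25):
                mid = 0.5 * (lo + hi)
                if profile_rg(mid) >= target:
                    lo = mid
                else:
                    hi = mid
                if abs(hi - lo) < 2e-3:
                    break
            return 0.5 * (lo + hi)

        rg_ci = (rg_endpoint(-1), rg_endpoint(+1))

    return BivariateACEFit(
        model=model,
        A=A, C=C, E=E,
        rg=rg, rg_ci=rg_ci,
        a2=(A11, A22), c2=(C11, C22), e2=(E11, E22),
        thresholds=(float(p["tau_i"]), float(p["tau_o"])),
        loglik=ll, k=k, aic=float(-2.0 * ll + 2.0 * k),
        converged=converged, note=note,
    )


def aic_select(fits: list):
    """Best fit by AIC; ties go to fewer parameters, then ACE > AE > CE > E."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(
        fits, key=lambda f: (f.aic, f.k, _MODEL_ORDER.get(f.model, 99))
    )


def univariate_fits_frame(fits: dict[tuple[str, str, str], UnivariateACEFit]) -> pd.DataFrame:
    """Tidy frame of univariate fits keyed by (criterion, measure, model)."""
    rows = []
    for (crit, measure, model), f in fits.items():
        row = {
            "criterion": crit, "measure": measure, "model": model,
            "a2": f.a2, "c2": f.c2, "e2": f.e2,
            "threshold": f.threshold,
            "loglik": f.loglik, "k": f.k, "aic": f.aic,
            "converged": f.converged,
        }
        for comp in ("a2", "c2", "e2"):
            lo, hi = f.ci.get(comp, (np.nan, np.nan))
            row[f"{comp}_ci_low"], row[f"{comp}_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def bivariate_fits_frame(fits: dict[tuple[str, str], BivariateACEFit]) -> pd.DataFrame:
    rows = []
    for (crit, model), f in fits.items():
        lo, hi = f.rg_ci if f.rg_ci is not None else (np.nan, np.nan)
        rows.append(
            {
                "criterion": crit, "model": model,
                "a2_in": f.a2[0], "a2_out": f.a2[1],
                "c2_in": f.c2[0], "c2_out": f.c2[1],
                "e2_in": f.e2[0], "e2_out": f.e2[1],
                "rg": np.nan if f.rg is None else f.rg,
                "rg_ci_low": lo, "rg_ci_high": hi,
                "loglik": f.loglik, "k": f.k, "aic": f.aic,
                "converged": f.converged, "note": f.note,
            }
        )
    return pd.DataFrame(rows)
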