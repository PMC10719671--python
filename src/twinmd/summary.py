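"""Across-criterion summaries: mean correlations, paired tests, reports.

Headline quantities average the nine per-criterion results: mean twin
correlations by zygosity and measure pair (computed on the Fisher-z scale
and back-transformed, with t-based 95% CIs from the between-criterion
spread), mean standardized variance components, the mean genetic
correlation, and a paired t test comparing two sets of nine correlations on
the Fisher-z scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .definitions import CRITERIA, N_CRITERIA

__all__ = [
    "SummaryRow",
    "PairedTestResult",
    "fisher_z",
    "inverse_fisher_z",
    "mean_correlation",
    "mean_components",
    "paired_fisher_test",
    "assemble_reports",
]


@dataclass
class SummaryRow:
    quantity: str
    mean: float
    ci_low: float
    ci_high: float
    n_criteria: int


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    df: int
    mean_z_difference: float


def fisher_z(r):
    """Variance-stabilizing transform z = arctanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must satisfy |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def mean_correlation(rs, quantity: str = "mean correlation") -> SummaryRow:
    """Mean of correlations on the Fisher-z scale with a t-based 95% CI.

    The CI uses the between-value spread on the z scale with n-1 degrees of
    freedom, endpoints back-transformed to the correlation scale.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.ndim != 1 or len(rs) < 2:
        raise ValueError("need at least 2 correlations for a CI")
    if np.any(~np.isfinite(rs)):
        raise ValueError("correlations must be finite")
    z = fisher_z(rs)
    n = len(z)
    m = z.mean()
    se = z.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return SummaryRow(
        quantity=quantity,
        mean=inverse_fisher_z(m),
        ci_low=inverse_fisher_z(m - tcrit * se),
        ci_high=inverse_fisher_z(m + tcrit * se),
        n_criteria=n,
    )


def mean_components(values, quantity: str) -> SummaryRow:
    """Arithmetic mean of per-criterion component estimates, t-based CI."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 values for a CI")
    n = len(v)
    m = v.mean()
    se = v.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return SummaryRow(quantity, float(m), float(m - tcrit * se), float(m + tcrit * se), n)


def paired_fisher_test(rs_a, rs_b) -> PairedTestResult:
    """Two-sided paired t test on Fisher-z-transformed correlation sets."""
    a = np.asarray(rs_a, dtype=float)
    b = np.asarray(rs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("correlation vectors must be 1-D with equal length")
    d = fisher_z(a) - fisher_z(b)
    n = len(d)
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedTestResult(0.0, 1.0, n - 1, 0.0)
        return PairedTestResult(float(np.sign(md)) * np.inf, 0.0, n - 1, md)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), n - 1, md)


def _prevalence_table(profiles: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for crit in CRITERIA:
        rec = {"criterion": crit}
        for measure in ("in", "out"):
            s = profiles[f"{measure}_{crit}"].dropna()
            rec[f"n_{measure}"] = int((s == 1).sum())
            rec[f"prevalence_{measure}"] = float((s == 1).mean()) if len(s) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def assemble_reports(
    profiles: pd.DataFrame,
    correlations: pd.DataFrame,
    univariate_fits: pd.DataFrame,
    bivariate_fits: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Build descriptive and key-estimate summary tables.

    Returns ``{"descriptives": ..., "key_estimates": ...}``: per-criterion
    IN/OUT counts and prevalences, and across-criterion means (with 95%
    CIs) of the twin correlations by measure pair and zygosity, of the
    standardized ACE components by measure, and of the genetic correlation.
    Raises ValueError listing gaps when a criterion is missing upstream.
    """
    missing = []
    for crit in CRITERIA:
        if f"in_{crit}" not in profiles.columns:
            missing.append(f"profiles: {crit}")
    for (mp, zyg), grp in correlations.groupby(["measure_pair", "zygosity"]):
        got = set(grp["criterion"])
        missing += [f"correlations {mp}/{zyg}: {c}" for c in CRITERIA if c not in got]
    if univariate_fits.empty:
        raise ValueError("empty univariate fits input")
    for measure, grp in univariate_fits.groupby("measure"):
        got = set(grp["criterion"])
        missing += [f"fits {measure}: {c}" for c in CRITERIA if c not in got]
    if missing:
        raise ValueError("missing criterion rows: " + "; ".join(sorted(missing)))

    descriptives = _prevalence_table(profiles)

    rows = []
    for mp in ("in-in", "out-out", "in-out"):
        for zyg in ("MZ", "DZ"):
            grp = correlations[
                (correlations["measure_pair"] == mp) & (correlations["zygosity"] == zyg)
            ]
            if grp.empty:
                continue
            rs = (
                grp.set_index("criterion").loc[list(CRITERIA), "rho"].to_numpy()
            )
            rows.append(mean_correlation(rs, f"mean r {zyg} {mp}"))
    for measure in ("in", "out"):
        grp = univariate_fits[univariate_fits["measure"] == measure]
        grp = grp.set_index("criterion").loc[list(CRITERIA)]
        for comp in ("a2", "c2", "e2"):
            rows.append(
                mean_components(grp[comp].to_numpy(), f"mean {comp} {measure.upper()}")
            )
    if bivariate_fits is not None and not bivariate_fits.empty:
        rg = bivariate_fits.set_index("criterion").reindex(list(CRITERIA))["rg"]
        if rg.notna().all():
            rows.append(mean_correlation(rg.to_numpy(), "mean rg IN-OUT"))

    key = pd.DataFrame(
        [
            {
                "quantity": r.quantity,
                "mean": r.mean,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_criteria": r.n_criteria,
            }
            for r in rows
        ]
    )
    return {"descriptives": descriptives, "key_estimates": key}
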