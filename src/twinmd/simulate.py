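"""Synthetic twin-data generators.

Two levels of simulation are provided, mirroring the two halves of the
analysis pipeline:

* :func:`simulate_liability_sample` draws ACE-structured multivariate-normal
  liabilities per twin pair and dichotomizes them at prevalence-implied
  thresholds, yielding binary IN/OUT criterion profiles directly.  This is
  the generator used to test the statistical stages (tetrachoric
  correlations, univariate/bivariate ACE fits) under known truth.
* :func:`simulate_interview_sample` emulates the interview itself: a latent
  episode liability decides whether a twin had a depressive episode in the
  last year; symptoms inside the episode form a temporal syndrome, stray
  symptoms occur on their own or in sub-threshold clusters, and a fraction
  of endorsed symptoms is attributed to illness/medication.  This exercises
  the symptom-classification stage end to end.

:func:`expected_cell_probabilities` gives the exact (infinite-data) cell
probabilities implied by a parameter set — the oracle against which both the
simulators and the model-fitting stages are checked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._normal import norm_ppf, same_trait_cell_probs, joint_cell_probs
from .classify import InterviewRecord
from .definitions import CRITERIA, ITEMS, N_CRITERIA, N_ITEMS, ZYGOSITY_GROUPS

__all__ = [
    "CriterionParams",
    "GenerativeConfig",
    "EpisodeModelConfig",
    "pair_covariance",
    "expected_cell_probabilities",
    "simulate_liability_sample",
    "simulate_criterion_pairs",
    "simulate_dichotomized_pairs",
    "simulate_interview_sample",
]


def _as_array(x, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class CriterionParams:
    """ACE parameters for one criterion's IN and OUT liabilities.

    Variance proportions are on the standardized liability scale
    (a2 + c2 + e2 = 1 per measure); ``rg``/``rc``/``re`` correlate the
    additive-genetic, shared-environment, and unique-environment components
    of the IN and OUT liabilities.
    """

    a2_in: float
    c2_in: float
    prevalence_in: float
    a2_out: float
    c2_out: float
    prevalence_out: float
    rg: float = 0.0
    rc: float = 0.0
    re: float = 0.0

    @property
    def e2_in(self) -> float:
        return 1.0 - self.a2_in - self.c2_in

    @property
    def e2_out(self) -> float:
        return 1.0 - self.a2_out - self.c2_out


def _check_criterion(p: CriterionParams, name: str) -> None:
    for label, a2, c2 in (("IN", p.a2_in, p.c2_in), ("OUT", p.a2_out, p.c2_out)):
        if a2 < 0 or c2 < 0 or a2 + c2 > 1:
            raise ValueError(
                f"criterion {name!r} ({label}): variance proportions must be "
                f"non-negative and sum to at most 1"
            )
    for label, prev in (("IN", p.prevalence_in), ("OUT", p.prevalence_out)):
        if not 0.0 < prev < 1.0:
            raise ValueError(f"criterion {name!r}: prevalence_{label.lower()} must be in (0, 1)")
    for label, r in (("rg", p.rg), ("rc", p.rc), ("re", p.re)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"criterion {name!r}: {label} must be in [-1, 1]")
    for zyg in ("MZ", "DZ"):
        sigma = pair_covariance(p, zyg)
        if np.linalg.eigvalsh(sigma).min() < -1e-9:
            raise ValueError(
                f"criterion {name!r}: implied liability covariance for {zyg} "
                f"pairs is not positive semi-definite"
            )


def pair_covariance(params: CriterionParams, zygosity: str) -> np.ndarray:
    """4x4 liability covariance over (IN1, OUT1, IN2, OUT2) for one pair.

    A is shared with coefficient 1 (MZ) or 0.5 (DZ/OS) across twins, C fully
    shared, E independent across twins; within a twin, the IN and OUT
    components correlate via rg/rc/re.
    """
    k = {"MZ": 1.0, "DZ": 0.5}[zygosity]
    p = params
    a_i, a_o = np.sqrt(p.a2_in), np.sqrt(p.a2_out)
    c_i, c_o = np.sqrt(p.c2_in), np.sqrt(p.c2_out)
    e_i, e_o = np.sqrt(max(p.e2_in, 0.0)), np.sqrt(max(p.e2_out, 0.0))
    within_ct = a_i * a_o * p.rg + c_i * c_o * p.rc + e_i * e_o * p.re
    cross_same_in = k * p.a2_in + p.c2_in
    cross_same_out = k * p.a2_out + p.c2_out
    cross_ct = k * a_i * a_o * p.rg + c_i * c_o * p.rc
    W = np.array([[1.0, within_ct], [within_ct, 1.0]])
    B = np.array([[cross_same_in, cross_ct], [cross_ct, cross_same_out]])
    return np.block([[W, B], [B, W]])


# Documented default prevalences: IN criteria are rare (1-6%), OUT criteria
# considerably more common (5-25%), matching the qualitative descriptive
# pattern of last-year depressive criteria in a community twin sample.
_DEFAULT_PREV_IN = (0.055, 0.045, 0.030, 0.040, 0.040, 0.035, 0.035, 0.030, 0.020)
_DEFAULT_PREV_OUT = (0.220, 0.090, 0.200, 0.170, 0.080, 0.210, 0.120, 0.070, 0.030)


@dataclass
class GenerativeConfig:
    """Configuration for the direct liability-level twin simulator.

    Sample-size defaults follow the study design: 1,461 complete same-sex MZ
    pairs, 1,079 complete same-sex DZ pairs, 1,411 complete opposite-sex
    pairs, with 285/338/476 incomplete twins respectively.  Variance
    proportions default to the fitted means (a2 = 0.31 IN, 0.15 OUT, with
    small shared-environment components) and a weak genetic correlation
    between the IN and OUT liabilities.
    """

    n_mz_pairs: int = 1461
    n_dzss_pairs: int = 1079
    n_os_pairs: int = 1411
    n_incomplete: dict = field(
        default_factory=lambda: {"MZ-ss": 285, "DZ-ss": 338, "OS": 476}
    )
    a2_in: object = 0.31
    c2_in: object = 0.04
    prevalence_in: object = _DEFAULT_PREV_IN
    a2_out: object = 0.15
    c2_out: object = 0.05
    prevalence_out: object = _DEFAULT_PREV_OUT
    rg: object = 0.07
    rc: object = 0.0
    re: object = 0.0
    seed: int = 0

    def criterion_params(self) -> list[CriterionParams]:
        n = N_CRITERIA
        cols = {
            name: _as_array(getattr(self, name), n, name)
            for name in (
                "a2_in", "c2_in", "prevalence_in",
                "a2_out", "c2_out", "prevalence_out",
                "rg", "rc", "re",
            )
        }
        out = []
        for i, crit in enumerate(CRITERIA):
            p = CriterionParams(**{k: float(v[i]) for k, v in cols.items()})
            _check_criterion(p, crit)
            out.append(p)
        return out

    def __post_init__(self):
        for n in (self.n_mz_pairs, self.n_dzss_pairs, self.n_os_pairs):
            if n < 0:
                raise ValueError("pair counts must be non-negative")
        self.criterion_params()  # validate eagerly

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2)


def expected_cell_probabilities(
    params: CriterionParams, zygosity: str, measure_pair: str
) -> np.ndarray:
    """Exact cell probabilities implied by an ACE parameter set.

    ``measure_pair`` is one of ``in-in``, ``out-out`` (4 cells,
    order p11, p10, p01, p00), ``in-out`` (4 cells: twin1's IN crossed with
    twin2's OUT), or ``joint`` (16 cells, shape (2,2,2,2) indexed
    [in1, out1, in2, out2]).
    """
    sigma = pair_covariance(params, zygosity)
    tau_in = float(norm_ppf(1.0 - params.prevalence_in))
    tau_out = float(norm_ppf(1.0 - params.prevalence_out))
    if measure_pair == "in-in":
        return same_trait_cell_probs(sigma[0, 2], tau_in, tau_in)
    if measure_pair == "out-out":
        return same_trait_cell_probs(sigma[1, 3], tau_out, tau_out)
    if measure_pair == "in-out":
        return same_trait_cell_probs(sigma[0, 3], tau_in, tau_out)
    if measure_pair == "joint":
        return joint_cell_probs(sigma[:2, :2], sigma[:2, 2:], np.array([tau_in, tau_out]))
    raise ValueError(f"unknown measure_pair {measure_pair!r}")


def _draw_mvn(cov: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-9:
        raise ValueError("covariance is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal((n, cov.shape[0]))
    return z * np.sqrt(evals) @ evecs.T


def simulate_dichotomized_pairs(
    sigma: np.ndarray,
    prevalences: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw pair liabilities from an explicit 4x4 covariance and dichotomize.

    Columns of the returned (n_pairs, 4) 0/1 array follow the covariance
    order (IN1, OUT1, IN2, OUT2); ``prevalences`` gives the marginal
    positive probability per trait (IN, OUT), applied to both twins.
    """
    taus = norm_ppf(1.0 - np.asarray(prevalences, dtype=float))
    taus = np.concatenate([taus, taus])
    liab = _draw_mvn(np.asarray(sigma, dtype=float), n_pairs, rng)
    return (liab > taus).astype(np.int64)


def simulate_criterion_pairs(
    rho: float, prevalence: float, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Binary outcomes for both twins of ``n_pairs`` pairs on one trait."""
    tau = float(norm_ppf(1.0 - prevalence))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    liab = _draw_mvn(cov, n_pairs, rng)
    x = (liab > tau).astype(np.int64)
    return x[:, 0], x[:, 1]


def _profile_columns() -> list[str]:
    return [f"in_{c}" for c in CRITERIA] + [f"out_{c}" for c in CRITERIA]


def simulate_liability_sample(config: GenerativeConfig) -> pd.DataFrame:
    """Simulate binary IN/OUT criterion profiles for the full twin sample.

    Returns a long-format frame, one row per twin, with columns ``pair_id``,
    ``twin_order``, ``zygosity_group`` and ``in_*``/``out_*`` status columns
    (nullable Int64; no unknowns are produced at this stage).  Incomplete
    twins are created by deleting one member of extra complete pairs at
    random; they retain their pair id with a single row.
    """
    rng = np.random.default_rng(config.seed)
    params = config.criterion_params()
    group_sizes = {
        "MZ-ss": config.n_mz_pairs,
        "DZ-ss": config.n_dzss_pairs,
        "OS": config.n_os_pairs,
    }
    frames = []
    for group in ZYGOSITY_GROUPS:
        n_complete = group_sizes[group]
        n_inc = int(config.n_incomplete.get(group, 0))
        n_total = n_complete + n_inc
        if n_total == 0:
            continue
        zyg = "MZ" if group == "MZ-ss" else "DZ"
        status = np.empty((n_total, 2, 2 * N_CRITERIA), dtype=np.int64)
        for ci, p in enumerate(params):
            sigma = pair_covariance(p, zyg)
            x = simulate_dichotomized_pairs(
                sigma, [p.prevalence_in, p.prevalence_out], n_total, rng
            )
            status[:, 0, ci] = x[:, 0]              # twin1 IN
            status[:, 1, ci] = x[:, 2]              # twin2 IN
            status[:, 0, N_CRITERIA + ci] = x[:, 1]  # twin1 OUT
            status[:, 1, N_CRITERIA + ci] = x[:, 3]  # twin2 OUT
        pair_ids = np.array([f"{group}-{i:05d}" for i in range(n_total)])
        rows = {
            "pair_id": np.repeat(pair_ids, 2),
            "twin_order": np.tile([1, 2], n_total),
            "zygosity_group": group,
        }
        flat = status.reshape(2 * n_total, 2 * N_CRITERIA)
        for j, col in enumerate(_profile_columns()):
            rows[col] = flat[:, j]
        df = pd.DataFrame(rows)
        if n_inc > 0:
            # delete one twin at random from the last n_inc pairs
            drop_pairs = pair_ids[n_complete:]
            drop_order = rng.integers(1, 3, size=n_inc)
            which = df["pair_id"].map(dict(zip(drop_pairs, drop_order)))
            drop_mask = which.notna() & (df["twin_order"] == which)
            df = df.loc[~drop_mask].reset_index(drop=True)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col in _profile_columns():
        out[col] = out[col].astype("Int64")
    return out


# ---------------------------------------------------------------------------
# Episode-level interview simulator
# ---------------------------------------------------------------------------

# Within-episode endorsement probabilities per disaggregated item: the
# cardinal symptoms are near-universal within an episode, vegetative and
# cognitive symptoms common, and each disaggregated alternative (e.g. weight
# up vs down) splits its criterion's mass.
_DEFAULT_ENDORSE = (
    0.95,  # depressed mood
    0.72,  # anhedonia
    0.28, 0.16, 0.30, 0.12,  # weight/appetite items
    0.58, 0.16,  # insomnia / hypersomnia
    0.32, 0.28,  # agitation / retardation
    0.70,  # fatigue
    0.62,  # concentration
    0.45,  # worthlessness
    0.22,  # thoughts of death
)

# Per-item annual rates of stray (outside-episode) symptoms; common somatic
# complaints dominate, consistent with depressive criteria being reported
# far more often outside than inside episodes.
_DEFAULT_STRAY = (
    0.150,  # depressed mood
    0.055,  # anhedonia
    0.055, 0.045, 0.050, 0.030,  # weight/appetite items
    0.110, 0.030,  # insomnia / hypersomnia
    0.030, 0.025,  # agitation / retardation
    0.160,  # fatigue
    0.085,  # concentration
    0.045,  # worthlessness
    0.020,  # thoughts of death
)


@dataclass
class EpisodeModelConfig:
    """Configuration for the episode-level interview simulator."""

    episode_a2: float = 0.35
    episode_c2: float = 0.05
    episode_prob: float = 0.075
    endorse_probs: tuple = _DEFAULT_ENDORSE
    stray_probs: tuple = _DEFAULT_STRAY
    somatic_rate: float = 0.04
    second_syndrome_prob: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.episode_a2 and 0 <= self.episode_c2
                and self.episode_a2 + self.episode_c2 <= 1):
            raise ValueError("episode ACE proportions must be non-negative and sum to <= 1")
        for name in ("episode_prob", "somatic_rate", "second_syndrome_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("endorse_probs", "stray_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_ITEMS,) or np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must be {N_ITEMS} probabilities in [0, 1]")

    @property
    def episode_e2(self) -> float:
        return 1.0 - self.episode_a2 - self.episode_c2

    def to_json(self) -> str:
        d = asdict(self)
        d["endorse_probs"] = list(d["endorse_probs"])
        d["stray_probs"] = list(d["stray_probs"])
        return json.dumps(d, indent=2)


def simulate_interview_sample(
    config: EpisodeModelConfig,
    n_mz_pairs: int = 1461,
    n_dzss_pairs: int = 1079,
    n_os_pairs: int = 1411,
    n_incomplete: dict | None = None,
    seed: int | None = None,
) -> list[InterviewRecord]:
    """Simulate raw interview records for a twin sample.

    Each twin's episode status is decided by an ACE-structured liability; an
    episode produces one temporal syndrome of within-episode symptoms, stray
    symptoms occur independently and either stay ungrouped or (with
    ``second_syndrome_prob``) cluster into a further syndrome, and endorsed
    symptoms are flagged as illness/medication-related with
    ``somatic_rate``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if n_incomplete is None:
        n_incomplete = {"MZ-ss": 285, "DZ-ss": 338, "OS": 476}
    group_sizes = {"MZ-ss": n_mz_pairs, "DZ-ss": n_dzss_pairs, "OS": n_os_pairs}
    tau = float(norm_ppf(1.0 - config.episode_prob)) if config.episode_prob < 1 else -np.inf
    endorse = np.asarray(config.endorse_probs, dtype=float)
    stray = np.asarray(config.stray_probs, dtype=float)

    records: list[InterviewRecord] = []
    for group in ZYGOSITY_GROUPS:
        n_complete = group_sizes.get(group, 0)
        n_inc = int(n_incomplete.get(group, 0))
        n_total = n_complete + n_inc
        if n_total == 0:
            continue
        k = 1.0 if group == "MZ-ss" else 0.5
        a2, c2, e2 = config.episode_a2, config.episode_c2, config.episode_e2
        r = k * a2 + c2
        cov = np.array([[1.0, r], [r, 1.0]])
        liab = _draw_mvn(cov, n_total, rng)
        episodes = liab > tau if config.episode_prob > 0 else np.zeros_like(liab, bool)
        if config.episode_prob >= 1.0:
            episodes = np.ones_like(liab, dtype=bool)

        if group == "OS":
            sexes = [("F", "M")] * n_total
        else:
            pair_sex = rng.choice(["F", "M"], size=n_total)
            sexes = [(s, s) for s in pair_sex]

        drop_order = rng.integers(1, 3, size=n_inc) if n_inc else np.array([], dtype=int)
        for i in range(n_total):
            pair_id = f"{group}-{i:05d}"
            for t in (0, 1):
                items = np.zeros(N_ITEMS, dtype=np.int64)
                syndromes: list[set[int]] = []
                if episodes[i, t]:
                    ep_items = rng.random(N_ITEMS) < endorse
                    items[ep_items] = 1
                    if ep_items.any():
                        syndromes.append(set(np.flatnonzero(ep_items)))
                stray_items = (rng.random(N_ITEMS) < stray) & (items == 0)
                items[stray_items] = 1
                stray_idx = np.flatnonzero(stray_items)
                if (
                    len(stray_idx) >= 2
                    and len(syndromes) < 2
                    and rng.random() < config.second_syndrome_prob
                ):
                    syndromes.append(set(stray_idx))
                somatic = np.where(
                    (items == 1) & (rng.random(N_ITEMS) < config.somatic_rate), 1, 0
                ).astype(np.int64)
                records.append(
                    InterviewRecord(
                        pair_id=pair_id,
                        twin_order=t + 1,
                        zygosity_group=group,
                        sex=sexes[i][t],
                        items=items,
                        somatic_flags=somatic,
                        syndromes=syndromes,
                    )
                )
        if n_inc:
            keep = []
            for rec in records:
                g, idx = rec.pair_id.rsplit("-", 1)
                if g == group and int(idx) >= n_complete:
                    if rec.twin_order == int(drop_order[int(idx) - n_complete]):
                        continue
                keep.append(rec)
            records = keep
    return records
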