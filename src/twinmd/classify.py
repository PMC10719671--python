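"""Symptom processing: somatic filtering, aggregation, IN/OUT classification.

The interview yields, per twin, 14 binary disaggregated symptom items, a
parallel set of illness/medication attribution flags, and up to two
temporal syndromes (sets of item indices that co-occurred).  Processing
proceeds in order:

1. :func:`filter_somatic_causes` — drop positively endorsed symptoms that
   were attributed to illness or medication use.
2. :func:`aggregate_criteria` — collapse the weight/appetite, sleep, and
   psychomotor items (logical OR) into single criteria, giving the nine
   official DSM criteria.
3. :func:`diagnose_md_syndrome` — a syndrome algorithmically meets MD
   criteria when it contains at least five of the nine criteria including a
   cardinal one (depressed mood or loss of interest).
4. :func:`classify_in_out` — criteria inside a diagnosing syndrome are IN;
   endorsed criteria not covered by a diagnosing syndrome (ungrouped or in a
   sub-threshold syndrome) are OUT.  The same criterion can be both, e.g.
   sleep problems inside a diagnosing episode and again in a separate
   sub-threshold cluster.
5. :func:`censor_four_symptom_clusters` — sensitivity re-analysis that marks
   as unknown the OUT status of criteria whose sub-threshold cluster held
   exactly four criteria (one short of a diagnosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .definitions import (
    CARDINAL_CRITERIA,
    CRITERIA,
    CRITERION_ITEMS,
    MD_CRITERION_COUNT,
    N_CRITERIA,
    N_ITEMS,
)

__all__ = [
    "InterviewRecord",
    "CriterionProfile",
    "filter_somatic_causes",
    "aggregate_criteria",
    "diagnose_md_syndrome",
    "classify_in_out",
    "classify_sample",
    "censor_four_symptom_clusters",
    "profiles_to_frame",
]


@dataclass
class InterviewRecord:
    """One twin's raw interview data."""

    pair_id: str
    twin_order: int
    zygosity_group: str
    sex: str
    items: np.ndarray  # 14 binary
    somatic_flags: np.ndarray  # 14 binary
    syndromes: list = field(default_factory=list)  # up to two sets of item indices

    def __post_init__(self):
        self.items = np.asarray(self.items, dtype=np.int64)
        self.somatic_flags = np.asarray(self.somatic_flags, dtype=np.int64)
        if self.items.shape != (N_ITEMS,) or self.somatic_flags.shape != (N_ITEMS,):
            raise ValueError(f"items and somatic_flags must have length {N_ITEMS}")
        if not np.all(np.isin(self.items, (0, 1))):
            raise ValueError("items must be binary")
        if not np.all(np.isin(self.somatic_flags, (0, 1))):
            raise ValueError("somatic_flags must be binary")
        if len(self.syndromes) > 2:
            raise ValueError("at most two syndromes per twin")
        self.syndromes = [set(int(i) for i in s) for s in self.syndromes]
        endorsed = set(np.flatnonzero(self.items))
        for s in self.syndromes:
            if not s <= endorsed:
                raise ValueError("syndrome contains unendorsed item indices")


# status codes in CriterionProfile arrays
UNKNOWN = -1


@dataclass
class CriterionProfile:
    """Per-twin IN/OUT status of the nine DSM criteria (0/1, -1 = unknown)."""

    pair_id: str
    twin_order: int
    zygosity_group: str
    in_status: np.ndarray
    out_status: np.ndarray

    def __post_init__(self):
        self.in_status = np.asarray(self.in_status, dtype=np.int64)
        self.out_status = np.asarray(self.out_status, dtype=np.int64)
        for arr in (self.in_status, self.out_status):
            if arr.shape != (N_CRITERIA,):
                raise ValueError(f"status vectors must have length {N_CRITERIA}")
            if not np.all(np.isin(arr, (0, 1, UNKNOWN))):
                raise ValueError("status values must be 0, 1 or unknown (-1)")


def filter_somatic_causes(record: InterviewRecord) -> InterviewRecord:
    """Zero out symptoms attributed to illness/medication and drop them
    from syndrome sets.  Returns a new record; the input is not mutated."""
    flagged = record.somatic_flags == 1
    items = np.where(flagged, 0, record.items)
    keep = set(np.flatnonzero(items))
    syndromes = [s & keep for s in record.syndromes]
    syndromes = [s for s in syndromes if s]
    return replace(record, items=items, syndromes=syndromes)


def aggregate_criteria(items) -> np.ndarray:
    """Collapse 14 binary items to the 9 DSM criteria by logical OR."""
    items = np.asarray(items)
    if items.shape != (N_ITEMS,) or not np.all(np.isin(items, (0, 1))):
        raise ValueError(f"items must be {N_ITEMS} binary values")
    return np.array(
        [int(items[list(idx)].any()) for idx in CRITERION_ITEMS.values()],
        dtype=np.int64,
    )


def _syndrome_criteria(syndrome: set) -> set:
    """Map a syndrome's item indices to the criterion indices it contains."""
    out = set()
    for ci, idxs in enumerate(CRITERION_ITEMS.values()):
        if any(i in syndrome for i in idxs):
            out.add(ci)
    return out


def diagnose_md_syndrome(criteria_in_syndrome: set) -> bool:
    """DSM-IV A-criterion count rule: >= 5 of 9 criteria, at least one of
    depressed mood / loss of interest."""
    crit = set(int(c) for c in criteria_in_syndrome)
    if not crit <= set(range(N_CRITERIA)):
        raise ValueError("criterion indices must be in 0..8")
    return len(crit) >= MD_CRITERION_COUNT and bool(crit & set(CARDINAL_CRITERIA))


def classify_in_out(record: InterviewRecord) -> CriterionProfile:
    """Assign each endorsed criterion to IN and/or OUT.

    The record must already be somatic-filtered.  Criteria in any syndrome
    meeting the MD count rule are IN; endorsed criteria not covered by a
    diagnosing syndrome — whether ungrouped or in a sub-threshold syndrome —
    are OUT.  A criterion present both in a diagnosing syndrome and in a
    separate sub-threshold one is 1 in both.
    """
    in_status = np.zeros(N_CRITERIA, dtype=np.int64)
    out_status = np.zeros(N_CRITERIA, dtype=np.int64)

    endorsed = aggregate_criteria(record.items)
    syndrome_crit = [_syndrome_criteria(s) for s in record.syndromes]
    diagnosing = [c for c in syndrome_crit if diagnose_md_syndrome(c)]
    subthreshold = [c for c in syndrome_crit if not diagnose_md_syndrome(c)]

    for crit in diagnosing:
        for ci in crit:
            in_status[ci] = 1

    # items covered by any syndrome at all
    grouped_items = set().union(*record.syndromes) if record.syndromes else set()
    for ci in range(N_CRITERIA):
        if not endorsed[ci]:
            continue
        # endorsed via a sub-threshold syndrome
        if any(ci in c for c in subthreshold):
            out_status[ci] = 1
            continue
        # an endorsed item occurring outside any syndrome grouping was, by
        # definition, not part of a diagnosing clustering
        item_idxs = set(CRITERION_ITEMS[CRITERIA[ci]])
        endorsed_items = {i for i in item_idxs if record.items[i]}
        if endorsed_items - grouped_items:
            out_status[ci] = 1

    return CriterionProfile(
        pair_id=record.pair_id,
        twin_order=record.twin_order,
        zygosity_group=record.zygosity_group,
        in_status=in_status,
        out_status=out_status,
    )


def classify_sample(records: list[InterviewRecord]) -> list[CriterionProfile]:
    """Somatic-filter and classify every record of a sample."""
    return [classify_in_out(filter_somatic_causes(r)) for r in records]


def censor_four_symptom_clusters(
    profiles: list[CriterionProfile], records: list[InterviewRecord]
) -> list[CriterionProfile]:
    """Sensitivity analysis: censor OUT statuses from 4-criterion clusters.

    A sub-threshold syndrome containing exactly four aggregated criteria is
    one criterion short of a diagnosable episode; under the sensitivity
    rule, the OUT status of each of its criteria becomes unknown.  IN
    statuses are untouched.  ``records`` must be parallel to ``profiles``
    (same twins, same order); records are somatic-filtered internally.
    """
    if len(profiles) != len(records):
        raise ValueError("profiles and records must be parallel")
    out = []
    for prof, rec in zip(profiles, records):
        if (prof.pair_id, prof.twin_order) != (rec.pair_id, rec.twin_order):
            raise ValueError("profiles and records are not aligned")
        rec = filter_somatic_causes(rec)
        new_out = prof.out_status.copy()
        for s in rec.syndromes:
            crit = _syndrome_criteria(s)
            if not diagnose_md_syndrome(crit) and len(crit) == 4:
                for ci in crit:
                    new_out[ci] = UNKNOWN
        out.append(replace(prof, out_status=new_out))
    return out


def profiles_to_frame(profiles: list[CriterionProfile]) -> pd.DataFrame:
    """Long-format frame, one row per twin; unknown becomes pandas NA."""
    rows = {
        "pair_id": [p.pair_id for p in profiles],
        "twin_order": [p.twin_order for p in profiles],
        "zygosity_group": [p.zygosity_group for p in profiles],
    }
    in_mat = np.array([p.in_status for p in profiles]).reshape(len(profiles), N_CRITERIA)
    out_mat = np.array([p.out_status for p in profiles]).reshape(len(profiles), N_CRITERIA)
    for j, c in enumerate(CRITERIA):
        rows[f"in_{c}"] = in_mat[:, j]
    for j, c in enumerate(CRITERIA):
        rows[f"out_{c}"] = out_mat[:, j]
    df = pd.DataFrame(rows)
    for c in CRITERIA:
        for col in (f"in_{c}", f"out_{c}"):
            s = df[col].astype("Int64")
            df[col] = s.mask(s == UNKNOWN)
    return df
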