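"""Symptom processing: somatic filter, aggregation, diagnosis, IN/OUT, censoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinmd.classify import (
    UNKNOWN,
    InterviewRecord,
    aggregate_criteria,
    censor_four_symptom_clusters,
    classify_in_out,
    classify_sample,
    diagnose_md_syndrome,
    filter_somatic_causes,
    profiles_to_frame,
)
from twinmd.definitions import CRITERIA, N_CRITERIA, N_ITEMS
from twinmd.simulate import EpisodeModelConfig, simulate_interview_sample

# item indices (interview order, 0-based)
MOOD, ANHED = 0, 1
WT_DEC, WT_INC, APP_DEC, APP_INC = 2, 3, 4, 5
INSOMNIA, HYPERSOMNIA = 6, 7
AGIT, RETARD = 8, 9
FATIGUE, CONC, WORTH, DEATH = 10, 11, 12, 13

# criterion indices
C_MOOD, C_INT, C_WP, C_SP, C_PP, C_FAT, C_CONC, C_WORTH, C_DEATH = range(9)


def record(items_on=(), somatic_on=(), syndromes=(), **kw):
    items = np.zeros(N_ITEMS, dtype=int)
    items[list(items_on)] = 1
    somatic = np.zeros(N_ITEMS, dtype=int)
    somatic[list(somatic_on)] = 1
    defaults = dict(pair_id="p1", twin_order=1, zygosity_group="MZ-ss", sex="F")
    defaults.update(kw)
    return InterviewRecord(items=items, somatic_flags=somatic,
                           syndromes=[set(s) for s in syndromes], **defaults)


class TestSomaticFilter:
    def test_flagged_symptom_zeroed_and_dropped_from_syndrome(self):
        r = record(items_on=[MOOD, INSOMNIA], somatic_on=[INSOMNIA],
                   syndromes=[{MOOD, INSOMNIA}])
        f = filter_somatic_causes(r)
        assert f.items[INSOMNIA] == 0 and f.items[MOOD] == 1
        assert f.syndromes == [{MOOD}]

    def test_no_flags_identity(self):
        r = record(items_on=[MOOD, FATIGUE], syndromes=[{MOOD, FATIGUE}])
        f = filter_somatic_causes(r)
        np.testing.assert_array_equal(f.items, r.items)
        assert f.syndromes == r.syndromes

    def test_all_flagged_empties_record(self):
        on = list(range(N_ITEMS))
        r = record(items_on=on, somatic_on=on, syndromes=[set(on[:5])])
        f = filter_somatic_causes(r)
        assert f.items.sum() == 0
        assert f.syndromes == []

    def test_input_not_mutated(self):
        r = record(items_on=[MOOD], somatic_on=[MOOD])
        filter_somatic_causes(r)
        assert r.items[MOOD] == 1


class TestAggregation:
    def test_sleep_or_rule(self):
        items = np.zeros(N_ITEMS, int)
        items[INSOMNIA] = 1
        assert aggregate_criteria(items)[C_SP] == 1

    def test_all_zero(self):
        np.testing.assert_array_equal(aggregate_criteria(np.zeros(N_ITEMS, int)),
                                      np.zeros(N_CRITERIA, int))

    def test_weight_items_collapse_to_single_criterion(self):
        items = np.zeros(N_ITEMS, int)
        items[[WT_DEC, APP_INC]] = 1
        crit = aggregate_criteria(items)
        assert crit[C_WP] == 1 and crit.sum() == 1

    def test_non_binary_rejected(self):
        bad = np.zeros(N_ITEMS, int)
        bad[0] = 2
        with pytest.raises(ValueError):
            aggregate_criteria(bad)

    @given(st.lists(st.integers(0, 1), min_size=N_ITEMS, max_size=N_ITEMS))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_counts(self, bits):
        items = np.array(bits)
        crit = aggregate_criteria(items)
        # every endorsed item makes its criterion positive; no phantom criteria
        assert crit.sum() <= items.sum()
        assert (crit == 1).sum() >= (items[[MOOD, ANHED, FATIGUE, CONC, WORTH, DEATH]]).sum()


class TestDiagnosis:
    @pytest.mark.parametrize(
        "crit,expected",
        [
            ({C_MOOD, C_SP, C_FAT, C_CONC, C_WORTH}, True),   # 5 incl cardinal
            ({C_WP, C_SP, C_PP, C_FAT, C_CONC}, False),       # no cardinal
            ({C_MOOD, C_SP, C_FAT, C_CONC}, False),           # only 4
            (set(), False),
            (set(range(9)), True),
        ],
    )
    def test_count_rule(self, crit, expected):
        assert diagnose_md_syndrome(crit) is expected


class TestClassifyInOut:
    def test_shared_criterion_in_both_groups(self):
        # diagnosing syndrome + separate sub-threshold cluster sharing sleep
        r = record(
            items_on=[MOOD, ANHED, INSOMNIA, FATIGUE, CONC, HYPERSOMNIA, WT_DEC],
            syndromes=[{MOOD, ANHED, INSOMNIA, FATIGUE, CONC}, {HYPERSOMNIA, WT_DEC}],
        )
        p = classify_in_out(r)
        assert p.in_status[C_SP] == 1 and p.out_status[C_SP] == 1
        assert p.out_status[C_WP] == 1 and p.in_status[C_WP] == 0
        assert p.in_status[C_MOOD] == 1 and p.out_status[C_MOOD] == 0

    def test_ungrouped_symptom_is_out(self):
        r = record(items_on=[FATIGUE])
        p = classify_in_out(r)
        assert p.out_status[C_FAT] == 1 and p.in_status[C_FAT] == 0

    def test_empty_record_all_zero(self):
        p = classify_in_out(record())
        assert p.in_status.sum() == 0 and p.out_status.sum() == 0

    def test_subthreshold_syndrome_criteria_are_out(self):
        r = record(items_on=[MOOD, INSOMNIA, FATIGUE],
                   syndromes=[{MOOD, INSOMNIA, FATIGUE}])
        p = classify_in_out(r)
        assert p.in_status.sum() == 0
        assert p.out_status[C_MOOD] == 1
        assert p.out_status[C_SP] == 1
        assert p.out_status[C_FAT] == 1

    def test_idempotent_and_deterministic(self):
        r = record(
            items_on=[MOOD, ANHED, INSOMNIA, FATIGUE, CONC, WT_DEC],
            syndromes=[{MOOD, ANHED, INSOMNIA, FATIGUE, CONC}],
        )
        p1, p2 = classify_in_out(r), classify_in_out(r)
        np.testing.assert_array_equal(p1.in_status, p2.in_status)
        np.testing.assert_array_equal(p1.out_status, p2.out_status)

    @given(
        items=st.lists(st.integers(0, 1), min_size=N_ITEMS, max_size=N_ITEMS),
        split=st.integers(0, N_ITEMS),
    )
    @settings(max_examples=60, deadline=None)
    def test_in_only_from_diagnosing_syndromes(self, items, split):
        items = np.array(items)
        on = list(np.flatnonzero(items))
        syndromes = [s for s in (set(on[:split]), set(on[split:])) if s]
        r = record(items_on=on, syndromes=syndromes[:2])
        p = classify_in_out(r)
        diag = [s for s in r.syndromes
                if diagnose_md_syndrome({c for c in range(N_CRITERIA)
                                          if aggregate_criteria(np.isin(np.arange(N_ITEMS), list(s)).astype(int))[c]})]
        if not diag:
            assert p.in_status.sum() == 0
        # every positive status criterion is endorsed
        endorsed = aggregate_criteria(items)
        assert np.all(p.in_status <= endorsed)
        assert np.all(p.out_status <= endorsed)


class TestCensoring:
    def test_four_criterion_cluster_censored(self):
        r = record(items_on=[MOOD, INSOMNIA, FATIGUE, CONC],
                   syndromes=[{MOOD, INSOMNIA, FATIGUE, CONC}])
        p = classify_in_out(r)
        (c,) = censor_four_symptom_clusters([p], [r])
        for ci in (C_MOOD, C_SP, C_FAT, C_CONC):
            assert c.out_status[ci] == UNKNOWN
        np.testing.assert_array_equal(c.in_status, p.in_status)

    def test_two_criterion_cluster_unchanged(self):
        r = record(items_on=[INSOMNIA, FATIGUE], syndromes=[{INSOMNIA, FATIGUE}])
        p = classify_in_out(r)
        (c,) = censor_four_symptom_clusters([p], [r])
        np.testing.assert_array_equal(c.out_status, p.out_status)

    def test_diagnosing_syndrome_untouched(self):
        r = record(items_on=[MOOD, ANHED, INSOMNIA, FATIGUE, CONC],
                   syndromes=[{MOOD, ANHED, INSOMNIA, FATIGUE, CONC}])
        p = classify_in_out(r)
        (c,) = censor_four_symptom_clusters([p], [r])
        np.testing.assert_array_equal(c.in_status, p.in_status)
        assert not np.any(c.out_status == UNKNOWN)

    def test_four_item_but_fewer_criteria_not_censored(self):
        # four items collapsing to two criteria is not a 4-criterion cluster
        r = record(items_on=[WT_DEC, WT_INC, INSOMNIA, HYPERSOMNIA],
                   syndromes=[{WT_DEC, WT_INC, INSOMNIA, HYPERSOMNIA}])
        p = classify_in_out(r)
        (c,) = censor_four_symptom_clusters([p], [r])
        assert not np.any(c.out_status == UNKNOWN)

    def test_unknown_only_in_out_status(self):
        recs = simulate_interview_sample(EpisodeModelConfig(seed=2), 150, 100, 100,
                                         {"MZ-ss": 0, "DZ-ss": 0, "OS": 0})
        profs = classify_sample(recs)
        cens = censor_four_symptom_clusters(profs, recs)
        assert all(not np.any(c.in_status == UNKNOWN) for c in cens)
        df = profiles_to_frame(cens)
        assert df[[f"in_{c}" for c in CRITERIA]].notna().all().all()


class TestRoundTrip:
    def test_full_endorsement_everything_in(self):
        cfg = EpisodeModelConfig(
            episode_prob=1.0, endorse_probs=(1.0,) * N_ITEMS,
            stray_probs=(0.0,) * N_ITEMS, somatic_rate=0.0, seed=5,
        )
        recs = simulate_interview_sample(cfg, 30, 20, 10,
                                         {"MZ-ss": 0, "DZ-ss": 0, "OS": 0})
        for p in classify_sample(recs):
            np.testing.assert_array_equal(p.in_status, np.ones(N_CRITERIA, int))
            np.testing.assert_array_equal(p.out_status, np.zeros(N_CRITERIA, int))
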