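import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from steroidscreen.classify import (ConcCall, DirectActivity,
                                    DirectObservation, Effect,
                                    FamilyClassification, MaskedBy,
                                    ci_overlap_diagnostic, classify_chemical,
                                    direct_receptor_calls, direction_profile,
                                    flag_cytotoxicity, loec, masking_rule,
                                    positivity_rule)
from steroidscreen.npstats import Direction

CONCS = [0.03, 0.1, 0.3, 1.0, 3.0]


def calls(pattern, direction=Direction.DOWN, concs=CONCS):
    """pattern: string of 's' (significant) / 'n' per ascending conc."""
    return [ConcCall(c, ch == "s", direction if ch == "s" else Direction.NONE)
            for c, ch in zip(concs, pattern)]


class TestFlagCytotoxicity:
    def _df(self, means):
        rows = []
        for conc, mean in means.items():
            for bio in (1, 2, 3):
                rows.append({"assay": "H295R", "conc": conc, "bio_rep": bio,
                             "pct_viability": mean})
        return pd.DataFrame(rows)

    def test_threshold(self):
        flags = flag_cytotoxicity(self._df({1.0: 75.0, 2.0: 95.0, 3.0: 38.2}))
        assert flags.is_cytotoxic("H295R", 1.0)
        assert not flags.is_cytotoxic("H295R", 2.0)
        assert flags.is_cytotoxic("H295R", 3.0)

    def test_spurious_dip_annotated_but_flagged(self):
        flags = flag_cytotoxicity(self._df({1.0: 70.0, 2.0: 95.0}))
        row = flags.table[flags.table["conc"] == 1.0].iloc[0]
        assert row["cytotoxic"] and row["spurious"]

    def test_boundary_is_not_cytotoxic(self):
        flags = flag_cytotoxicity(self._df({1.0: 80.0}))
        assert not flags.is_cytotoxic("H295R", 1.0)


class TestPositivityRule:
    def test_consecutive_run(self):
        runs = positivity_rule(calls("nnsss"))
        assert len(runs) == 1
        assert [c.conc for c in runs[0]] == [0.3, 1.0, 3.0]

    def test_isolated_low_hit_discarded(self):
        assert positivity_rule(calls("snnnn")) == []

    def test_top_concentration_branch(self):
        runs = positivity_rule(calls("nnnns"))
        assert len(runs) == 1 and runs[0][0].conc == 3.0

    def test_top_branch_uses_highest_noncytotoxic(self):
        # top conc cytotoxic: an isolated hit there no longer qualifies...
        assert positivity_rule(calls("nnnns"), frozenset({3.0})) == []
        # ...but an isolated hit at the highest noncytotoxic conc does
        runs = positivity_rule(calls("nnnsn"), frozenset({3.0}))
        assert len(runs) == 1 and runs[0][0].conc == 1.0

    def test_direction_break_splits_runs(self):
        mixed = [ConcCall(0.03, True, Direction.DOWN),
                 ConcCall(0.1, True, Direction.DOWN),
                 ConcCall(0.3, True, Direction.UP),
                 ConcCall(1.0, True, Direction.UP)]
        runs = positivity_rule(mixed)
        assert len(runs) == 2


class TestLoec:
    def test_lowest_of_run(self):
        assert loec(positivity_rule(calls("nnsss"))) == 0.3

    def test_isolated_hit_does_not_lower(self):
        # forskolin-style: isolated hit below the qualifying run is discarded
        runs = positivity_rule(calls("snsss"))
        assert loec(runs) == 0.3

    def test_full_run_gives_lowest_tested(self):
        assert loec(positivity_rule(calls("sssss"))) == 0.03

    def test_negative_endpoint(self):
        with pytest.raises(ValueError):
            loec([])


class TestDirectionProfile:
    def test_all_up(self):
        assert direction_profile(positivity_rule(calls("nnsss", Direction.UP))) is Effect.UP

    def test_all_down(self):
        assert direction_profile(positivity_rule(calls("sssss"))) is Effect.DOWN

    def test_down_then_up(self):
        mixed = [ConcCall(0.03, True, Direction.DOWN),
                 ConcCall(0.1, True, Direction.DOWN),
                 ConcCall(0.3, False, Direction.NONE),
                 ConcCall(1.0, True, Direction.UP),
                 ConcCall(3.0, True, Direction.UP)]
        assert direction_profile(positivity_rule(mixed)) is Effect.DOWN_THEN_UP

    def test_empty(self):
        assert direction_profile([]) is Effect.ND


def observations(sig_concs, relevant=True, cytotoxic=(), fold=3.0, concs=CONCS):
    return [DirectObservation(
        conc_nominal=c, conc_calux=c / fold, significant=c in sig_concs,
        mean_deviation=30.0 if (c in sig_concs and relevant) else 2.0,
        calux_cytotoxic=c in cytotoxic) for c in concs]


class TestDirectReceptorCalls:
    def test_run_gives_loec_on_calux_scale(self):
        act = direct_receptor_calls(observations({0.3, 1.0, 3.0}))
        assert act.present
        assert act.loec_nominal == 0.3
        assert act.loec_calux == pytest.approx(0.1)

    def test_cytotoxic_concs_excluded(self):
        act = direct_receptor_calls(observations({1.0, 3.0}, cytotoxic={3.0}))
        # the surviving singleton sits at the top usable conc -> still a call
        assert act.present and act.loec_nominal == 1.0

    def test_irrelevant_signal_is_no_call(self):
        act = direct_receptor_calls(observations({0.3, 1.0, 3.0}, relevant=False))
        assert not act.present

    def test_no_significance(self):
        act = direct_receptor_calls(observations(set()))
        assert not act.present and act.loec_calux is None


class TestMaskingRule:
    def test_clean_inhibitor_survives(self):
        fc = masking_rule(positivity_rule(calls("sssss")),
                          DirectActivity(False), frozenset(), frozenset())
        assert fc.effect is Effect.DOWN and fc.loec_h295r == 0.03
        assert fc.masked_by is MaskedBy.NONE

    def test_direct_receptor_masks_overlapping_run(self):
        direct = DirectActivity(True, loec_calux=1.0, loec_nominal=3.0,
                                active_nominal_concs=frozenset({3.0}))
        fc = masking_rule(positivity_rule(calls("nnnss")), direct,
                          frozenset(), frozenset())
        assert fc.effect is Effect.ND
        assert fc.masked_by is MaskedBy.DIRECT_RECEPTOR
        assert fc.apparent_loec == 1.0

    def test_cytotoxicity_masks_down_run(self):
        fc = masking_rule(positivity_rule(calls("nnnss")), DirectActivity(False),
                          frozenset({1.0, 3.0}), frozenset())
        assert fc.effect is Effect.ND
        assert fc.masked_by is MaskedBy.CYTOTOXICITY

    def test_up_run_never_masked_by_cytotoxicity(self):
        fc = masking_rule(positivity_rule(calls("nnnss", Direction.UP)),
                          DirectActivity(False), frozenset({1.0, 3.0}), frozenset())
        assert fc.effect is Effect.UP

    def test_never_promotes(self):
        fc = masking_rule([], DirectActivity(True,
                                             active_nominal_concs=frozenset(CONCS)),
                          frozenset(), frozenset())
        assert fc.effect is Effect.ND and fc.masked_by is MaskedBy.NONE

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.booleans(), min_size=5, max_size=5), st.integers(0, 4))
    def test_loec_monotone_under_added_higher_hits(self, pattern, extra):
        base = [ConcCall(c, s, Direction.DOWN if s else Direction.NONE)
                for c, s in zip(CONCS, pattern)]
        runs = positivity_rule(base)
        more = [ConcCall(c.conc, True, Direction.DOWN)
                if i >= extra and not c.significant else c
                for i, c in enumerate(base)]
        runs_more = positivity_rule(more)
        if runs:
            assert loec(runs_more) <= loec(runs)


class TestCiOverlap:
    def test_disjoint_groups(self):
        a = list(np.arange(30.0, 39.0))
        b = list(np.arange(60.0, 69.0))
        d = ci_overlap_diagnostic(a, b, seed=0)
        assert not d["overlap"] and d["delta_ge_10"]

    def test_identical_groups(self):
        a = [50.0, 52.0, 48.0, 51.0, 49.0]
        d = ci_overlap_diagnostic(a, a, seed=0)
        assert d["overlap"] and not d["delta_ge_10"]

    def test_close_groups_within_band(self):
        # disjoint CIs but separation below the 10-point relevance band
        a = [50.0, 50.5, 49.5, 50.2, 49.8, 50.1, 49.9, 50.3, 49.7]
        b = [v + 2.0 for v in a]
        d = ci_overlap_diagnostic(a, b, seed=0)
        assert not d["overlap"] and not d["delta_ge_10"]

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ci_overlap_diagnostic([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFamilyClassificationInvariants:
    def test_loec_iff_effect(self):
        with pytest.raises(ValueError):
            FamilyClassification(Effect.DOWN, None, MaskedBy.NONE)
        with pytest.raises(ValueError):
            FamilyClassification(Effect.ND, 1.0, MaskedBy.NONE)

    def test_masked_implies_nd(self):
        with pytest.raises(ValueError):
            FamilyClassification(Effect.DOWN, 1.0, MaskedBy.CYTOTOXICITY)


class TestClassifyChemical:
    def test_unreliable_detection_wells_carry_no_evidence(self):
        # a down-run only at concs where the detection cells die is not a call
        cc = classify_chemical(
            "x", {"estrogens": calls("nnnss")},
            {"estrogens": DirectActivity(False)},
            h295r_cytotoxic=frozenset(),
            calux_cytotoxic_nominal={"estrogens": frozenset({1.0, 3.0})})
        assert cc.families["estrogens"].effect is Effect.ND

    def test_integrates_both_families(self):
        cc = classify_chemical(
            "x",
            {"estrogens": calls("nnsss", Direction.UP), "androgens": calls("nnnnn")},
            {"estrogens": DirectActivity(False), "androgens": DirectActivity(False)},
            h295r_cytotoxic=frozenset())
        assert cc.families["estrogens"].effect is Effect.UP
        assert cc.families["androgens"].effect is Effect.ND
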