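import pytest
from hypothesis import given, settings, strategies as st

from frtscan.evaluate import (
    check_spacer,
    element_checks,
    evaluate_window,
    homopolymer_ok,
    match_mask,
    proximal8_checks,
    score,
)
from frtscan.model import ELEMENT_POSITIONS, SiteWindow, revcomp

from conftest import WT_FRT, random_windows
from oracle import oracle_accepts, oracle_base

window_strategy = st.text(alphabet="ACGT", min_size=34, max_size=34)


def mutate(seq, index, base):
    return seq[:index] + base + seq[index + 1:]


class TestCheckSpacer:
    def test_wild_type_spacer_passes(self, model):
        assert check_spacer("TCTAGAAA", model)

    @pytest.mark.parametrize("spacer", [
        "GCTAGAAA",   # s1 not T
        "TCTAGAAG",   # s8 not A
        "TCCGGCGA",   # 5/8 GC
        "TCTANAAA",   # non-ACGT
    ])
    def test_bad_spacers_fail(self, spacer, model):
        assert not check_spacer(spacer, model)

    def test_gc_boundary_four_is_allowed(self, model):
        assert check_spacer("TGCGCAAA", model)  # exactly 4 G/C


class TestHomopolymer:
    def test_wild_type_ok(self, model):
        assert homopolymer_ok(WT_FRT, model)

    def test_run_of_five_fails(self, model):
        assert not homopolymer_ok("AAAAA" + WT_FRT[5:], model)

    def test_run_of_four_is_boundary_ok(self, model):
        seq = "TTTTG" + WT_FRT[5:]
        assert homopolymer_ok(seq, model)


class TestMatchMask:
    def test_wild_type_all_match(self, model):
        mask = match_mask(SiteWindow(WT_FRT), model)
        assert all(mask[p] for p in ELEMENT_POSITIONS)
        assert len(mask) == 26

    def test_single_mismatch_localized(self, model):
        seq = mutate(WT_FRT, 21, "C")  # position 1: G -> C
        mask = match_mask(SiteWindow(seq), model)
        assert not mask[1]
        assert all(mask[p] for p in ELEMENT_POSITIONS if p != 1)

    def test_agrees_with_independent_base_in_set_check(self, model):
        for seq in random_windows(1000, seed=42):
            mask = match_mask(SiteWindow(seq), model)
            for p in ELEMENT_POSITIONS:
                expected = oracle_base(seq, p) in model.element_allowed[p]
                assert mask[p] == expected


class TestProximal8Checks:
    def test_wild_type_full_match(self, model):
        w = SiteWindow(WT_FRT)
        count, ok, reason = proximal8_checks(w, match_mask(w, model), model)
        assert (count, ok, reason) == (8, True, None)

    def test_adjacent_mismatches_same_segment(self, model):
        # -3 (T) and -2 (A/T) both mutated to mismatches: G at -3, C at -2
        seq = mutate(mutate(WT_FRT, 10, "G"), 11, "C")
        w = SiteWindow(seq)
        count, ok, reason = proximal8_checks(w, match_mask(w, model), model)
        assert count == 6
        assert not ok and reason == "consecutive_mismatch_in_segment"

    def test_forbidden_base_at_minus1(self, model):
        seq = mutate(WT_FRT, 12, "G")  # -1: C -> G (mismatch AND forbidden)
        w = SiteWindow(seq)
        count, ok, reason = proximal8_checks(w, match_mask(w, model), model)
        assert count == 7
        assert not ok and reason == "forbidden_base_pm1"


class TestElementChecks:
    def test_all_true_mask(self, model):
        mask = {p: True for p in ELEMENT_POSITIONS}
        assert element_checks(mask, model) == (True, 13, None)

    def test_position7_rule(self, model):
        mask = {p: p not in (-7, 7) for p in ELEMENT_POSITIONS}
        ok, run, reason = element_checks(mask, model)
        assert not ok and reason == "position7"

    def test_alternating_mask_fails_run_rule(self, model):
        mask = {p: p % 2 == 0 for p in ELEMENT_POSITIONS}
        ok, run, reason = element_checks(mask, model)
        assert not ok and run == 1

    def test_strict_both_elements_flag(self, model):
        # run of 13 on the left, run of 5 on the right
        mask = {p: (p < 0 or p <= 5) for p in ELEMENT_POSITIONS}
        mask.update({p: False for p in range(6, 14)})
        ok, run, _ = element_checks(mask, model)
        assert ok and run == 13
        strict = model.with_overrides(require_run_both_elements=True)
        ok, _, reason = element_checks(mask, strict)
        assert not ok and reason == "consecutive_run"


class TestScore:
    def test_scores_on_simple_masks(self, model):
        full = {p: True for p in ELEMENT_POSITIONS}
        assert score(full, model) == (26, 26.0, 13)
        empty = {p: False for p in ELEMENT_POSITIONS}
        assert score(empty, model) == (0, 0.0, 0)
        right_only = {p: p > 0 for p in ELEMENT_POSITIONS}
        assert score(right_only, model) == (13, 13.0, 13)

    def test_weights_change_weighted_score_only(self, model):
        weighted = model.with_overrides(weights={1: 5.0})
        full = {p: True for p in ELEMENT_POSITIONS}
        overall, wsum, cons = score(full, weighted)
        assert (overall, cons) == (26, 13)
        assert wsum == 25 + 5.0


class TestEvaluateWindow:
    def test_wild_type_accepted_class8(self, model):
        v = evaluate_window(WT_FRT, model)
        assert v.accepted and v.proximal8_matches == 8
        assert v.overall_score == 26 and v.consecutive_score == 13

    def test_lowercase_is_folded(self, model):
        assert evaluate_window(WT_FRT.lower(), model).accepted

    @pytest.mark.parametrize("seq, reason", [
        (WT_FRT[:13] + "GCTAGAAA" + WT_FRT[21:], "spacer_ends"),
        (WT_FRT[:13] + "TCCGGCGA" + WT_FRT[21:], "spacer_gc"),
        (WT_FRT[:13] + "TCTANAAA" + WT_FRT[21:], "non_acgt"),
        (mutate(mutate(WT_FRT, 12, "A"), 21, "T"), "both_proximal_mismatch"),
        (mutate(WT_FRT, 12, "G"), "forbidden_base_pm1"),
    ])
    def test_failure_reasons(self, seq, reason, model):
        v = evaluate_window(seq, model)
        assert not v.accepted and v.failure_reason == reason

    def test_wrong_length_is_usage_error(self, model):
        with pytest.raises(ValueError):
            evaluate_window("ACGT", model)

    def test_oracle_equivalence_random_windows(self, model):
        disagreements = [
            seq for seq in random_windows(10_000, seed=7)
            if evaluate_window(seq, model).accepted != oracle_accepts(seq)
        ]
        assert disagreements == []

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(window_strategy)
    def test_reverse_complement_closure(self, model, seq):
        assert (evaluate_window(seq, model).accepted
                == evaluate_window(revcomp(seq), model).accepted)

    def test_accepted_window_invariants(self, model, rng):
        from frtscan import random_site

        for k in (5, 6, 7, 8):
            for _ in range(20):
                seq = random_site(k, model, rng)
                v = evaluate_window(seq, model)
                assert v.accepted
                assert v.proximal8_matches == k
                spacer = seq[13:21]
                assert spacer.count("G") + spacer.count("C") <= 4
                assert v.overall_score >= v.proximal8_matches
                assert v.overall_score == sum(v.match_mask.values())
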