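"""Per-window rule evaluation: decide whether one 34-mer is FRT-like.

The rule set, applied in a fixed order so that the failure reason is
deterministic:

1. only A/C/G/T after case-folding (soft-masked lowercase is scanned);
2. spacer starts with T (s1) and ends with A (s8);
3. spacer G+C count at most 4 (<= 50%);
4. no single-nucleotide run longer than 4 anywhere in the 34-mer;
5. proximal-8: at least 5 matches, no adjacent mismatches within the same
   4-bp segment, not both -1 and 1 mismatched, no G at -1 and no C at 1;
6. elements: a match at -7 or 7, at least 5 matches in one element, and a
   run of at least 6 consecutive matches within an element.

Scores (overall, weighted, consecutive) annotate accepted windows; they
never gate acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    ConsensusModel,
    LEFT_POSITIONS,
    PROXIMAL8_POSITIONS,
    RIGHT_POSITIONS,
    SiteWindow,
    WINDOW_SIZE,
)

__all__ = [
    "Verdict",
    "check_spacer",
    "match_mask",
    "homopolymer_ok",
    "proximal8_checks",
    "element_checks",
    "score",
    "evaluate_window",
]

_ACGT = frozenset("ACGT")

#: Rejection reasons in the order the rules are applied.
FAILURE_REASONS = (
    "non_acgt",
    "spacer_ends",
    "spacer_gc",
    "homopolymer",
    "proximal8_count",
    "consecutive_mismatch_in_segment",
    "both_proximal_mismatch",
    "forbidden_base_pm1",
    "position7",
    "element_matches",
    "consecutive_run",
)


@dataclass
class Verdict:
    accepted: bool
    failure_reason: Optional[str] = None
    match_mask: Optional[dict[int, bool]] = None
    overall_score: Optional[int] = None
    weighted_score: Optional[float] = None
    consecutive_score: Optional[int] = None
    proximal8_matches: Optional[int] = None


def check_spacer(spacer: str, model: ConsensusModel) -> bool:
    """True iff the 8-mer starts/ends with the required bases and its
    G+C count does not exceed the model's limit."""
    if len(spacer) != 8:
        raise ValueError(f"spacer must be 8 nt, got {len(spacer)}")
    if not _ACGT.issuperset(spacer):
        return False
    if spacer[0] != model.spacer_first_base or spacer[7] != model.spacer_last_base:
        return False
    return spacer.count("G") + spacer.count("C") <= model.spacer_max_gc_bases


def match_mask(window: SiteWindow, model: ConsensusModel) -> dict[int, bool]:
    """Per-position consensus match over all 26 element positions."""
    seq = window.sequence
    allowed = model.element_allowed
    mask = {}
    for i, pos in enumerate(LEFT_POSITIONS):
        mask[pos] = seq[i] in allowed[pos]
    for i, pos in enumerate(RIGHT_POSITIONS):
        mask[pos] = seq[21 + i] in allowed[pos]
    return mask


def homopolymer_ok(sequence: str, model: ConsensusModel) -> bool:
    """True iff no single-base run exceeds ``max_homopolymer_run``."""
    limit = model.max_homopolymer_run
    run = 1
    prev = sequence[0]
    for ch in sequence[1:]:
        if ch == prev:
            run += 1
            if run > limit:
                return False
        else:
            prev = ch
            run = 1
    return True


def proximal8_checks(
    window: SiteWindow, mask: dict[int, bool], model: ConsensusModel
) -> tuple[int, bool, Optional[str]]:
    """Count proximal-8 matches and apply the proximal-8 rules.

    Returns (count, ok, reason).  The segments are -4..-1 and 1..4;
    adjacent mismatches are only forbidden within one segment.
    """
    count = sum(mask[p] for p in PROXIMAL8_POSITIONS)
    if count < model.min_proximal8_matches:
        return count, False, "proximal8_count"
    for segment in ((-4, -3, -2, -1), (1, 2, 3, 4)):
        for a, b in zip(segment, segment[1:]):
            if not mask[a] and not mask[b]:
                return count, False, "consecutive_mismatch_in_segment"
    if not mask[-1] and not mask[1]:
        return count, False, "both_proximal_mismatch"
    if (window.base_at(-1) == model.forbidden_base_minus1
            or window.base_at(1) == model.forbidden_base_plus1):
        return count, False, "forbidden_base_pm1"
    return count, True, None


def _longest_run(mask: dict[int, bool], positions: tuple[int, ...]) -> int:
    best = run = 0
    for p in positions:
        run = run + 1 if mask[p] else 0
        best = max(best, run)
    return best


def element_checks(
    mask: dict[int, bool], model: ConsensusModel
) -> tuple[bool, int, Optional[str]]:
    """Apply the element-level rules: position-7 match, matches on at
    least one side, and the consecutive-run requirement.

    The run requirement compares the maximum run over the two elements to
    the threshold; with ``require_run_both_elements`` each element must
    contain such a run.
    """
    left_run = _longest_run(mask, LEFT_POSITIONS)
    right_run = _longest_run(mask, RIGHT_POSITIONS)
    longest = max(left_run, right_run)
    if model.position7_rule and not (mask[-7] or mask[7]):
        return False, longest, "position7"
    left = sum(mask[p] for p in LEFT_POSITIONS)
    right = sum(mask[p] for p in RIGHT_POSITIONS)
    need = model.min_element_matches_one_side
    if left < need and right < need:
        return False, longest, "element_matches"
    if model.require_run_both_elements:
        if min(left_run, right_run) < model.min_consecutive_matches:
            return False, longest, "consecutive_run"
    elif longest < model.min_consecutive_matches:
        return False, longest, "consecutive_run"
    return True, longest, None


def score(mask: dict[int, bool], model: ConsensusModel) -> tuple[int, float, int]:
    """(overall, weighted, consecutive) scores for a match mask."""
    overall = sum(mask.values())
    weighted = sum(model.weight(p) for p, m in mask.items() if m)
    consecutive = max(_longest_run(mask, LEFT_POSITIONS),
                      _longest_run(mask, RIGHT_POSITIONS))
    return overall, float(weighted), consecutive


def evaluate_window(sequence: str, model: ConsensusModel) -> Verdict:
    """Run the full rule cascade on one 34-mer.

    Lowercase input is case-folded; windows containing any character
    outside A/C/G/T after folding are rejected (reason ``non_acgt``),
    never raised, so masked assemblies remain scannable.
    """
    if len(sequence) != WINDOW_SIZE:
        raise ValueError(f"window must be {WINDOW_SIZE} nt, got {len(sequence)}")
    seq = sequence.upper()
    if not _ACGT.issuperset(seq):
        return Verdict(False, "non_acgt")
    spacer = seq[13:21]
    if spacer[0] != model.spacer_first_base or spacer[7] != model.spacer_last_base:
        return Verdict(False, "spacer_ends")
    if spacer.count("G") + spacer.count("C") > model.spacer_max_gc_bases:
        return Verdict(False, "spacer_gc")
    if not homopolymer_ok(seq, model):
        return Verdict(False, "homopolymer")
    window = SiteWindow(seq)
    mask = match_mask(window, model)
    overall, weighted, consecutive = score(mask, model)
    p8_count, p8_ok, p8_reason = proximal8_checks(window, mask, model)
    annotations = dict(
        match_mask=mask,
        overall_score=overall,
        weighted_score=weighted,
        consecutive_score=consecutive,
        proximal8_matches=p8_count,
    )
    if not p8_ok:
        return Verdict(False, p8_reason, **annotations)
    el_ok, _, el_reason = element_checks(mask, model)
    if not el_ok:
        return Verdict(False, el_reason, **annotations)
    return Verdict(True, None, **annotations)
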