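"""Class/subclass assignment and the theoretical subclass catalogue.

A site's class is its number of proximal-8 matches (5-8).  Within a
class, sites are bucketed by the concrete proximal-8 sequence, encoded as
an 8-digit number (A=1, T=2, G=3, C=4 over positions -4..-1, 1..4) and
canonicalized by taking the minimum of the forward code and the code of
the reverse-complemented site, so orientation never splits a subclass.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

from .model import (
    CandidateSite,
    ConsensusModel,
    PROXIMAL8_POSITIONS,
    SiteWindow,
    SubclassKey,
    revcomp,
)

__all__ = [
    "BASE_DIGIT",
    "encode_proximal8",
    "forward_code",
    "flipped_code",
    "canonical_key",
    "is_flipped",
    "assign",
    "valid_patterns",
    "enumerate_subclasses",
    "subclass_counts",
]

BASE_DIGIT = {"A": 1, "T": 2, "G": 3, "C": 4}


def encode_proximal8(left4: str, right4: str) -> int:
    """8-digit code for a proximal-8 region read as left4 then right4."""
    if len(left4) != 4 or len(right4) != 4:
        raise ValueError("proximal-8 halves must each be 4 nt")
    digits = []
    for base in left4 + right4:
        try:
            digits.append(BASE_DIGIT[base])
        except KeyError:
            raise ValueError(f"non-ACGT base in proximal-8 region: {base!r}") from None
    return int("".join(str(d) for d in digits))


def forward_code(window: SiteWindow) -> int:
    left4, right4 = window.proximal8
    return encode_proximal8(left4, right4)


def flipped_code(window: SiteWindow) -> int:
    """Code of the proximal-8 region of the reverse-complemented site."""
    left4, right4 = window.proximal8
    return encode_proximal8(revcomp(right4), revcomp(left4))


def canonical_key(window: SiteWindow) -> SubclassKey:
    """Orientation-independent subclass key (minimum of the two codes)."""
    return SubclassKey(code=min(forward_code(window), flipped_code(window)))


def is_flipped(window: SiteWindow) -> bool:
    """True when the canonical reading of the site is its reverse
    complement (the flipped code is strictly lower)."""
    return flipped_code(window) < forward_code(window)


def assign(
    sites: Iterable[CandidateSite], model: ConsensusModel
) -> dict[int, dict[int, list[CandidateSite]]]:
    """Bucket sites into class -> subclass code -> sites.

    Classes are ordered descending (8 first), subclass codes ascending,
    and sites within a bucket keep genome order.
    """
    buckets: dict[int, dict[int, list[CandidateSite]]] = {}
    for site in sites:
        k = site.proximal8_matches
        if not model.min_proximal8_matches <= k <= 8:
            raise ValueError(
                f"site at {site.chromosome}:{site.chrom_linear_pos} has "
                f"proximal-8 match count {k} outside the accepted range")
        buckets.setdefault(k, {}).setdefault(site.subclass_key.code, []).append(site)
    out: dict[int, dict[int, list[CandidateSite]]] = {}
    for k in sorted(buckets, reverse=True):
        out[k] = {}
        for code in sorted(buckets[k]):
            members = sorted(
                buckets[k][code],
                key=lambda s: (s.chromosome, s.chrom_linear_pos),
            )
            out[k][code] = members
    return out


def _pattern_ok(pattern: str, model: ConsensusModel, k: int) -> bool:
    """Does an 8-mer proximal-8 pattern (left4+right4) have exactly k
    matches and satisfy every proximal-8-local rule?"""
    allowed = model.element_allowed
    matches = {
        p: pattern[i] in allowed[p] for i, p in enumerate(PROXIMAL8_POSITIONS)
    }
    if sum(matches.values()) != k:
        return False
    for segment in ((-4, -3, -2, -1), (1, 2, 3, 4)):
        for a, b in zip(segment, segment[1:]):
            if not matches[a] and not matches[b]:
                return False
    if not matches[-1] and not matches[1]:
        return False
    if pattern[3] == model.forbidden_base_minus1:
        return False
    if pattern[4] == model.forbidden_base_plus1:
        return False
    return True


def _pattern_revcomp(pattern: str) -> str:
    """Proximal-8 pattern of the reverse-complemented site: positions
    -4..-1 become the complement of 4..1 and vice versa."""
    left4, right4 = pattern[:4], pattern[4:]
    return revcomp(right4) + revcomp(left4)


def valid_patterns(k: int, model: ConsensusModel) -> list[str]:
    """All proximal-8 sequences (both orientations, not collapsed) with
    exactly ``k`` matches that satisfy the proximal-8 rules."""
    if not 5 <= k <= 8:
        raise ValueError(f"class must be in 5..8, got {k}")
    return ["".join(c) for c in itertools.product("ATGC", repeat=8)
            if _pattern_ok("".join(c), model, k)]


def enumerate_subclasses(k: int, model: ConsensusModel) -> list[str]:
    """All theoretically possible class-``k`` subclasses.

    Enumerates the 4^8 proximal-8 sequences, keeps those with exactly
    ``k`` matches that satisfy the proximal-8 rules, and collapses each
    pattern with its reverse complement into one canonical pattern (the
    orientation with the lower numeric code).  Returned sorted by code.
    """
    canonical: set[str] = set()
    for pattern in valid_patterns(k, model):
        flipped = _pattern_revcomp(pattern)
        fwd = encode_proximal8(pattern[:4], pattern[4:])
        rev = encode_proximal8(flipped[:4], flipped[4:])
        canonical.add(pattern if fwd <= rev else flipped)
    return sorted(canonical, key=lambda p: encode_proximal8(p[:4], p[4:]))


def subclass_counts(model: ConsensusModel, ks: Sequence[int] = (8, 7, 6, 5)) -> dict[int, int]:
    """Number of theoretical subclasses per class."""
    return {k: len(enumerate_subclasses(k, model)) for k in ks}
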