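"""Identity-count homology search for counter-selection targets.

When evolving a Flp variant toward one genomic target, the sites most
similar to it are the most likely off-targets; reporting them lets the
experimenter include them as counter-selection substrates.  Homology here
is strictly positionwise identity on the fixed-length 34-mer (no gaps),
taking the better of the two orientations of the subject, optionally
restricted to the 26 element positions (spacer excluded).
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal

from .evaluate import evaluate_window
from .model import CandidateSite, ConsensusModel, SiteWindow, WINDOW_SIZE, revcomp
from .subclass import canonical_key

__all__ = ["identity_count", "find_homologs", "subclass_report"]

Mode = Literal["full", "elements_only"]

#: 0-based indices of the 26 element positions within the 34-mer.
_ELEMENT_INDICES = tuple(range(0, 13)) + tuple(range(21, 34))


def _identity_one_orientation(a: str, b: str, mode: Mode) -> int:
    if mode == "elements_only":
        return sum(a[i] == b[i] for i in _ELEMENT_INDICES)
    return sum(x == y for x, y in zip(a, b))


def identity_count(
    a: str,
    b: str,
    mode: Mode = "full",
    both_orientations: bool = True,
) -> int:
    """Number of identical bases between two 34-mers.

    ``b`` is compared as-is and reverse-complemented and the maximum is
    returned (disable with ``both_orientations=False``); ``elements_only``
    counts only the 26 element positions.
    """
    if len(a) != WINDOW_SIZE or len(b) != WINDOW_SIZE:
        raise ValueError("identity_count requires two 34-mers")
    best = _identity_one_orientation(a, b, mode)
    if both_orientations:
        best = max(best, _identity_one_orientation(a, revcomp(b), mode))
    return best


def find_homologs(
    query: str,
    sites: Iterable[CandidateSite],
    threshold: int,
    mode: Mode = "full",
    both_orientations: bool = True,
    query_location: tuple[str, int] | None = None,
) -> list[tuple[CandidateSite, int]]:
    """All sites at identity >= threshold to ``query``, ranked.

    Results are sorted by identity descending, then genome order.  When
    ``query_location`` (chromosome, 0-based linear position) is given,
    that exact coordinate is excluded — and only that one, so exact
    duplicates of the query elsewhere in the genome are still reported.
    A threshold above 34 can never be met; it yields an empty list.
    """
    if len(query) != WINDOW_SIZE:
        raise ValueError("query must be a 34-mer")
    query = query.upper()
    if threshold > WINDOW_SIZE:
        logging.getLogger(__name__).warning(
            "homology threshold %d exceeds the window size; no site can match", threshold)
        return []
    ranked = []
    for site in sites:
        if query_location is not None and (
            site.chromosome == query_location[0]
            and site.chrom_linear_pos == query_location[1]
        ):
            continue
        ident = identity_count(query, site.sequence, mode, both_orientations)
        if ident >= threshold:
            ranked.append((site, ident))
    ranked.sort(key=lambda pair: (-pair[1], pair[0].chromosome, pair[0].chrom_linear_pos))
    return ranked


def subclass_report(
    query: str,
    classified: dict[int, dict[int, list[CandidateSite]]],
    mode: Mode = "full",
    model: ConsensusModel | None = None,
    query_location: tuple[str, int] | None = None,
) -> list[tuple[CandidateSite, int]]:
    """Every member of the query's own subclass with its identity count.

    Subclass members share the query's proximal-8 region, so they are the
    first-choice counter-selection candidates regardless of threshold.
    The query must itself be a valid site (it needs a class and
    subclass); otherwise a ValueError names the failed rule.
    """
    from .model import default_consensus

    model = model or default_consensus()
    verdict = evaluate_window(query, model)
    if not verdict.accepted:
        raise ValueError(
            f"query is not a valid FRT-like site (failed rule: {verdict.failure_reason})")
    window = SiteWindow(query.upper())
    key = canonical_key(window)
    members = classified.get(verdict.proximal8_matches, {}).get(key.code, [])
    report = []
    for site in members:
        if query_location is not None and (
            site.chromosome == query_location[0]
            and site.chrom_linear_pos == query_location[1]
        ):
            continue
        report.append((site, identity_count(query, site.sequence, mode)))
    report.sort(key=lambda pair: (-pair[1], pair[0].chromosome, pair[0].chrom_linear_pos))
    return report
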