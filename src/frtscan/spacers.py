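"""Spacer-identity grouping within a subclass.

Two sites of the same subclass can, in principle, be recombined by one
Flp variant only if their 8-bp spacers are identical; because a site may
be read in either orientation, spacers are compared through a canonical
form (lexicographic minimum of the spacer and its reverse complement).
Spacers are taken in the site's canonical reading by default so the
comparison is orientation-consistent; ``raw_orientation`` compares them
as they appear on the scanned strand instead.
"""

from __future__ import annotations

from .model import CandidateSite, revcomp

__all__ = ["canonical_spacer", "group_by_spacer"]

_ACGT = frozenset("ACGT")


def canonical_spacer(spacer: str) -> str:
    """Lexicographic minimum of an 8-mer spacer and its reverse complement."""
    if len(spacer) != 8 or not _ACGT.issuperset(spacer):
        raise ValueError(f"spacer must be an uppercase ACGT 8-mer, got {spacer!r}")
    return min(spacer, revcomp(spacer))


def group_by_spacer(
    subclass_sites: list[CandidateSite],
    raw_orientation: bool = False,
) -> tuple[list[list[CandidateSite]], list[CandidateSite]]:
    """Bucket one subclass's sites by canonical spacer.

    Returns (groups, singletons): buckets of two or more sites, ordered
    by size descending then spacer, then the sites whose spacer is
    unique.  Members keep genome order.
    """
    buckets: dict[str, list[CandidateSite]] = {}
    for site in subclass_sites:
        spacer = site.window.spacer if raw_orientation else site.canonical_spacer
        buckets.setdefault(canonical_spacer(spacer), []).append(site)
    for members in buckets.values():
        members.sort(key=lambda s: (s.chromosome, s.chrom_linear_pos))
    groups = [
        members
        for _, members in sorted(
            ((spacer, members) for spacer, members in buckets.items() if len(members) >= 2),
            key=lambda item: (-len(item[1]), item[0]),
        )
    ]
    singletons = sorted(
        (members[0] for members in buckets.values() if len(members) == 1),
        key=lambda s: (s.chromosome, s.chrom_linear_pos),
    )
    return groups, singletons
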