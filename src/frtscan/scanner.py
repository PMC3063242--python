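"""Sliding-window genome scan and duplicate partitioning.

Contigs are streamed in ~10-kb chunks with a 33-bp carry-over, so memory
stays bounded regardless of contig size while producing output identical
to scanning the whole string.  Scanning is single-strand (forward only):
because the default rule set is closed under reverse complement, a site
on the minus strand is found through its plus-strand reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import io as io_layer
from .evaluate import evaluate_window
from .model import (
    CandidateSite,
    ConsensusModel,
    DuplicateGroup,
    GenomeLayout,
    SiteWindow,
    WINDOW_SIZE,
    revcomp,
)
from .subclass import canonical_key, is_flipped

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "scan_contig", "scan_chunks", "scan_genome", "partition_duplicates"]

CHUNK_SIZE = 10_000
CARRY = WINDOW_SIZE - 1  # 33 bp: minimal overlap for which no window is lost


@dataclass
class ScanResult:
    """Outcome of a genome scan: all hits plus the unique/duplicated split."""

    hits: list[CandidateSite]
    unique_pool: list[CandidateSite]
    duplicate_groups: list[DuplicateGroup]
    stats: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        total = len(self.unique_pool) + sum(g.copy_number for g in self.duplicate_groups)
        if total != len(self.hits):
            raise AssertionError(
                f"pool conservation violated: {len(self.hits)} hits vs "
                f"{len(self.unique_pool)} unique + {total - len(self.unique_pool)} duplicated")


def _make_site(
    seq: str,
    offset: int,
    contig_id: str,
    chromosome: str,
    linear_pos: int,
    model: ConsensusModel,
) -> CandidateSite | None:
    verdict = evaluate_window(seq, model)
    if not verdict.accepted:
        return None
    window = SiteWindow(seq.upper())
    spacer = window.spacer
    canonical_spacer = revcomp(spacer) if is_flipped(window) else spacer
    return CandidateSite(
        window=window,
        contig_id=contig_id,
        contig_offset=offset,
        chromosome=chromosome,
        chrom_linear_pos=linear_pos,
        match_mask=verdict.match_mask,
        overall_score=verdict.overall_score,
        weighted_score=verdict.weighted_score,
        consecutive_score=verdict.consecutive_score,
        proximal8_matches=verdict.proximal8_matches,
        subclass_key=canonical_key(window),
        canonical_spacer=canonical_spacer,
    )


def _candidate_offsets(buf: str, model: ConsensusModel) -> np.ndarray:
    """Offsets in ``buf`` whose spacer end bases can satisfy the spacer
    rule — a cheap vectorized prefilter before full evaluation."""
    n = len(buf) - WINDOW_SIZE + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(buf.upper().encode("ascii"), dtype=np.uint8)
    first = arr[13:13 + n] == ord(model.spacer_first_base)
    last = arr[20:20 + n] == ord(model.spacer_last_base)
    return np.flatnonzero(first & last)


def scan_chunks(
    chunks: Iterable[str],
    contig_id: str,
    model: ConsensusModel,
    chromosome: str = "",
    linear_offset: int = 0,
) -> Iterator[CandidateSite]:
    """Scan a contig supplied as a stream of sequence pieces.

    Pieces are accumulated into a bounded buffer of about ``CHUNK_SIZE``
    bases; after each buffer is scanned only the trailing 33 bp are kept,
    so a window spanning a chunk boundary is still seen exactly once.
    """
    buf = ""
    base = 0  # contig offset of buf[0]
    pieces = iter(chunks)
    exhausted = False
    while True:
        while not exhausted and len(buf) < CHUNK_SIZE:
            piece = next(pieces, None)
            if piece is None:
                exhausted = True
            else:
                buf += piece
        if len(buf) < WINDOW_SIZE:
            return
        for off in _candidate_offsets(buf, model):
            o = int(off)
            site = _make_site(
                buf[o:o + WINDOW_SIZE], base + o, contig_id,
                chromosome, linear_offset + base + o, model,
            )
            if site is not None:
                yield site
        if exhausted:
            return
        base += len(buf) - CARRY
        buf = buf[-CARRY:]


def scan_contig(
    contig_sequence: str,
    contig_id: str,
    model: ConsensusModel,
    chromosome: str = "",
    linear_offset: int = 0,
) -> list[CandidateSite]:
    """Scan one contig string; short contigs (< 34 bp) yield no hits."""
    chunks = (
        contig_sequence[i:i + CHUNK_SIZE]
        for i in range(0, len(contig_sequence), CHUNK_SIZE)
    )
    return list(scan_chunks(chunks, contig_id, model, chromosome, linear_offset))


def partition_duplicates(
    hits: list[CandidateSite],
) -> tuple[list[CandidateSite], list[DuplicateGroup]]:
    """Split hits into unique sites and orientation-independent
    exact-duplicate groups, keyed by min(sequence, revcomp)."""
    by_key: dict[str, list[CandidateSite]] = {}
    for site in hits:
        by_key.setdefault(site.canonical_seq, []).append(site)
    unique: list[CandidateSite] = []
    groups: list[DuplicateGroup] = []
    for key in sorted(by_key):
        members = by_key[key]
        if len(members) == 1:
            unique.append(members[0])
        else:
            groups.append(DuplicateGroup(canonical_seq=key, members=members))
    unique.sort(key=lambda s: (s.chromosome, s.chrom_linear_pos))
    return unique, groups


def scan_genome(
    fasta_dir: str | Path,
    layout: GenomeLayout,
    model: ConsensusModel,
) -> ScanResult:
    """Scan every contig of a genome build directory in manifest order.

    Chromosome-linear coordinates come from the layout's cumulative
    contig offsets.  Contigs found on disk but missing from the layout
    are appended at the end of their chromosome with a warning.
    """
    hits: list[CandidateSite] = []
    per_chrom: dict[str, int] = {}
    scanned_bases = 0
    for contig_id, seq in io_layer.read_fasta_dir(fasta_dir, layout):
        chrom = layout.chromosome_of(contig_id)
        offset = layout.offset_of(contig_id)
        contig_hits = scan_contig(seq, contig_id, model, chrom, offset)
        hits.extend(contig_hits)
        per_chrom[chrom] = per_chrom.get(chrom, 0) + len(contig_hits)
        scanned_bases += len(seq)
        logger.info("scanned %s (%s): %d bp, %d hits",
                    contig_id, chrom, len(seq), len(contig_hits))
    hits.sort(key=lambda s: (s.chromosome, s.chrom_linear_pos))
    unique, groups = partition_duplicates(hits)
    result = ScanResult(
        hits=hits,
        unique_pool=unique,
        duplicate_groups=groups,
        stats={
            "per_chromosome": per_chrom,
            "scanned_bases": scanned_bases,
            "total_hits": len(hits),
            "unique": len(unique),
            "duplicated_distinct": len(groups),
            "duplicated_total": sum(g.copy_number for g in groups),
        },
    )
    result.check_conservation()
    return result
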