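"""Readers and writers: FASTA input, manifests, hit tables, subclass
directories, spacer-group files and BED export.

Coordinate conventions: TSV reports are 1-based inclusive (traditional
genomics tables); BED export is 0-based half-open.  All writers are
deterministic — stable column order, stable row order, no timestamps.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .model import CandidateSite, ConsensusModel, DuplicateGroup, GenomeLayout, SiteWindow

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta_dir",
    "read_manifest",
    "write_manifest",
    "hits_to_dataframe",
    "write_hits",
    "write_pools",
    "read_hits",
    "write_subclass_dirs",
    "write_groups",
    "write_bed",
    "write_catalogue",
]

FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}

HIT_COLUMNS = [
    "chromosome", "chrom_linear_pos_1based", "contig_id", "contig_offset_1based",
    "sequence", "spacer", "class", "subclass_code",
    "overall_score", "weighted_score", "consecutive_score",
]


def _guess_chromosome(contig_id: str, layout: GenomeLayout) -> str:
    for sep in (".", "_", ":"):
        prefix = contig_id.split(sep)[0]
        if prefix in layout.ordered_contigs:
            return prefix
    return "unplaced"


def read_fasta_dir(path: str | Path, layout: GenomeLayout) -> Iterator[tuple[str, str]]:
    """Yield (contig_id, uppercase sequence) in manifest order.

    Multi-record files are supported.  A contig listed in the manifest
    but absent from the directory is an error naming it; a record on disk
    that the manifest does not mention is appended at the end of its
    (guessed) chromosome with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in FASTA_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no FASTA inputs in {path}")
    records: dict[str, str] = {}
    for f in files:
        try:
            for rec in SeqIO.parse(str(f), "fasta"):
                if rec.id in records:
                    raise OSError(f"duplicate FASTA record id {rec.id!r} in {f}")
                records[rec.id] = str(rec.seq).upper()
        except ValueError as exc:
            raise OSError(f"malformed FASTA in {f}: {exc}") from exc
    missing = [cid for cid in layout.contig_ids if cid not in records]
    if missing:
        raise FileNotFoundError(
            f"manifest contig(s) not found under {path}: {', '.join(missing)}")
    for cid in layout.contig_ids:
        yield cid, records[cid]
    for cid in sorted(set(records) - set(layout.contig_ids)):
        chrom = _guess_chromosome(cid, layout)
        logger.warning(
            "contig %s not in manifest; appending at end of chromosome %s", cid, chrom)
        layout.append_contig(chrom, cid, len(records[cid]))
        yield cid, records[cid]


def read_manifest(path: str | Path) -> GenomeLayout:
    """Load a layout manifest (TSV: chromosome, order, contig_id, length)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "contig_id": str})
    required = {"chromosome", "order", "contig_id", "length"}
    if not required <= set(df.columns):
        raise ValueError(
            f"manifest {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}")
    return GenomeLayout.from_records(
        df[["chromosome", "order", "contig_id", "length"]].itertuples(index=False, name=None))


def write_manifest(layout: GenomeLayout, path: str | Path) -> None:
    df = pd.DataFrame(layout.iter_records(),
                      columns=["chromosome", "order", "contig_id", "length"])
    df.to_csv(path, sep="\t", index=False)


def _hit_row(site: CandidateSite) -> dict:
    return {
        "chromosome": site.chromosome,
        "chrom_linear_pos_1based": site.chrom_linear_pos + 1,
        "contig_id": site.contig_id,
        "contig_offset_1based": site.contig_offset + 1,
        "sequence": site.sequence,
        "spacer": site.window.spacer,
        "class": site.proximal8_matches,
        "subclass_code": f"{site.subclass_key.code:08d}",
        "overall_score": site.overall_score,
        "weighted_score": site.weighted_score,
        "consecutive_score": site.consecutive_score,
    }


def hits_to_dataframe(sites: Iterable[CandidateSite]) -> pd.DataFrame:
    rows = [_hit_row(s) for s in sites]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(sites: Iterable[CandidateSite], path: str | Path) -> None:
    hits_to_dataframe(sites).to_csv(path, sep="\t", index=False)


def write_pools(
    unique_pool: list[CandidateSite],
    duplicate_groups: list[DuplicateGroup],
    unique_path: str | Path,
    duplicated_path: str | Path,
) -> None:
    """Write the unique pool and the duplicated pool (the latter with
    canonical sequence and copy number on every member row)."""
    write_hits(unique_pool, unique_path)
    rows = []
    for group in duplicate_groups:
        for site in sorted(group.members, key=lambda s: (s.chromosome, s.chrom_linear_pos)):
            row = _hit_row(site)
            row["canonical_seq"] = group.canonical_seq
            row["copy_number"] = group.copy_number
            rows.append(row)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS + ["canonical_seq", "copy_number"])
    df.to_csv(duplicated_path, sep="\t", index=False)


def read_hits(path: str | Path, model: ConsensusModel) -> list[CandidateSite]:
    """Rebuild candidate sites from a hits TSV.

    Masks and scores are re-derived from the stored 34-mer under the
    given model, so a round trip reproduces the in-memory records.
    """
    from .scanner import _make_site  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "contig_id": str})
    sites = []
    for row in df.itertuples(index=False):
        site = _make_site(
            row.sequence,
            int(row.contig_offset_1based) - 1,
            row.contig_id,
            row.chromosome,
            int(row.chrom_linear_pos_1based) - 1,
            model,
        )
        if site is None:
            raise ValueError(
                f"{path}: stored sequence at {row.chromosome}:"
                f"{row.chrom_linear_pos_1based} is not accepted by the model")
        sites.append(site)
    return sites


def write_subclass_dirs(
    classified: dict[int, dict[int, list[CandidateSite]]],
    outdir: str | Path,
) -> list[Path]:
    """Emit one TSV per subclass under class_<k>/subclass_<code>.tsv."""
    outdir = Path(outdir)
    written = []
    for k, subclasses in classified.items():
        class_dir = outdir / f"class_{k}"
        class_dir.mkdir(parents=True, exist_ok=True)
        for code, members in subclasses.items():
            path = class_dir / f"subclass_{code:08d}.tsv"
            write_hits(members, path)
            written.append(path)
    return written


def write_catalogue(
    catalogue: dict[int, list[str]],
    path: str | Path,
    observed: set[tuple[int, int]] | None = None,
) -> None:
    """Theoretical subclass catalogue as TSV (class, code, pattern,
    observed flag when a scan is supplied)."""
    from .subclass import encode_proximal8

    rows = []
    for k in sorted(catalogue, reverse=True):
        for pattern in catalogue[k]:
            code = encode_proximal8(pattern[:4], pattern[4:])
            row = {"class": k, "subclass_code": f"{code:08d}", "pattern": pattern}
            if observed is not None:
                row["observed"] = (k, code) in observed
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_groups(
    groups: list[list[CandidateSite]],
    singletons: list[CandidateSite],
    human_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Spacer-group output, twice.

    ``human_path`` mirrors the classic layout: shared-spacer groups
    first, one blank line between groups, then sites with unique spacers.
    ``tsv_path`` is the machine-readable version with a group_id column
    (0 marks singletons).
    """
    lines = []
    rows = []
    for gid, group in enumerate(groups, start=1):
        for site in group:
            row = _hit_row(site)
            lines.append("\t".join(str(row[c]) for c in HIT_COLUMNS))
            row["group_id"] = gid
            row["canonical_spacer"] = site.canonical_spacer
            rows.append(row)
        lines.append("")
    for site in singletons:
        row = _hit_row(site)
        lines.append("\t".join(str(row[c]) for c in HIT_COLUMNS))
        row["group_id"] = 0
        row["canonical_spacer"] = site.canonical_spacer
        rows.append(row)
    Path(human_path).write_text("\n".join(lines) + "\n")
    df = pd.DataFrame(rows, columns=HIT_COLUMNS + ["canonical_spacer", "group_id"])
    df.to_csv(tsv_path, sep="\t", index=False)


def write_bed(sites: Iterable[CandidateSite], path: str | Path) -> None:
    """BED6 export: 0-based half-open, name = subclass code, score =
    overall score scaled to 0-1000, strand '+' (forward-strand scan)."""
    lines = []
    for site in sites:
        start = site.chrom_linear_pos
        score = round(site.overall_score / 26 * 1000)
        lines.append("\t".join(map(str, [
            site.chromosome, start, start + 34,
            f"{site.subclass_key.code:08d}", score, "+",
        ])))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
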