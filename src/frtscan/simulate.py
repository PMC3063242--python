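"""Synthetic genomes with known ground truth.

Fixture genomes stand in for a real genome build: random background of
configurable GC content, planted FRT-like sites of a chosen class, and
repeat families (a unit carrying a valid site copied N times, optionally
with per-copy point mutations).  The truth table is defined by an
exhaustive rule scan of the *final assembled* sequence, not just the
planted coordinates, because random background legitimately contains
FRT-like sites (roughly one per several kb at human-like GC), and
splice junctions can create new ones.

All randomness flows from the spec seed, so a spec reproduces its genome
byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import evaluate_window
from .io import write_manifest
from .model import (
    ConsensusModel,
    GenomeLayout,
    SiteWindow,
    WINDOW_SIZE,
    default_consensus,
    revcomp,
)
from .subclass import canonical_key, valid_patterns

__all__ = [
    "PlantedSite",
    "RepeatFamily",
    "SyntheticGenomeSpec",
    "GeneratedGenome",
    "random_spacer",
    "random_site",
    "generate_genome",
]

TRUTH_COLUMNS = ["chromosome", "pos_0based", "sequence", "class", "subclass_code", "group_id"]


@dataclass
class PlantedSite:
    """One site to splice into the background at a known position."""

    chromosome: str
    position: int
    k: int = 8
    sequence: str | None = None  # explicit 34-mer; drawn at random if None
    orientation: str = "+"


@dataclass
class RepeatFamily:
    """A repeat unit carrying one valid site, copied across a chromosome."""

    chromosome: str
    copies: int
    mutation_rate: float = 0.0
    unit: str | None = None      # explicit unit; generated if None
    unit_length: int = 300
    site_k: int = 8
    positions: list[int] | None = None  # unit start positions; random if None


@dataclass
class SyntheticGenomeSpec:
    chromosomes: list[tuple[str, int, float]]  # (name, length bp, GC fraction)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    repeat_families: list[RepeatFamily] = field(default_factory=list)
    seed: int = 0
    contig_length: int | None = None  # split chromosomes into contigs of this size


@dataclass
class GeneratedGenome:
    fasta_dir: Path
    manifest_path: Path
    truth_path: Path
    truth: pd.DataFrame
    layout: GenomeLayout
    sequences: dict[str, str]


_MAX_DRAWS = 1000


def random_spacer(model: ConsensusModel, rng: random.Random) -> str:
    """An 8-mer satisfying the spacer rules (fixed ends, GC cap)."""
    for _ in range(_MAX_DRAWS):
        middle = "".join(rng.choice("ACGT") for _ in range(6))
        spacer = model.spacer_first_base + middle + model.spacer_last_base
        if spacer.count("G") + spacer.count("C") <= model.spacer_max_gc_bases:
            return spacer
    raise RuntimeError("could not draw a rule-satisfying spacer")


_pattern_cache: dict[tuple, list[str]] = {}


def _patterns_for(k: int, model: ConsensusModel) -> list[str]:
    key = (
        k,
        tuple(tuple(sorted(model.element_allowed[p])) for p in (-4, -3, -2, -1, 1, 2, 3, 4)),
        model.forbidden_base_minus1,
        model.forbidden_base_plus1,
    )
    if key not in _pattern_cache:
        _pattern_cache[key] = valid_patterns(k, model)
    return _pattern_cache[key]


def random_site(k: int, model: ConsensusModel, rng: random.Random) -> str:
    """Draw a 34-mer accepted by the rule set with exactly ``k``
    proximal-8 matches.

    The proximal-8 pattern is drawn from the valid class-k patterns and
    the spacer from the spacer rules; distal element positions are drawn
    with a strong bias toward the consensus so the element-level rules
    usually hold, and the whole window is rejection-sampled against the
    full evaluator (homopolymer runs, consecutive-run rule).
    """
    patterns = _patterns_for(k, model)
    for _ in range(_MAX_DRAWS):
        pattern = rng.choice(patterns)
        spacer = random_spacer(model, rng)
        left_distal = "".join(
            rng.choice(sorted(model.element_allowed[p])) if rng.random() < 0.9
            else rng.choice("ACGT")
            for p in range(-13, -4)
        )
        right_distal = "".join(
            rng.choice(sorted(model.element_allowed[p])) if rng.random() < 0.9
            else rng.choice("ACGT")
            for p in range(5, 14)
        )
        seq = left_distal + pattern[:4] + spacer + pattern[4:] + right_distal
        verdict = evaluate_window(seq, model)
        if verdict.accepted and verdict.proximal8_matches == k:
            return seq
    raise RuntimeError(
        f"could not draw an accepted class-{k} site in {_MAX_DRAWS} tries; "
        "the rule model may be internally inconsistent")


def _random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return codes.tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != base])
    return "".join(out)


def _truth_scan(seq: str, chrom: str, model: ConsensusModel) -> list[dict]:
    """Exhaustive rule scan of one assembled chromosome (defines truth)."""
    n = len(seq) - WINDOW_SIZE + 1
    if n <= 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    cand = np.flatnonzero(
        (arr[13:13 + n] == ord(model.spacer_first_base))
        & (arr[20:20 + n] == ord(model.spacer_last_base)))
    rows = []
    for off in cand:
        o = int(off)
        window = seq[o:o + WINDOW_SIZE]
        verdict = evaluate_window(window, model)
        if verdict.accepted:
            rows.append({
                "chromosome": chrom,
                "pos_0based": o,
                "sequence": window,
                "class": verdict.proximal8_matches,
                "subclass_code": f"{canonical_key(SiteWindow(window)).code:08d}",
            })
    return rows


def _place(
    occupied: list[tuple[int, int]], length: int, span: int, rng: random.Random
) -> int:
    """A start position for an interval of ``span`` bp keeping >= 34 bp
    clear of every occupied interval."""
    for _ in range(_MAX_DRAWS):
        start = rng.randrange(0, length - span)
        if all(start + span + WINDOW_SIZE <= s or e + WINDOW_SIZE <= start
               for s, e in occupied):
            return start
    raise RuntimeError("could not place interval without overlap; genome too crowded")


def generate_genome(
    spec: SyntheticGenomeSpec,
    outdir: str | Path,
    model: ConsensusModel | None = None,
) -> GeneratedGenome:
    """Assemble, verify and write a fixture genome.

    Writes one FASTA per chromosome (split into contigs when
    ``contig_length`` is set), the scanner manifest, and the truth TSV
    derived from an exhaustive scan of the assembled sequences, with
    duplicate groups keyed by canonical 34-mer.
    """
    model = model or default_consensus()
    outdir = Path(outdir)
    fasta_dir = outdir / "fasta"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    nrng = np.random.default_rng(spec.seed)

    sequences: dict[str, list[str]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for name, length, gc in spec.chromosomes:
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"GC fraction for {name} must be in [0,1], got {gc}")
        sequences[name] = list(_random_background(length, gc, nrng))
        occupied[name] = []

    def reserve(chrom: str, start: int, span: int, what: str) -> None:
        seq = sequences[chrom]
        if start < 0 or start + span > len(seq):
            raise ValueError(f"{what} outside chromosome {chrom}: {start}+{span}")
        for s, e in occupied[chrom]:
            if not (start + span <= s or e <= start):
                raise ValueError(f"overlapping plants on {chrom} at {start}")
        occupied[chrom].append((start, start + span))

    def splice(chrom: str, start: int, piece: str) -> None:
        sequences[chrom][start:start + len(piece)] = piece

    # Reserve fixed planted positions first so random repeat placement
    # can never collide with them; draw plant sequences now so the RNG
    # stream stays a pure function of the spec.
    plants: list[tuple[str, int, str]] = []
    for plant in spec.planted_sites:
        if plant.chromosome not in sequences:
            raise ValueError(f"planted site references unknown chromosome {plant.chromosome}")
        site = plant.sequence or random_site(plant.k, model, rng)
        verdict = evaluate_window(site, model)
        if not verdict.accepted:
            raise ValueError(
                f"explicit planted site at {plant.chromosome}:{plant.position} "
                f"fails the rule set ({verdict.failure_reason})")
        if plant.orientation == "-":
            site = revcomp(site)
        reserve(plant.chromosome, plant.position, WINDOW_SIZE, "planted site")
        plants.append((plant.chromosome, plant.position, site))

    for fam in spec.repeat_families:
        if fam.chromosome not in sequences:
            raise ValueError(f"repeat family references unknown chromosome {fam.chromosome}")
        unit = fam.unit
        if unit is None:
            flank = _random_background(fam.unit_length, 0.41, nrng)
            site = random_site(fam.site_k, model, rng)
            mid = (fam.unit_length - WINDOW_SIZE) // 2
            unit = flank[:mid] + site + flank[mid + WINDOW_SIZE:]
        length = len(sequences[fam.chromosome])
        positions = fam.positions
        if positions is None:
            positions = []
            for _ in range(fam.copies):
                start = _place(occupied[fam.chromosome], length, len(unit), rng)
                occupied[fam.chromosome].append((start, start + len(unit)))
                positions.append(start)
        else:
            for start in positions:
                reserve(fam.chromosome, start, len(unit), "repeat unit")
        for start in positions:
            splice(fam.chromosome, start, _mutate(unit, fam.mutation_rate, rng))

    for chrom, position, site in plants:
        splice(chrom, position, site)

    assembled = {name: "".join(seq) for name, seq in sequences.items()}

    # Truth from an exhaustive scan of the final assembly.
    rows: list[dict] = []
    for name, _, _ in spec.chromosomes:
        rows.extend(_truth_scan(assembled[name], name, model))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS[:-1])
    if truth.empty:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    else:
        canon = truth["sequence"].map(lambda s: min(s, revcomp(s)))
        counts = canon.value_counts()
        group_ids = {
            seq: f"g{i}" for i, seq in enumerate(
                sorted(counts.index[counts >= 2]), start=1)
        }
        truth["group_id"] = canon.map(lambda s: group_ids.get(s, ""))
        truth = truth.sort_values(["chromosome", "pos_0based"]).reset_index(drop=True)

    # Emit FASTA + manifest.
    records = []
    for name, length, _ in spec.chromosomes:
        seq = assembled[name]
        if spec.contig_length:
            pieces = [
                seq[i:i + spec.contig_length]
                for i in range(0, len(seq), spec.contig_length)
            ]
        else:
            pieces = [seq]
        lines = []
        for i, piece in enumerate(pieces, start=1):
            cid = f"{name}.{i}" if len(pieces) > 1 else name
            records.append((name, i, cid, len(piece)))
            lines.append(f">{cid}")
            lines.extend(piece[j:j + 70] for j in range(0, len(piece), 70))
        (fasta_dir / f"{name}.fa").write_text("\n".join(lines) + "\n")

    layout = GenomeLayout.from_records(records)
    manifest_path = outdir / "manifest.tsv"
    write_manifest(layout, manifest_path)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return GeneratedGenome(
        fasta_dir=fasta_dir,
        manifest_path=manifest_path,
        truth_path=truth_path,
        truth=truth,
        layout=layout,
        sequences=assembled,
    )
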