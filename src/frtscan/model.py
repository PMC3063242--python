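"""Site anatomy, consensus model and shared domain types.

An FRT site is 34 bp long: two 13-bp inverted Flp-binding elements
(positions -13..-1 and 1..13; there is no position 0) flanking an 8-bp
asymmetric spacer (positions s1..s8).  The eight spacer-adjacent element
positions (-4..-1 and 1..4) form the *proximal-8* region, the most
critical determinant of Flp recognition.  The number of proximal-8
matches to the consensus (5-8) is a site's **class**; the concrete
proximal-8 sequence, canonicalized over reverse complement, is its
**subclass**.

The consensus used for discovery is the wild-type FRT with a small amount
of experimentally tolerated degeneracy: A or G at position 1 (hence C or T
at position -1) and A or T at positions -2 and 2.  All rule thresholds
live in :class:`ConsensusModel` so that the whole rule set is one
configurable object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "COMPLEMENT",
    "ELEMENT_POSITIONS",
    "LEFT_POSITIONS",
    "RIGHT_POSITIONS",
    "PROXIMAL8_POSITIONS",
    "WINDOW_SIZE",
    "WT_FRT",
    "ConfigError",
    "ConsensusModel",
    "SiteWindow",
    "CandidateSite",
    "SubclassKey",
    "DuplicateGroup",
    "GenomeLayout",
    "revcomp",
    "default_consensus",
    "load_consensus",
]

WINDOW_SIZE = 34

#: Element positions in left-to-right reading order of the 34-mer.
LEFT_POSITIONS: tuple[int, ...] = tuple(range(-13, 0))
RIGHT_POSITIONS: tuple[int, ...] = tuple(range(1, 14))
ELEMENT_POSITIONS: tuple[int, ...] = LEFT_POSITIONS + RIGHT_POSITIONS
PROXIMAL8_POSITIONS: tuple[int, ...] = (-4, -3, -2, -1, 1, 2, 3, 4)

#: Wild-type minimal FRT: left element, spacer TCTAGAAA, right element.
WT_FRT = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

_TRANS = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_TRANS)[::-1]


def position_index(pos: int) -> int:
    """0-based index of an element position within the 34-mer."""
    if -13 <= pos <= -1:
        return pos + 13
    if 1 <= pos <= 13:
        return pos + 20
    raise ValueError(f"not an element position: {pos}")


class ConfigError(ValueError):
    """Raised for malformed consensus/rule configuration."""


@dataclass(frozen=True)
class ConsensusModel:
    """Allowed bases per element position plus every rule threshold.

    ``element_allowed`` maps each of the 26 element positions to a
    non-empty set of bases; a position *matches* when the observed base
    is in the set.  Spacer constraints, the proximal-8 rules and the
    element-level rules are all parameters so variant rule sets can be
    explored without touching the scanner.
    """

    element_allowed: Mapping[int, frozenset[str]]
    spacer_first_base: str = "T"
    spacer_last_base: str = "A"
    spacer_max_gc_bases: int = 4
    min_proximal8_matches: int = 5
    forbidden_base_minus1: str = "G"
    forbidden_base_plus1: str = "C"
    min_element_matches_one_side: int = 5
    min_consecutive_matches: int = 6
    max_homopolymer_run: int = 4
    position7_rule: bool = True
    require_run_both_elements: bool = False
    weights: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {p: frozenset(b.upper() for b in bases)
                   for p, bases in self.element_allowed.items()}
        if set(allowed) != set(ELEMENT_POSITIONS):
            missing = set(ELEMENT_POSITIONS) - set(allowed)
            extra = set(allowed) - set(ELEMENT_POSITIONS)
            raise ConfigError(
                f"element_allowed must cover exactly positions -13..-1,1..13 "
                f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for p, bases in allowed.items():
            if not bases or not bases <= {"A", "C", "G", "T"}:
                raise ConfigError(
                    f"element_allowed[{p}] must be a non-empty subset of ACGT, "
                    f"got {sorted(bases)}")
        object.__setattr__(self, "element_allowed", allowed)
        w = dict(self.weights) if self.weights else {p: 1.0 for p in ELEMENT_POSITIONS}
        for p in ELEMENT_POSITIONS:
            w.setdefault(p, 1.0)
        if any(v < 0 for v in w.values()):
            raise ConfigError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    def weight(self, pos: int) -> float:
        return self.weights[pos]

    def is_rc_symmetric(self) -> bool:
        """True when the allowed set at -p is the complement of that at p."""
        return all(
            self.element_allowed[-p] == frozenset(COMPLEMENT[b] for b in self.element_allowed[p])
            for p in range(1, 14)
        )

    def with_overrides(self, **kwargs) -> "ConsensusModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SiteWindow:
    """One 34-mer partitioned as 13-bp element + 8-bp spacer + 13-bp element."""

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_SIZE:
            raise ValueError(
                f"window must be {WINDOW_SIZE} nt, got {len(self.sequence)}")

    @property
    def left_element(self) -> str:
        return self.sequence[:13]

    @property
    def spacer(self) -> str:
        return self.sequence[13:21]

    @property
    def right_element(self) -> str:
        return self.sequence[21:]

    def base_at(self, pos: int) -> str:
        """Base at element position ``pos`` (-13..-1 or 1..13)."""
        return self.sequence[position_index(pos)]

    @property
    def proximal8(self) -> tuple[str, str]:
        """(left4, right4): bases at -4..-1 and 1..4 in reading order."""
        return self.sequence[9:13], self.sequence[21:25]

    def reverse_complement(self) -> "SiteWindow":
        return SiteWindow(revcomp(self.sequence))


@dataclass(frozen=True)
class SubclassKey:
    """8-digit numeric code identifying a proximal-8 subclass.

    Digits come from the proximal-8 bases in order -4,-3,-2,-1,1,2,3,4
    under A=1, T=2, G=3, C=4.  The canonical code is the minimum of the
    forward code and the code read from the reverse-complemented site, so
    a site and its reverse complement share one subclass.
    """

    code: int
    is_canonical: bool = True

    def __str__(self) -> str:
        return f"{self.code:08d}"


@dataclass
class CandidateSite:
    """One accepted 34-mer with location, match annotation and scores."""

    window: SiteWindow
    contig_id: str
    contig_offset: int
    chromosome: str
    chrom_linear_pos: int
    match_mask: Mapping[int, bool]
    overall_score: int
    weighted_score: float
    consecutive_score: int
    proximal8_matches: int
    subclass_key: SubclassKey
    canonical_spacer: str

    @property
    def sequence(self) -> str:
        return self.window.sequence

    @property
    def canonical_seq(self) -> str:
        """Lexicographic minimum of the 34-mer and its reverse complement."""
        s = self.window.sequence
        return min(s, revcomp(s))


@dataclass
class DuplicateGroup:
    """Sites sharing one canonical 34-mer irrespective of orientation."""

    canonical_seq: str
    members: list[CandidateSite]

    @property
    def copy_number(self) -> int:
        return len(self.members)


@dataclass
class GenomeLayout:
    """Ordered contig list per chromosome with cumulative linear offsets.

    Emulates the contig sets of a genome build: each chromosome is an
    ordered list of contigs and a site's chromosome-linear coordinate is
    the contig's cumulative offset plus its offset within the contig.
    """

    ordered_contigs: dict[str, list[tuple[str, int]]]

    def __post_init__(self) -> None:
        self._offsets: dict[str, tuple[str, int]] = {}
        for chrom, contigs in self.ordered_contigs.items():
            running = 0
            for contig_id, length in contigs:
                if contig_id in self._offsets:
                    raise ConfigError(f"duplicate contig id {contig_id!r} in layout")
                self._offsets[contig_id] = (chrom, running)
                running += length

    @property
    def chromosomes(self) -> list[str]:
        return list(self.ordered_contigs)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for contigs in self.ordered_contigs.values() for cid, _ in contigs]

    def chromosome_of(self, contig_id: str) -> str:
        return self._offsets[contig_id][0]

    def offset_of(self, contig_id: str) -> int:
        return self._offsets[contig_id][1]

    def linear_pos(self, contig_id: str, contig_offset: int) -> int:
        chrom, off = self._offsets[contig_id]
        return off + contig_offset

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._offsets

    def append_contig(self, chrom: str, contig_id: str, length: int) -> None:
        """Register a contig at the end of a chromosome (used for inputs
        present on disk but absent from the manifest)."""
        contigs = self.ordered_contigs.setdefault(chrom, [])
        running = sum(l for _, l in contigs)
        contigs.append((contig_id, length))
        self._offsets[contig_id] = (chrom, running)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, str, int]]) -> "GenomeLayout":
        """Build from (chromosome, order, contig_id, length) records."""
        per_chrom: dict[str, list[tuple[int, str, int]]] = {}
        for chrom, order, contig_id, length in records:
            per_chrom.setdefault(str(chrom), []).append((int(order), str(contig_id), int(length)))
        ordered = {
            chrom: [(cid, length) for _, cid, length in sorted(rows)]
            for chrom, rows in per_chrom.items()
        }
        return cls(ordered)

    def iter_records(self) -> Iterator[tuple[str, int, str, int]]:
        for chrom, contigs in self.ordered_contigs.items():
            for order, (cid, length) in enumerate(contigs, start=1):
                yield chrom, order, cid, length


# --- Default consensus -----------------------------------------------------

# Wild-type FRT element bases with the experimentally tolerated degeneracy
# at the innermost positions.  Left element read -13..-1, right 1..13.
_LEFT_ALLOWED = ["G", "A", "A", "G", "T", "T", "C", "C", "T", "A", "T", "AT", "CT"]
_RIGHT_ALLOWED = ["AG", "AT", "A", "T", "A", "G", "G", "A", "A", "C", "T", "T", "C"]


def default_consensus() -> ConsensusModel:
    """The default discovery model: wild-type FRT elements with A/G at
    position 1 (C/T at -1) and A/T at positions -2/2, and the standard
    rule thresholds."""
    allowed: dict[int, frozenset[str]] = {}
    for pos, bases in zip(LEFT_POSITIONS, _LEFT_ALLOWED):
        allowed[pos] = frozenset(bases)
    for pos, bases in zip(RIGHT_POSITIONS, _RIGHT_ALLOWED):
        allowed[pos] = frozenset(bases)
    return ConsensusModel(element_allowed=allowed)


# IUPAC degeneracy codes for configuration strings.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_INT_FIELDS = (
    "spacer_max_gc_bases", "min_proximal8_matches",
    "min_element_matches_one_side", "min_consecutive_matches",
    "max_homopolymer_run",
)
_BASE_FIELDS = (
    "spacer_first_base", "spacer_last_base",
    "forbidden_base_minus1", "forbidden_base_plus1",
)
_BOOL_FIELDS = ("position7_rule", "require_run_both_elements")


def _parse_element(name: str, text: str, positions: tuple[int, ...]) -> dict[int, frozenset[str]]:
    text = str(text).strip().upper()
    if len(text) != 13:
        raise ConfigError(f"{name}: element string must be 13 IUPAC characters, got {len(text)}")
    allowed = {}
    for pos, ch in zip(positions, text):
        if ch not in _IUPAC:
            raise ConfigError(f"{name}: invalid IUPAC code {ch!r}")
        allowed[pos] = frozenset(_IUPAC[ch])
    return allowed


def load_consensus(config_text: str | Mapping) -> ConsensusModel:
    """Build a :class:`ConsensusModel` from YAML text or a mapping.

    Recognized keys: ``left_element`` / ``right_element`` (13-character
    IUPAC strings, read -13..-1 and 1..13), the threshold fields of
    :class:`ConsensusModel`, and ``weights`` (position -> weight).
    Unspecified fields fall back to the defaults.
    """
    if isinstance(config_text, str):
        cfg = yaml.safe_load(config_text) or {}
    else:
        cfg = dict(config_text)
    if not isinstance(cfg, Mapping):
        raise ConfigError("consensus config must be a mapping")

    base = default_consensus()
    allowed = dict(base.element_allowed)
    if "left_element" in cfg:
        allowed.update(_parse_element("left_element", cfg.pop("left_element"), LEFT_POSITIONS))
    if "right_element" in cfg:
        allowed.update(_parse_element("right_element", cfg.pop("right_element"), RIGHT_POSITIONS))

    kwargs: dict = {"element_allowed": allowed}
    for name in _INT_FIELDS:
        if name in cfg:
            try:
                kwargs[name] = int(cfg.pop(name))
            except (TypeError, ValueError):
                raise ConfigError(f"{name}: expected an integer") from None
    for name in _BASE_FIELDS:
        if name in cfg:
            val = str(cfg.pop(name)).strip().upper()
            if val not in {"A", "C", "G", "T"}:
                raise ConfigError(f"{name}: expected a single base A/C/G/T, got {val!r}")
            kwargs[name] = val
    for name in _BOOL_FIELDS:
        if name in cfg:
            kwargs[name] = bool(cfg.pop(name))
    if "weights" in cfg:
        raw = cfg.pop("weights")
        if not isinstance(raw, Mapping):
            raise ConfigError("weights: expected a mapping position -> weight")
        weights = {}
        for key, val in raw.items():
            try:
                pos, w = int(key), float(val)
            except (TypeError, ValueError):
                raise ConfigError(f"weights: bad entry {key!r}: {val!r}") from None
            if pos not in ELEMENT_POSITIONS:
                raise ConfigError(f"weights: {pos} is not an element position")
            weights[pos] = w
        kwargs["weights"] = weights
    if cfg:
        raise ConfigError(f"unknown consensus config fields: {sorted(cfg)}")
    return ConsensusModel(**kwargs)
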