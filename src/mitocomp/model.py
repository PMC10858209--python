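"""Domain types for annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout (GenBank convention).  Features
on the light strand store their coordinates on the heavy-strand frame;
sequence extraction reverse-complements on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "MitocompError",
    "ParseError",
    "ValidationError",
    "GeneFeature",
    "AnnotatedMitogenome",
    "revcomp",
    "assign_copy_indices",
    "rotate_genome",
]

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control", "origin", "unknown")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


class MitocompError(Exception):
    """Base class for package errors."""


class ParseError(MitocompError):
    """A file could not be interpreted; the message names the offender."""


class ValidationError(MitocompError):
    """A structural invariant was violated."""


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated element (PCG / tRNA / rRNA / control region / origin).

    ``start``/``end`` are 1-based inclusive on the heavy-strand frame.  A
    feature spanning the circular origin has ``wraps_origin=True`` and
    ``start > end``; its length is ``(L - start + 1) + end``.
    """

    name: str
    start: int
    end: int
    strand: str = "H"
    ftype: str = "unknown"
    raw_name: str = ""
    copy_index: int = 0
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.raw_name:
            self.raw_name = self.name
        if self.strand not in ("H", "L"):
            raise ValidationError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.name}: coordinates must be >= 1")
        if not self.wraps_origin and self.start > self.end:
            raise ValidationError(
                f"{self.name}: start {self.start} > end {self.end} without wrap flag")

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValidationError(f"{self.name}: wrap feature needs genome length")
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1

    def contains(self, other: "GeneFeature",
                 genome_length: int | None = None) -> bool:
        """Whole containment of *other*'s arc within this feature's arc.

        Origin-wrapping features need ``genome_length`` to unroll the circle;
        without it, wrap cases conservatively return False.
        """
        if self.wraps_origin or other.wraps_origin:
            if genome_length is None:
                return False
            L = genome_length
            fs = self.start
            fe = self.end + (L if self.wraps_origin else 0)
            for shift in (0, L):
                os_ = other.start + shift
                oe = other.end + shift + (L if other.wraps_origin else 0)
                if fs <= os_ and oe <= fe and (fs, fe) != (os_, oe):
                    return True
            return False
        return self.start <= other.start and other.end <= self.end and (
            (self.start, self.end) != (other.start, other.end))

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.copy_index)

    def label(self) -> str:
        """Name decorated with the copy index for duplicated features."""
        if self.copy_index:
            return f"{self.name}_{self.copy_index}"
        return self.name


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome: sequence (optional) plus ordered gene features."""

    species: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None
    accession: str = ""
    circular: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.species}: non-positive genome length")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"{self.species}: length {self.length} != sequence length "
                    f"{len(self.sequence)}")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise ValidationError(
                    f"{self.species}: feature {f.name} ({f.start}..{f.end}) "
                    f"beyond genome end {self.length}")

    # -- lookup helpers -------------------------------------------------

    def features_of_class(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def get(self, name: str, copy_index: int = 0) -> GeneFeature:
        for f in self.features:
            if f.name == name and f.copy_index == copy_index:
                return f
        raise KeyError(f"{self.species}: no feature {name} (copy {copy_index})")

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    # -- sequence access ------------------------------------------------

    def h_frame_slice(self, feature: GeneFeature) -> str:
        """Bases covered by *feature* read on the heavy-strand frame.

        Wrap features are concatenated across the origin.  No
        reverse-complementing happens here regardless of strand.
        """
        if self.sequence is None:
            raise ValidationError(f"{self.species}: genome carries no sequence")
        if feature.wraps_origin:
            return self.sequence[feature.start - 1:] + self.sequence[:feature.end]
        return self.sequence[feature.start - 1:feature.end]

    def oriented_slice(self, feature: GeneFeature) -> str:
        """Feature sequence 5'->3' in its own reading orientation."""
        s = self.h_frame_slice(feature)
        return revcomp(s) if feature.strand == "L" else s


def assign_copy_indices(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    """Assign ``copy_index`` per canonical name by ascending start position."""
    feats = list(features)
    by_name: dict[str, list[GeneFeature]] = {}
    for f in feats:
        by_name.setdefault(f.name, []).append(f)
    for group in by_name.values():
        for i, f in enumerate(sorted(group, key=lambda g: (g.start, g.end))):
            f.copy_index = i
    return feats


def rotate_genome(genome: AnnotatedMitogenome, offset: int) -> AnnotatedMitogenome:
    """Rotate the circular origin so old position ``offset + 1`` becomes 1.

    Returns a new genome; the input is untouched.  Features crossing the new
    origin come back flagged ``wraps_origin``.
    """
    L = genome.length
    offset %= L

    def shift(pos: int) -> int:
        return (pos - offset - 1) % L + 1

    feats = []
    for f in genome.features:
        ns, ne = shift(f.start), shift(f.end)
        if f.wraps_origin:
            wraps = ns > ne
        else:
            wraps = ns > ne
        feats.append(replace(f, start=ns, end=ne, wraps_origin=wraps))
    seq = None
    if genome.sequence is not None:
        seq = genome.sequence[offset:] + genome.sequence[:offset]
    return AnnotatedMitogenome(
        species=genome.species, length=L, features=feats, sequence=seq,
        accession=genome.accession, circular=True)
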