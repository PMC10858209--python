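"""Codon-level analytics for mitochondrial protein-coding genes.

Uses the vertebrate mitochondrial genetic code (NCBI translation table 2)
throughout: AGA/AGG are stops, ATA codes Met, TGA codes Trp.  Incomplete
stop codons (a terminal T or TA completed by polyadenylation) are detected
from CDS length modulo 3, never from annotation strings.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

from .model import AnnotatedMitogenome, GeneFeature, ValidationError

__all__ = [
    "GENETIC_CODE_ID",
    "CODON_TABLE",
    "STOP_CODONS",
    "ALL_CODONS",
    "CodingSequence",
    "CodonUsageTable",
    "extract_cds",
    "call_start_stop",
    "count_codons",
    "rscu",
    "degeneracy_classes",
    "family_of_codon",
    "amino_acid_composition",
    "AA_3LETTER",
]

GENETIC_CODE_ID = 2  # vertebrate mitochondrial
CODON_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]
STOP_CODONS = frozenset(CODON_TABLE.stop_codons)
ALL_CODONS = tuple("".join(p) for p in product("TCAG", repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

AA_3LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

_COMPLETENESS = {0: "complete", 2: "TA_incomplete", 1: "T_incomplete"}


@dataclass
class CodingSequence:
    """An oriented (5'->3') protein-coding sequence plus codon bookkeeping."""

    gene: str
    oriented_seq: str
    start_codon: str
    stop_codon: str  # complete 3-mer, "TA-" or "T--"
    completeness: str
    complete_codons: int
    trailing_partial: int
    non_canonical_start: bool = False

    def stop_notation(self) -> str:
        """Stop codon in report notation: TAA, TA(A) or T(AA)."""
        if self.completeness == "TA_incomplete":
            return f"{self.stop_codon[:2]}(A)"
        if self.completeness == "T_incomplete":
            return f"{self.stop_codon[:1]}(AA)"
        return self.stop_codon


def extract_cds(genome: AnnotatedMitogenome, feature: GeneFeature) -> CodingSequence:
    """Pull the coding sequence of a PCG feature out of the genome.

    Light-strand features are reverse-complemented; origin-wrapping features
    are concatenated across the circular origin.
    """
    if feature.ftype != "PCG":
        raise ValidationError(f"{feature.name}: extract_cds expects a PCG feature")
    seq = genome.oriented_slice(feature)
    start, stop, completeness = call_start_stop(seq)
    trailing = len(seq) % 3
    return CodingSequence(
        gene=feature.label(), oriented_seq=seq, start_codon=start,
        stop_codon=stop, completeness=completeness,
        complete_codons=len(seq) // 3, trailing_partial=trailing,
        non_canonical_start=(start != "ATG"))


def call_start_stop(oriented_seq: str) -> tuple[str, str, str]:
    """Classify start and stop codons of an oriented CDS.

    The trailing length (``len mod 3``) decides the completeness class:
    0 -> complete 3-mer stop, 2 -> ``TA-``, 1 -> ``T--``.  A trailing
    residue that is not the expected T/TA is reported as-is with a warning.
    """
    if len(oriented_seq) < 4:
        raise ValidationError("call_start_stop: CDS shorter than 4 nt")
    seq = oriented_seq.upper()
    start = seq[:3]
    trailing = len(seq) % 3
    completeness = _COMPLETENESS[trailing]
    if trailing == 0:
        stop = seq[-3:]
        if stop not in STOP_CODONS:
            warnings.warn(f"complete CDS ends in non-stop codon {stop}", stacklevel=2)
    elif trailing == 2:
        stop = seq[-2:] + "-"
        if seq[-2:] != "TA":
            warnings.warn(f"length=2 (mod 3) CDS ends in {seq[-2:]!r}, not TA",
                          stacklevel=2)
    else:
        stop = seq[-1:] + "--"
        if seq[-1:] != "T":
            warnings.warn(f"length=1 (mod 3) CDS ends in {seq[-1:]!r}, not T",
                          stacklevel=2)
    return start, stop, completeness


@dataclass
class CodonUsageTable:
    """Codon counts over complete codons, stop codons excluded from totals."""

    counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)
    n_ambiguous: int = 0
    genetic_code_id: int = GENETIC_CODE_ID

    @property
    def total_codons_excluding_stops(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_list) -> CodonUsageTable:
    """Count complete codons across coding sequences.

    Complete stop codons are tallied apart and excluded from the total;
    trailing partial nucleotides are ignored; codons containing ambiguity
    characters are excluded and counted in ``n_ambiguous``.
    """
    table = CodonUsageTable()
    for cds in cds_list:
        seq = cds.oriented_seq.upper() if isinstance(cds, CodingSequence) else cds.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if any(b not in "ACGT" for b in codon):
                table.n_ambiguous += 1
            elif codon in STOP_CODONS:
                table.stop_counts[codon] += 1
            else:
                table.counts[codon] += 1
    return table


def degeneracy_classes() -> dict[str, tuple[str, ...]]:
    """Synonymous-codon families derived from the genetic code table.

    Amino acids whose codons span more than one first-two-base box split
    into numbered families -- under table 2 that is Leu (Leu1 = CTN 4-fold,
    Leu2 = TTR 2-fold) and Ser (Ser1 = AGY 2-fold, Ser2 = TCN 4-fold).
    Every sense codon lands in exactly one family.
    """
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(CODON_TABLE.forward_table[codon], []).append(codon)

    special = {("L", "CT"): "Leu1", ("L", "TT"): "Leu2",
               ("S", "AG"): "Ser1", ("S", "TC"): "Ser2"}
    families: dict[str, tuple[str, ...]] = {}
    for aa, codons in sorted(by_aa.items()):
        boxes = sorted({c[:2] for c in codons})
        if len(boxes) == 1:
            families[AA_3LETTER[aa]] = tuple(sorted(codons))
        else:
            for i, box in enumerate(boxes, start=1):
                name = special.get((aa, box), f"{AA_3LETTER[aa]}{i}")
                families[name] = tuple(sorted(c for c in codons if c[:2] == box))
    return families


_FAMILIES = None


def family_of_codon(codon: str) -> str:
    """Family name for a sense codon (raises KeyError for stop codons)."""
    global _FAMILIES
    if _FAMILIES is None:
        _FAMILIES = {c: name for name, cods in degeneracy_classes().items()
                     for c in cods}
    return _FAMILIES[codon]


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    ``RSCU(c) = count(c) * k / sum(family counts)`` for a family of size
    ``k``; families with zero total get 0 for every member.
    """
    values: dict[str, float] = {}
    for family, codons in degeneracy_classes().items():
        total = sum(table.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = (table.counts.get(c, 0) * k / total) if total else 0.0
    return values


def amino_acid_composition(table: CodonUsageTable, split: bool = True) -> dict[str, float]:
    """Amino-acid percentages over all counted (non-stop) codons.

    With ``split=True`` Leu and Ser report per sub-family (Leu1/Leu2,
    Ser1/Ser2); otherwise merged under Leu/Ser.
    """
    total = table.total_codons_excluding_stops
    out: dict[str, float] = {}
    for family, codons in degeneracy_classes().items():
        name = family
        if not split:
            name = family.rstrip("12") if family[:3] in ("Leu", "Ser") else family
        count = sum(table.counts.get(c, 0) for c in codons)
        pct = 100.0 * count / total if total else 0.0
        out[name] = out.get(name, 0.0) + pct
    return out
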