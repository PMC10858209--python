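"""Linearized signed gene orders, duplication census, and order comparison.

Orders are rotation-invariant: features are sorted by start position on the
circle and rotated so a fixed anchor (trnF by default) comes first.  The
breakpoint distance counts adjacencies present in one order but not the
other, computed on the tokens that occur exactly once in both genomes;
duplications are censused separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model import AnnotatedMitogenome, ValidationError

__all__ = [
    "GeneOrder",
    "DuplicationReport",
    "extract_gene_order",
    "detect_duplications",
    "breakpoint_distance",
    "order_comparison_report",
]


@dataclass(frozen=True)
class OrderToken:
    name: str
    strand: str
    copy_index: int

    def __str__(self) -> str:
        sign = "-" if self.strand == "L" else ""
        suffix = f"_{self.copy_index}" if self.copy_index else ""
        return f"{sign}{self.name}{suffix}"


@dataclass
class GeneOrder:
    species: str
    tokens: tuple[OrderToken, ...]

    def token_string(self) -> str:
        return " ".join(str(t) for t in self.tokens)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneOrder) and self.tokens == other.tokens


@dataclass
class DuplicationEntry:
    name: str
    n_copies: int
    spans: list[tuple[int, int]]
    region_class: str


DuplicationReport = list  # list[DuplicationEntry]


def extract_gene_order(genome: AnnotatedMitogenome, anchor: str = "trnF",
                       classes: tuple[str, ...] | None = None) -> GeneOrder:
    """Rotation-invariant token list for a genome.

    Every feature appears exactly once (optionally restricted to ``classes``).
    If the anchor is missing, the lowest-start feature is used with a warning.
    """
    import warnings

    feats = [f for f in genome.features
             if classes is None or f.ftype in classes]
    if not feats:
        raise ValidationError(f"{genome.species}: no features for gene order")
    feats = sorted(feats, key=lambda f: (f.start, f.end))
    names = [f.name for f in feats]
    if anchor in names:
        idx = next(i for i, f in enumerate(feats)
                   if f.name == anchor and f.copy_index == 0)
    else:
        warnings.warn(f"{genome.species}: anchor {anchor!r} absent, "
                      "starting from lowest-start feature", stacklevel=2)
        idx = 0
    rotated = feats[idx:] + feats[:idx]
    return GeneOrder(species=genome.species, tokens=tuple(
        OrderToken(f.name, f.strand, f.copy_index) for f in rotated))


def detect_duplications(genome: AnnotatedMitogenome) -> DuplicationReport:
    """Features whose canonical name occurs more than once."""
    groups: dict[str, list] = {}
    for f in genome.features:
        groups.setdefault(f.name, []).append(f)
    report = []
    for name, feats in groups.items():
        if len(feats) < 2:
            continue
        feats = sorted(feats, key=lambda f: f.start)
        report.append(DuplicationEntry(
            name=name, n_copies=len(feats),
            spans=[(f.start, f.end) for f in feats],
            region_class=feats[0].ftype))
    report.sort(key=lambda e: e.spans[0][0])
    return report


def _single_copy_reduction(a: GeneOrder, b: GeneOrder):
    ca = Counter(t.name for t in a.tokens)
    cb = Counter(t.name for t in b.tokens)
    shared = {n for n in ca if ca[n] == 1 and cb.get(n, 0) == 1}
    ra = [t for t in a.tokens if t.name in shared]
    rb = [t for t in b.tokens if t.name in shared]
    return ra, rb


def _adjacency_set(tokens) -> set[frozenset]:
    n = len(tokens)
    adj = set()
    for i in range(n):
        t, u = tokens[i], tokens[(i + 1) % n]
        adj.add(frozenset(((t.name, t.strand), (u.name, u.strand))))
    return adj


def breakpoint_distance(order_a: GeneOrder, order_b: GeneOrder) -> int:
    """Number of circular adjacencies of A absent from B (symmetric).

    Both orders are first reduced to the tokens shared as single copies;
    fewer than 3 shared tokens is an error.
    """
    ra, rb = _single_copy_reduction(order_a, order_b)
    if len(ra) < 3:
        raise ValidationError(
            f"breakpoint_distance: only {len(ra)} shared single-copy tokens "
            f"between {order_a.species!r} and {order_b.species!r}")
    return len(_adjacency_set(ra) - _adjacency_set(rb))


def order_comparison_report(genomes, anchor: str = "trnF",
                            classes: tuple[str, ...] | None = None):
    """Group genomes by identical gene order and emit a pairwise breakpoint
    matrix.  Returns ``(groups, distance DataFrame)`` where ``groups`` maps a
    token string to the list of species sharing it."""
    import pandas as pd

    if len(genomes) < 2:
        raise ValidationError("order_comparison_report: need >= 2 genomes")
    orders = [extract_gene_order(g, anchor=anchor, classes=classes)
              for g in genomes]
    groups: dict[str, list[str]] = {}
    for o in orders:
        groups.setdefault(o.token_string(), []).append(o.species)
    names = [o.species for o in orders]
    mat = [[breakpoint_distance(a, b) if i != j else 0
            for j, b in enumerate(orders)] for i, a in enumerate(orders)]
    return groups, pd.DataFrame(mat, index=names, columns=names)
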