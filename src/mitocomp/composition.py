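"""Base composition and strand-asymmetry (AT/GC skew) statistics.

Skews are ``(A - T) / (A + T)`` and ``(G - C) / (G + C)``.  Per-region rows
concatenate same-class features in genomic order read on the heavy-strand
frame (no reverse-complementing of L-strand genes), so every genome yields
one comparable row per region class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import AnnotatedMitogenome, ValidationError

__all__ = [
    "CompositionProfile",
    "SkewResult",
    "base_composition",
    "skew",
    "skew_from_percentages",
    "region_composition_report",
    "REGION_CLASSES",
]

REGION_CLASSES = ("whole", "PCG", "rRNA", "tRNA", "CR")

_BASES = ("A", "C", "G", "T")


@dataclass
class CompositionProfile:
    """Counts and percentages of the four unambiguous bases.

    ``n_effective`` excludes N and other IUPAC ambiguity codes, which are
    tallied in ``n_ambiguous``.
    """

    counts: dict[str, int]
    n_effective: int
    n_ambiguous: int = 0
    region_class: str = "whole"

    def percent(self, base: str) -> float:
        if self.n_effective == 0:
            return math.nan
        return 100.0 * self.counts.get(base, 0) / self.n_effective

    @property
    def percentages(self) -> dict[str, float]:
        return {b: self.percent(b) for b in _BASES}


@dataclass
class SkewResult:
    at_skew: float
    gc_skew: float
    at_percent: float
    gc_percent: float
    at_defined: bool = True
    gc_defined: bool = True

    def rounded(self) -> "SkewResult":
        """Report rounding: percentages to 2 decimals, skews to 3."""
        return SkewResult(
            at_skew=round(self.at_skew, 3) if self.at_defined else math.nan,
            gc_skew=round(self.gc_skew, 3) if self.gc_defined else math.nan,
            at_percent=round(self.at_percent, 2),
            gc_percent=round(self.gc_percent, 2),
            at_defined=self.at_defined, gc_defined=self.gc_defined)


def base_composition(sequence: str, region_class: str = "whole") -> CompositionProfile:
    """Count bases case-insensitively; ambiguity codes are excluded from
    ``n_effective`` and reported separately."""
    if not sequence:
        raise ValidationError("base_composition: empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in _BASES}
    n_eff = sum(counts.values())
    return CompositionProfile(counts=counts, n_effective=n_eff,
                              n_ambiguous=len(seq) - n_eff,
                              region_class=region_class)


def _skew(x: float, y: float) -> tuple[float, bool]:
    denom = x + y
    if denom == 0:
        return math.nan, False
    return (x - y) / denom, True


def skew(profile: CompositionProfile) -> SkewResult:
    """Skews from a composition profile; zero denominators are flagged
    undefined instead of raising."""
    a, c, g, t = (profile.counts.get(b, 0) for b in _BASES)
    at, at_ok = _skew(a, t)
    gc, gc_ok = _skew(g, c)
    n = profile.n_effective
    at_pct = 100.0 * (a + t) / n if n else math.nan
    gc_pct = 100.0 * (g + c) / n if n else math.nan
    return SkewResult(at_skew=at, gc_skew=gc, at_percent=at_pct,
                      gc_percent=gc_pct, at_defined=at_ok, gc_defined=gc_ok)


def skew_from_percentages(a: float, c: float, g: float, t: float) -> SkewResult:
    """Skews straight from printed percentages (identical formulas)."""
    at, at_ok = _skew(a, t)
    gc, gc_ok = _skew(g, c)
    return SkewResult(at_skew=at, gc_skew=gc, at_percent=a + t,
                      gc_percent=g + c, at_defined=at_ok, gc_defined=gc_ok)


@dataclass
class RegionRow:
    region_class: str
    region_length: int
    profile: CompositionProfile | None
    skews: SkewResult | None


def region_composition_report(genome: AnnotatedMitogenome) -> list[RegionRow]:
    """One row per region class (whole / PCG / rRNA / tRNA / CR).

    Region sequences are concatenations, in genomic order, of same-class
    features taken on the heavy-strand frame; overlapping same-class features
    contribute each base once per feature.  A missing class yields a row with
    length 0 and undefined statistics.
    """
    if genome.sequence is None:
        raise ValidationError(f"{genome.species}: composition needs a sequence")
    class_map = {"PCG": "PCG", "rRNA": "rRNA", "tRNA": "tRNA", "CR": "control"}
    rows = [
        _region_row("whole", genome.sequence),
    ]
    order = sorted(genome.features, key=lambda f: (f.start, f.end))
    for region, ftype in class_map.items():
        chunks = [genome.h_frame_slice(f) for f in order if f.ftype == ftype]
        rows.append(_region_row(region, "".join(chunks)))
    return rows


def _region_row(region: str, seq: str) -> RegionRow:
    if not seq:
        return RegionRow(region_class=region, region_length=0,
                         profile=None, skews=None)
    prof = base_composition(seq, region_class=region)
    return RegionRow(region_class=region, region_length=len(seq),
                     profile=prof, skews=skew(prof))


def report_frame(genomes) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate region rows for one or more genomes (TSV-ready)."""
    import pandas as pd
    records = []
    for g in genomes:
        for row in region_composition_report(g):
            rec = {"species": g.species, "region": row.region_class,
                   "length": row.region_length}
            if row.skews is not None:
                s = row.skews.rounded()
                rec.update({"GC%": s.gc_percent, "AT%": s.at_percent,
                            "GC_skew": s.gc_skew, "AT_skew": s.at_skew})
            else:
                rec.update({"GC%": math.nan, "AT%": math.nan,
                            "GC_skew": math.nan, "AT_skew": math.nan})
            records.append(rec)
    return pd.DataFrame(records)
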