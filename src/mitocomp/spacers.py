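"""Signed inter-feature distances on the circular genome.

For consecutive features the signed gap is ``start(next) - end(prev) - 1``:
positive = intergenic spacer (IGS), negative = overlap, zero = abutting.
The chain closes circularly from the last feature back to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnnotatedMitogenome, GeneFeature, ValidationError

__all__ = [
    "GapRecord",
    "SpacerSummary",
    "build_gap_chain",
    "compute_gaps",
    "genome_gaps",
    "summarize_spacers",
    "compare_spacers",
    "CHAIN_POLICIES",
]

CHAIN_POLICIES = ("exclude-container", "keep-all")


@dataclass
class GapRecord:
    """Signed distance between two chain-adjacent features."""

    upstream: str
    downstream: str
    signed_length: int
    wraps_origin: bool = False
    upstream_key: tuple[str, int] = ("", 0)
    downstream_key: tuple[str, int] = ("", 0)

    @property
    def is_igs(self) -> bool:
        return self.signed_length > 0

    @property
    def is_overlap(self) -> bool:
        return self.signed_length < 0

    @property
    def pair(self) -> str:
        return f"{self.upstream}/{self.downstream}"


@dataclass
class SpacerSummary:
    n_igs: int
    total_igs_bp: int
    longest_igs_bp: int
    longest_igs_pair: str
    n_overlaps: int
    overlap_lengths: list[int] = field(default_factory=list)
    longest_is_tie: bool = False

    @property
    def overlap_range(self) -> tuple[int, int]:
        if not self.overlap_lengths:
            return (0, 0)
        mags = sorted(abs(x) for x in self.overlap_lengths)
        return (mags[0], mags[-1])


def build_gap_chain(genome: AnnotatedMitogenome,
                    policy: str = "exclude-container") -> list[GeneFeature]:
    """Order the features that participate in gap accounting.

    Under ``exclude-container`` (the default) a control-region feature that
    wholly contains another annotated feature is dropped from the chain --
    that removes a D-loop umbrella annotation while keeping the OH feature
    inside it.  ``keep-all`` keeps everything.  Two features with identical
    spans are an error.
    """
    if policy not in CHAIN_POLICIES:
        raise ValidationError(f"unknown chain policy {policy!r}")
    feats = list(genome.features)
    if not feats:
        raise ValidationError(f"{genome.species}: cannot chain an empty feature set")

    spans: dict[tuple[int, int], GeneFeature] = {}
    for f in feats:
        key = (f.start, f.end)
        if key in spans:
            raise ValidationError(
                f"{genome.species}: features {spans[key].raw_name!r} and "
                f"{f.raw_name!r} have identical spans {key}")
        spans[key] = f

    if policy == "exclude-container":
        feats = [f for f in feats
                 if not (f.ftype == "control"
                         and any(f.contains(g, genome.length)
                                 for g in genome.features if g is not f))]
        if not feats:  # chain must keep at least the container itself
            feats = list(genome.features)

    # Wrap features sort to the end of the circle by their start coordinate.
    return sorted(feats, key=lambda f: (f.start, f.end))


def compute_gaps(chain: list[GeneFeature], genome_length: int) -> list[GapRecord]:
    """One signed GapRecord per adjacent pair, including the circular wrap."""
    if not chain:
        return []
    records: list[GapRecord] = []
    n = len(chain)
    for i in range(n):
        up, down = chain[i], chain[(i + 1) % n]
        wrap = (i == n - 1)
        if wrap:
            if up.wraps_origin:
                gap = down.start - up.end - 1
            else:
                gap = (genome_length - up.end) + down.start - 1
            if n == 1:
                gap = genome_length - up.length(genome_length)
        else:
            gap = down.start - up.end - 1
        records.append(GapRecord(
            upstream=up.label(), downstream=down.label(), signed_length=gap,
            wraps_origin=wrap, upstream_key=up.key, downstream_key=down.key))
    return records


def genome_gaps(genome: AnnotatedMitogenome,
                policy: str = "exclude-container") -> list[GapRecord]:
    """Convenience: chain then compute gaps for one genome."""
    return compute_gaps(build_gap_chain(genome, policy=policy), genome.length)


def summarize_spacers(gaps: list[GapRecord]) -> SpacerSummary:
    """Counts, totals and the longest spacer (ties broken by genomic order
    and flagged)."""
    igs = [g for g in gaps if g.is_igs]
    overlaps = [g.signed_length for g in gaps if g.is_overlap]
    if igs:
        longest = max(g.signed_length for g in igs)
        winners = [g for g in igs if g.signed_length == longest]
        pair = winners[0].pair
        tie = len(winners) > 1
    else:
        longest, pair, tie = 0, "", False
    return SpacerSummary(
        n_igs=len(igs), total_igs_bp=sum(g.signed_length for g in igs),
        longest_igs_bp=longest, longest_igs_pair=pair,
        n_overlaps=len(overlaps), overlap_lengths=overlaps,
        longest_is_tie=tie)


def compare_spacers(genomes, policy: str = "exclude-container"):
    """Per-species spacer/overlap table plus the count of gap boundaries
    (upstream/downstream name pairs) conserved across all genomes.

    Returns ``(DataFrame, conserved_boundary_count)``.
    """
    import pandas as pd

    if not genomes:
        raise ValidationError("compare_spacers: need at least one genome")
    rows = []
    boundary_sets = []
    for g in genomes:
        gaps = genome_gaps(g, policy=policy)
        s = summarize_spacers(gaps)
        lo, hi = s.overlap_range
        rows.append({
            "species": g.species,
            "total_igs_bp": s.total_igs_bp,
            "n_igs": s.n_igs,
            "longest_igs_bp": s.longest_igs_bp,
            "longest_igs_region": s.longest_igs_pair,
            "n_overlaps": s.n_overlaps,
            "overlap_range": f"-{lo} to -{hi}" if s.n_overlaps else "",
        })
        boundary_sets.append({(r.upstream, r.downstream) for r in gaps})
    conserved = set.intersection(*boundary_sets) if boundary_sets else set()
    df = pd.DataFrame(rows)
    df["conserved_boundaries"] = len(conserved)
    return df, len(conserved)
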