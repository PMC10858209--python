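"""Synthetic annotated mitogenomes with full ground truth.

The generator lays a planned feature chain onto a circle, realizes signed
inter-feature gaps exactly, draws sequence towards per-region composition
targets, writes protein-coding genes codon-aware (configured start codon, a
complete or incomplete stop, no internal in-frame stops), and can plant a
control-region tandem repeat with per-copy point mutations.  Everything is
driven by one seeded generator, so a seed reproduces the genome byte for
byte.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .codons import STOP_CODONS
from .model import (AnnotatedMitogenome, GeneFeature, ValidationError,
                    assign_copy_indices, revcomp)
from .names import normalize_gene_name

__all__ = [
    "GenePlanEntry",
    "RepeatPlan",
    "SimulationConfig",
    "GroundTruth",
    "generate_mitogenome",
    "make_family",
    "dussumieri_config",
    "canonical_config",
    "default_config",
    "random_sequence",
    "targets_from_skew",
]

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, n: int,
                    probs: tuple[float, float, float, float]) -> str:
    """i.i.d. nucleotide string with P(A), P(C), P(G), P(T) = ``probs``."""
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(_BASES, size=n, p=p))


def targets_from_skew(gc_pct: float, at_pct: float,
                      gc_skew: float, at_skew: float) -> tuple[float, float, float, float]:
    """Invert GC%/AT% plus skews into (pA, pC, pG, pT) fractions."""
    g = gc_pct * (1 + gc_skew) / 2
    c = gc_pct * (1 - gc_skew) / 2
    a = at_pct * (1 + at_skew) / 2
    t = at_pct * (1 - at_skew) / 2
    tot = a + c + g + t
    return (a / tot, c / tot, g / tot, t / tot)


#: Per-region composition targets (fractions A, C, G, T) mimicking a
#: teleost mitogenome: AT-rich overall, strongly negative whole-genome
#: GC skew, AT-rich control region.
DEFAULT_COMPOSITION = {
    "whole": (0.2968, 0.2790, 0.1553, 0.2687),
    "PCG": targets_from_skew(43.64, 56.31, -0.311, -0.053),
    "rRNA": targets_from_skew(45.11, 54.89, -0.111, 0.251),
    "tRNA": targets_from_skew(43.89, 56.11, 0.042, 0.029),
    "control": targets_from_skew(34.65, 65.35, -0.194, 0.088),
}


@dataclass
class GenePlanEntry:
    """One planned feature: name, length, strand, and (for PCGs) codons.

    ``stop`` is a complete stop codon ("TAA"/"TAG") or an incomplete class
    ("TA-" or "T--"); it must be consistent with ``length mod 3``.
    """

    name: str
    length: int
    strand: str = "H"
    start_codon: str = "ATG"
    stop: str = "TAA"
    ftype: str = ""

    def __post_init__(self):
        if not self.ftype:
            canonical, ftype = normalize_gene_name(self.name)
            self.ftype = ftype
            self.name = canonical if ftype != "unknown" else self.name

    @property
    def trailing(self) -> int:
        return {"TA-": 2, "T--": 1}.get(self.stop, 0)


@dataclass
class RepeatPlan:
    period: int = 131
    copies: float = 2.4
    divergence: float = 0.03
    offset: int = 20  # from the control-region start

    @property
    def span_length(self) -> int:
        return int(round(self.period * self.copies))


@dataclass
class SimulationConfig:
    seed: int = 0
    species: str = "Simulatus mitogenomus"
    gene_plan: list[GenePlanEntry] = field(default_factory=list)
    #: signed gap after each plan entry; the last entry's gap wraps the origin
    gap_plan: list[int] = field(default_factory=list)
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    repeat: RepeatPlan | None = None
    #: overlay an umbrella control-region feature from the end of the feature
    #: preceding OH to genome length - 1 (mirrors D-loop-over-OH annotations)
    cr_overlay: bool = False
    genome_length: int | None = None

    def copy(self) -> "SimulationConfig":
        return copy.deepcopy(self)


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from the emitted genome."""

    seed: int
    species: str
    genome_length: int
    features: list[GeneFeature]
    gaps: list[tuple[str, str, int]]          # (upstream, downstream, signed)
    composition: dict                          # region -> base counts
    start_stops: dict                          # gene label -> (start, stop)
    repeat: dict | None                        # planted repeat record
    duplications: list[tuple[str, int]]

    def to_json(self) -> str:
        d = {
            "seed": self.seed, "species": self.species,
            "genome_length": self.genome_length,
            "features": [asdict(f) for f in self.features],
            "gaps": self.gaps, "composition": self.composition,
            "start_stops": self.start_stops, "repeat": self.repeat,
            "duplications": self.duplications,
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# stock plans
# ---------------------------------------------------------------------------

# (name, length, strand, start, stop, gap-after) for a circular teleost-style
# mitogenome; gaps realize 17 spacers (899 bp, longest 495) and 7 overlaps.
_CHAIN = [
    ("trnF",  68, "H", "", "", 0),
    ("rrnS", 948, "H", "", "", 0),
    ("trnV",  72, "H", "", "", 51),
    ("rrnL", 1640, "H", "", "", 8),
    ("trnL2", 75, "H", "", "", 0),
    ("ND1",  975, "H", "ATG", "TAA", 4),
    ("trnI",  70, "H", "", "", -1),
    ("trnQ",  71, "L", "", "", -1),
    ("trnM",  69, "H", "", "", 0),
    ("ND2", 1047, "H", "ATG", "TAA", 0),
    ("trnW",  71, "H", "", "", 2),
    ("trnA",  69, "L", "", "", 1),
    ("trnN",  73, "L", "", "", 4),
    ("OL",    31, "H", "", "", 0),
    ("trnC",  65, "L", "", "", 0),
    ("trnY",  71, "L", "", "", 1),
    ("COI", 1554, "H", "GTG", "TAA", 0),
    ("trnS2", 71, "L", "", "", 3),
    ("trnD",  72, "H", "", "", 4),
    ("COII", 691, "H", "ATG", "T--", 0),
    ("trnK",  76, "H", "", "", 1),
    ("ATP8", 165, "H", "ATG", "TAG", -7),
    ("ATP6", 686, "H", "ATG", "TA-", 117),
    ("COIII", 653, "H", "ATG", "TA-", 14),
    ("trnG",  72, "H", "", "", 0),
    ("ND3",  351, "H", "ATG", "TAG", -2),
    ("trnR",  69, "H", "", "", 0),
    ("ND4L", 297, "H", "ATG", "TAA", -7),
    ("ND4", 1381, "H", "ATG", "T--", 0),
    ("trnH",  69, "H", "", "", 0),
    ("trnS1", 68, "H", "", "", 3),
    ("trnL1", 73, "H", "", "", 0),
    ("ND5", 1839, "H", "ATG", "TAA", -4),
    ("ND6",  525, "L", "ATG", "TAG", -3),
    ("trnE",  69, "L", "", "", 5),
    ("CYTB", 1141, "H", "ATG", "T--", 0),
    ("trnT",  73, "H", "", "", 1),
    ("trnP",  70, "L", "", "", 495),
    ("OH",   331, "H", "", "", 185),
]


def _entries(rows) -> tuple[list[GenePlanEntry], list[int]]:
    entries, gaps = [], []
    for name, length, strand, start, stop, gap in rows:
        entries.append(GenePlanEntry(name=name, length=length, strand=strand,
                                     start_codon=start or "ATG",
                                     stop=stop or "TAA"))
        gaps.append(gap)
    return entries, gaps


def dussumieri_config(seed: int = 0, repeat: RepeatPlan | None = None,
                      species: str = "Simulatus dussumieroides") -> SimulationConfig:
    """A 16,685 bp plan mirroring the packaged coordinate fixture: 37 genes
    plus OL and OH on the chain and a control-region umbrella overlay."""
    entries, gaps = _entries(_CHAIN)
    return SimulationConfig(seed=seed, species=species, gene_plan=entries,
                            gap_plan=gaps, repeat=repeat, cr_overlay=True,
                            genome_length=16_685)


def canonical_config(seed: int = 0, repeat: RepeatPlan | None = None,
                     cr_length: int = 1010,
                     species: str = "Simulatus canonicus") -> SimulationConfig:
    """Canonical plan with an explicit CR chain feature and no OH/overlay."""
    rows = [r for r in _CHAIN if r[0] != "OH"]
    entries, gaps = _entries(rows)
    gaps[-1] = 0  # trnP abuts the control region
    entries.append(GenePlanEntry(name="CR", length=cr_length))
    gaps.append(1)  # small wrap spacer back to trnF
    return SimulationConfig(seed=seed, species=species, gene_plan=entries,
                            gap_plan=gaps, repeat=repeat)


def default_config(seed: int = 0) -> SimulationConfig:
    """Canonical plan with a planted 131 bp x 2.4 control-region repeat."""
    return canonical_config(seed=seed, repeat=RepeatPlan())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _validate(config: SimulationConfig) -> int:
    if not config.gene_plan:
        raise ValidationError("simulation: empty gene plan")
    if len(config.gap_plan) != len(config.gene_plan):
        raise ValidationError("simulation: gap plan length must match gene plan")
    pos = 1
    for entry, gap in zip(config.gene_plan, config.gap_plan):
        if entry.length < 1:
            raise ValidationError(f"simulation: {entry.name} has non-positive length")
        if entry.ftype == "PCG":
            if entry.length % 3 != entry.trailing:
                raise ValidationError(
                    f"simulation: {entry.name} length {entry.length} inconsistent "
                    f"with stop class {entry.stop!r}")
            if entry.length < 9:
                raise ValidationError(f"simulation: PCG {entry.name} too short")
        pos += entry.length + gap
        if pos < 2:
            raise ValidationError("simulation: negative residual length in plan")
    L = pos - 1
    if config.gap_plan[-1] < 0:
        raise ValidationError("simulation: wrap gap must be non-negative")
    if config.genome_length is not None and config.genome_length != L:
        raise ValidationError(
            f"simulation: plan realizes {L} bp, config says {config.genome_length}")
    return L


def _layout(config: SimulationConfig) -> list[GeneFeature]:
    feats = []
    pos = 1
    for entry, gap in zip(config.gene_plan, config.gap_plan):
        start = pos
        end = start + entry.length - 1
        feats.append(GeneFeature(name=entry.name, start=start, end=end,
                                 strand=entry.strand, ftype=entry.ftype,
                                 raw_name=entry.name))
        pos = end + gap + 1
    return feats


def _pcg_coding(entry: GenePlanEntry, rng: np.random.Generator,
                probs) -> str:
    n_codons = entry.length // 3
    n_internal = n_codons - 1 - (1 if entry.trailing == 0 else 0)
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    parts = [entry.start_codon]
    for _ in range(n_internal):
        while True:
            codon = "".join(rng.choice(_BASES, size=3, p=p))
            if codon not in STOP_CODONS:
                break
        parts.append(codon)
    if entry.trailing == 0:
        parts.append(entry.stop)
    elif entry.trailing == 2:
        parts.append("TA")
    else:
        parts.append("T")
    seq = "".join(parts)
    assert len(seq) == entry.length
    return seq


def _forced_positions(entry: GenePlanEntry, feat: GeneFeature) -> dict[int, str]:
    """H-frame 0-based positions pinned by the start and stop codons."""
    forced: dict[int, str] = {}
    s, e = feat.start - 1, feat.end - 1
    if entry.strand == "H":
        for k, b in enumerate(entry.start_codon):
            forced[s + k] = b
        if entry.trailing == 0:
            tail = entry.stop
        elif entry.trailing == 2:
            tail = "TA"
        else:
            tail = "T"
        for k, b in enumerate(tail):
            forced[e - len(tail) + 1 + k] = b
    else:
        rc_start = revcomp(entry.start_codon)
        for k, b in enumerate(rc_start):
            forced[e - 2 + k] = b
        tail = entry.stop if entry.trailing == 0 else ("TA" if entry.trailing == 2 else "T")
        rc_tail = revcomp(tail)
        for k, b in enumerate(rc_tail):
            forced[s + k] = b
    return forced


def _plant_repeat(plan: RepeatPlan, rng: np.random.Generator, probs,
                  region_start: int, region_limit: int):
    """Build the repeat string; returns (h_start_0based, text, copies, truth)."""
    span = plan.span_length
    start0 = region_start - 1 + plan.offset
    if start0 + span > region_limit:
        raise ValidationError(
            f"simulation: repeat span {span} bp does not fit in the control "
            f"region segment ({region_start}..{region_limit})")
    motif = random_sequence(rng, plan.period, probs)
    full, partial = divmod(span, plan.period)
    copies = [motif]
    # deterministic mutation count per copy (random placement) so the
    # realized divergence equals the configured one instead of a binomial
    # draw whose tails would defeat recovery-tolerance guarantees
    k = int(round(plan.period * plan.divergence))
    for _ in range(full - 1 + (1 if partial else 0)):
        c = list(motif)
        for pos in rng.choice(plan.period, size=min(k, plan.period), replace=False):
            alts = [b for b in "ACGT" if b != c[pos]]
            c[pos] = alts[rng.integers(3)]
        copies.append("".join(c))
    text = "".join(copies[:full]) + (copies[-1][:partial] if partial else "")
    # truth identity: mean pairwise ungapped identity over realized copies
    cut = copies[:full] + ([copies[-1][:partial]] if partial else [])
    idents = []
    for i in range(len(cut)):
        for j in range(i + 1, len(cut)):
            m = min(len(cut[i]), len(cut[j]))
            idents.append(sum(a == b for a, b in zip(cut[i][:m], cut[j][:m])) / m)
    truth = {
        "span_start": start0 + 1, "span_end": start0 + span,
        "period": plan.period, "copy_number": round(span / plan.period, 3),
        "divergence": plan.divergence, "motif": motif,
        "mean_copy_identity": round(float(np.mean(idents)), 4) if idents else 1.0,
    }
    return start0, text, truth


def generate_mitogenome(config: SimulationConfig
                        ) -> tuple[AnnotatedMitogenome, GroundTruth]:
    """Realize a config into an annotated genome plus its ground truth."""
    L = _validate(config)
    rng = np.random.default_rng(config.seed)
    feats = _layout(config)
    comp = config.composition

    seq = np.array(list(random_sequence(rng, L, comp["whole"])), dtype="U1")

    overlay = None
    if config.cr_overlay:
        oh_idx = next((i for i, f in enumerate(feats) if f.name == "OH"), None)
        if oh_idx is None or oh_idx == 0:
            raise ValidationError("simulation: cr_overlay needs an OH chain feature")
        ov_start = feats[oh_idx - 1].end + 1
        ov_end = L - 1
        overlay = GeneFeature(name="CR", start=ov_start, end=ov_end,
                              ftype="control", raw_name="D-loop")
        seq[ov_start - 1:ov_end] = list(random_sequence(
            rng, ov_end - ov_start + 1, comp["control"]))

    start_stops: dict[str, tuple[str, str]] = {}
    pcg_entries: list[tuple[GenePlanEntry, GeneFeature]] = []
    for entry, feat in zip(config.gene_plan, feats):
        probs = comp.get(entry.ftype, comp["whole"])
        if entry.ftype == "PCG":
            coding = _pcg_coding(entry, rng, comp["PCG"])
            content = revcomp(coding) if entry.strand == "L" else coding
            pcg_entries.append((entry, feat))
        else:
            content = random_sequence(rng, entry.length, probs)
        seq[feat.start - 1:feat.end] = list(content)

    repeat_truth = None
    repeat_span0: tuple[int, int] | None = None
    if config.repeat is not None:
        if overlay is not None:
            oh = next(f for f in feats if f.name == "OH")
            region_start, region_limit = overlay.start, oh.start - 1
        else:
            crs = [f for f in feats if f.ftype == "control"]
            if not crs:
                raise ValidationError("simulation: repeat plan needs a control region")
            region_start, region_limit = crs[0].start, crs[0].end
        start0, text, repeat_truth = _plant_repeat(
            config.repeat, rng, comp["control"], region_start, region_limit)
        seq[start0:start0 + len(text)] = list(text)
        repeat_span0 = (start0, start0 + len(text) - 1)
        # the random flank may continue the periodic matching by chance;
        # the realized tandem span (what a scanner can see) includes it
        p = config.repeat.period
        lo, hi = repeat_span0
        while lo - 1 >= region_start - 1 and seq[lo - 1] == seq[lo - 1 + p]:
            lo -= 1
        while hi + 1 <= region_limit - 1 and seq[hi + 1] == seq[hi + 1 - p]:
            hi += 1
        repeat_truth.update({
            "span_start": lo + 1, "span_end": hi + 1,
            "copy_number": round((hi - lo + 1) / p, 3),
        })

    # pin start/stop codons last so overlapping neighbours cannot clobber them
    forced: dict[int, str] = {}
    for entry, feat in pcg_entries:
        for pos, base in _forced_positions(entry, feat).items():
            if pos in forced and forced[pos] != base:
                raise ValidationError(
                    f"simulation: conflicting codon constraints at position "
                    f"{pos + 1} (plan infeasible)")
            forced[pos] = base
    for pos, base in forced.items():
        seq[pos] = base

    _repair_internal_stops(seq, pcg_entries, forced, repeat_span0)

    all_feats = feats + ([overlay] if overlay is not None else [])
    assign_copy_indices(all_feats)
    all_feats.sort(key=lambda f: (f.start, f.end))
    genome = AnnotatedMitogenome(
        species=config.species, length=L, features=all_feats,
        sequence="".join(seq), accession=f"SIM{config.seed:07d}")

    gaps = []
    n = len(feats)
    for i in range(n):
        up, down = feats[i], feats[(i + 1) % n]
        signed = (down.start - up.end - 1) if i < n - 1 else (
            L - up.end + down.start - 1)
        gaps.append((up.label(), down.label(), signed))

    for entry, feat in pcg_entries:
        start_stops[feat.label()] = (entry.start_codon, entry.stop)

    comp_truth = _composition_truth(genome)
    dup_counts: dict[str, int] = {}
    for f in all_feats:
        dup_counts[f.name] = dup_counts.get(f.name, 0) + 1
    duplications = sorted((n_, c) for n_, c in dup_counts.items() if c >= 2)

    truth = GroundTruth(
        seed=config.seed, species=config.species, genome_length=L,
        features=all_feats, gaps=gaps, composition=comp_truth,
        start_stops=start_stops, repeat=repeat_truth,
        duplications=duplications)
    return genome, truth


def _composition_truth(genome: AnnotatedMitogenome) -> dict:
    """Direct base counts per region class (construction-side bookkeeping)."""
    out = {}
    seq = genome.sequence
    out["whole"] = {b: seq.count(b) for b in "ACGT"}
    for region, ftype in (("PCG", "PCG"), ("rRNA", "rRNA"), ("tRNA", "tRNA"),
                          ("CR", "control")):
        chunks = "".join(genome.h_frame_slice(f)
                         for f in sorted(genome.features, key=lambda f: f.start)
                         if f.ftype == ftype)
        out[region] = {b: chunks.count(b) for b in "ACGT"}
    return out


def _codon_ranges(entry: GenePlanEntry, feat: GeneFeature):
    """Internal-codon index range (start codon and stop region excluded)."""
    n_codons = entry.length // 3
    last_internal = n_codons - 1 - (1 if entry.trailing == 0 else 0)
    return 1, last_internal


def _oriented_index(entry: GenePlanEntry, feat: GeneFeature, pos0: int) -> int:
    if entry.strand == "H":
        return pos0 - (feat.start - 1)
    return (feat.end - 1) - pos0


def _h_position(entry: GenePlanEntry, feat: GeneFeature, oi: int) -> int:
    if entry.strand == "H":
        return feat.start - 1 + oi
    return feat.end - 1 - oi


def _codon_of(seq, entry, feat, idx) -> str:
    bases = []
    for k in range(3):
        pos = _h_position(entry, feat, idx * 3 + k)
        b = seq[pos]
        bases.append(revcomp(b) if entry.strand == "L" else b)
    return "".join(bases)


def _repair_internal_stops(seq, pcg_entries, forced, repeat_span0,
                           max_passes: int = 200) -> None:
    """Mutate free bases until no PCG carries an internal in-frame stop."""
    def in_repeat(pos):
        return repeat_span0 is not None and repeat_span0[0] <= pos <= repeat_span0[1]

    def offending():
        for entry, feat in pcg_entries:
            lo, hi = _codon_ranges(entry, feat)
            for idx in range(lo, hi + 1):
                if _codon_of(seq, entry, feat, idx) in STOP_CODONS:
                    yield entry, feat, idx

    for _ in range(max_passes):
        hit = next(iter(offending()), None)
        if hit is None:
            return
        entry, feat, idx = hit
        fixed = False
        for k in (2, 1, 0):
            pos = _h_position(entry, feat, idx * 3 + k)
            if pos in forced or in_repeat(pos):
                continue
            current = seq[pos]
            for b in "ACGT":
                if b == current:
                    continue
                seq[pos] = b
                bad = any(
                    _codon_of(seq, e2, f2, _oriented_index(e2, f2, pos) // 3)
                    in STOP_CODONS
                    for e2, f2 in pcg_entries
                    if f2.start - 1 <= pos <= f2.end - 1
                    and _codon_ranges(e2, f2)[0]
                    <= _oriented_index(e2, f2, pos) // 3
                    <= _codon_ranges(e2, f2)[1])
                if not bad:
                    fixed = True
                    break
                seq[pos] = current
            if fixed:
                break
        if not fixed:
            raise ValidationError(
                f"simulation: cannot remove in-frame stop in {feat.name}")
    raise ValidationError("simulation: stop-repair did not converge")


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def _apply_variant(config: SimulationConfig, variant: dict) -> SimulationConfig:
    cfg = config.copy()
    cfg.genome_length = None  # variants change the realized length
    for key, value in variant.items():
        if key == "species":
            cfg.species = value
        elif key == "seed":
            cfg.seed = value
        elif key == "repeat":
            if value is None:
                cfg.repeat = None
            elif isinstance(value, RepeatPlan):
                cfg.repeat = value
            else:
                cfg.repeat = RepeatPlan(**value)
        elif key == "cr_length":
            idx = next((i for i, e in enumerate(cfg.gene_plan)
                        if e.name == "CR"), None)
            if idx is None:
                raise ValidationError("variant cr_length: plan has no CR entry")
            cfg.gene_plan[idx].length = value
        elif key == "duplicate":
            for name, spec in value.items():
                idx = next((i for i, e in enumerate(cfg.gene_plan)
                            if e.name == name), None)
                if idx is None:
                    raise ValidationError(f"variant duplicate: no entry {name!r}")
                lengths = (spec if isinstance(spec, (list, tuple))
                           else [cfg.gene_plan[idx].length] * (spec - 1))
                for off, ln in enumerate(lengths, start=1):
                    dup = copy.deepcopy(cfg.gene_plan[idx])
                    dup.length = ln
                    cfg.gene_plan.insert(idx + off, dup)
                    cfg.gap_plan.insert(idx + off, cfg.gap_plan[idx])
                    if dup.ftype == "PCG":
                        # keep codon bookkeeping consistent with the length
                        dup.stop = {0: "TAA", 2: "TA-", 1: "T--"}[ln % 3]
        elif key == "gap_tweaks":
            for i, g in value.items():
                cfg.gap_plan[int(i)] = g
        else:
            raise ValidationError(f"unknown variant key {key!r}")
    return cfg


def make_family(base_config: SimulationConfig, variants: list[dict],
                out_dir=None) -> list[tuple[AnnotatedMitogenome, GroundTruth]]:
    """Generate one genome per variant override of the base config.

    Deterministic per seed.  With ``out_dir`` set, writes GenBank, FASTA,
    feature table and truth JSON per member.
    """
    from .io import write_fasta, write_feature_table, write_genbank

    results = []
    for i, variant in enumerate(variants):
        cfg = _apply_variant(base_config, dict(variant))
        if "seed" not in variant:
            cfg.seed = base_config.seed + i
        if "species" not in variant:
            cfg.species = f"{base_config.species} v{i}"
        genome, truth = generate_mitogenome(cfg)
        results.append((genome, truth))
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            stem = f"member{i:02d}"
            write_genbank(genome, out / f"{stem}.gb")
            write_fasta(genome, out / f"{stem}.fasta")
            write_feature_table(genome, out / f"{stem}.tsv")
            (out / f"{stem}.truth.json").write_text(truth.to_json())
    return results
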