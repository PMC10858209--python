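"""Readers and writers: GenBank flat files, FASTA, plain feature tables.

The feature-table format is a TSV with header ``name\tfrom\tto\tstrand`` and
optional ``type`` and ``wraps`` columns; coordinates are 1-based inclusive on
the heavy-strand frame, matching the GenBank convention.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import (AnnotatedMitogenome, GeneFeature, ParseError,
                    ValidationError, assign_copy_indices)
from .names import normalize_gene_name

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "write_feature_report",
    "load_dussumieri",
    "DUSSUMIERI_LENGTH",
]

#: Genome length of the packaged B. dussumieri coordinate fixture.
DUSSUMIERI_LENGTH = 16_685

_GB_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature")


def _feature_name(feat) -> str | None:
    for key in ("gene", "standard_name", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    if feat.type == "D-loop":
        return "D-loop"
    return None


def read_genbank(path) -> AnnotatedMitogenome:
    """Read an annotated mitogenome from a GenBank flat file.

    Feature names are normalized, coordinates converted to 1-based inclusive,
    complement-strand features get ``strand='L'``, and origin-spanning join
    locations set ``wraps_origin``.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    length = len(rec.seq)
    if length == 0:
        raise ParseError(f"{path}: record has no sequence/LOCUS length")

    raw_feats = [f for f in rec.features if f.type in _GB_FEATURE_TYPES]
    if not raw_feats:
        raw_feats = [f for f in rec.features if f.type == "gene"]

    feats: list[GeneFeature] = []
    for f in raw_feats:
        raw = _feature_name(f)
        if raw is None:
            continue
        canonical, ftype = normalize_gene_name(raw)
        parts = f.location.parts
        wraps = False
        if len(parts) == 2 and int(parts[0].end) == length and int(parts[1].start) == 0:
            start = int(parts[0].start) + 1
            end = int(parts[1].end)
            wraps = True
        elif len(parts) == 1:
            start = int(f.location.start) + 1
            end = int(f.location.end)
        else:
            raise ParseError(f"{path}: unparseable location for feature {raw!r}: "
                             f"{f.location}")
        if end > length and not wraps:
            raise ParseError(f"{path}: feature {raw!r} extends beyond sequence "
                             f"end ({end} > {length})")
        strand = "L" if f.location.strand == -1 else "H"
        feats.append(GeneFeature(name=canonical, start=start, end=end,
                                 strand=strand, ftype=ftype, raw_name=raw,
                                 wraps_origin=wraps))
    assign_copy_indices(feats)
    species = rec.annotations.get("organism", "") or rec.description or rec.id
    return AnnotatedMitogenome(
        species=species, length=length, features=feats,
        sequence=str(rec.seq).upper(), accession=rec.id or "")


def write_genbank(genome: AnnotatedMitogenome, path) -> None:
    """Write the genome (sequence required) as a GenBank flat file."""
    if genome.sequence is None:
        raise ValidationError(f"{genome.species}: cannot write GenBank without sequence")
    rec = SeqRecord(Seq(genome.sequence), id=genome.accession or "MITOCOMP1",
                    name="MITOCOMP", description=genome.species)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    rec.annotations["organism"] = genome.species
    type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "control": "D-loop", "origin": "rep_origin"}
    for f in genome.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, genome.length, strand=strand),
                FeatureLocation(0, f.end, strand=strand)])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        quals = {"gene": [f.raw_name or f.name]}
        rec.features.append(SeqFeature(loc, type=type_map.get(f.ftype, "misc_feature"),
                                       qualifiers=quals))
    SeqIO.write(rec, str(path), "genbank")


def read_fasta(path, species: str | None = None) -> AnnotatedMitogenome:
    """Read a single-record FASTA as a feature-less genome."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ParseError(f"{path}: no FASTA records")
    rec = recs[0]
    return AnnotatedMitogenome(species=species or rec.description or rec.id,
                               length=len(rec.seq), features=[],
                               sequence=str(rec.seq).upper(), accession=rec.id)


def write_fasta(genome: AnnotatedMitogenome, path) -> None:
    if genome.sequence is None:
        raise ValidationError(f"{genome.species}: cannot write FASTA without sequence")
    header = genome.accession or genome.species.replace(" ", "_")
    with open(path, "w") as fh:
        fh.write(f">{header} {genome.species}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def read_feature_table(path, genome_length: int, species: str) -> AnnotatedMitogenome:
    """Read a plain feature table into a sequence-less genome.

    Required columns: ``name``, ``from``, ``to``, ``strand``; optional
    ``type`` (inferred from the name map when absent) and ``wraps`` (truthy
    for origin-spanning features, in which case ``from > to`` is legal).
    """
    feats: list[GeneFeature] = []
    seen_spans: dict[tuple[int, int], str] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"name", "from", "to", "strand"}
        if reader.fieldnames is None or not required.issubset(set(reader.fieldnames)):
            raise ParseError(f"{path}: feature table needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            raw = row["name"].strip()
            if not raw:
                continue
            start, end = int(row["from"]), int(row["to"])
            wraps = str(row.get("wraps", "") or "").strip().lower() in ("1", "true", "yes")
            if start > end and not wraps:
                raise ParseError(f"{path} line {i}: {raw!r} has from > to "
                                 "without a wrap flag")
            if (start, end) in seen_spans:
                raise ParseError(f"{path} line {i}: {raw!r} duplicates the exact "
                                 f"span of {seen_spans[(start, end)]!r}")
            seen_spans[(start, end)] = raw
            canonical, ftype = normalize_gene_name(raw)
            declared = (row.get("type") or "").strip()
            if declared:
                ftype = declared
            feats.append(GeneFeature(name=canonical, start=start, end=end,
                                     strand=row["strand"].strip().upper(),
                                     ftype=ftype, raw_name=raw, wraps_origin=wraps))
    assign_copy_indices(feats)
    return AnnotatedMitogenome(species=species, length=genome_length, features=feats)


def write_feature_table(genome: AnnotatedMitogenome, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "from", "to", "strand", "type", "wraps"])
        for f in genome.features:
            w.writerow([f.raw_name or f.name, f.start, f.end, f.strand, f.ftype,
                        "1" if f.wraps_origin else ""])


def load_dussumieri() -> AnnotatedMitogenome:
    """The packaged B. dussumieri coordinate fixture (no sequence)."""
    ref = resources.files("mitocomp.data") / "boleophthalmus_dussumieri.tsv"
    with resources.as_file(ref) as p:
        return read_feature_table(p, genome_length=DUSSUMIERI_LENGTH,
                                  species="Boleophthalmus dussumieri")


def write_feature_report(genome: AnnotatedMitogenome, policy: str = "exclude-container"):
    """One row per feature in genomic order, with the downstream intergenic
    distance from the spacer chain and start/stop codons when sequence is
    present.  Returns a :class:`pandas.DataFrame`.
    """
    import pandas as pd

    from .codons import call_start_stop, extract_cds
    from .spacers import build_gap_chain, compute_gaps

    chain = build_gap_chain(genome, policy=policy)
    gaps = compute_gaps(chain, genome.length)
    gap_after = {g.upstream_key: g.signed_length for g in gaps}

    rows = []
    order = sorted(genome.features, key=lambda f: (f.start, f.end))
    for f in order:
        codons = ""
        if genome.sequence is not None and f.ftype == "PCG":
            cds = extract_cds(genome, f)
            start, stop, _ = call_start_stop(cds.oriented_seq)
            codons = f"{start}/{stop}"
        rows.append({
            "gene": f.label(), "raw_name": f.raw_name, "from": f.start,
            "to": f.end, "length": f.length(genome.length),
            "intergenic": gap_after.get(f.key, None),
            "start_stop": codons, "strand": f.strand, "type": f.ftype,
        })
    return pd.DataFrame(rows)


def report_to_json(df, path) -> None:
    records = json.loads(df.to_json(orient="records"))
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
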