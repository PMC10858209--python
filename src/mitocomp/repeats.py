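"""Tandem-repeat detection with fractional copy numbers.

The scanner is a self-comparison at candidate periods: positions ``i`` with
``seq[i] == seq[i + p]`` form match runs in the shifted-mismatch profile; a
run of length ``m`` corresponds to a repeat span of ``m + p`` bases, i.e.
``(m + p) / p`` copies.  Runs are merged across isolated mismatches while
the overall divergence stays within budget.  Only the forward (5'->3')
orientation is scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .model import AnnotatedMitogenome, ValidationError

__all__ = [
    "RepeatRecord",
    "find_tandem_repeats",
    "copy_identity_matrix",
    "scan_control_regions",
    "DEFAULTS",
]

#: Default scan parameters: tuned so control-region motifs of one to a few
#: hundred bp with a couple of copies are found while microsatellite noise
#: and chance self-matches are suppressed.
DEFAULTS = dict(min_period=10, max_period=400, min_copies=1.8,
                max_divergence=0.1, min_match_run=12)


@dataclass
class RepeatRecord:
    """A detected tandem repeat (coordinates 1-based inclusive)."""

    span_start: int
    span_end: int
    period: int
    copy_number: float
    consensus_motif: str
    mean_copy_identity: float
    strand_direction: str = "5'-3'"

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1

    def copy_number_1dp(self) -> float:
        return round(self.copy_number, 1)


def _match_runs(d: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of matches (False values) as (start, end) inclusive."""
    if d.size == 0:
        return []
    padded = np.concatenate(([True], d, [True]))
    change = np.flatnonzero(padded[1:] != padded[:-1])
    # change pairs delimit runs of equal value; keep the False runs
    runs = []
    for a, b in zip(change[::2], change[1::2]):
        # padded[1+a] .. padded[b] is one run; value is d[a]
        if not d[a]:
            runs.append((int(a), int(b) - 1))
    return runs


_MISMATCH_PENALTY = 4.0
_MERGE_LOOKAHEAD = 6  # runs to probe past a temporarily-over-budget gap


def _trim(d: np.ndarray, a: int, b: int) -> tuple[int, int, int]:
    """Best-scoring subsegment of d[a..b] (match +1, mismatch -penalty).

    Stops the segment from creeping into flanking sequence that happens to
    match at ~random rates: random flank scores negative per base, so the
    maximum-score subsegment ends near the true repeat boundary.
    """
    best = cur = 0.0
    best_a = best_b = cur_a = a
    for i in range(a, b + 1):
        step = -_MISMATCH_PENALTY if d[i] else 1.0
        if cur <= 0:
            cur, cur_a = step, i
        else:
            cur += step
        if cur > best:
            best, best_a, best_b = cur, cur_a, i
    mm = int(np.count_nonzero(d[best_a:best_b + 1]))
    return best_a, best_b, mm


def _segments(d: np.ndarray, max_divergence: float) -> list[tuple[int, int, int]]:
    """Greedy merge of match runs into low-divergence segments.

    Returns ``(start, end, mismatches)`` triples; segments begin and end on
    matches.  A gap of mismatches between runs is absorbed when the merged
    segment's mismatch fraction stays <= max_divergence; each merged segment
    is then trimmed to its best-scoring core (see :func:`_trim`).
    """
    runs = _match_runs(d)
    segments = []
    i = 0
    while i < len(runs):
        a, b = runs[i]
        mm = 0
        # probe a few runs ahead so a local mismatch cluster near the segment
        # start does not fragment an otherwise low-divergence repeat
        t_b, t_mm = b, mm
        last_ok = i
        j = i + 1
        while j < len(runs) and j - last_ok <= _MERGE_LOOKAHEAD:
            na, nb = runs[j]
            t_mm += na - t_b - 1
            t_b = nb
            if t_mm <= max_divergence * (t_b - a + 1):
                b, mm = t_b, t_mm
                last_ok = j
            j += 1
        segments.append(_trim(d, a, b))
        i = last_ok + 1
    return segments


def find_tandem_repeats(sequence: str,
                        min_period: int = DEFAULTS["min_period"],
                        max_period: int = DEFAULTS["max_period"],
                        min_copies: float = DEFAULTS["min_copies"],
                        max_divergence: float = DEFAULTS["max_divergence"],
                        min_match_run: int = DEFAULTS["min_match_run"],
                        ) -> list[RepeatRecord]:
    """Scan a sequence for tandem repeats.

    Candidate hits at every period are resolved by longest span, then
    smallest period, keeping non-overlapping records.  Deterministic for
    fixed inputs.
    """
    if min_period < 1:
        raise ValidationError("min_period must be >= 1")
    if min_copies < 1.5:
        raise ValidationError("min_copies must be >= 1.5")
    if not 0 <= max_divergence < 1:
        raise ValidationError("max_divergence must be in [0, 1)")
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_period:
        raise ValidationError("sequence shorter than two minimum periods")

    s = np.frombuffer(seq.encode("ascii"), dtype="S1")
    candidates = []
    hi = min(max_period, n // 2)
    for p in range(min_period, hi + 1):
        d = s[:-p] != s[p:]
        need_run = max(min_match_run, ceil((min_copies - 1.0) * p))
        runs = _match_runs(d)
        if not runs:
            continue
        longest_run = max(b - a + 1 for a, b in runs)
        # cheap reject: a segment of length l holds <= floor(dv*l) mismatches,
        # so it must contain a pure run of >= l*(1-dv)/(dv*l+1)
        bound = need_run * (1.0 - max_divergence) / (max_divergence * need_run + 1.0)
        if longest_run < bound:
            continue
        for a, b, mm in _segments(d, max_divergence):
            run = b - a + 1
            if run < need_run:
                continue
            span_len = run + p
            candidates.append((run, span_len, p, a + 1, b + p + 1))

    # rank by matched-evidence length (the self-match run), which -- unlike
    # the raw span -- does not reward harmonic multiples of the true period;
    # ties break toward the smaller period
    candidates.sort(key=lambda c: (-c[0], c[2], c[3]))
    taken: list[tuple[int, int]] = []
    records: list[RepeatRecord] = []
    for _run, span_len, p, start, end in candidates:
        if any(not (end < ts or start > te) for ts, te in taken):
            continue
        taken.append((start, end))
        rec = RepeatRecord(
            span_start=start, span_end=end, period=p,
            copy_number=span_len / p,
            consensus_motif=_consensus(seq, start, end, p),
            mean_copy_identity=0.0)
        rec.mean_copy_identity = float(np.mean(copy_identity_matrix(rec, seq)[
            np.triu_indices(_n_copies(rec), k=1)])) if _n_copies(rec) > 1 else 1.0
        records.append(rec)
    records.sort(key=lambda r: r.span_start)
    return records


def _n_copies(record: RepeatRecord) -> int:
    full, partial = divmod(record.span_length, record.period)
    return full + (1 if partial else 0)


def _copies(record: RepeatRecord, sequence: str) -> list[str]:
    seq = sequence.upper()
    chunk = seq[record.span_start - 1:record.span_end]
    return [chunk[i:i + record.period] for i in range(0, len(chunk), record.period)]


def _consensus(seq: str, start: int, end: int, period: int) -> str:
    chunk = seq[start - 1:end]
    full = [chunk[i:i + period] for i in range(0, len(chunk) - period + 1, period)]
    if not full:
        return chunk[:period]
    cols = []
    for j in range(period):
        bases = [c[j] for c in full]
        cols.append(max(set(bases), key=bases.count))
    return "".join(cols)


def copy_identity_matrix(record: RepeatRecord, sequence: str) -> np.ndarray:
    """Pairwise ungapped identity between repeat copies.

    Copies are cut at period boundaries; the final partial copy is compared
    over its own length.  Identity = matches / compared length.
    """
    copies = _copies(record, sequence)
    k = len(copies)
    mat = np.ones((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            m = min(len(copies[i]), len(copies[j]))
            matches = sum(a == b for a, b in zip(copies[i][:m], copies[j][:m]))
            mat[i, j] = mat[j, i] = matches / m if m else 0.0
    return mat


def scan_control_regions(genomes, flank: int = 0, **params):
    """Scan each genome's control-region span (plus an optional flank).

    Genomes lacking a sequence are skipped with a warning; a genome without
    a CR feature falls back to its OH span.  Returns a
    :class:`pandas.DataFrame` with one row per detected repeat.
    """
    import warnings

    import pandas as pd

    opts = dict(DEFAULTS)
    opts.update(params)
    rows = []
    for g in genomes:
        if g.sequence is None:
            warnings.warn(f"{g.species}: no sequence, skipped", stacklevel=2)
            continue
        targets = g.features_of_class("control") or [
            f for f in g.features if f.name == "OH"]
        for f in targets:
            lo = max(1, f.start - flank)
            hi = min(g.length, f.end + flank)
            sub = g.sequence[lo - 1:hi]
            if len(sub) < 2 * opts["min_period"]:
                continue
            local = dict(opts)
            local["max_period"] = min(local["max_period"], len(sub) // 2)
            for rec in find_tandem_repeats(sub, **local):
                rows.append({
                    "species": g.species,
                    "region": f.label(),
                    "start": rec.span_start + lo - 1,
                    "end": rec.span_end + lo - 1,
                    "period": rec.period,
                    "copy_number": rec.copy_number_1dp(),
                    "mean_identity": round(rec.mean_copy_identity, 3),
                    "consensus": rec.consensus_motif,
                    "direction": rec.strand_direction,
                })
    return pd.DataFrame(rows, columns=[
        "species", "region", "start", "end", "period", "copy_number",
        "mean_identity", "consensus", "direction"])
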