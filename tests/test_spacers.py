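import numpy as np
import pytest

from mitocomp.model import (AnnotatedMitogenome, GeneFeature, ValidationError,
                            assign_copy_indices, rotate_genome)
from mitocomp.spacers import (build_gap_chain, compare_spacers, compute_gaps,
                              genome_gaps, summarize_spacers)


class TestFixtureAccounting:
    """The packaged coordinate fixture reproduces the published accounting."""

    def test_summary(self, dussumieri):
        s = summarize_spacers(genome_gaps(dussumieri))
        assert s.n_igs == 17
        assert s.total_igs_bp == 899
        assert s.longest_igs_bp == 495
        assert s.longest_igs_pair == "trnP/OH"
        assert s.n_overlaps == 7
        assert s.overlap_range == (1, 7)

    def test_named_gaps(self, dussumieri):
        gaps = {g.pair: g.signed_length for g in genome_gaps(dussumieri)}
        assert gaps["ATP6/COIII"] == 117
        assert gaps["trnV/rrnL"] == 51
        assert gaps["OH/trnF"] == 185
        assert gaps["ATP8/ATP6"] == -7
        assert gaps["ND4L/ND4"] == -7

    def test_wrap_gap_flagged(self, dussumieri):
        wrap = [g for g in genome_gaps(dussumieri) if g.wraps_origin]
        assert len(wrap) == 1
        assert wrap[0].pair == "OH/trnF"

    def test_total_overlap_recomputed(self, dussumieri):
        s = summarize_spacers(genome_gaps(dussumieri))
        assert sum(abs(x) for x in s.overlap_lengths) == 25

    def test_dloop_excluded_from_chain(self, dussumieri):
        chain = build_gap_chain(dussumieri)
        assert "CR" not in [f.name for f in chain]
        assert len(chain) == 39

    def test_keep_all_policy_differs(self, dussumieri):
        chain = build_gap_chain(dussumieri, policy="keep-all")
        assert "CR" in [f.name for f in chain]


class TestChain:
    def test_identical_spans_error(self):
        g = AnnotatedMitogenome("sp", 100, features=[
            GeneFeature("ND1", 10, 20, ftype="PCG", raw_name="a"),
            GeneFeature("ND2", 10, 20, ftype="PCG", raw_name="b")])
        with pytest.raises(ValidationError, match="identical spans"):
            build_gap_chain(g)

    def test_unknown_policy(self, dussumieri):
        with pytest.raises(ValidationError):
            build_gap_chain(dussumieri, policy="bogus")

    def test_empty_rejected(self):
        g = AnnotatedMitogenome("sp", 100)
        with pytest.raises(ValidationError):
            build_gap_chain(g)

    def test_single_feature_wrap_gap(self):
        g = AnnotatedMitogenome("sp", 1000,
                                features=[GeneFeature("ND1", 101, 300,
                                                      ftype="PCG")])
        gaps = genome_gaps(g)
        assert len(gaps) == 1
        assert gaps[0].signed_length == 1000 - 200
        assert gaps[0].wraps_origin

    def test_sorted_by_start_oracle(self, rng):
        for _ in range(20):
            feats = []
            used = set()
            for i in range(int(rng.integers(2, 10))):
                s = int(rng.integers(1, 900))
                e = int(rng.integers(s, 1000))
                if (s, e) in used:
                    continue
                used.add((s, e))
                feats.append(GeneFeature(f"g{i}", s, e, ftype="PCG"))
            if not feats:
                continue
            g = AnnotatedMitogenome("sp", 1000, features=feats)
            chain = build_gap_chain(g, policy="keep-all")
            assert [f.start for f in chain] == sorted(f.start for f in feats)


class TestGaps:
    def test_abutting_zero(self):
        g = AnnotatedMitogenome("sp", 100, features=[
            GeneFeature("ND1", 1, 50, ftype="PCG"),
            GeneFeature("ND2", 51, 90, ftype="PCG")])
        gaps = genome_gaps(g)
        assert gaps[0].signed_length == 0
        assert gaps[0].pair == "ND1/ND2"

    def test_zero_is_neither_igs_nor_overlap(self):
        g = AnnotatedMitogenome("sp", 100, features=[
            GeneFeature("ND1", 1, 50, ftype="PCG"),
            GeneFeature("ND2", 51, 100, ftype="PCG")])
        s = summarize_spacers(genome_gaps(g))
        assert s.n_igs == 0 and s.n_overlaps == 0 and s.total_igs_bp == 0

    def test_occupancy_oracle_nonoverlapping(self, rng):
        """Positive gaps equal uncovered-run lengths from a coverage mask."""
        for _ in range(100):
            L = int(rng.integers(200, 2000))
            n = int(rng.integers(2, 10))
            cuts = np.sort(rng.choice(np.arange(1, L + 1), size=2 * n,
                                      replace=False))
            feats = [GeneFeature(f"g{i}", int(cuts[2 * i]),
                                 int(cuts[2 * i + 1]), ftype="PCG")
                     for i in range(n)]
            g = AnnotatedMitogenome("sp", L, features=feats)
            gaps = genome_gaps(g, policy="keep-all")

            mask = np.zeros(L, dtype=int)
            for f in feats:
                mask[f.start - 1:f.end] += 1
            # oracle: uncovered bases strictly between end(i) and start(i+1)
            for i, rec in enumerate(gaps):
                up = feats[i]
                down = feats[(i + 1) % n]
                if rec.wraps_origin:
                    arc = np.concatenate([mask[up.end:], mask[:down.start - 1]])
                else:
                    arc = mask[up.end:down.start - 1]
                assert rec.signed_length == int((arc == 0).sum())
            # conservation on a <=1x-covered chain
            total_len = sum(f.length(L) for f in feats)
            pos = sum(r.signed_length for r in gaps if r.signed_length > 0)
            neg = sum(-r.signed_length for r in gaps if r.signed_length < 0)
            assert total_len + pos - neg == L

    def test_occupancy_oracle_with_overlaps(self, rng):
        """Negative gaps equal doubly-covered base counts."""
        for _ in range(100):
            L = int(rng.integers(500, 2000))
            feats = []
            pos = 1
            while pos < L - 140:
                length = int(rng.integers(60, 90))
                feats.append(GeneFeature(f"g{len(feats)}", pos,
                                         pos + length - 1, ftype="PCG"))
                # overlaps capped below the minimum length so neighbours
                # overlap without nesting
                shift = int(rng.integers(-25, 40))
                pos = pos + length + shift
            g = AnnotatedMitogenome("sp", L, features=feats)
            gaps = genome_gaps(g, policy="keep-all")
            mask = np.zeros(L, dtype=int)
            for f in feats:
                mask[f.start - 1:f.end] += 1
            for i, rec in enumerate(gaps[:-1]):
                if rec.signed_length < 0:
                    up, down = feats[i], feats[i + 1]
                    shared = mask[down.start - 1:up.end]
                    assert -rec.signed_length == int((shared >= 2).sum())
            # conservation holds when coverage never exceeds 2
            if mask.max() <= 2:
                total_len = sum(f.length(L) for f in feats)
                p = sum(r.signed_length for r in gaps if r.signed_length > 0)
                o = sum(-r.signed_length for r in gaps if r.signed_length < 0)
                assert total_len + p - o == L

    def test_rotation_leaves_signed_lengths(self, dussumieri, rng):
        base = sorted(r.signed_length for r in genome_gaps(dussumieri))
        for off in (1, 137, 5000, 16000):
            rot = rotate_genome(dussumieri, off)
            got = sorted(r.signed_length for r in genome_gaps(rot))
            assert got == base


class TestSummaryAndCompare:
    def test_tie_flagged(self):
        g = AnnotatedMitogenome("sp", 100, features=[
            GeneFeature("ND1", 1, 20, ftype="PCG"),
            GeneFeature("ND2", 31, 50, ftype="PCG"),
            GeneFeature("ND3", 61, 90, ftype="PCG")])
        s = summarize_spacers(genome_gaps(g))
        assert s.longest_is_tie
        assert s.longest_igs_pair == "ND1/ND2"  # first in genomic order

    def test_single_genome_row_matches_summary(self, dussumieri):
        df, _ = compare_spacers([dussumieri])
        s = summarize_spacers(genome_gaps(dussumieri))
        row = df.iloc[0]
        assert row.n_igs == s.n_igs
        assert row.total_igs_bp == s.total_igs_bp
        assert row.longest_igs_bp == s.longest_igs_bp

    def test_identical_genomes_identical_rows(self, dussumieri):
        df, conserved = compare_spacers([dussumieri, dussumieri])
        a, b = df.drop(columns="species").iloc[0], df.drop(columns="species").iloc[1]
        assert (a == b).all()
        assert conserved == 39  # every boundary shared with itself

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            compare_spacers([])

    def test_generator_family_conserved_boundaries(self):
        from mitocomp.simulate import canonical_config, generate_mitogenome
        g1, _ = generate_mitogenome(canonical_config(seed=1))
        g2, _ = generate_mitogenome(canonical_config(seed=2))
        _, conserved = compare_spacers([g1, g2])
        assert conserved == len(genome_gaps(g1))  # same plan, same boundaries
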