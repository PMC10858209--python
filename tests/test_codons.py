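import warnings
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from mitocomp.codons import (ALL_CODONS, CODON_TABLE, STOP_CODONS,
                             amino_acid_composition, call_start_stop,
                             count_codons, degeneracy_classes, extract_cds,
                             family_of_codon, rscu)
from mitocomp.model import (AnnotatedMitogenome, GeneFeature, ValidationError,
                            revcomp)
from mitocomp.simulate import (GenePlanEntry, SimulationConfig,
                               generate_mitogenome)


class TestExtractCds:
    def test_h_strand_literal_slice(self):
        g = AnnotatedMitogenome(
            "sp", 30, sequence="ATGAAACCCGGGTAAATGAAACCCTAAGGG",
            features=[GeneFeature("ND1", 1, 15, ftype="PCG")])
        cds = extract_cds(g, g.features[0])
        assert cds.oriented_seq == g.sequence[:15]

    def test_l_strand_reverse_complement_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(60, 300))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            s = int(rng.integers(1, L - 20))
            e = int(rng.integers(s + 10, L))
            g = AnnotatedMitogenome(
                "sp", L, sequence=seq,
                features=[GeneFeature("ND6", s, e, strand="L", ftype="PCG")])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cds = extract_cds(g, g.features[0])
            assert cds.oriented_seq == revcomp(seq[s - 1:e])

    def test_wrap_feature_concatenates(self):
        seq = "ATGAAATAA" + "C" * 21
        # place gene across the origin: last 3 bases + first 9
        g = AnnotatedMitogenome(
            "sp", 30, sequence=seq,
            features=[GeneFeature("ND1", 28, 9, ftype="PCG",
                                  wraps_origin=True)])
        cds = extract_cds(g, g.features[0])
        assert cds.oriented_seq == seq[27:] + seq[:9]

    def test_non_pcg_rejected(self):
        g = AnnotatedMitogenome("sp", 10, sequence="A" * 10,
                                features=[GeneFeature("trnF", 1, 10,
                                                      ftype="tRNA")])
        with pytest.raises(ValidationError):
            extract_cds(g, g.features[0])

    def test_non_canonical_start_flagged(self):
        g = AnnotatedMitogenome(
            "sp", 9, sequence="GTGAAATAA",
            features=[GeneFeature("COI", 1, 9, ftype="PCG")])
        cds = extract_cds(g, g.features[0])
        assert cds.start_codon == "GTG"
        assert cds.non_canonical_start


class TestCallStartStop:
    def test_complete(self):
        assert call_start_stop("ATGAAATAA") == ("ATG", "TAA", "complete")

    def test_ta_incomplete(self):
        assert call_start_stop("ATGAAATA") == ("ATG", "TA-", "TA_incomplete")

    def test_t_incomplete(self):
        assert call_start_stop("ATGAAAT") == ("ATG", "T--", "T_incomplete")

    def test_unexpected_tail_warns(self):
        with pytest.warns(UserWarning):
            call_start_stop("ATGAAAG")

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            call_start_stop("ATG")

    def test_planted_classes_recovered_generator(self):
        """All three stop classes x many genes recovered exactly."""
        classes = [("TAA", 0), ("TAG", 0), ("TA-", 2), ("T--", 1)]
        plan, gaps = [], []
        plan.append(GenePlanEntry(name="trnF", length=70))
        gaps.append(0)
        want = {}
        for i in range(48):
            stop, trailing = classes[i % len(classes)]
            length = 90 + 3 * (i % 7) + trailing
            name = f"gene{i:02d}"
            e = GenePlanEntry(name=name, length=length,
                              strand="L" if i % 5 == 0 else "H",
                              start_codon="ATG", stop=stop)
            e.ftype = "PCG"
            plan.append(e)
            gaps.append(2)
            want[name] = (stop, {0: "complete", 2: "TA_incomplete",
                                 1: "T_incomplete"}[trailing])
        cfg = SimulationConfig(seed=99, gene_plan=plan, gap_plan=gaps)
        g, truth = generate_mitogenome(cfg)
        for f in g.features_of_class("PCG"):
            cds = extract_cds(g, f)
            stop, completeness = want[f.name]
            assert cds.completeness == completeness, f.name
            assert cds.stop_codon == stop, f.name
            assert cds.start_codon == "ATG"


class TestCountCodons:
    def test_stop_excluded(self):
        t = count_codons(["ATGAAATAA"])
        assert t.total_codons_excluding_stops == 2
        assert t.counts["ATG"] == 1 and t.counts["AAA"] == 1
        assert t.stop_counts["TAA"] == 1

    def test_empty(self):
        t = count_codons([])
        assert t.total_codons_excluding_stops == 0

    def test_trailing_partial_ignored(self):
        t = count_codons(["ATGAAATA"])
        assert t.total_codons_excluding_stops == 2

    def test_ambiguous_tallied_separately(self):
        t = count_codons(["ATGANATAA"])
        assert t.n_ambiguous == 1
        assert t.total_codons_excluding_stops == 1

    def test_multinomial_stream_bookkeeping(self, rng):
        codons = [c for c in ALL_CODONS if c not in STOP_CODONS]
        drawn = list(rng.choice(codons, size=500))
        t = count_codons(["".join(drawn)])
        assert t.counts == Counter(drawn)


class TestRscu:
    def test_uniform_family(self):
        fams = degeneracy_classes()
        t = count_codons([])
        for c in fams["Gly"]:
            t.counts[c] = 5
        vals = rscu(t)
        assert all(vals[c] == 1.0 for c in fams["Gly"])

    def test_sole_codon_twofold(self):
        fams = degeneracy_classes()
        t = count_codons([])
        c0 = fams["Lys"][0]
        t.counts[c0] = 7
        vals = rscu(t)
        assert vals[c0] == 2.0

    def test_zero_family_flagged_zero(self):
        vals = rscu(count_codons([]))
        assert all(v == 0.0 for v in vals.values())

    def test_brute_force_oracle_50_random_tables(self, rng):
        fams = degeneracy_classes()
        for _ in range(50):
            t = count_codons([])
            for c in rng.choice(
                    [c for c in ALL_CODONS if c not in STOP_CODONS],
                    size=40, replace=True):
                t.counts[c] += 1
            vals = rscu(t)
            # independent recomputation straight from the definition
            for fam, codons in fams.items():
                total = sum(t.counts.get(c, 0) for c in codons)
                for c in codons:
                    expected = (t.counts.get(c, 0) * len(codons) / total
                                if total else 0.0)
                    assert vals[c] == pytest.approx(expected)

    @given(st.dictionaries(st.sampled_from([c for c in ALL_CODONS
                                            if c not in STOP_CODONS]),
                           st.integers(0, 50), max_size=30))
    def test_family_sum_property(self, counts):
        t = count_codons([])
        t.counts.update(counts)
        vals = rscu(t)
        for fam, codons in degeneracy_classes().items():
            s = sum(vals[c] for c in codons)
            total = sum(t.counts.get(c, 0) for c in codons)
            assert s == pytest.approx(len(codons) if total else 0.0)


class TestDegeneracy:
    def test_gly_four_fold(self):
        assert set(degeneracy_classes()["Gly"]) == {"GGA", "GGC", "GGG", "GGT"}

    def test_partition(self):
        seen = []
        for codons in degeneracy_classes().values():
            seen.extend(codons)
        sense = [c for c in ALL_CODONS if c not in STOP_CODONS]
        assert sorted(seen) == sorted(sense)

    def test_families_regenerate_from_code_table(self):
        """Independent groupby-(aa, first-two-bases) oracle."""
        oracle = {}
        for codon, aa in CODON_TABLE.forward_table.items():
            oracle.setdefault((aa, codon[:2]), set()).add(codon)
        boxes_per_aa = {}
        for (aa, box) in oracle:
            boxes_per_aa.setdefault(aa, set()).add(box)
        got = {frozenset(v) for v in degeneracy_classes().values()}
        want = set()
        for aa, boxes in boxes_per_aa.items():
            if len(boxes) == 1:
                want.add(frozenset(c for (a, b), cs in oracle.items()
                                   if a == aa for c in cs))
            else:
                for box in boxes:
                    want.add(frozenset(oracle[(aa, box)]))
        assert got == want

    def test_leu_ser_split(self):
        fams = degeneracy_classes()
        assert set(fams["Leu1"]) == {"CTA", "CTC", "CTG", "CTT"}
        assert set(fams["Leu2"]) == {"TTA", "TTG"}
        assert set(fams["Ser1"]) == {"AGC", "AGT"}
        assert set(fams["Ser2"]) == {"TCA", "TCC", "TCG", "TCT"}

    def test_trp_met_two_fold_under_table2(self):
        fams = degeneracy_classes()
        assert len(fams["Trp"]) == 2  # TGA + TGG
        assert len(fams["Met"]) == 2  # ATA + ATG

    def test_family_of_codon(self):
        assert family_of_codon("CTA") == "Leu1"
        assert family_of_codon("AGT") == "Ser1"
        with pytest.raises(KeyError):
            family_of_codon("TAA")


class TestAminoAcidComposition:
    def test_single_codon(self):
        t = count_codons(["ATGGGG"])
        del t.counts["ATG"]
        pct = amino_acid_composition(t)
        assert pct["Gly"] == 100.0

    def test_sums_to_100(self, sim_canonical):
        g, _ = sim_canonical
        cds = [extract_cds(g, f) for f in g.features_of_class("PCG")]
        pct = amino_acid_composition(count_codons(cds))
        assert sum(pct.values()) == pytest.approx(100.0)
        merged = amino_acid_composition(count_codons(cds), split=False)
        assert sum(merged.values()) == pytest.approx(100.0)
        assert merged["Leu"] == pytest.approx(pct["Leu1"] + pct["Leu2"])

    def test_ten_codon_toy_hand_computed(self):
        # 4x Gly, 3x Lys (AAA), 2x Leu2 (TTA), 1x Trp (TGA)
        seq = "GGA" * 4 + "AAA" * 3 + "TTA" * 2 + "TGA"
        t = count_codons([seq])
        pct = amino_acid_composition(t)
        assert pct["Gly"] == pytest.approx(40.0)
        assert pct["Lys"] == pytest.approx(30.0)
        assert pct["Leu2"] == pytest.approx(20.0)
        assert pct["Trp"] == pytest.approx(10.0)
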