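import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from conftest import make_record
from gcfate import seqfeatures as sf


class TestGcFraction:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.50),
        ("AAAA", 0.00),
        ("GNNC", 1.00),   # N excluded from the denominator
        ("NNNN", math.nan),
        ("", math.nan),
    ])
    def test_examples(self, seq, expected):
        got = sf.gc_fraction(seq)
        assert got == pytest.approx(expected, nan_ok=True)


class TestRegionGc:
    def test_hand_counted_regions(self):
        # mRNA "ATGTAAAT": 1 G+C over 8; CDS "ATGTAA": 1/6; empty 5'UTR -> NaN
        rec = make_record(utr5="", cds="ATGTAA", utr3="AT")
        mrna, u5, cds, u3 = sf.region_gc(rec)
        assert mrna == pytest.approx(1 / 8)
        assert math.isnan(u5)
        assert cds == pytest.approx(1 / 6)
        assert u3 == 0.0

    def test_uniform_sequence_gives_equal_regions(self):
        rec = make_record(utr5="GCGC", cds="GCGCGC", utr3="GCGC")
        assert len(set(sf.region_gc(rec))) == 1

    def test_mrna_gc_is_length_weighted_region_mean(self, rng):
        for _ in range(20):
            parts = ["".join(rng.choice(list("ACGT"), size=rng.integers(3, 60)))
                     for _ in range(3)]
            parts[1] = parts[1][:len(parts[1]) - len(parts[1]) % 3] or "ATG"
            rec = make_record(*parts)
            mrna, u5, cds, u3 = sf.region_gc(rec)
            lens = [len(rec.utr5), len(rec.cds), len(rec.utr3)]
            weighted = np.average([u5, cds, u3], weights=lens)
            assert mrna == pytest.approx(weighted)


class TestGc3:
    @pytest.mark.parametrize("cds,expected", [
        ("ATGAAA", 0.50),   # third bases G, A
        ("GCGGCC", 1.00),
        ("ATTAAT", 0.00),
        ("ATNAAA", 0.00),   # N third base excluded
    ])
    def test_examples(self, cds, expected):
        assert sf.gc3(cds) == pytest.approx(expected)

    def test_rejects_out_of_frame(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            sf.gc3("ATGA")

    def test_equals_gc_of_extracted_third_bases(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 200))
            cds = "".join(rng.choice(list("ACGTN"), size=3 * n))
            third = cds[2::3]
            assert sf.gc3(cds) == pytest.approx(
                sf.gc_fraction(third), nan_ok=True)

    def test_mean_gc3_converges_to_third_base_composition(self, rng):
        """Law of large numbers: synthetic CDS with known third-base GC
        probability p has mean GC3 near p at 1000 codons."""
        p = 0.65
        third = rng.choice(list("GC") + list("AT"), size=1000,
                           p=[p / 2, p / 2, (1 - p) / 2, (1 - p) / 2])
        cds = "".join("AA" + b for b in third)
        assert sf.gc3(cds) == pytest.approx(p, abs=0.03)


class TestAminoAcidFrequencies:
    def test_single_amino_acid(self):
        freqs = sf.amino_acid_frequencies("AAAAAATAA")
        assert freqs["K"] == 1.0
        assert freqs.drop("K").sum() == 0.0

    def test_two_amino_acids(self):
        freqs = sf.amino_acid_frequencies("ATGGCC")
        assert freqs["M"] == 0.5 and freqs["A"] == 0.5

    def test_internal_stop_flagged_but_computed(self):
        with pytest.warns(UserWarning, match="internal stop"):
            freqs = sf.amino_acid_frequencies("AAATAAAAA")
        assert freqs["K"] == 1.0

    def test_matches_biopython_translation(self, rng):
        """Random 300-codon CDS: frequencies equal an independent
        translate-and-count through Biopython."""
        for _ in range(10):
            cds = "".join(rng.choice(list("ACGT"), size=900))
            prot = str(Seq(cds).translate())
            expected = pd.Series(
                {aa: prot.count(aa) for aa in sf.AMINO_ACIDS}, dtype=float)
            expected /= expected.sum()
            got = sf.amino_acid_frequencies(cds)
            pd.testing.assert_series_equal(got, expected, check_names=False)
            assert got.sum() == pytest.approx(1.0, abs=1e-9)


class TestCodonUsage:
    def test_uniform_glycine_family_rscu_one(self):
        table = sf.codon_usage(["GGTGGCGGAGGG"])
        for codon in ("GGT", "GGC", "GGA", "GGG"):
            assert table.rscu[codon] == pytest.approx(1.0)

    def test_exclusive_leucine_codon(self):
        table = sf.codon_usage(["CTG" * 5])
        assert table.rscu["CTG"] == pytest.approx(6.0)
        for codon in ("TTA", "TTG", "CTT", "CTC", "CTA"):
            assert table.rscu[codon] == 0.0

    def test_counts_additive_over_cds(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=90)) for _ in range(5)]
        pooled = sf.codon_usage(seqs)
        summed = sum(sf.codon_usage([s]).counts for s in seqs)
        pd.testing.assert_series_equal(pooled.counts, summed)

    def test_family_mean_rscu_is_one(self, rng):
        table = sf.codon_usage(
            ["".join(rng.choice(list("ACGT"), size=3000))])
        for aa, family in sf.SYN_FAMILIES.items():
            vals = table.rscu[family].dropna()
            if len(vals) == len(family):
                assert vals.mean() == pytest.approx(1.0, abs=1e-9)

    def test_sense_frequencies_sum_to_one(self, rng):
        table = sf.codon_usage(["".join(rng.choice(list("ACGT"), size=600))])
        assert table.frequency.sum() == pytest.approx(1.0)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sf.codon_usage([])


class TestLowUsageAudit:
    def test_human_reference_audit(self):
        """The bundled human reference yields 29 synonymous codons with
        RSCU < 1 (22 ending A/U); 14 of the 18 per-amino-acid lowest-usage
        codons are NNA/NNU, the exceptions encoding Thr, Ser, Pro, Ala."""
        low, lowest = sf.audit_low_usage_codons(sf.load_reference_usage())
        assert len(low) == 29
        assert sum(1 for c in low if c[2] in "AT") == 22
        assert len(lowest) == 18
        nna_nnu = {aa for aa, c in lowest.items() if c[2] in "AT"}
        assert len(nna_nnu) == 14
        assert set(lowest) - nna_nnu == {"T", "S", "P", "A"}

    def test_uniform_usage_gives_empty_low_set(self):
        counts = pd.Series(10.0, index=sf.ALL_CODONS)
        low, lowest = sf.audit_low_usage_codons(sf.usage_from_counts(counts))
        assert low == set()
        assert len(lowest) == 18  # ties resolved lexicographically

    def test_unobserved_amino_acid_warns(self):
        counts = pd.Series(10.0, index=sf.ALL_CODONS)
        counts[sf.SYN_FAMILIES["K"]] = 0.0
        with pytest.warns(UserWarning, match="K unobserved"):
            _, lowest = sf.audit_low_usage_codons(sf.usage_from_counts(counts))
        assert "K" not in lowest


class TestLowUsageStats:
    def test_fraction_and_count(self):
        low = {"ATA", "GTA"}
        cds = "ATA" * 3 + "AAA" * 7
        assert sf.low_usage_stats(cds, low) == (0.3, 3)

    def test_no_members(self):
        assert sf.low_usage_stats("AAA" * 4, {"ATA"}) == (0.0, 0)

    def test_matches_sliding_window_oracle(self, rng):
        _, lowest = sf.audit_low_usage_codons(sf.load_reference_usage())
        low = set(lowest.values())
        for _ in range(100):
            cds = "".join(rng.choice(list("ACGT"), size=3 * rng.integers(5, 80)))
            count = sum(1 for i in range(0, len(cds), 3)
                        if cds[i:i + 3] in low
                        and sf.CODON_TO_AA[cds[i:i + 3]] != "*")
            sense = sum(1 for i in range(0, len(cds), 3)
                        if sf.CODON_TO_AA[cds[i:i + 3]] != "*")
            freq, got = sf.low_usage_stats(cds, low)
            assert got == count
            assert freq == pytest.approx(count / sense)

    def test_count_additive_under_concatenation(self, rng):
        low = {"ATA"}
        a = "".join(rng.choice(list("ACGT"), size=90))
        b = "".join(rng.choice(list("ACGT"), size=60))
        assert (sf.low_usage_stats(a + b, low)[1]
                == sf.low_usage_stats(a, low)[1] + sf.low_usage_stats(b, low)[1])


class TestUsageLogRatio:
    def test_identical_groups_all_zero(self):
        seqs = ["ATGGCCAAATAA"]
        ratio = sf.usage_log_ratio(seqs, seqs)
        assert np.allclose(ratio.dropna(), 0.0)

    def test_sign_contract(self):
        ratio = sf.usage_log_ratio(["TTA" * 10], ["CTG" * 10])
        assert ratio["TTA"] > 0 > ratio["CTG"]

    def test_antisymmetric(self, rng):
        a = ["".join(rng.choice(list("ACGT"), size=300))]
        b = ["".join(rng.choice(list("ACGT"), size=300))]
        fwd, rev = sf.usage_log_ratio(a, b), sf.usage_log_ratio(b, a)
        pd.testing.assert_series_equal(fwd, -rev)


class TestTrnaAdaptation:
    def test_all_weights_one(self):
        assert sf.trna_adaptation("ATGAAA", {"ATG": 1.0, "AAA": 1.0}) == 1.0

    def test_geometric_mean(self):
        w = {"ATG": 0.25, "AAA": 1.0}
        assert sf.trna_adaptation("ATGAAA", w) == pytest.approx(0.5)

    def test_order_invariant(self):
        w = {"ATG": 0.3, "AAA": 0.9, "GCC": 0.5}
        assert sf.trna_adaptation("ATGAAAGCC", w) == pytest.approx(
            sf.trna_adaptation("GCCATGAAA", w))

    def test_bundled_synthetic_weights_load_normalized(self):
        w = sf.load_trna_weights()
        assert len(w) == 61
        assert max(w.values()) == 1.0 and min(w.values()) > 0
        score = sf.trna_adaptation("ATGGCCAAA", w)
        assert 0 < score <= 1

    def test_zero_weight_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            got = sf.trna_adaptation("ATGAAA", {"ATG": 0.0, "AAA": 1.0},
                                     floor=1e-4)
        assert got == pytest.approx(math.sqrt(1e-4))


class TestComputeFeatures:
    def test_feature_table_shape_and_invariant(self):
        recs = [make_record(tid=f"t{i}", gid=f"g{i}") for i in range(3)]
        df = sf.compute_features(recs)
        assert len(df) == 3
        # low_usage_count == round(freq * sense codons)
        sense = 2  # ATGAAATAA has codons ATG, AAA, TAA(stop)
        for _, row in df.iterrows():
            assert row.low_usage_count == round(row.low_usage_freq * sense)
        aa_cols = [c for c in df.columns if c.startswith("aa_")]
        assert np.allclose(df[aa_cols].sum(axis=1), 1.0)
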