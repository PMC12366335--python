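"""Trait estimators: coverage ratios, GC moments, ENC/ENC', SAP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metatraits import synthetic as syn
from metatraits import traits as tr
from metatraits._codons import SYNONYMOUS_CODONS, SYNONYMOUS_FAMILIES


def uniform_counts(per_codon: int) -> tr.CodonCounts:
    return tr.CodonCounts({c: per_codon for c in SYNONYMOUS_CODONS})


def fully_biased_counts(per_family: int = 10) -> tr.CodonCounts:
    return tr.CodonCounts(
        {codons[0]: per_family for codons in SYNONYMOUS_FAMILIES.values()}
    )


class TestCoverageEstimators:
    def test_genome_equivalents_constant(self):
        assert tr.genome_equivalents(np.full(35, 10.0)) == 10.0

    def test_genome_equivalents_mixed(self):
        scg = np.array([5.0] * 17 + [15.0] * 18)
        assert tr.genome_equivalents(scg) == pytest.approx((17 * 5 + 18 * 15) / 35)

    @pytest.mark.parametrize(
        "bad", [np.zeros(35), np.full(34, 1.0), np.full(35, np.nan), -np.ones(35)]
    )
    def test_genome_equivalents_rejects(self, bad):
        with pytest.raises(ValueError):
            tr.genome_equivalents(bad)

    def test_ags(self):
        assert tr.average_genome_size(4e7, 10.0) == 4e6
        with pytest.raises(ValueError):
            tr.average_genome_size(4e7, 0.0)

    def test_ags_is_abundance_weighted_mean(self, two_genome_panel):
        s = syn.simulate_read_summary(
            two_genome_panel, [1.0, 1.0], depth_factor=1, noise="none", seed=0
        )
        geq = tr.genome_equivalents(s.scg_coverage)
        assert tr.average_genome_size(s.total_bases, geq) == pytest.approx(4e6)

    def test_acn(self, two_genome_panel):
        assert tr.average_16s_copy_number(40.0, 10.0) == 4.0
        assert tr.average_16s_copy_number(0.0, 10.0) == 0.0
        # rrn copies {1, 7}, equal abundance, noiseless -> ACN = 4
        s = syn.simulate_read_summary(
            two_genome_panel, [1.0, 1.0], depth_factor=3, noise="none", seed=0
        )
        geq = tr.genome_equivalents(s.scg_coverage)
        assert tr.average_16s_copy_number(s.ssu_coverage, geq) == pytest.approx(4.0)


class TestGcStatistics:
    def test_constant(self):
        assert tr.gc_statistics([0.5, 0.5]) == (0.5, 0.0)

    def test_population_variance(self):
        mean, var = tr.gc_statistics([0.4, 0.6])
        assert mean == pytest.approx(0.5)
        assert var == pytest.approx(0.01)

    @pytest.mark.parametrize("bad", [[], [1.2], [-0.1]])
    def test_rejects(self, bad):
        with pytest.raises(ValueError):
            tr.gc_statistics(bad)


class TestEnc:
    def test_full_bias_closed_form(self):
        # one codon per family: F = 1 everywhere, ENC = 2 + 9 + 1 + 5 + 3 = 20
        assert tr.enc(fully_biased_counts()) == 20.0

    def test_uniform_large_counts_capped_at_61(self):
        # exactly uniform counts give F-hat < 1/m, so the cap lands on 61
        assert tr.enc(uniform_counts(10)) == 61.0

    def test_wright_f_two_fold_example(self):
        # 2-fold family counts (3, 1): F = (4 * 0.625 - 1) / 3 = 0.5
        n, f = tr._wright_f(np.array([3.0, 1.0]))
        assert (n, f) == (4, 0.5)

    def test_in_bounds_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = tr.CodonCounts(rng.integers(0, 40, size=59).astype(float))
            assert 20.0 <= tr.enc(counts) <= 61.0

    def test_no_usable_family_errors(self):
        with pytest.raises(ValueError):
            tr.enc(tr.CodonCounts(np.zeros(59)))

    def test_missing_three_fold_family_imputed(self):
        counts = fully_biased_counts().counts.copy()
        for codon in SYNONYMOUS_FAMILIES["I"]:  # drop all Ile observations
            counts[codon] = 0
        assert tr.enc(tr.CodonCounts(counts)) == 20.0  # F3 imputed from F2=F4=1


class TestEncPrime:
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=59, max_size=59)
    )
    def test_reduces_to_enc_under_uniform_background(self, raw):
        counts = tr.CodonCounts(np.asarray(raw, dtype=float))
        total_by_family = {
            aa: counts.family_counts(aa).sum() for aa in SYNONYMOUS_FAMILIES
        }
        if all(t < 2 for t in total_by_family.values()):
            return  # no usable family; both estimators reject
        try:
            expected = tr.enc(counts)
        except ValueError:
            with pytest.raises(ValueError):
                tr.enc_prime(counts, [0.25] * 4)
            return
        assert tr.enc_prime(counts, [0.25] * 4) == pytest.approx(expected, abs=1e-9)

    def test_full_bias_uniform_background(self):
        assert tr.enc_prime(fully_biased_counts(), [0.25] * 4) == 20.0

    def test_correction_removes_composition(self):
        # counts exactly proportional to a skewed background's expectations:
        # ENC' says no bias beyond composition (61) while plain ENC < 61
        background = np.array([0.4, 0.3, 0.2, 0.1])
        digits = {"A": 4, "C": 3, "G": 2, "T": 1}
        counts = {}
        for codons in SYNONYMOUS_FAMILIES.values():
            for codon in codons:
                w = digits[codon[0]] * digits[codon[1]] * digits[codon[2]]
                counts[codon] = 50 * w  # integer counts proportional to expectation
        cc = tr.CodonCounts(counts)
        assert tr.enc_prime(cc, background) == 61.0
        assert tr.enc(cc) < 61.0

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError):
            tr.enc_prime(uniform_counts(5), [0.5, 0.5, 0.0, 0.0])


class TestCodonUsageBias:
    def test_single_fully_biased_gene(self):
        assert tr.codon_usage_bias([fully_biased_counts()], [0.25] * 4) == 0.05

    def test_uniform_genes(self):
        cub = tr.codon_usage_bias([uniform_counts(10)] * 3, [0.25] * 4)
        assert cub == pytest.approx(1 / 61)

    def test_mean_inverse(self):
        genes = [fully_biased_counts(), uniform_counts(10)]  # ENC' = 20 and 61
        assert tr.codon_usage_bias(genes, [0.25] * 4) == pytest.approx(1 / 40.5)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            genes = [
                tr.CodonCounts(rng.integers(0, 30, size=59).astype(float))
                for _ in range(3)
            ]
            assert 1 / 61 <= tr.codon_usage_bias(genes) <= 1 / 20

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            tr.codon_usage_bias([])


class TestAnnotationTraits:
    @pytest.mark.parametrize(
        "u,a,expected", [(0, 5, 0.0), (5, 5, 0.5), (3, 7, 0.3)]
    )
    def test_proportion_unannotated(self, u, a, expected):
        assert tr.proportion_unannotated(u, a) == pytest.approx(expected)

    def test_proportion_unannotated_zero_total(self):
        with pytest.raises(ValueError):
            tr.proportion_unannotated(0, 0)

    def test_sap_weights_one_degeneracy(self):
        abund = pd.Series({"g1": 30.0, "g2": 10.0})
        pm = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "class": ["sugar", "acid"], "weight": [1.0, 1.0]}
        )
        assert tr.sugar_acid_preference(abund, pm) == (3.0, 3.0)

    def test_sap_shared_gene_downweighted(self):
        # two sugar genes (abund 2 each, one in 2 pathways -> w = 0.5),
        # one acid gene (abund 2, w = 1): unweighted 2.0, weighted 1.5
        abund = pd.Series({"s1": 2.0, "s2": 2.0, "a1": 2.0})
        pm = pd.DataFrame(
            {
                "gene_id": ["s1", "s2", "s2", "a1"],
                "class": ["sugar", "sugar", "sugar", "acid"],
                "pathway": ["p1", "p1", "p2", "p3"],
            }
        )
        weighted, unweighted = tr.sugar_acid_preference(abund, pm)
        assert unweighted == pytest.approx(2.0)
        assert weighted == pytest.approx(1.5)

    def test_sap_zero_acid_errors(self):
        abund = pd.Series({"g1": 1.0, "g2": 0.0})
        pm = pd.DataFrame({"gene_id": ["g1", "g2"], "class": ["sugar", "acid"]})
        with pytest.raises(ValueError):
            tr.sugar_acid_preference(abund, pm)


class TestCodonIO:
    def test_sequence_round_trip(self):
        seq = "TTTTTCGGG"  # Phe, Phe, Gly
        counts = tr.codon_counts_from_sequence(seq)
        assert counts.counts["TTT"] == 1 and counts.counts["TTC"] == 1
        assert counts.counts["GGG"] == 1

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            tr.codon_counts_from_sequence("TTTT")


class TestTraitProfiles:
    def test_single_sample_consistency(self, two_genome_panel):
        s = syn.simulate_read_summary(
            two_genome_panel, [1.0, 1.0], depth_factor=1, noise="none",
            n_reads=100, seed=0, sample_id="s1",
        )
        table = syn.summaries_to_table([s])
        profiles = tr.compute_trait_profiles(table, read_gc={"s1": s.read_gc})
        geq = tr.genome_equivalents(s.scg_coverage)
        assert profiles.loc["s1", "ags_bp"] == tr.average_genome_size(s.total_bases, geq)
        assert profiles.loc["s1", "acn"] == tr.average_16s_copy_number(s.ssu_coverage, geq)
        mean, var = tr.gc_statistics(s.read_gc)
        assert profiles.loc["s1", "gc_mean"] == mean
        assert np.isnan(profiles.loc["s1", "cub"])  # flagged missing, not zero

    def test_inconsistent_sample_sets_error_lists_mismatch(self, two_genome_panel):
        s = syn.simulate_read_summary(
            two_genome_panel, [1.0, 1.0], n_reads=50, seed=0, sample_id="s1"
        )
        table = syn.summaries_to_table([s])
        with pytest.raises(ValueError, match="s2"):
            tr.compute_trait_profiles(table, read_gc={"s2": s.read_gc})
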