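"""Generator contracts: determinism, moment recovery, coverage conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metatraits import synthetic as syn
from metatraits.traits import enc
from metatraits._util import sha256_of


class TestGenerateGenomes:
    def test_empty_panel(self):
        panel = syn.generate_genomes(0, seed=1)
        assert len(panel) == 0

    def test_same_seed_identical(self):
        a = syn.generate_genomes(50, seed=3)
        b = syn.generate_genomes(50, seed=3)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_lognormal_mean_recovered(self):
        # sample mean of lognormal(mu, sigma) converges to exp(mu + sigma^2/2)
        mu, sigma, n = float(np.log(3e6)), 0.4, 5000
        panel = syn.generate_genomes(n, size_mu=mu, size_sigma=sigma, seed=5)
        expected = np.exp(mu + sigma**2 / 2)
        mc_se = np.sqrt((np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2) / n)
        assert abs(panel.length_bp.mean() - expected) < 3 * mc_se

    def test_field_invariants(self):
        panel = syn.generate_genomes(200, seed=7)
        assert (panel.length_bp > 0).all()
        assert ((panel.gc_fraction > 0) & (panel.gc_fraction < 1)).all()
        assert (panel.rrn_copies >= 1).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_genomes(10, gc_a=-1.0)
        with pytest.raises(ValueError):
            syn.generate_genomes(-1)


class TestReadSummary:
    def test_single_genome_identity(self):
        panel = syn.GenomePanel(("g",), np.array([4_000_000]), np.array([0.5]), np.array([1]))
        s = syn.simulate_read_summary(panel, [1.0], depth_factor=10, noise="none", seed=0)
        assert np.allclose(s.scg_coverage, 10.0)
        assert s.total_bases == 40_000_000
        assert s.ssu_coverage == 10.0

    def test_two_genome_arithmetic(self, two_genome_panel):
        s = syn.simulate_read_summary(
            two_genome_panel, [1.0, 1.0], depth_factor=1, noise="none", seed=0
        )
        assert np.allclose(s.scg_coverage, 2.0)
        assert s.total_bases == 8e6
        assert s.ssu_coverage == 8.0  # 1 + 7 rrn copies

    def test_all_zero_abundance_errors(self, two_genome_panel):
        with pytest.raises(ValueError, match="all-zero"):
            syn.simulate_read_summary(two_genome_panel, [0.0, 0.0])

    def test_read_gc_in_open_interval(self, two_genome_panel):
        s = syn.simulate_read_summary(
            two_genome_panel, [1.0, 2.0], n_reads=500, seed=4
        )
        assert s.read_gc.shape == (500,)
        assert ((s.read_gc > 0) & (s.read_gc < 1)).all()

    def test_poisson_noise_centred_on_contract(self, two_genome_panel):
        s = syn.simulate_read_summary(
            two_genome_panel, [50.0, 50.0], depth_factor=10, noise="poisson", seed=8
        )
        # mean coverage 1000; 35 draws give a tight mean
        assert abs(s.scg_coverage.mean() - 1000) < 4 * np.sqrt(1000 / 35)


class TestGeneCatalog:
    def test_all_unannotated_boundary(self):
        catalog, _, _ = syn.simulate_gene_catalog(100, label_scheme={}, seed=1)
        assert all(lab == () for lab in catalog.labels_of().values())

    def test_unannotated_abundance_in_binomial_interval(self):
        # u = 0.4, equal true abundances: realized unannotated count fraction
        # falls in the 99% binomial interval
        u, n_genes = 0.4, 10_000
        scheme = {"cat_a": 0.3, "cat_b": 0.3}
        catalog, matrix, _ = syn.simulate_gene_catalog(
            n_genes, label_scheme=scheme, abundance_mode="equal",
            reads_per_sample=50_000, seed=2,
        )
        labels = catalog.labels_of()
        counts = matrix.counts.iloc[:, 0]
        unannot = counts[[len(labels[g]) == 0 for g in counts.index]].sum()
        lo, hi = stats.binom(counts.sum(), u).ppf([0.005, 0.995])
        assert lo <= unannot <= hi

    def test_fixed_seed_identical(self):
        a = syn.simulate_gene_catalog(500, seed=9)
        b = syn.simulate_gene_catalog(500, seed=9)
        pd.testing.assert_frame_equal(a[0].frame, b[0].frame)
        pd.testing.assert_frame_equal(a[1].counts, b[1].counts)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_gene_catalog(10, label_scheme={"x": -0.1})


class TestCodonCounts:
    def test_full_bias_gives_enc_20(self):
        genes = syn.simulate_codon_counts(1.0, n_genes=3, codons_per_gene=300, seed=3)
        assert all(enc(g) == 20.0 for g in genes)

    def test_uniform_limit_gives_enc_near_61(self):
        gene = syn.simulate_codon_counts(0.0, n_genes=1, codons_per_gene=500_000, seed=3)[0]
        assert enc(gene) > 60.5

    def test_bias_ladder_monotone(self):
        means = []
        for b in (0.0, 0.5, 1.0):
            genes = syn.simulate_codon_counts(b, n_genes=10, codons_per_gene=400, seed=6)
            means.append(np.mean([enc(g) for g in genes]))
        assert means[0] > means[1] > means[2]

    def test_bias_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_codon_counts(1.5)


class TestVirusHost:
    def test_temperate_fraction_in_binomial_interval(self, small_panel, small_truth):
        viral = syn.simulate_virus_host(
            small_panel, small_truth, n_viruses=200, p_temperate=0.7, seed=4
        )
        n_temp = (viral.meta["lifestyle"] == "temperate").sum()
        lo, hi = stats.binom(200, 0.7).ppf([0.005, 0.995])
        assert lo <= n_temp <= hi

    def test_negative_noise_rejected(self, small_panel, small_truth):
        with pytest.raises(ValueError):
            syn.simulate_virus_host(small_panel, small_truth, noise_sd=-0.1)

    def test_host_links_resolve(self, small_panel, small_truth):
        viral = syn.simulate_virus_host(small_panel, small_truth, n_viruses=50, seed=5)
        assert set(viral.meta["host_genome_id"]) <= set(small_panel.genome_id)


class TestFixtureIO:
    @pytest.fixture()
    def fixture_objects(self, small_panel, small_design, small_truth):
        summaries = [
            syn.simulate_read_summary(
                small_panel, small_truth.abundance[s].to_numpy(),
                n_reads=100, seed=1, sample_id=s,
            )
            for s in small_design.sample_ids
        ]
        catalog, gene_counts, _ = syn.simulate_gene_catalog(
            100, sample_ids=small_design.sample_ids, reads_per_sample=5000, seed=1
        )
        codon_sets = {
            s: syn.simulate_codon_counts(0.3, n_genes=3, codons_per_gene=120, seed=i)
            for i, s in enumerate(small_design.sample_ids)
        }
        viral = syn.simulate_virus_host(small_panel, small_truth, n_viruses=20, seed=1)
        return dict(
            panel=small_panel, design=small_design, truth=small_truth,
            summaries=summaries, catalog=catalog, gene_counts=gene_counts,
            codon_sets=codon_sets, viral=viral,
        )

    def test_round_trip(self, tmp_path, fixture_objects):
        fo = fixture_objects
        syn.write_fixture(
            tmp_path / "fx", fo["panel"], fo["design"], fo["truth"], fo["summaries"],
            fo["catalog"], fo["gene_counts"], fo["codon_sets"], fo["viral"], seed=1,
        )
        fx = syn.read_fixture(tmp_path / "fx")
        pd.testing.assert_frame_equal(fx["panel"].to_frame(), fo["panel"].to_frame())
        pd.testing.assert_frame_equal(fx["truth"].abundance, fo["truth"].abundance)
        pd.testing.assert_frame_equal(fx["viral"].abundance, fo["viral"].abundance)
        # codon tables survive the FASTA round trip exactly
        for s, genes in fo["codon_sets"].items():
            assert fx["codon_sets"][s] == list(genes)

    def test_byte_identical_across_runs(self, tmp_path, fixture_objects):
        fo = fixture_objects
        sums = []
        for d in ("a", "b"):
            paths = syn.write_fixture(
                tmp_path / d, fo["panel"], fo["design"], fo["truth"], fo["summaries"],
                fo["catalog"], fo["gene_counts"], fo["codon_sets"], fo["viral"], seed=1,
            )
            sums.append([sha256_of(p) for p in sorted(paths)])
        assert sums[0] == sums[1]


class TestAbundanceTruth:
    def test_true_summaries(self, two_genome_panel):
        truth = syn.AbundanceTruth(
            pd.DataFrame({"s1": [1.0, 1.0]}, index=["gA", "gB"])
        )
        assert truth.true_ags(two_genome_panel)["s1"] == 4e6
        assert truth.true_acn(two_genome_panel)["s1"] == 4.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            syn.AbundanceTruth(pd.DataFrame({"s1": [-1.0]}, index=["g"]))
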