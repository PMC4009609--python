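"""Generator checks: mixture composition, count structure, convergence."""

import math

import numpy as np
import pandas as pd
import pytest

from regevol import SimulationConfig, sample_gene_effects, simulate_experiment
from regevol.containers import ROLE_HYBRID1, ROLE_HYBRID2
from regevol.simulate import ConfigError


def _truths(**kw):
    return sample_gene_effects(SimulationConfig(**kw))


class TestGeneEffects:
    def test_degenerate_conserved_mixture(self):
        truths = _truths(architecture_proportions={"conserved": 1.0}, n_genes=100)
        assert len(truths) == 100
        assert all(t.cis_log2 == 0 and t.trans_log2 == 0 for t in truths)

    def test_compensatory_effects_cancel_exactly(self):
        truths = _truths(
            architecture_proportions={"compensatory": 1.0},
            n_genes=50,
            cis_low=1.0,
            cis_high=1.0,
        )
        assert all(
            (t.cis_log2, t.trans_log2) in {(1.0, -1.0), (-1.0, 1.0)} for t in truths
        )

    def test_mixture_split_and_magnitude_mean(self):
        truths = _truths(
            architecture_proportions={"all_cis": 0.5, "all_trans": 0.5},
            n_genes=1000,
            seed=1,
        )
        archs = pd.Series([t.architecture for t in truths]).value_counts()
        assert archs["all_cis"] == 500 and archs["all_trans"] == 500
        cfg = SimulationConfig()
        mags = np.abs([t.cis_log2 for t in truths if t.architecture == "all_cis"])
        mean = (cfg.cis_low + cfg.cis_high) / 2
        se = (cfg.cis_high - cfg.cis_low) / math.sqrt(12 * len(mags))
        assert abs(mags.mean() - mean) < 3 * se

    def test_signs_balanced(self):
        truths = _truths(
            architecture_proportions={"all_cis": 1.0}, n_genes=2000, seed=3
        )
        pos = sum(t.cis_log2 > 0 for t in truths)
        assert abs(pos - 1000) < 3 * math.sqrt(2000 * 0.25)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigError):
            _truths(architecture_proportions={"conserved": 0.8})
        with pytest.raises(ConfigError):
            _truths(architecture_proportions={"nonsense": 1.0})


class TestSimulateExperiment:
    def test_column_sums_exact_without_overdispersion(self, small_experiment):
        cfg, exp = small_experiment
        assert (exp.counts.counts.sum() == cfg.library_size).all()

    def test_allele_counts_bounded_by_totals(self, small_experiment):
        _, exp = small_experiment
        for s in exp.alleles.samples:
            assert (exp.alleles.totals(s) <= exp.counts.counts[s].to_numpy()).all()

    def test_seed_reproducibility_byte_identical(self):
        cfg = SimulationConfig(n_genes=100, library_size=50_000, seed=9)
        a, b = simulate_experiment(cfg), simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.alleles.counts, b.alleles.counts)
        pd.testing.assert_series_equal(a.cross_map_rate, b.cross_map_rate)

    def test_conserved_hybrid_allele_share_is_half(self):
        cfg = SimulationConfig(n_genes=500, library_size=2_000_000, seed=4)
        exp = simulate_experiment(cfg)
        h1 = exp.alleles.sample_for_role(ROLE_HYBRID1)
        a1, a2 = exp.alleles.pair(h1)
        n = int((a1 + a2).sum())
        share = a1.sum() / n
        assert abs(share - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_cis_gene_ratio_converges_at_high_depth(self):
        # one strong cis gene among a conserved background, depth 1e6
        cfg = SimulationConfig(
            n_genes=10,
            library_size=1_000_000,
            architecture_proportions={"all_cis": 0.1, "conserved": 0.9},
            cis_low=1.0,
            cis_high=1.0,
            informative_mean=0.99,
            informative_concentration=5000.0,
            seed=6,
        )
        exp = simulate_experiment(cfg)
        truth = exp.truth_frame()
        gene = truth.index[truth.architecture == "all_cis"][0]
        h1 = exp.alleles.sample_for_role(ROLE_HYBRID1)
        a1, a2 = exp.alleles.pair(h1)
        i = list(exp.alleles.gene_ids).index(gene)
        ratio = a1[i] / a2[i]
        expect = 2.0 ** truth.loc[gene, "cis_log2"]
        assert ratio == pytest.approx(expect, rel=0.05)
        # parental count ratio matches the same (all-cis) total effect
        c = exp.counts.counts.loc[gene]
        assert c["parent1"] / c["parent2"] == pytest.approx(expect, rel=0.05)

    def test_mito_reads_are_maternal_only(self, small_experiment):
        _, exp = small_experiment
        mito = exp.truth_frame()["is_mito"].to_numpy()
        assert mito.sum() == 3
        h1 = exp.alleles.sample_for_role(ROLE_HYBRID1)
        h2 = exp.alleles.sample_for_role(ROLE_HYBRID2)
        assert exp.alleles.pair(h1)[1][mito].sum() == 0  # cross 1: mother = parent 1
        assert exp.alleles.pair(h2)[0][mito].sum() == 0  # cross 2: mother = parent 2

    def test_imprinting_artifact_shifts_cross1_only(self):
        cfg = SimulationConfig(
            n_genes=50,
            library_size=500_000,
            n_imprinted=5,
            imprinted_shift=0.4,
            seed=8,
        )
        exp = simulate_experiment(cfg)
        assert len(exp.imprinted_genes) == 5
        idx = [list(exp.alleles.gene_ids).index(g) for g in exp.imprinted_genes]
        for role, lo, hi in ((ROLE_HYBRID1, 0.8, 1.0), (ROLE_HYBRID2, 0.35, 0.65)):
            s = exp.alleles.sample_for_role(role)
            a1, a2 = exp.alleles.pair(s)
            share = a1[idx].sum() / (a1[idx] + a2[idx]).sum()
            assert lo <= share <= hi

    def test_overdispersion_inflates_variance_but_keeps_depth_close(self):
        base = dict(n_genes=200, library_size=100_000, seed=10)
        tight = simulate_experiment(SimulationConfig(**base))
        wide = simulate_experiment(SimulationConfig(**base, overdispersion=0.5))
        # same expected depth; dispersed counts spread further around it
        assert wide.counts.counts["parent1"].sum() == 100_000
        r_t = tight.counts.counts["parent1"] / tight.counts.counts["parent2"]
        r_w = wide.counts.counts["parent1"] / wide.counts.counts["parent2"]
        assert np.log(r_w).std() > np.log(r_t).std() * 2
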