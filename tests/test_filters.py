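"""Gene-inclusion rules: boundaries, idempotence, order independence."""

import math

import numpy as np
import pandas as pd
import pytest

from regevol import SimulationConfig, simulate_experiment
from regevol.containers import (
    ROLE_HYBRID1,
    ROLE_HYBRID2,
    CountMatrix,
    ROLE_PARENT1,
    ROLE_PARENT2,
    allele_table_from_pairs,
)
from regevol.filters import (
    build_filter_report,
    filter_allele_assignment,
    filter_imprinting,
    filter_min_reads,
    maternal_fraction_qc,
)


class TestMinReads:
    def test_boundary_inclusive_and_min_over_samples(self):
        df = pd.DataFrame(
            {"a": [20, 19, 1000], "b": [20, 1000, 1000], "c": [20, 1000, 19]},
            index=["g0", "g1", "g2"],
        )
        m = CountMatrix(df, {s: r for s, r in zip("abc", (ROLE_PARENT1, ROLE_PARENT2, ROLE_HYBRID1))})
        mask = filter_min_reads(m, 20)
        assert mask.tolist() == [True, False, False]

    def test_allele_version_uses_pair_totals(self, tiny_allele_table):
        # gc totals: p1=40, h2=45 ... threshold 46 keeps nothing for gc
        mask = filter_min_reads(tiny_allele_table, 46, samples=["h1", "h2"])
        assert mask.loc["gc"] == False  # noqa: E712  (45 < 46 in h1/h2)
        assert mask.loc["ga"] == True  # noqa: E712

    def test_removed_fraction_matches_binomial_tail(self):
        # conserved simulation at shallow depth: P(count < 20) from the
        # multinomial marginal Binomial(L, mu_g / sum mu) per gene
        cfg = SimulationConfig(n_genes=300, library_size=15_000, seed=21)
        exp = simulate_experiment(cfg)
        from scipy.stats import binom

        counts = exp.counts.counts
        p_gene = counts.mean(axis=1) / cfg.library_size  # plug-in proportions
        p_below = binom.cdf(19, cfg.library_size, p_gene)
        p_any = 1 - (1 - p_below) ** 4  # 4 independent libraries
        expect = p_any.sum()
        observed = int((~filter_min_reads(exp.counts, 20)).sum())
        se = math.sqrt(float((p_any * (1 - p_any)).sum()))
        assert abs(observed - expect) < 3 * max(se, 1.0)


class TestAlleleAssignment:
    def test_boundary_strictly_greater(self):
        rate = pd.Series([0.10, 0.11, 0.0], index=["g0", "g1", "g2"])
        mask = filter_allele_assignment(rate, 0.10)
        assert mask.tolist() == [True, False, True]

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="g0"):
            filter_allele_assignment(pd.Series([1.2], index=["g0"]))

    def test_simulated_high_rate_genes_all_fail(self):
        cfg = SimulationConfig(
            n_genes=200, library_size=20_000, cross_map_high_fraction=0.05, seed=5
        )
        exp = simulate_experiment(cfg)
        mask = filter_allele_assignment(exp.cross_map_rate)
        assert (~mask).sum() == 10
        assert set(exp.cross_map_rate[~mask]) == {0.2}


class TestImprinting:
    def _table(self, h1_pairs, h2_pairs):
        n = len(h1_pairs[0])
        return allele_table_from_pairs(
            [f"g{i}" for i in range(n)],
            {"h1": h1_pairs, "h2": h2_pairs},
            {"h1": ROLE_HYBRID1, "h2": ROLE_HYBRID2},
        )

    def test_identical_ratios_retained(self):
        t = self._table(([50, 10], [50, 10]), ([50, 10], [50, 10]))
        mask, report = filter_imprinting(t, "h1", "h2")
        assert mask.all()
        assert (report["p_imprinting"] == 1.0).all()

    def test_flipped_extreme_gene_removed(self):
        a1 = [1000] + [50] * 20
        a2 = [10] + [50] * 20
        t = self._table((np.array(a1), np.array(a2)), (np.array(a2), np.array(a1)))
        mask, _ = filter_imprinting(t, "h1", "h2")
        assert not mask.iloc[0]
        assert mask.iloc[1:].all()

    def test_missing_hybrid_errors(self):
        t = self._table(([10], [10]), ([10], [10]))
        with pytest.raises(ValueError, match="missing"):
            filter_imprinting(t, "h1", "nope")

    def test_null_simulation_removes_almost_nothing(self):
        removed = 0
        total = 0
        for seed in range(5):
            exp = simulate_experiment(
                SimulationConfig(n_genes=400, library_size=400_000, seed=100 + seed)
            )
            h1 = exp.alleles.sample_for_role(ROLE_HYBRID1)
            h2 = exp.alleles.sample_for_role(ROLE_HYBRID2)
            mask, _ = filter_imprinting(exp.alleles, h1, h2)
            removed += int((~mask).sum())
            total += len(mask)
        assert removed / total <= 0.05


class TestMaternalFraction:
    def test_simulator_default_is_one(self, small_experiment):
        _, exp = small_experiment
        mito = exp.truth_frame()["is_mito"]
        h1 = exp.alleles.sample_for_role(ROLE_HYBRID1)
        h2 = exp.alleles.sample_for_role(ROLE_HYBRID2)
        out = maternal_fraction_qc(exp.alleles, mito, {h1: "a1", h2: "a2"})
        assert out[h1] == 1.0 and out[h2] == 1.0

    def test_arithmetic(self):
        t = allele_table_from_pairs(
            ["mt0"], {"h1": ([995], [5])}, {"h1": ROLE_HYBRID1}
        )
        out = maternal_fraction_qc(t, pd.Series([True], index=["mt0"]), {"h1": "a1"})
        assert out["h1"] == pytest.approx(0.995)

    def test_no_mito_reads_warns_and_is_missing(self):
        t = allele_table_from_pairs(
            ["g0"], {"h1": ([5], [5])}, {"h1": ROLE_HYBRID1}
        )
        with pytest.warns(UserWarning, match="maternal-fraction"):
            out = maternal_fraction_qc(t, pd.Series([False], index=["g0"]), {"h1": "a1"})
        assert math.isnan(out["h1"])


class TestCombinedReport:
    def _report(self, exp, **kw):
        truth = exp.truth_frame()
        h1 = exp.alleles.sample_for_role(ROLE_HYBRID1)
        h2 = exp.alleles.sample_for_role(ROLE_HYBRID2)
        return build_filter_report(
            exp.alleles,
            exp.cross_map_rate,
            truth["is_mito"],
            h1,
            h2,
            allele_samples=[h1, h2],
            **kw,
        )

    def test_mask_is_intersection_and_idempotent(self, small_experiment):
        _, exp = small_experiment
        rep = self._report(exp)
        f = rep.flags
        expect = (
            f["passes_min_reads"]
            & f["passes_allele_assignment"]
            & f["passes_imprinting"]
            & ~f["is_mito"]
        )
        assert rep.final_mask.equals(expect)
        # masks are deterministic: recomputation gives identical flags
        rep2 = self._report(exp)
        pd.testing.assert_frame_equal(rep.flags, rep2.flags)

    def test_mito_excluded_from_final_set(self, small_experiment):
        _, exp = small_experiment
        rep = self._report(exp)
        mito_genes = exp.truth_frame().index[exp.truth_frame()["is_mito"]]
        assert not rep.final_mask.loc[mito_genes].any()

    def test_removal_counts_sum_to_total_removed(self, small_experiment):
        _, exp = small_experiment
        rep = self._report(exp)
        assert sum(rep.removed.values()) == int((~rep.final_mask).sum())
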