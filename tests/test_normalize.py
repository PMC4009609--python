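"""Down-sampling: exact depth conservation, unbiasedness, mixed construction."""

import math

import numpy as np
import pandas as pd
import pytest

from regevol.containers import (
    ROLE_HYBRID1,
    ROLE_HYBRID2,
    ROLE_MIXED,
    ROLE_PARENT1,
    ROLE_PARENT2,
    CountMatrix,
    allele_table_from_pairs,
)
from regevol.normalize import (
    build_mixed_parental,
    downsample_alleles,
    downsample_total,
    thin_alleles,
)


def _matrix(cols: dict[str, list[int]]) -> CountMatrix:
    roles = dict(zip(cols, (ROLE_PARENT1, ROLE_PARENT2, ROLE_HYBRID1, ROLE_HYBRID2)))
    return CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))]), roles)


class TestDownsampleTotal:
    def test_sample_already_at_target_unchanged(self):
        m = _matrix({"a": [600, 400], "b": [300, 200]})
        out = downsample_total(m, 500, seed=0)
        assert out.counts["b"].tolist() == [300, 200]
        assert out.counts["a"].sum() == 500

    def test_every_column_sums_exactly_to_target(self):
        rng = np.random.default_rng(0)
        m = _matrix({k: rng.integers(0, 500, 50).tolist() for k in "abcd"})
        target = int(m.counts.sum().min())
        out = downsample_total(m, target, seed=1)
        assert (out.counts.sum() == target).all()

    def test_target_zero_gives_all_zero(self):
        m = _matrix({"a": [600, 400], "b": [5, 5]})
        out = downsample_total(m, 0, seed=0)
        assert (out.counts == 0).all().all()

    def test_error_names_underdepth_sample(self):
        m = _matrix({"a": [600, 400], "b": [5, 5]})
        with pytest.raises(ValueError, match="'b'"):
            downsample_total(m, 500)

    def test_hypergeometric_mean_unbiased(self):
        # (600, 400) down to 500: expected retained gene-1 count is 300
        m = _matrix({"a": [600, 400], "b": [600, 400]})
        draws = np.array(
            [downsample_total(m, 500, seed=s).counts.iloc[0, 0] for s in range(2000)]
        )
        var = 500 * 0.6 * 0.4 * (1000 - 500) / (1000 - 1)
        se = math.sqrt(var / len(draws))
        assert abs(draws.mean() - 300) < 3 * se

    def test_seed_determinism(self):
        m = _matrix({"a": [600, 400], "b": [600, 400]})
        x = downsample_total(m, 500, seed=7).counts
        y = downsample_total(m, 500, seed=7).counts
        pd.testing.assert_frame_equal(x, y)


def _alleles(pairs, roles=None):
    n = len(next(iter(pairs.values()))[0])
    roles = roles or {
        s: r
        for s, r in zip(pairs, (ROLE_PARENT1, ROLE_PARENT2, ROLE_HYBRID1, ROLE_HYBRID2))
    }
    return allele_table_from_pairs([f"g{i}" for i in range(n)], pairs, roles)


class TestMixedParental:
    def test_definition(self):
        t = _alleles(
            {"p1": ([120, 0], [0, 0]), "p2": ([0, 0], [80, 0])},
            {"p1": ROLE_PARENT1, "p2": ROLE_PARENT2},
        )
        out = build_mixed_parental(t, "p1", "p2", parent_depths=(1000, 1000))
        a1, a2 = out.pair("mixed_parental")
        assert a1.tolist() == [120, 0] and a2.tolist() == [80, 0]
        assert out.roles["mixed_parental"] == ROLE_MIXED

    def test_unequal_parental_depths_rejected(self):
        t = _alleles(
            {"p1": ([10], [0]), "p2": ([0], [10])},
            {"p1": ROLE_PARENT1, "p2": ROLE_PARENT2},
        )
        with pytest.raises(ValueError, match="equal parental read depths"):
            build_mixed_parental(t, "p1", "p2", parent_depths=(1000, 900))

    def test_identical_parents_center_log_ratio_at_zero(self):
        # all-conserved world: genome-wide mixed log2(a1/a2) centered at 0
        from regevol import SimulationConfig, simulate_experiment

        exp = simulate_experiment(
            SimulationConfig(n_genes=400, library_size=2_000_000, seed=13)
        )
        t = build_mixed_parental(
            exp.alleles,
            exp.alleles.sample_for_role(ROLE_PARENT1),
            exp.alleles.sample_for_role(ROLE_PARENT2),
        )
        a1, a2 = t.pair("mixed_parental")
        ok = (a1 > 0) & (a2 > 0)
        lr = np.log2(a1[ok] / a2[ok])
        assert abs(np.mean(lr)) < 3 * lr.std() / math.sqrt(ok.sum())


class TestDownsampleAlleles:
    def test_minimal_sample_and_equal_totals_unchanged(self):
        t = _alleles({"x": ([90], [10]), "y": ([40], [60]), "z": ([50], [50])})
        out = downsample_alleles(t, seed=0)
        for s in ("x", "y", "z"):
            assert out.totals(s).tolist() == [100]
            if s == "x":
                pass  # totals equal everywhere: all unchanged
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_reduction_to_per_gene_minimum(self):
        t = _alleles({"x": ([90], [10]), "y": ([40], [60]), "z": ([30], [30])})
        out = downsample_alleles(t, seed=1)
        assert out.totals("x").tolist() == [60]
        assert out.totals("y").tolist() == [60]
        assert out.pair("z")[0].tolist() == [30]  # minimal sample untouched

    def test_hypergeometric_mean_for_reduced_pair(self):
        t = _alleles({"x": ([90], [10]), "y": ([40], [60]), "z": ([30], [30])})
        vals = np.array(
            [downsample_alleles(t, seed=s).pair("x")[0][0] for s in range(2000)]
        )
        var = 60 * 0.9 * 0.1 * (100 - 60) / (100 - 1)
        se = math.sqrt(var / len(vals))
        assert abs(vals.mean() - 54) < 3 * se

    def test_zero_total_collapses_gene_everywhere(self):
        t = _alleles({"x": ([90], [10]), "y": ([0], [0]), "z": ([30], [30])})
        out = downsample_alleles(t, seed=0)
        for s in ("x", "y", "z"):
            assert out.totals(s).tolist() == [0]

    def test_totals_conserved_across_samples(self, small_experiment):
        _, exp = small_experiment
        out = downsample_alleles(exp.alleles, seed=3)
        totals = np.column_stack([out.totals(s) for s in out.samples])
        assert (totals == totals[:, :1]).all()
        assert (totals[:, 0] == np.column_stack(
            [exp.alleles.totals(s) for s in exp.alleles.samples]
        ).min(axis=1)).all()


class TestThinAlleles:
    def test_total_kept_exact_and_bounded(self, tiny_allele_table):
        out = thin_alleles(tiny_allele_table, "h1", 100, seed=0)
        assert int(out.totals("h1").sum()) == 100
        a1, a2 = out.pair("h1")
        o1, o2 = tiny_allele_table.pair("h1")
        assert (a1 <= o1).all() and (a2 <= o2).all()

    def test_keep_everything_is_identity(self, tiny_allele_table):
        total = int(tiny_allele_table.totals("h1").sum())
        out = thin_alleles(tiny_allele_table, "h1", total, seed=0)
        pd.testing.assert_frame_equal(out.counts, tiny_allele_table.counts)
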