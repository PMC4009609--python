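"""Pipeline orchestration: simulate -> normalize -> filter -> test -> classify -> summarize.

One *comparison* is a pair of parental genotypes plus their two reciprocal F1
hybrids.  :func:`run_comparison` executes the full per-comparison analysis:

Total-expression side
    down-sample every library to a common depth; apply the minimum-read
    floor; per-gene Fisher tests of each genotype pair (gene vs rest of the
    library); inheritance-mode calls for each hybrid.

Allele-specific side
    thin each sample's allele-informative reads in proportion to the
    total-depth down-sampling; build the in-silico mixed-parental sample;
    apply the allele-data-set filters; equalize per-gene allele totals
    across samples; binomial tests for parental and allelic (cis) imbalance
    and Fisher tests for trans; cis/trans effect sizes, %cis, and regulatory
    classes — separately for each reciprocal hybrid.

:func:`run_study` runs several comparisons (ordered by divergence time) and
adds the cross-comparison layers: the nine-class per-gene trajectory
analysis, tempo tables of significant-gene proportions with Fisher tests
between consecutive comparisons, and bootstrap comparisons of 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_FDR,
    DEFAULT_FOLD_CUTOFF,
    classify_inheritance,
    classify_regulatory,
    classify_trajectory,
    direction_concordance,
    direction_concordance_test,
    fold_change,
    pairwise_difference_call,
)
from .containers import (
    ROLE_HYBRID1,
    ROLE_HYBRID2,
    ROLE_MIXED,
    ROLE_PARENT1,
    ROLE_PARENT2,
    AlleleCountTable,
    CountMatrix,
)
from .filters import (
    DEFAULT_CROSS_MAP_MAX,
    DEFAULT_MIN_READS,
    FilterReport,
    build_filter_report,
    filter_min_reads,
)
from .normalize import build_mixed_parental, downsample_alleles, downsample_total, thin_alleles
from .simulate import SimulatedExperiment
from .stats import (
    bh_fdr,
    binomial_equal_expression_vec,
    cis_trans_effects,
    fet_gene_vs_rest_vec,
    fet_ratio_difference_vec,
    percent_cis,
)
from .summarize import bootstrap_rho, bootstrap_rho_difference, cis_total_regression, compare_proportions, spearman_divergence

TOTAL_ROLES = (ROLE_PARENT1, ROLE_PARENT2, ROLE_HYBRID1, ROLE_HYBRID2)


@dataclass
class AnalysisParams:
    """Thresholds and sizes shared across pipeline stages."""

    min_reads: int = DEFAULT_MIN_READS
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF
    fdr: float = DEFAULT_FDR
    cross_map_max: float = DEFAULT_CROSS_MAP_MAX
    target_depth: int | None = None
    n_boot: int = 10_000
    bootstrap: bool = True
    seed: int = 0


@dataclass
class ComparisonData:
    """Inputs of one comparison: counts, allele counts, and QC channels."""

    counts: CountMatrix
    alleles: AlleleCountTable
    cross_map_rate: pd.Series | None = None
    is_mito: pd.Series | None = None
    name: str = "comparison"

    @classmethod
    def from_simulation(
        cls, experiment: SimulatedExperiment, name: str = "comparison"
    ) -> "ComparisonData":
        truth = experiment.truth_frame()
        return cls(
            counts=experiment.counts,
            alleles=experiment.alleles,
            cross_map_rate=experiment.cross_map_rate,
            is_mito=truth["is_mito"],
            name=name,
        )

    def validate(self) -> None:
        for role in TOTAL_ROLES:
            self.counts.sample_for_role(role)  # raises if missing
            self.alleles.sample_for_role(role)
        if not self.counts.gene_ids.equals(self.alleles.gene_ids):
            raise ValueError(f"{self.name}: count and allele tables disagree on genes")


@dataclass
class ComparisonResult:
    name: str
    params: AnalysisParams
    target_depth: int
    total_counts: CountMatrix
    total_mask: pd.Series
    total_tests: dict[tuple[str, str], pd.DataFrame]
    inheritance: dict[str, pd.Series]
    parental_fold: pd.Series
    filter_report: FilterReport
    equalized: AlleleCountTable
    gene_results: dict[str, pd.DataFrame]
    summary: dict
    log: list[str] = field(default_factory=list)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("downsample_total", "thin_alleles", "equalize", "bootstrap")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _total_contrasts(roles: dict[str, str]) -> list[tuple[str, str]]:
    return [
        (ROLE_PARENT1, ROLE_PARENT2),
        (ROLE_HYBRID1, ROLE_PARENT1),
        (ROLE_HYBRID1, ROLE_PARENT2),
        (ROLE_HYBRID2, ROLE_PARENT1),
        (ROLE_HYBRID2, ROLE_PARENT2),
        (ROLE_HYBRID1, ROLE_HYBRID2),
    ]


def analyze_total(
    data: ComparisonData, params: AnalysisParams, seed: int
) -> tuple[CountMatrix, pd.Series, dict, dict, pd.Series, list[str]]:
    """Total-expression side: down-sample, floor-filter, pairwise tests."""
    log: list[str] = []
    depths = {s: data.counts.depth(s) for s in data.counts.samples}
    target = params.target_depth if params.target_depth is not None else min(depths.values())
    log.append(f"target depth: {target} (library depths {depths})")
    ds = downsample_total(data.counts, target, seed)

    mask = filter_min_reads(ds, params.min_reads)
    log.append(f"min-read floor ({params.min_reads}): removed {int((~mask).sum())} genes, kept {int(mask.sum())}")
    dsf = ds.subset_genes(mask)

    sample_of = {role: dsf.sample_for_role(role) for role in TOTAL_ROLES}
    totals = {role: int(dsf.counts[sample_of[role]].sum()) for role in TOTAL_ROLES}

    tests: dict[tuple[str, str], pd.DataFrame] = {}
    for role_a, role_b in _total_contrasts(dsf.roles):
        ca = dsf.counts[sample_of[role_a]].to_numpy()
        cb = dsf.counts[sample_of[role_b]].to_numpy()
        p = fet_gene_vs_rest_vec(ca, cb, totals[role_a], totals[role_b])
        q = bh_fdr(p)
        calls = [
            pairwise_difference_call(a, b, qq, params.fold_cutoff, params.fdr)
            for a, b, qq in zip(ca, cb, q)
        ]
        folds = [fold_change(a, b) for a, b in zip(ca, cb)]
        tests[(role_a, role_b)] = pd.DataFrame(
            {"count_a": ca, "count_b": cb, "fold": folds, "p": p, "q": q, "call": calls},
            index=dsf.gene_ids,
        )

    inheritance: dict[str, pd.Series] = {}
    p1 = dsf.counts[sample_of[ROLE_PARENT1]].to_numpy()
    p2 = dsf.counts[sample_of[ROLE_PARENT2]].to_numpy()
    for hyb in (ROLE_HYBRID1, ROLE_HYBRID2):
        h = dsf.counts[sample_of[hyb]].to_numpy()
        call_pp = tests[(ROLE_PARENT1, ROLE_PARENT2)]["call"].to_numpy()
        call_h1 = tests[(hyb, ROLE_PARENT1)]["call"].to_numpy()
        call_h2 = tests[(hyb, ROLE_PARENT2)]["call"].to_numpy()
        labels = [
            classify_inheritance(cp, c1, c2, a, b, hh)
            for cp, c1, c2, a, b, hh in zip(call_pp, call_h1, call_h2, p1, p2, h)
        ]
        inheritance[hyb] = pd.Series(labels, index=dsf.gene_ids, name=f"inheritance_{hyb}")

    parental_fold = pd.Series(
        tests[(ROLE_PARENT1, ROLE_PARENT2)]["fold"], name="parental_fold"
    )
    return ds, mask, tests, inheritance, parental_fold, log


def normalize_alleles(
    data: ComparisonData, target: int, seed: int
) -> AlleleCountTable:
    """Thin allele counts to the common total depth and add the mixed sample.

    Each sample's allele-informative reads are down-sampled in proportion to
    the whole-library down-sampling (emulating allele counting on the
    depth-equalized read sets), then the two parents' own-genome reads are
    pooled into the mixed-parental sample.
    """
    alleles = data.alleles
    thinnable = [s for s in alleles.samples if s in data.counts.samples]
    children = np.random.SeedSequence(seed).spawn(len(thinnable))
    for sample, child in zip(thinnable, children):
        total_depth = data.counts.depth(sample)
        if total_depth == target:
            continue
        informative = int(alleles.totals(sample).sum())
        n_keep = int(round(informative * target / total_depth))
        alleles = thin_alleles(
            alleles, sample, n_keep, int(child.generate_state(1)[0] % (2**31))
        )
    p1 = alleles.sample_for_role(ROLE_PARENT1)
    p2 = alleles.sample_for_role(ROLE_PARENT2)
    return build_mixed_parental(alleles, p1, p2, parent_depths=(target, target))


def analyze_alleles(
    alleles: AlleleCountTable,
    data: ComparisonData,
    params: AnalysisParams,
    seed: int,
) -> tuple[FilterReport, AlleleCountTable, dict[str, pd.DataFrame], list[str]]:
    """Allele-specific side: filters, per-gene equalization, tests, classes."""
    log: list[str] = []
    mixed = alleles.sample_for_role(ROLE_MIXED)
    h1 = alleles.sample_for_role(ROLE_HYBRID1)
    h2 = alleles.sample_for_role(ROLE_HYBRID2)
    genes = alleles.gene_ids

    xmap = (
        data.cross_map_rate.reindex(genes)
        if data.cross_map_rate is not None
        else pd.Series(0.0, index=genes)
    )
    mito = (
        data.is_mito.reindex(genes).fillna(False).astype(bool)
        if data.is_mito is not None
        else pd.Series(False, index=genes)
    )
    report = build_filter_report(
        alleles,
        xmap,
        mito,
        h1,
        h2,
        allele_samples=[mixed, h1, h2],
        min_reads=params.min_reads,
        cross_map_max=params.cross_map_max,
        imprint_fdr=params.fdr,
        maternal_allele={h1: "a1", h2: "a2"},
    )
    log.extend(report.log_lines())

    kept = alleles.subset_genes(report.final_mask)
    equalized = downsample_alleles(kept, seed, samples=[mixed, h1, h2])

    g1, g2 = equalized.pair(mixed)
    p_parental = binomial_equal_expression_vec(g1, g1 + g2)
    q_parental = bh_fdr(p_parental)

    results: dict[str, pd.DataFrame] = {}
    for hyb_role, hyb in ((ROLE_HYBRID1, h1), (ROLE_HYBRID2, h2)):
        a1, a2 = equalized.pair(hyb)
        p_cis = binomial_equal_expression_vec(a1, a1 + a2)
        q_cis = bh_fdr(p_cis)
        p_trans = fet_ratio_difference_vec(g1, g2, a1, a2)
        q_trans = bh_fdr(p_trans)

        total, cis, trans = cis_trans_effects(g1, g2, a1, a2)
        pct = percent_cis(cis, trans)
        sig_par = np.nan_to_num(q_parental, nan=1.0) <= params.fdr
        sig_cis = np.nan_to_num(q_cis, nan=1.0) <= params.fdr
        sig_trans = np.nan_to_num(q_trans, nan=1.0) <= params.fdr

        reg = [
            classify_regulatory(bool(sp), bool(sc), bool(st), c, t)
            for sp, sc, st, c, t in zip(sig_par, sig_cis, sig_trans, cis, trans)
        ]
        conc = [direction_concordance(c, t) for c, t in zip(cis, trans)]
        results[hyb_role] = pd.DataFrame(
            {
                "g1": g1,
                "g2": g2,
                "a1": a1,
                "a2": a2,
                "total_log2": total,
                "cis_log2": cis,
                "trans_log2": trans,
                "percent_cis": pct,
                "p_parental": p_parental,
                "q_parental": q_parental,
                "p_cis": p_cis,
                "q_cis": q_cis,
                "p_trans": p_trans,
                "q_trans": q_trans,
                "sig_parental": sig_par,
                "sig_cis": sig_cis,
                "sig_trans": sig_trans,
                "regulatory_class": reg,
                "direction": conc,
            },
            index=equalized.gene_ids,
        )
        log.append(
            f"{hyb_role}: {int(sig_par.sum())} parental-, {int(sig_cis.sum())} cis-, "
            f"{int(sig_trans.sum())} trans-significant of {len(g1)} genes"
        )
    return report, equalized, results, log


def summarize_comparison(
    result_tables: dict[str, pd.DataFrame],
    total_counts: CountMatrix,
    total_mask: pd.Series,
    equalized: AlleleCountTable,
    inheritance: dict[str, pd.Series],
    params: AnalysisParams,
    seed: int,
) -> dict:
    """Genome-scale summary of one comparison."""
    sample_of = {r: total_counts.sample_for_role(r) for r in TOTAL_ROLES}
    tc = total_counts.counts.loc[total_mask]
    vec = {r: tc[sample_of[r]].to_numpy() for r in TOTAL_ROLES}

    hyb_parent = [
        spearman_divergence(vec[h], vec[p])
        for h in (ROLE_HYBRID1, ROLE_HYBRID2)
        for p in (ROLE_PARENT1, ROLE_PARENT2)
    ]
    summary: dict = {
        "n_genes_total": int(total_mask.sum()),
        "divergence": {
            "parent_parent": spearman_divergence(vec[ROLE_PARENT1], vec[ROLE_PARENT2]),
            "hybrid_parent_mean": float(np.nanmean(hyb_parent)),
            "hybrid_hybrid": spearman_divergence(vec[ROLE_HYBRID1], vec[ROLE_HYBRID2]),
        },
        "inheritance_proportions": {},
        "hybrids": {},
    }
    for hyb, calls in inheritance.items():
        counts = calls.value_counts(normalize=True).to_dict()
        counts["misexpressed"] = counts.get("overdominant", 0.0) + counts.get(
            "underdominant", 0.0
        )
        summary["inheritance_proportions"][hyb] = counts

    mixed = equalized.sample_for_role(ROLE_MIXED)
    g1, g2 = equalized.pair(mixed)
    seeds = iter(np.random.SeedSequence(seed).spawn(8))
    for hyb_role, table in result_tables.items():
        hyb = equalized.sample_for_role(hyb_role)
        a1, a2 = equalized.pair(hyb)
        n = len(table)
        n_same = int((table["direction"] == "same").loc[
            table["sig_cis"] & table["sig_trans"]
        ].sum())
        n_opp = int((table["direction"] == "opposite").loc[
            table["sig_cis"] & table["sig_trans"]
        ].sum())
        slope, intercept, r2 = cis_total_regression(
            table["cis_log2"].to_numpy(), table["total_log2"].to_numpy()
        )
        entry = {
            "n_genes_allele": n,
            "prop_sig_parental": float(table["sig_parental"].mean()) if n else float("nan"),
            "prop_sig_cis": float(table["sig_cis"].mean()) if n else float("nan"),
            "prop_sig_trans": float(table["sig_trans"].mean()) if n else float("nan"),
            "regulatory_class_proportions": table["regulatory_class"]
            .value_counts(normalize=True)
            .to_dict(),
            "median_percent_cis": float(np.nanmedian(table["percent_cis"]))
            if n
            else float("nan"),
            "n_same_direction": n_same,
            "n_opposite_direction": n_opp,
            "p_direction_concordance": direction_concordance_test(n_same, n_opp),
            "regression_total_on_cis": {"slope": slope, "intercept": intercept, "r2": r2},
            "divergence_total_mixed": spearman_divergence(g1, g2),
            "divergence_cis": spearman_divergence(a1, a2),
        }
        if params.bootstrap and n >= 3:
            s1 = int(next(seeds).generate_state(1)[0] % (2**31))
            s2 = int(next(seeds).generate_state(1)[0] % (2**31))
            bt = bootstrap_rho(g1, g2, params.n_boot, s1)
            bc = bootstrap_rho(a1, a2, params.n_boot, s2)
            entry["bootstrap_total_mixed"] = {
                "point_1_minus_rho": 1.0 - bt.point,
                "q025_rho": bt.q025,
                "q975_rho": bt.q975,
            }
            entry["bootstrap_cis"] = {
                "point_1_minus_rho": 1.0 - bc.point,
                "q025_rho": bc.q025,
                "q975_rho": bc.q975,
            }
        summary["hybrids"][hyb_role] = entry
    return summary


def run_comparison(data: ComparisonData, params: AnalysisParams) -> ComparisonResult:
    """Execute every per-comparison stage in order and collect the results."""
    data.validate()
    seeds = _stage_seeds(params.seed)
    log = [f"comparison {data.name}: seed {params.seed}, stage seeds {seeds}"]

    ds, mask, tests, inheritance, parental_fold, tlog = analyze_total(
        data, params, seeds["downsample_total"]
    )
    log.extend(tlog)
    target = int(ds.counts[ds.samples[0]].sum())

    with_mixed = normalize_alleles(data, target, seeds["thin_alleles"])
    report, equalized, gene_results, alog = analyze_alleles(
        with_mixed, data, params, seeds["equalize"]
    )
    log.extend(alog)

    summary = summarize_comparison(
        gene_results, ds, mask, equalized, inheritance, params, seeds["bootstrap"]
    )
    return ComparisonResult(
        name=data.name,
        params=params,
        target_depth=target,
        total_counts=ds,
        total_mask=mask,
        total_tests=tests,
        inheritance=inheritance,
        parental_fold=parental_fold,
        filter_report=report,
        equalized=equalized,
        gene_results=gene_results,
        summary=summary,
        log=log,
    )


@dataclass
class StudyResult:
    comparisons: list[ComparisonResult]
    trajectory: pd.DataFrame | None = None
    trajectory_counts: dict[str, int] | None = None
    tempo: pd.DataFrame | None = None
    proportion_tests: pd.DataFrame | None = None
    rho_differences: dict | None = None


def trajectory_table(
    results: list[ComparisonResult], cutoff: float = DEFAULT_FOLD_CUTOFF
) -> pd.DataFrame:
    """Nine-class trajectory call per gene over three ordered comparisons.

    Uses the parental expression fold change of each comparison, restricted
    to genes passing the minimum-read floor in all three.
    """
    if len(results) != 3:
        raise ValueError("trajectory analysis requires exactly 3 comparisons")
    shared = results[0].parental_fold.index
    for r in results[1:]:
        shared = shared.intersection(r.parental_fold.index)
    rows = []
    for gene in shared:
        folds = tuple(float(r.parental_fold.loc[gene]) for r in results)
        s1, s2, label = classify_trajectory(folds, cutoff)
        rows.append((gene, *folds, s1, s2, label))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "fold_1", "fold_2", "fold_3", "step1", "step2", "class"],
    ).set_index("gene_id")


def run_study(
    datasets: list[ComparisonData], params: AnalysisParams
) -> StudyResult:
    """Run every comparison and, with three of them, the cross-comparison layer."""
    results = [run_comparison(d, params) for d in datasets]
    out = StudyResult(comparisons=results)
    if len(results) != 3:
        return out

    out.trajectory = trajectory_table(results, params.fold_cutoff)
    out.trajectory_counts = out.trajectory["class"].value_counts().to_dict()

    # tempo table on the allele-specific data set, hybrid of cross 1
    rows = []
    for r in results:
        t = r.gene_results[ROLE_HYBRID1]
        rows.append(
            {
                "comparison": r.name,
                "n": len(t),
                "k_parental": int(t["sig_parental"].sum()),
                "k_cis": int(t["sig_cis"].sum()),
                "k_trans": int(t["sig_trans"].sum()),
            }
        )
    tempo = pd.DataFrame(rows).set_index("comparison")
    for kind in ("parental", "cis", "trans"):
        tempo[f"prop_{kind}"] = tempo[f"k_{kind}"] / tempo["n"]
    out.tempo = tempo

    prop_rows = []
    for i in range(2):
        a, b = tempo.iloc[i], tempo.iloc[i + 1]
        for kind in ("parental", "cis", "trans"):
            prop_rows.append(
                {
                    "pair": f"{tempo.index[i]}-vs-{tempo.index[i + 1]}",
                    "test": kind,
                    "p": compare_proportions(
                        int(a[f"k_{kind}"]), int(a["n"]), int(b[f"k_{kind}"]), int(b["n"])
                    ),
                }
            )
    out.proportion_tests = pd.DataFrame(prop_rows)

    if params.bootstrap:
        diffs = {}
        seeds = iter(np.random.SeedSequence(params.seed).spawn(4))
        for i in range(2):
            ra, rb = results[i], results[i + 1]
            key = f"{ra.name}-vs-{rb.name}"
            pair = {}
            for label, getter in (
                ("total_mixed", lambda r: r.equalized.pair(
                    r.equalized.sample_for_role(ROLE_MIXED))),
                ("cis", lambda r: r.equalized.pair(
                    r.equalized.sample_for_role(ROLE_HYBRID1))),
            ):
                xa, ya = getter(ra)
                xb, yb = getter(rb)
                d = bootstrap_rho_difference(
                    xa, ya, xb, yb, params.n_boot,
                    int(next(seeds).generate_state(1)[0] % (2**31)),
                )
                pair[label] = d
            diffs[key] = pair
        out.rho_differences = diffs
    return out
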