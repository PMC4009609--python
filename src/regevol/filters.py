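"""Gene-inclusion rules for the total-expression and allele-specific data sets.

Four rules control which genes enter the allele-specific analysis:

1. a minimum-read floor (default 20) in every relevant sample — exact tests
   on fewer reads have essentially no power;
2. an allele-assignment QC cut removing genes whose reads cross-map between
   parental genomes at a rate above 10%;
3. an imprinting screen removing genes whose allelic ratio differs
   significantly between reciprocal hybrids (parent-of-origin expression is
   not cis divergence), Fisher exact test + BH-FDR;
4. exclusion of mitochondrial genes, which are retained only for the
   maternal-fraction QC metric (in a clean experiment every mitochondrial
   allele-informative read maps to the maternal allele).

All masks are idempotent and order-independent; the final allele data set is
their intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleCountTable, CountMatrix
from .stats import bh_fdr, fet_ratio_difference_vec

DEFAULT_MIN_READS = 20
DEFAULT_CROSS_MAP_MAX = 0.10
DEFAULT_IMPRINT_FDR = 0.05


def filter_min_reads(
    data: CountMatrix | AlleleCountTable,
    threshold: int = DEFAULT_MIN_READS,
    samples: list[str] | None = None,
) -> pd.Series:
    """Genes with at least ``threshold`` reads in *every* relevant sample.

    For a :class:`CountMatrix` the per-sample quantity is the total count;
    for an :class:`AlleleCountTable` it is ``a1 + a2``.  The boundary is
    inclusive (exactly ``threshold`` reads passes).
    """
    if isinstance(data, CountMatrix):
        sub = data.counts[samples] if samples is not None else data.counts
        mins = sub.min(axis=1)
    else:
        use = samples if samples is not None else data.samples
        totals = np.column_stack([data.totals(s) for s in use])
        mins = pd.Series(totals.min(axis=1), index=data.gene_ids)
    return (mins >= threshold).rename("passes_min_reads")


def filter_allele_assignment(
    cross_mapping_rate: pd.Series, threshold: float = DEFAULT_CROSS_MAP_MAX
) -> pd.Series:
    """Genes whose parental cross-mapping rate is not above ``threshold``.

    A gene fails iff strictly more than the threshold fraction of one
    parent's reads align solely to the other parent's genome.
    """
    rate = cross_mapping_rate.astype(float)
    if ((rate < 0) | (rate > 1)).any():
        bad = rate.index[(rate < 0) | (rate > 1)][0]
        raise ValueError(f"cross-mapping rate outside [0, 1] for gene {bad!r}")
    return (rate <= threshold).rename("passes_allele_assignment")


def filter_imprinting(
    alleles: AlleleCountTable,
    hybrid1: str,
    hybrid2: str,
    fdr: float = DEFAULT_IMPRINT_FDR,
    exclude: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Screen out genes with reciprocal-hybrid allelic-ratio differences.

    Per gene, a Fisher exact test compares the (a1, a2) pair between the two
    reciprocal hybrids; genes significant after BH-FDR are removed
    (parent-of-origin effects such as imprinting, not cis divergence).
    Genes in ``exclude`` (e.g. mitochondrial genes, which are maternal-only
    by construction and removed a priori) do not enter the test family.
    Genes whose table is all-zero cannot be tested and pass.  Returns the
    pass mask and a (p, q) frame.
    """
    for h in (hybrid1, hybrid2):
        if h not in alleles.samples:
            raise ValueError(f"reciprocal hybrid sample {h!r} missing")
    a1, a2 = alleles.pair(hybrid1)
    b1, b2 = alleles.pair(hybrid2)
    p = fet_ratio_difference_vec(a1, a2, b1, b2)
    if exclude is not None:
        skip = exclude.reindex(alleles.gene_ids).fillna(False).to_numpy(dtype=bool)
        p[skip] = np.nan
    q = bh_fdr(p)
    fail = np.nan_to_num(q, nan=1.0) <= fdr
    mask = pd.Series(~fail, index=alleles.gene_ids, name="passes_imprinting")
    report = pd.DataFrame({"p_imprinting": p, "q_imprinting": q}, index=alleles.gene_ids)
    return mask, report


def maternal_fraction_qc(
    alleles: AlleleCountTable,
    is_mito: pd.Series,
    maternal_allele: dict[str, str],
) -> dict[str, float]:
    """Fraction of mitochondrial allele-informative reads on the maternal allele.

    ``maternal_allele`` maps each hybrid sample to ``"a1"`` or ``"a2"``
    depending on the direction of its cross.  Returns NaN (with a warning)
    for a hybrid without mitochondrial reads, or when no gene is flagged
    mitochondrial.
    """
    mito = is_mito.reindex(alleles.gene_ids).fillna(False).to_numpy(dtype=bool)
    out: dict[str, float] = {}
    for sample, allele in maternal_allele.items():
        if allele not in ("a1", "a2"):
            raise ValueError(f"maternal allele must be 'a1' or 'a2', got {allele!r}")
        a1, a2 = alleles.pair(sample)
        total = int(a1[mito].sum() + a2[mito].sum())
        if not mito.any() or total == 0:
            warnings.warn(
                f"no mitochondrial allele-specific reads for {sample!r}; "
                "maternal-fraction QC undefined",
                stacklevel=2,
            )
            out[sample] = float("nan")
            continue
        maternal = int((a1 if allele == "a1" else a2)[mito].sum())
        out[sample] = maternal / total
    return out


@dataclass
class FilterReport:
    """Per-gene filter flags plus per-filter removal counts.

    A gene enters the allele-specific data set iff all three pass flags are
    true and it is not mitochondrial.
    """

    flags: pd.DataFrame
    removed: dict[str, int] = field(default_factory=dict)
    imprinting_tests: pd.DataFrame | None = None
    maternal_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def final_mask(self) -> pd.Series:
        f = self.flags
        return (
            f["passes_min_reads"]
            & f["passes_allele_assignment"]
            & f["passes_imprinting"]
            & ~f["is_mito"]
        ).rename("in_allele_dataset")

    def log_lines(self) -> list[str]:
        lines = [f"genes considered: {len(self.flags)}"]
        for name, n in self.removed.items():
            lines.append(f"removed by {name}: {n}")
        lines.append(f"genes in allele-specific data set: {int(self.final_mask.sum())}")
        return lines


def build_filter_report(
    alleles: AlleleCountTable,
    cross_mapping_rate: pd.Series,
    is_mito: pd.Series,
    hybrid1: str,
    hybrid2: str,
    allele_samples: list[str],
    min_reads: int = DEFAULT_MIN_READS,
    cross_map_max: float = DEFAULT_CROSS_MAP_MAX,
    imprint_fdr: float = DEFAULT_IMPRINT_FDR,
    maternal_allele: dict[str, str] | None = None,
) -> FilterReport:
    """Apply all allele-data-set inclusion rules and tally removals.

    ``allele_samples`` are the samples subject to the per-sample minimum
    allele-informative read floor (mixed parental plus both hybrids).
    Removal counts are attributed filter-by-filter in the order
    cross-mapping, minimum reads, mitochondrial, imprinting — each counting
    genes that survive the previous rules — mirroring how exclusion tables
    are usually reported.
    """
    genes = alleles.gene_ids
    mito = is_mito.reindex(genes).fillna(False).astype(bool).rename("is_mito")
    pass_xmap = filter_allele_assignment(
        cross_mapping_rate.reindex(genes), cross_map_max
    )
    pass_min = filter_min_reads(alleles, min_reads, allele_samples)
    pass_imp, imp_tests = filter_imprinting(
        alleles, hybrid1, hybrid2, imprint_fdr, exclude=mito
    )

    flags = pd.concat([pass_min, pass_xmap, pass_imp, mito], axis=1)
    removed = {
        "allele_assignment": int((~pass_xmap).sum()),
        "min_reads": int((pass_xmap & ~pass_min).sum()),
        "mitochondrial": int((pass_xmap & pass_min & mito).sum()),
        "imprinting": int((pass_xmap & pass_min & ~mito & ~pass_imp).sum()),
    }
    maternal: dict[str, float] = {}
    if maternal_allele and mito.any():
        maternal = maternal_fraction_qc(alleles, mito, maternal_allele)
    return FilterReport(flags, removed, imp_tests, maternal)
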