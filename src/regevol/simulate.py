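"""Synthetic RNA-seq experiment generator with known regulatory ground truth.

Emulates the data structure the analysis assumes: total read counts for two
parental genotypes and their two reciprocal F1 hybrids, plus allele-informative
read counts, for genes carrying configurable cis- and trans-regulatory effects.

Generative model
----------------
Each gene ``g`` gets a baseline abundance ``mu_g = 2**N(baseline_log2_mean,
baseline_log2_sd)`` (log-normal; heavy-tailed like real RNA-seq libraries).
Expected expression is

* parent 2:  ``mu_g``
* parent 1:  ``mu_g * 2**(cis + trans)``  (total divergence is the sum of the
  cis and trans effects on the log2 scale)
* hybrids:   midpoint of the parental expectations, shifted by the per-gene
  dominance parameter ``d`` in [-1, 1] (``d = -1`` reproduces the parent-2
  level, ``+1`` the parent-1 level, ``0`` the additive midpoint).

Per library, counts are a multinomial allocation of ``library_size`` reads over
genes (optionally overdispersed by gamma-multiplied gene weights, giving
negative-binomial-like marginals).  Allele-informative counts thin each
sample's gene count binomially with the gene's informative fraction (Beta
distributed across genes, mimicking the dependence of allele assignability on
sequence divergence) and, in hybrids, split allele 1 vs allele 2 binomially
with ``p = 2**cis / (1 + 2**cis)`` — both hybrid alleles share one trans
environment, so only the cis effect separates them.  Parental samples emit
informative reads for their own genome only.  Mitochondrial genes emit
allele-informative reads solely for the maternal allele of each cross
(cross 1: parent 1 mother; cross 2: parent 2 mother).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ROLE_HYBRID1,
    ROLE_HYBRID2,
    ROLE_PARENT1,
    ROLE_PARENT2,
    AlleleCountTable,
    CountMatrix,
    allele_table_from_pairs,
)

ARCHITECTURES = (
    "conserved",
    "all_cis",
    "all_trans",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
)

#: default sample names, one per role
SAMPLE_NAMES = {
    ROLE_PARENT1: "parent1",
    ROLE_PARENT2: "parent2",
    ROLE_HYBRID1: "hybrid1",
    ROLE_HYBRID2: "hybrid2",
}


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated comparison (2 parents + 2 reciprocal hybrids).

    ``architecture_proportions`` gives the fraction of genes in each
    regulatory architecture; effect magnitudes (|log2|) are uniform on
    ``[cis_low, cis_high]`` and ``[trans_low, trans_high]`` with random sign.
    ``informative_mean``/``informative_concentration`` parameterize the Beta
    distribution of per-gene allele-informative read fractions.
    """

    n_genes: int = 1000
    library_size: int = 1_000_000
    architecture_proportions: dict[str, float] = field(
        default_factory=lambda: {"conserved": 1.0}
    )
    cis_low: float = math.log2(1.5)
    cis_high: float = 2.0
    trans_low: float = math.log2(1.5)
    trans_high: float = 2.0
    informative_mean: float = 0.4
    informative_concentration: float = 30.0
    dominance_low: float = 0.0
    dominance_high: float = 0.0
    n_mito_genes: int = 0
    overdispersion: float = 0.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    # parent-of-origin artifact: shift the allele-1 proportion of the first
    # n_imprinted autosomal genes by imprinted_shift in cross 1 only
    n_imprinted: int = 0
    imprinted_shift: float = 0.0
    # fabricated mapping-QC channel: fraction of genes with an elevated
    # cross-mapping rate (the rest draw uniformly from [0, 0.09])
    cross_map_high_fraction: float = 0.0
    cross_map_high_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.library_size < self.n_genes:
            raise ConfigError("library_size must be >= n_genes")
        props = self.architecture_proportions
        unknown = set(props) - set(ARCHITECTURES)
        if unknown:
            raise ConfigError(f"unknown architectures {sorted(unknown)}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"architecture proportions sum to {total}, not 1")
        if any(not 0.0 <= v <= 1.0 for v in props.values()):
            raise ConfigError("architecture proportions must lie in [0, 1]")
        if not 0.0 < self.informative_mean < 1.0:
            raise ConfigError("informative_mean must lie in (0, 1)")
        if self.informative_concentration <= 0:
            raise ConfigError("informative_concentration must be positive")
        for d in (self.dominance_low, self.dominance_high):
            if not -1.0 <= d <= 1.0:
                raise ConfigError("dominance bounds must lie in [-1, 1]")
        if self.dominance_low > self.dominance_high:
            raise ConfigError("dominance_low > dominance_high")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be >= 0")
        if self.n_mito_genes < 0 or self.n_mito_genes >= self.n_genes:
            raise ConfigError("n_mito_genes must be in [0, n_genes)")
        if not 0.0 <= self.cross_map_high_fraction <= 1.0:
            raise ConfigError("cross_map_high_fraction must lie in [0, 1]")


@dataclass
class GeneTruth:
    """Ground-truth regulatory state of one simulated gene."""

    gene_id: str
    cis_log2: float
    trans_log2: float
    architecture: str
    dominance: float
    is_mito: bool


@dataclass
class SimulatedExperiment:
    """Everything one simulated comparison produces.

    Iterating yields ``(counts, alleles, truths)``; the fabricated per-gene
    cross-mapping rate (mapping-QC channel consumed by the allele-assignment
    filter) and the ids of artificially imprinted genes ride along as extra
    attributes.
    """

    counts: CountMatrix
    alleles: AlleleCountTable
    truths: list[GeneTruth]
    cross_map_rate: pd.Series
    imprinted_genes: list[str]

    def __iter__(self):
        return iter((self.counts, self.alleles, self.truths))

    def truth_frame(self) -> pd.DataFrame:
        return truths_to_frame(self.truths)


def truths_to_frame(truths: list[GeneTruth]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "cis_log2": [t.cis_log2 for t in truths],
            "trans_log2": [t.trans_log2 for t in truths],
            "architecture": [t.architecture for t in truths],
            "dominance": [t.dominance for t in truths],
            "is_mito": [t.is_mito for t in truths],
        }
    )
    return df.set_index("gene_id")


def _architecture_counts(props: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over architectures."""
    ideal = {a: props.get(a, 0.0) * n for a in ARCHITECTURES}
    counts = {a: int(math.floor(v)) for a, v in ideal.items()}
    short = n - sum(counts.values())
    # break ties by the fixed architecture order
    order = sorted(
        ARCHITECTURES, key=lambda a: (ideal[a] - counts[a]), reverse=True
    )
    for a in order[:short]:
        counts[a] += 1
    return counts


def sample_gene_effects(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneTruth]:
    """Draw per-gene ground-truth cis/trans effects from the configured mixture.

    Architecture counts follow the configured proportions up to rounding
    (largest remainder); effect magnitudes are uniform with equiprobable
    random sign; compensatory genes satisfy ``trans = -cis`` exactly.
    Mitochondrial genes occupy the last ``n_mito_genes`` slots and carry no
    regulatory divergence.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_auto = config.n_genes - config.n_mito_genes
    counts = _architecture_counts(config.architecture_proportions, n_auto)
    labels: list[str] = []
    for a in ARCHITECTURES:
        labels.extend([a] * counts[a])

    width = len(str(config.n_genes))
    truths: list[GeneTruth] = []
    for i, arch in enumerate(labels):
        cis = trans = 0.0
        if arch in ("all_cis", "cis_plus_trans", "cis_times_trans", "compensatory"):
            cis = rng.uniform(config.cis_low, config.cis_high)
            cis *= rng.choice((-1.0, 1.0))
        if arch == "compensatory":
            trans = -cis
        elif arch in ("all_trans", "cis_plus_trans", "cis_times_trans"):
            trans = rng.uniform(config.trans_low, config.trans_high)
            if arch == "cis_plus_trans":
                trans *= math.copysign(1.0, cis)
            elif arch == "cis_times_trans":
                trans *= -math.copysign(1.0, cis)
            else:
                trans *= rng.choice((-1.0, 1.0))
        dom = rng.uniform(config.dominance_low, config.dominance_high)
        truths.append(GeneTruth(f"g{i:0{width}d}", cis, trans, arch, dom, False))
    for j in range(config.n_mito_genes):
        i = n_auto + j
        truths.append(GeneTruth(f"mt{i:0{width}d}", 0.0, 0.0, "conserved", 0.0, True))
    return truths


def _sample_counts(
    rng: np.random.Generator,
    weights: np.ndarray,
    library_size: int,
    overdispersion: float,
) -> np.ndarray:
    w = weights.astype(float)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        w = w * rng.gamma(shape, overdispersion, size=w.shape)
    return rng.multinomial(library_size, w / w.sum())


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate one full comparison: totals, allele counts, and ground truth.

    All randomness flows from ``config.seed`` through deterministically
    spawned per-purpose streams, so fixed seeds reproduce byte-identical
    tables.  With ``overdispersion = 0`` every total column sums exactly to
    ``library_size``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("effects", "baseline", "fractions", "crossmap",
             "parent1", "parent2", "hybrid1", "hybrid2"),
            ss.spawn(8),
        )
    }

    truths = sample_gene_effects(config, streams["effects"])
    gene_ids = pd.Index([t.gene_id for t in truths], name="gene_id")
    cis = np.array([t.cis_log2 for t in truths])
    trans = np.array([t.trans_log2 for t in truths])
    dom = np.array([t.dominance for t in truths])
    is_mito = np.array([t.is_mito for t in truths])

    mu = np.exp2(
        streams["baseline"].normal(
            config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
        )
    )
    # split each gene's total divergence symmetrically around its baseline:
    # the parental expression ratio is still exactly 2**(cis+trans), but the
    # two libraries' weight sums stay equal in expectation, so multinomial
    # normalization does not leak a global compositional shift into the
    # conserved genes' ratios
    w1 = mu * np.exp2(0.5 * (cis + trans))
    w2 = mu * np.exp2(-0.5 * (cis + trans))
    # expected per-library counts at equal depth
    e1 = config.library_size * w1 / w1.sum()
    e2 = config.library_size * w2 / w2.sum()
    mid = 0.5 * (e1 + e2)
    wh = mid + 0.5 * dom * (e1 - e2)

    m = config.informative_mean
    k = config.informative_concentration
    frac = streams["fractions"].beta(m * k, (1.0 - m) * k, config.n_genes)

    # hybrid allele-1 share: the two alleles share one trans environment,
    # so only the cis effect separates them
    p1_share = np.exp2(cis) / (1.0 + np.exp2(cis))
    auto_idx = np.flatnonzero(~is_mito)
    imprinted = [gene_ids[i] for i in auto_idx[: config.n_imprinted]]

    sample_names = dict(SAMPLE_NAMES)
    counts_cols: dict[str, np.ndarray] = {}
    pairs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    for role, weights in (
        (ROLE_PARENT1, w1),
        (ROLE_PARENT2, w2),
        (ROLE_HYBRID1, wh),
        (ROLE_HYBRID2, wh),
    ):
        name = sample_names[role]
        rng = streams[name]
        total = _sample_counts(rng, weights, config.library_size, config.overdispersion)
        informative = rng.binomial(total, frac)
        if role == ROLE_PARENT1:
            a1, a2 = informative, np.zeros_like(informative)
        elif role == ROLE_PARENT2:
            a1, a2 = np.zeros_like(informative), informative
        else:
            share = p1_share.copy()
            if role == ROLE_HYBRID1 and imprinted:
                sel = auto_idx[: config.n_imprinted]
                share[sel] = np.clip(share[sel] + config.imprinted_shift, 0.0, 1.0)
            # maternal-only mitochondrial transcripts
            share[is_mito] = 1.0 if role == ROLE_HYBRID1 else 0.0
            a1 = rng.binomial(informative, share)
            a2 = informative - a1
        counts_cols[name] = total
        pairs[name] = (a1, a2)

    roles = {v: k for k, v in sample_names.items()}
    counts = CountMatrix(pd.DataFrame(counts_cols, index=gene_ids), roles)
    alleles = allele_table_from_pairs(gene_ids, pairs, roles)

    rate = streams["crossmap"].uniform(0.0, 0.09, config.n_genes)
    n_high = int(round(config.cross_map_high_fraction * config.n_genes))
    if n_high:
        high = streams["crossmap"].choice(config.n_genes, size=n_high, replace=False)
        rate[high] = config.cross_map_high_rate
    cross_map = pd.Series(rate, index=gene_ids, name="cross_map_rate")

    return SimulatedExperiment(counts, alleles, truths, cross_map, imprinted)
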