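"""Read-count down-sampling and the in-silico mixed-parental sample.

Power of the exact tests used downstream depends directly on read depth, so
depth differences among libraries (and, per gene, among samples) are removed
by sampling reads without replacement rather than by rescaling:

* :func:`downsample_total` equalizes whole-library depth — each retained read
  is chosen uniformly without replacement, i.e. per-gene retained counts are
  multivariate hypergeometric.
* :func:`build_mixed_parental` pools the two equal-depth parents' own-genome
  informative reads into one pseudo-sample, so parental expression ratios are
  measured with the same allele-assignment machinery (and on the same scale)
  as hybrid allelic ratios.
* :func:`downsample_alleles` equalizes per-gene allele-informative totals
  across samples by univariate hypergeometric draws down to the per-gene
  minimum.

Both down-samplers are exactly depth-conserving and unbiased (the expected
retained proportion of a gene equals its input proportion).
"""

from __future__ import annotations

import numpy as np

from .containers import ROLE_MIXED, AlleleCountTable, CountMatrix


def _per_sample_rngs(seed: int, samples: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(samples))
    return {s: np.random.default_rng(c) for s, c in zip(samples, children)}


def downsample_total(
    matrix: CountMatrix, target_depth: int, seed: int = 0
) -> CountMatrix:
    """Down-sample every library to exactly ``target_depth`` mapped reads.

    Reads are removed uniformly without replacement (multivariate
    hypergeometric over genes), so every column of the result sums exactly
    to ``target_depth``.  Samples already at the target are returned
    unchanged.  Raises if any library is below the target, naming it.
    """
    if target_depth < 0:
        raise ValueError("target_depth must be non-negative")
    rngs = _per_sample_rngs(seed, matrix.samples)
    out = matrix.counts.copy()
    for sample in matrix.samples:
        col = matrix.counts[sample].to_numpy()
        depth = int(col.sum())
        if depth < target_depth:
            raise ValueError(
                f"sample {sample!r} has only {depth} reads, "
                f"below target depth {target_depth}"
            )
        if depth == target_depth:
            continue
        out[sample] = rngs[sample].multivariate_hypergeometric(col, target_depth)
    return CountMatrix(out, dict(matrix.roles))


def build_mixed_parental(
    alleles: AlleleCountTable,
    parent1: str,
    parent2: str,
    parent_depths: tuple[int, int] | None = None,
    name: str = "mixed_parental",
) -> AlleleCountTable:
    """Add the in-silico mixed-parental sample to an allele-count table.

    Per gene, the mixed pair is ``(parent-1 sample's own-genome informative
    count, parent-2 sample's likewise)``.  ``parent_depths`` — the parents'
    total mapped-read depths — may be supplied to enforce the equal-depth
    precondition of the pooling.
    """
    if parent_depths is not None and parent_depths[0] != parent_depths[1]:
        raise ValueError(
            f"mixed-parental sample requires equal parental read depths, "
            f"got {parent_depths[0]} and {parent_depths[1]}"
        )
    p1a1, p1a2 = alleles.pair(parent1)
    p2a1, p2a2 = alleles.pair(parent2)
    if p1a2.any() or p2a1.any():
        raise ValueError(
            "parental samples must carry informative reads for their own "
            "genome only"
        )
    return alleles.with_sample(name, p1a1, p2a2, ROLE_MIXED)


def thin_alleles(
    alleles: AlleleCountTable, sample: str, n_keep: int, seed: int = 0
) -> AlleleCountTable:
    """Down-sample one sample's allele-informative reads to ``n_keep`` total.

    Retained reads are drawn without replacement across the sample's
    ``2 * n_genes`` (gene, allele) cells, emulating read-level down-sampling
    of the library the informative reads came from.
    """
    a1, a2 = alleles.pair(sample)
    total = int(a1.sum() + a2.sum())
    if n_keep > total:
        raise ValueError(
            f"sample {sample!r} has {total} informative reads, fewer than {n_keep}"
        )
    if n_keep == total:
        return alleles
    rng = np.random.default_rng(seed)
    cells = np.concatenate([a1, a2])
    kept = rng.multivariate_hypergeometric(cells, n_keep)
    n = len(a1)
    return alleles.with_sample(sample, kept[:n], kept[n:], alleles.roles[sample])


def downsample_alleles(
    alleles: AlleleCountTable,
    seed: int = 0,
    samples: list[str] | None = None,
) -> AlleleCountTable:
    """Equalize per-gene allele-informative totals across samples.

    For each gene, every sample's (a1, a2) pair is reduced to the minimum
    total ``m`` observed for that gene across ``samples``: the retained
    allele-1 count is hypergeometric (population ``a1 + a2``, successes
    ``a1``, draws ``m``).  The minimal sample is returned bit-identical;
    per-gene totals are exactly conserved across samples afterwards.
    """
    if samples is None:
        samples = alleles.samples
    totals = np.column_stack([alleles.totals(s) for s in samples])
    m = totals.min(axis=1)
    rngs = _per_sample_rngs(seed, samples)
    out = alleles
    for j, sample in enumerate(samples):
        a1, a2 = alleles.pair(sample)
        reduce = totals[:, j] > m
        if not reduce.any():
            continue
        new_a1 = a1.copy()
        new_a1[reduce] = rngs[sample].hypergeometric(
            a1[reduce], a2[reduce], m[reduce]
        )
        new_a2 = np.where(reduce, m - new_a1, a2)
        out = out.with_sample(sample, new_a1, new_a2, alleles.roles[sample])
    return out
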