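"""Count containers shared by every pipeline stage.

Two tables drive the whole analysis:

* :class:`CountMatrix` — total mapped-read counts, genes x samples, with a
  role label (parent, reciprocal hybrid, in-silico mixed parental) attached
  to every sample.
* :class:`AlleleCountTable` — allele-informative read counts: for each
  sample a pair of columns ``(a1, a2)`` counting reads that align perfectly
  and uniquely to the genome of parent 1 or parent 2, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLE_PARENT1 = "parent1"
ROLE_PARENT2 = "parent2"
ROLE_HYBRID1 = "hybrid_cross1"
ROLE_HYBRID2 = "hybrid_cross2"
ROLE_MIXED = "mixed_parental"

ROLES = frozenset(
    {ROLE_PARENT1, ROLE_PARENT2, ROLE_HYBRID1, ROLE_HYBRID2, ROLE_MIXED}
)


def _check_counts_frame(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{what}: duplicated gene ids {dups[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise ValueError(f"{what}: non-integer counts present")
    if (values < 0).any():
        rows, cols = np.nonzero(values < 0)
        gene = df.index[rows[0]]
        col = df.columns[cols[0]]
        raise ValueError(f"{what}: negative count at gene {gene!r}, column {col!r}")


def _check_roles(samples: list[str], roles: dict[str, str], what: str) -> None:
    for s in samples:
        if s not in roles:
            raise ValueError(f"{what}: sample {s!r} has no role assigned")
        if roles[s] not in ROLES:
            raise ValueError(
                f"{what}: sample {s!r} has unknown role {roles[s]!r}; "
                f"expected one of {sorted(ROLES)}"
            )


@dataclass
class CountMatrix:
    """Gene x sample table of non-negative integer total read counts.

    ``roles`` maps every sample (column) to exactly one role label from
    :data:`ROLES`.
    """

    counts: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_counts_frame(self.counts, "CountMatrix")
        _check_roles(list(self.counts.columns), self.roles, "CountMatrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def depth(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def sample_for_role(self, role: str) -> str:
        hits = [s for s, r in self.roles.items() if r == role and s in self.counts.columns]
        if len(hits) != 1:
            raise ValueError(
                f"expected exactly one sample with role {role!r}, found {hits}"
            )
        return hits[0]

    def subset_genes(self, mask: pd.Series | np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts.loc[mask].copy(), dict(self.roles))

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), dict(self.roles))


@dataclass
class AlleleCountTable:
    """Per-gene, per-sample allele-informative read-count pairs.

    The underlying frame has a two-level column index ``(sample, allele)``
    with allele in ``{"a1", "a2"}``; ``a1`` counts reads assignable to the
    parent-1 genome and ``a2`` to the parent-2 genome.  A parental sample
    can only emit reads for its own genome, so its other column is zero;
    the mixed-parental sample combines the two parents' informative reads.
    """

    counts: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = self.counts.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("AlleleCountTable needs (sample, allele) columns")
        bad = set(cols.get_level_values(1)) - {"a1", "a2"}
        if bad:
            raise ValueError(f"AlleleCountTable: unknown allele labels {bad}")
        _check_counts_frame(self.counts, "AlleleCountTable")
        _check_roles(self.samples, self.roles, "AlleleCountTable")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns.get_level_values(0):
            if s not in seen:
                seen.append(s)
        return seen

    def pair(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """(allele-1, allele-2) count vectors for one sample, in gene order."""
        return (
            self.counts[(sample, "a1")].to_numpy(),
            self.counts[(sample, "a2")].to_numpy(),
        )

    def totals(self, sample: str) -> np.ndarray:
        a1, a2 = self.pair(sample)
        return a1 + a2

    def sample_for_role(self, role: str) -> str:
        hits = [s for s, r in self.roles.items() if r == role and s in self.samples]
        if len(hits) != 1:
            raise ValueError(
                f"expected exactly one sample with role {role!r}, found {hits}"
            )
        return hits[0]

    def with_sample(
        self, sample: str, a1: np.ndarray, a2: np.ndarray, role: str
    ) -> "AlleleCountTable":
        """Return a new table with an extra (or replaced) sample column pair."""
        df = self.counts.copy()
        df[(sample, "a1")] = np.asarray(a1, dtype=np.int64)
        df[(sample, "a2")] = np.asarray(a2, dtype=np.int64)
        roles = dict(self.roles)
        roles[sample] = role
        return AlleleCountTable(df, roles)

    def subset_genes(self, mask: pd.Series | np.ndarray) -> "AlleleCountTable":
        return AlleleCountTable(self.counts.loc[mask].copy(), dict(self.roles))

    def subset_samples(self, samples: list[str]) -> "AlleleCountTable":
        df = self.counts.loc[:, [(s, a) for s in samples for a in ("a1", "a2")]]
        roles = {s: self.roles[s] for s in samples}
        return AlleleCountTable(df.copy(), roles)

    def copy(self) -> "AlleleCountTable":
        return AlleleCountTable(self.counts.copy(), dict(self.roles))


def allele_table_from_pairs(
    gene_ids: pd.Index | list[str],
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    roles: dict[str, str],
) -> AlleleCountTable:
    """Assemble an :class:`AlleleCountTable` from per-sample (a1, a2) arrays."""
    data = {}
    for sample, (a1, a2) in pairs.items():
        data[(sample, "a1")] = np.asarray(a1, dtype=np.int64)
        data[(sample, "a2")] = np.asarray(a2, dtype=np.int64)
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "allele"])
    return AlleleCountTable(df, roles)
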