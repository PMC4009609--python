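"""Flat-file formats: TSV count tables, sample-role maps, YAML run configs.

Every table is plain tab-separated text with a header row and ``gene_id`` as
the first column.  Allele tables use two columns per sample, suffixed
``_a1``/``_a2``.  Sample roles live in a separate two-column ``samples.tsv``
so the count files stay pure matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AlleleCountTable, CountMatrix, allele_table_from_pairs
from .pipeline import AnalysisParams, ComparisonData
from .simulate import SimulationConfig

COUNTS_FILE = "counts.tsv"
ALLELES_FILE = "alleles.tsv"
SAMPLES_FILE = "samples.tsv"
TRUTH_FILE = "truth.tsv"
CROSS_MAP_FILE = "cross_map.tsv"
GENES_FILE = "genes.tsv"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated gene_id {dup!r}")
    return df.set_index("gene_id")


def _validate_integer_cells(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (np.mod(vals.fillna(0), 1) != 0)
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(f"{path}: non-integer count at gene {gene!r}, column {col!r}")
        neg = vals < 0
        if neg.any():
            gene = df.index[neg.to_numpy()][0]
            raise ValueError(f"{path}: negative count at gene {gene!r}, column {col!r}")
    return df.astype(np.int64)


def read_roles(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "role"]:
        raise ValueError(f"{path}: expected columns 'sample' and 'role'")
    return dict(zip(df["sample"], df["role"]))


def write_roles(roles: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample": list(roles), "role": list(roles.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_count_matrix(path: str | Path, roles: dict[str, str]) -> CountMatrix:
    df = _validate_integer_cells(_read_tsv(path), path)
    return CountMatrix(df, {s: roles[s] for s in df.columns})


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_allele_table(path: str | Path, roles: dict[str, str]) -> AlleleCountTable:
    df = _validate_integer_cells(_read_tsv(path), path)
    samples: list[str] = []
    for col in df.columns:
        if not (col.endswith("_a1") or col.endswith("_a2")):
            raise ValueError(f"{path}: allele column {col!r} lacks _a1/_a2 suffix")
        s = col[:-3]
        if s not in samples:
            samples.append(s)
    pairs = {}
    for s in samples:
        for suffix in ("_a1", "_a2"):
            if s + suffix not in df.columns:
                raise ValueError(f"{path}: missing column {s + suffix!r}")
        pairs[s] = (df[s + "_a1"].to_numpy(), df[s + "_a2"].to_numpy())
    return allele_table_from_pairs(df.index, pairs, {s: roles[s] for s in samples})


def write_allele_table(table: AlleleCountTable, path: str | Path) -> None:
    flat = table.counts.copy()
    flat.columns = [f"{s}_{a}" for s, a in flat.columns]
    flat.rename_axis("gene_id").to_csv(path, sep="\t")


def write_experiment(experiment, out_dir: str | Path) -> None:
    """Persist a simulated experiment as the standard TSV file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(experiment.counts, out / COUNTS_FILE)
    write_allele_table(experiment.alleles, out / ALLELES_FILE)
    write_roles(experiment.counts.roles, out / SAMPLES_FILE)
    experiment.truth_frame().rename_axis("gene_id").to_csv(out / TRUTH_FILE, sep="\t")
    experiment.cross_map_rate.rename("cross_map_rate").rename_axis("gene_id").to_csv(
        out / CROSS_MAP_FILE, sep="\t"
    )
    genes = pd.DataFrame(
        {"is_mito": experiment.truth_frame()["is_mito"].astype(int)}
    )
    genes.rename_axis("gene_id").to_csv(out / GENES_FILE, sep="\t")


def load_comparison(data_dir: str | Path, name: str = "comparison") -> ComparisonData:
    """Load one comparison's tables from a directory of standard TSVs."""
    d = Path(data_dir)
    roles = read_roles(d / SAMPLES_FILE)
    counts = read_count_matrix(d / COUNTS_FILE, roles)
    alleles = read_allele_table(d / ALLELES_FILE, roles)
    cross_map = None
    if (d / CROSS_MAP_FILE).exists():
        cross_map = _read_tsv(d / CROSS_MAP_FILE)["cross_map_rate"].astype(float)
    is_mito = None
    if (d / GENES_FILE).exists():
        is_mito = _read_tsv(d / GENES_FILE)["is_mito"].astype(bool)
    return ComparisonData(counts, alleles, cross_map, is_mito, name=name)


def simulation_config_from_dict(raw: dict) -> SimulationConfig:
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return simulation_config_from_dict(raw)


def params_from_dict(raw: dict) -> AnalysisParams:
    known = set(AnalysisParams.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown analysis parameter keys: {sorted(unknown)}")
    return AnalysisParams(**raw)


def load_run_config(path: str | Path) -> tuple[list[dict], AnalysisParams]:
    """Read a multi-comparison run config.

    YAML layout::

        params: {fdr: 0.05, n_boot: 1000, ...}
        comparisons:
          - name: comp1
            simulate: {n_genes: 500, ...}      # generate in memory, or
          - name: comp2
            data_dir: path/to/tsvs             # load from disk
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = params_from_dict(raw.get("params", {}))
    comparisons = raw.get("comparisons", [])
    if not comparisons:
        raise ValueError(f"{path}: no comparisons defined")
    for c in comparisons:
        if "simulate" not in c and "data_dir" not in c:
            raise ValueError(
                f"comparison {c.get('name', '?')!r} needs 'simulate' or 'data_dir'"
            )
    return comparisons, params


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default, allow_nan=True)
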