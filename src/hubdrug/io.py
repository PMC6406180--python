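"""Readers and writers for the pipeline's tabular formats.

All files are plain text. Expression matrices are gene x sample TSV/CSV
with gene ids in the first column and sample ids in the header;
sensitivity tables are long-format with header
``cell_line, drug, value, measure``; networks export as upper-triangle
edge lists; models serialize to JSON; predictions follow the
samples-in-rows / drugs-in-columns layout. Floats are written with 17
significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hubdrug.network import CorrelationNetwork

FLOAT_FMT = "%.17g"


def _delimiter(path, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a gene x sample expression matrix (first column = gene ids)."""
    sep = _delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        first = dup[0]
        line = int(np.flatnonzero(df.index == first)[-1]) + 2  # +1 header, +1 1-based
        raise ValueError(f"duplicate gene id {first!r} (line {line}) in {path}")
    dup_s = df.columns[df.columns.duplicated()]
    if len(dup_s):
        raise ValueError(f"duplicate sample id {dup_s[0]!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value at gene {bad[0]!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    return df


def write_expression_table(expr: pd.DataFrame, path, dialect: str | None = None) -> None:
    sep = _delimiter(path, dialect)
    expr.rename_axis("gene_id").to_csv(path, sep=sep, float_format=FLOAT_FMT)


_SENS_COLUMNS = ["cell_line", "drug", "value", "measure"]


def read_sensitivity_table(path, dialect: str | None = None) -> pd.DataFrame:
    sep = _delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _SENS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensitivity table {path} lacks columns: {missing}")
    df = df[_SENS_COLUMNS].copy()
    df["value"] = pd.to_numeric(df["value"])
    if df.duplicated(["cell_line", "drug"]).any():
        pair = df[df.duplicated(["cell_line", "drug"])].iloc[0]
        raise ValueError(
            f"duplicate (cell_line, drug) record ({pair.cell_line!r}, {pair.drug!r})"
        )
    measures = df["measure"].unique()
    if len(measures) > 1:
        raise ValueError(f"a sensitivity table must carry a single measure, got {list(measures)}")
    return df


def write_sensitivity_table(sens: pd.DataFrame, path, dialect: str | None = None) -> None:
    sep = _delimiter(path, dialect)
    sens[_SENS_COLUMNS].to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def write_network_edges(net: CorrelationNetwork, path) -> None:
    """Upper-triangle edge list: gene_a, gene_b, raw_r, weight."""
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    nodes = np.asarray(net.node_ids)
    df = pd.DataFrame({
        "gene_a": nodes[iu],
        "gene_b": nodes[ju],
        "raw_r": net.raw_corr[iu, ju],
        "weight": net.weights[iu, ju],
    })
    with open(path, "w") as fh:
        fh.write(f"# transform={net.transform}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_network_edges(path) -> CorrelationNetwork:
    transform = "abs"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# transform="):
            transform = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    nodes = list(dict.fromkeys(pd.concat([df["gene_a"], df["gene_b"]]).astype(str)))
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    r = np.eye(n)
    for a, b, raw in zip(df["gene_a"].astype(str), df["gene_b"].astype(str), df["raw_r"]):
        r[pos[a], pos[b]] = r[pos[b], pos[a]] = raw
    return CorrelationNetwork(node_ids=nodes, raw_corr=r, transform=transform)


def write_hub_table(hub_table: pd.DataFrame, path) -> None:
    """Hub table TSV with run metadata echoed as header comments."""
    with open(path, "w") as fh:
        for key in ("B", "alpha", "seed", "transform", "null"):
            if key in hub_table.attrs:
                fh.write(f"# {key}={hub_table.attrs[key]}\n")
        hub_table.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_hub_table(path) -> pd.DataFrame:
    attrs = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            attrs[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    df.attrs.update(attrs)
    return df


def write_prediction_table(pred: pd.DataFrame, path, dialect: str | None = None) -> None:
    """Samples in rows, drugs in columns, full float precision."""
    if pred.shape[1] == 0:
        raise ValueError("prediction table has no drug columns; refusing to write")
    sep = _delimiter(path, dialect)
    pred.rename_axis("sample_id").to_csv(path, sep=sep, float_format=FLOAT_FMT)


def read_prediction_table(path, dialect: str | None = None) -> pd.DataFrame:
    sep = _delimiter(path, dialect)
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; defaults are the study-faithful values."""

    percentile: float = 99.0
    transform: str = "abs"
    n_permutations: int = 100_000
    alpha: float = 0.05
    ridge_lambda: float = 1e-8
    cv_k: int = 10
    cv_scheme: str = "kfold"
    standardization: str = "global"
    orientation: str = "direct"
    null: str = "matrix"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
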