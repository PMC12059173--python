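"""Readers and writers for the pipeline's interchange formats.

All tabular formats are UTF-8 delimited text with mandatory headers
(comma-separated by default, tab-separated on request); floats are
serialized with 12 significant digits so round-trips are lossless at that
precision. Count matrices travel as Matrix Market (.mtx) plus genes/barcodes
index files; receptor chains as AIRR Rearrangement TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from tlsarch.matrix import CountMatrix

FLOAT_FMT = "%.12g"
VALID_STATUSES = ("nTLS", "imTLS", "mTLS")
CELL_TABLE_REQUIRED = ("cell_id", "sample_id", "tls_status", "subcluster")
AIRR_REQUIRED = ("cell_id", "locus", "junction", "v_call", "j_call")
POINTS_REQUIRED = ("core_id", "tls_status", "x", "y", "phenotype")


def _require(df: pd.DataFrame, required: tuple, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} {path}: missing required column(s) {missing}")


def write_table(df: pd.DataFrame, path, sep: str = ",", index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FMT)


def read_cell_table(path, sep: str = ",", statuses=VALID_STATUSES) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    _require(df, CELL_TABLE_REQUIRED, "cell table", path)
    unknown = set(df["tls_status"].unique()) - set(statuses)
    if unknown:
        raise ValueError(
            f"cell table {path}: unknown TLS status label(s) {sorted(unknown)}; "
            f"allowed: {list(statuses)}"
        )
    return df


def write_cell_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    write_table(df, path, sep=sep)


def write_counts(matrix: CountMatrix, prefix) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under directory ``prefix``."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(prefix / "matrix.mtx"), sp.coo_matrix(matrix.X))
    (prefix / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (prefix / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")


def read_counts(prefix) -> CountMatrix:
    prefix = Path(prefix)
    try:
        X = sio.mmread(str(prefix / "matrix.mtx"))
    except ValueError as e:
        raise ValueError(f"malformed MTX file {prefix / 'matrix.mtx'}: {e}") from e
    genes = (prefix / "genes.tsv").read_text().splitlines()
    barcodes = (prefix / "barcodes.tsv").read_text().splitlines()
    return CountMatrix(sp.csr_matrix(X), pd.Index(barcodes), pd.Index(genes))


def write_airr(chains: pd.DataFrame, path) -> None:
    write_table(chains, path, sep="\t")


def read_airr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, AIRR_REQUIRED, "AIRR table", path)
    return df


def read_10x_contigs(path) -> pd.DataFrame:
    """10x filtered_contig CSV mapped onto the AIRR column vocabulary."""
    df = pd.read_csv(path)
    mapping = {"barcode": "cell_id", "chain": "locus", "cdr3_nt": "junction",
               "v_gene": "v_call", "j_gene": "j_call", "cdr3": "junction_aa"}
    _require(df, tuple(mapping), "10x contig table", path)
    return df.rename(columns=mapping)[list(mapping.values())]


def write_spots(abund: pd.DataFrame, path, sep: str = ",") -> None:
    write_table(abund.rename_axis("spot_id"), path, sep=sep, index=True)


def read_spots(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if "spot_id" not in df.columns:
        raise ValueError(f"spot table {path}: missing required column(s) ['spot_id']")
    df = df.set_index("spot_id")
    non_coord = [c for c in df.columns if c not in ("x", "y")]
    if not non_coord:
        raise ValueError(f"spot table {path}: no cell-type columns")
    return df[non_coord]


def write_points(points: pd.DataFrame, path, sep: str = ",") -> None:
    write_table(points, path, sep=sep)


def read_points(path, sep: str = ",", statuses=VALID_STATUSES) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    _require(df, POINTS_REQUIRED, "point table", path)
    unknown = set(df["tls_status"].unique()) - set(statuses)
    if unknown:
        raise ValueError(
            f"point table {path}: unknown TLS status label(s) {sorted(unknown)}"
        )
    return df


def write_ground_truth(truth: dict, path) -> None:
    """JSON sidecar of planted generator parameters."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(_stringify_keys(truth), indent=1, default=_default))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {
            ("|".join(map(str, k)) if isinstance(k, tuple) else str(k)): _stringify_keys(v)
            for k, v in obj.items()
        }
    return obj
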