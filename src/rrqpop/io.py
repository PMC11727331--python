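"""Schema-validated plain-text table I/O.

All pipeline artifacts are inspectable text: CSV/TSV tables, MatrixMarket
counts with row/column index files, and JSON for models and panels.  Each
table format declares its required columns and dtypes; reads and writes
validate against the schema and fail with the offending column named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

__all__ = [
    "SCHEMAS", "read_table", "write_table",
    "read_counts_mtx", "write_counts_mtx",
    "write_json", "read_json",
]

#: column -> kind ('num' numeric, 'int' integer, 'str' free text)
SCHEMAS = {
    "plate": {"drug": "str", "dose_uM": "num", "replicate": "int",
              "raw": "num", "viability": "num"},
    "screen": {"run": "int", "replicate": "int", "viability": "num"},
    "clonogenic": {"dose_Gy": "num", "plated": "int", "colonies": "int",
                   "replicate": "int"},
    "survival": {"time": "num", "event": "int"},
    "de": {"gene": "str", "log2fc": "num", "pvalue": "num", "padj": "num"},
}


def _validate(df, schema_name):
    schema = SCHEMAS[schema_name]
    for col, kind in schema.items():
        if col not in df.columns:
            raise ValueError(f"{schema_name} table lacks column {col!r}")
        if kind in ("num", "int"):
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValueError(f"{schema_name} column {col!r} must be "
                                 f"numeric, got {df[col].dtype}")
            if kind == "int" and not np.array_equal(
                    df[col], df[col].astype(int)):
                raise ValueError(f"{schema_name} column {col!r} must hold "
                                 "integers")
    return df


def read_table(path, schema):
    """Read a CSV/TSV table and validate it against a named schema."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return _validate(pd.read_csv(path, sep=sep), schema)


def write_table(df, path, schema=None):
    """Write a table as CSV/TSV (by extension), validating first."""
    path = Path(path)
    if schema is not None:
        _validate(df, schema)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)
    return path


def write_counts_mtx(counts, prefix):
    """Counts as MatrixMarket plus `<prefix>.genes.txt` / `.samples.txt`."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")),
            csr_matrix(counts.to_numpy(dtype=int)))
    prefix.with_suffix(".genes.txt").write_text(
        "\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".samples.txt").write_text(
        "\n".join(map(str, counts.columns)) + "\n")
    return prefix.with_suffix(".mtx")


def read_counts_mtx(prefix):
    """Inverse of :func:`write_counts_mtx`; returns a genes x samples frame."""
    prefix = Path(prefix)
    mat = mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(int)
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=genes, columns=samples)


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
    return Path(path)


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
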