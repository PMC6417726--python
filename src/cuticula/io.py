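"""Plain-text readers and writers for the pipeline's file contracts.

Expression matrices and sample metadata travel as TSV, GC-MS peak and
standard tables as CSV, ortholog maps as three-ID-column TSV with blanks
for absent members, and ground truth / run reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_meta",
    "read_meta",
    "write_ortholog_map",
    "read_ortholog_map",
    "write_csv",
    "read_csv",
    "write_json",
    "read_json",
]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ortholog_map(omap: pd.DataFrame, path: str | Path) -> None:
    omap.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    omap = pd.read_csv(path, sep="\t", keep_default_na=False)
    return omap.astype(str)


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
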