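"""Text-format I/O: counts (TSV / MatrixMarket triplet), GMT gene sets,
tab-delimited result tables with a one-line provenance header."""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix.

    ``.tsv`` / ``.txt``: tab-delimited, first column gene ids, header row
    sample ids. ``.mtx``: MatrixMarket triplet with sidecar ``<stem>.rows.txt``
    (gene ids) and ``<stem>.cols.txt`` (sample ids), one id per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(path.with_suffix(".rows.txt")).read_text().split()
        samples = Path(path.with_suffix(".cols.txt")).read_text().split()
        return pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.to_numpy()))
        path.with_suffix(".rows.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        counts.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, provenance: str = "", index: bool = True) -> None:
    """Write a TSV with a one-line ``#`` provenance header."""
    path = Path(path)
    stamp = datetime.datetime.now().strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write(f"# bulkdecon {stamp} {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")
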