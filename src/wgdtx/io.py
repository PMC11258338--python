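"""Count-matrix readers: TSV or MatrixMarket with name sidecars."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy.io import mmread

__all__ = ["read_counts"]


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples raw count matrix.

    ``.tsv`` files carry gene ids in the first column and sample ids in the
    header.  ``.mtx`` files (MatrixMarket) need ``<stem>.rows`` and
    ``<stem>.cols`` sidecar files listing gene and sample ids, one per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        rows = Path(str(path.with_suffix("")) + ".rows")
        cols = Path(str(path.with_suffix("")) + ".cols")
        for side in (rows, cols):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar {side}")
        mat = mmread(path)
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        genes = rows.read_text().split()
        samples = cols.read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
        df.index.name = "gene_id"
        return df
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df
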