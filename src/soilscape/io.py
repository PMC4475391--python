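"""Readers and writers for the pipeline's plain-text formats.

Sample metadata travels as CSV (sample_id, x, y, covariates..., land
management); OTU tables as TSV with OTUs in rows and samples in columns, or
as BIOM-format v1 JSON (which is plain JSON and needs no extra library).
Every writer has a reader whose composition is the identity on valid data.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "read_sample_frame",
    "write_sample_frame",
    "read_otu_table",
    "write_otu_table",
    "read_biom_json",
    "write_biom_json",
    "write_diversity",
]

REQUIRED_FRAME_COLUMNS = ("x", "y")


class ParseError(ValueError):
    """Structured parse failure naming the offending rows/cells."""


def read_sample_frame(path) -> pd.DataFrame:
    """Sample metadata CSV indexed by sample_id; coordinates in meters."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError("missing required column 'sample_id'")
    for col in REQUIRED_FRAME_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"missing required coordinate column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"duplicate sample ids: {dup}")
    bad = df.index[df[list(REQUIRED_FRAME_COLUMNS)].isna().any(axis=1)].tolist()
    if bad:
        raise ParseError(f"missing coordinates in rows {bad}")
    return df.set_index("sample_id")


def write_sample_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=True, index_label="sample_id")


def read_otu_table(path) -> pd.DataFrame:
    """OTU table from TSV (rows = OTUs, columns = samples) or BIOM v1 JSON.

    Returns a samples × OTUs integer DataFrame.  Non-integer counts,
    duplicate ids and empty tables are structured errors.
    """
    path = str(path)
    if path.endswith(".json") or path.endswith(".biom"):
        return read_biom_json(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ParseError("empty OTU table")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicate OTU ids: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"duplicate sample ids: {dup}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError("non-numeric entries in OTU table")
    frac = arr != np.round(arr)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ParseError(
            f"non-integer count {arr[i, j]} at OTU {df.index[i]!r}, "
            f"sample {df.columns[j]!r}")
    if (arr < 0).any():
        raise ParseError("negative counts in OTU table")
    out = df.T.astype(np.int64)
    out.index.name = "sample_id"
    out.columns.name = None
    return out


def write_otu_table(table: pd.DataFrame, path) -> None:
    """Write a samples × OTUs table as TSV with OTUs in rows."""
    table.T.rename_axis("otu_id").to_csv(path, sep="\t")


def read_biom_json(path) -> pd.DataFrame:
    """BIOM v1 (JSON) OTU table -> samples × OTUs integer DataFrame."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = doc["shape"]
        mtype = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed BIOM JSON: missing {exc}") from exc
    arr = np.zeros((shape[0], shape[1]))
    if mtype == "dense":
        arr[:] = np.asarray(data, dtype=float)
    else:
        for i, j, v in data:
            arr[int(i), int(j)] = v
    if not np.allclose(arr, np.round(arr)):
        raise ParseError("non-integer counts in BIOM table")
    df = pd.DataFrame(arr.T.astype(np.int64),
                      index=pd.Index(sample_ids, name="sample_id"),
                      columns=otu_ids)
    if df.empty or df.shape[1] == 0:
        raise ParseError("empty OTU table")
    return df


def write_biom_json(table: pd.DataFrame, path, table_id: str = "otu-table") -> None:
    """Write a samples × OTUs table as BIOM v1 sparse JSON."""
    t = table.T  # rows = OTUs
    rows, cols = np.nonzero(t.to_numpy())
    data = [[int(i), int(j), int(t.iat[i, j])] for i, j in zip(rows, cols)]
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "soilscape",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [int(t.shape[0]), int(t.shape[1])],
        "rows": [{"id": str(i), "metadata": None} for i in t.index],
        "columns": [{"id": str(c), "metadata": None} for c in t.columns],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_diversity(profile: pd.DataFrame, path) -> None:
    """Diversity profile (richness, shannon, evenness, depth) as CSV."""
    profile.to_csv(path, index=True, index_label="sample_id")


def write_ascii_grid(df: pd.DataFrame, path, value: str = "estimate",
                     nodata: float = -9999.0) -> None:
    """Kriged map (x, y, value rows) as an ESRI ASCII grid (plain text)."""
    xs = np.unique(df["x"].round(6))
    ys = np.unique(df["y"].round(6))
    dx = np.diff(xs).min() if len(xs) > 1 else 1.0
    grid = np.full((len(ys), len(xs)), nodata)
    xi = np.searchsorted(xs, df["x"].round(6))
    yi = np.searchsorted(ys, df["y"].round(6))
    grid[yi, xi] = df[value]
    with open(path, "w") as fh:
        fh.write(f"ncols {len(xs)}\nnrows {len(ys)}\n")
        fh.write(f"xllcorner {xs[0]}\nyllcorner {ys[0]}\n")
        fh.write(f"cellsize {dx}\nNODATA_value {nodata}\n")
        for row in grid[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
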