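"""Per-sample diversity metrics from OTU count tables.

Samples are first rarefied (subsampled without replacement) to a common read
depth — 10,800 reads by default, matching the sequencing effort the analysis
was designed around — and then summarised by OTU richness S, Shannon index H
(natural log) and Pielou evenness J = H / ln S.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_RAREFACTION_DEPTH",
    "RarefactionError",
    "rarefy",
    "shannon",
    "richness",
    "evenness",
    "diversity_profile",
]

DEFAULT_RAREFACTION_DEPTH = 10_800


class RarefactionError(ValueError):
    """A sample holds fewer reads than the requested rarefaction depth."""

    def __init__(self, shallow: list, depth: int):
        self.shallow = list(shallow)
        self.depth = depth
        super().__init__(
            f"samples below the rarefaction depth {depth}: {self.shallow}; "
            "refusing to drop samples silently")


def _as_table(table) -> pd.DataFrame:
    """Coerce to a samples x OTUs integer DataFrame and validate."""
    df = pd.DataFrame(table)
    if df.empty:
        raise ValueError("empty OTU table")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate sample or OTU ids in the table")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("OTU counts must be integers")
        df = df.round().astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in OTU table")
    return df


def rarefy(table: pd.DataFrame, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample (row) to exactly `depth` reads without replacement.

    Equivalent to drawing `depth` reads from the sample's read pool — a
    multivariate hypergeometric draw per sample.  Deterministic given `seed`.
    Samples below `depth` raise :class:`RarefactionError` listing their ids.
    """
    df = _as_table(table)
    totals = df.sum(axis=1)
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        raise RarefactionError(shallow, depth)
    rng = np.random.default_rng(seed)
    out = np.empty(df.shape, dtype=np.int64)
    for i, (_, row) in enumerate(df.iterrows()):
        counts = row.to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _positive(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero sample: diversity undefined")
    return c


def shannon(counts) -> float:
    """Shannon index H = −Σ p_i ln p_i in nats."""
    return float(stats.entropy(_positive(counts)))


def richness(counts) -> int:
    """Number of OTUs with a positive count."""
    return int((_positive(counts) > 0).sum())


def evenness(counts) -> float:
    """Pielou evenness J = H / ln S; NaN for a single-OTU sample."""
    c = _positive(counts)
    s = c.size
    if s == 1:
        return float("nan")
    return float(stats.entropy(c) / np.log(s))


def diversity_profile(table: pd.DataFrame,
                      depth: int | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Richness, Shannon and evenness per sample, optionally after rarefaction.

    Returns a DataFrame indexed by sample id with columns
    ``richness``, ``shannon``, ``evenness`` and ``depth`` (reads used).
    """
    df = _as_table(table)
    if depth is not None:
        df = rarefy(df, depth, seed=seed)
    rows = {}
    for sid, row in df.iterrows():
        c = row.to_numpy()
        rows[sid] = {
            "richness": richness(c),
            "shannon": shannon(c),
            "evenness": evenness(c),
            "depth": int(c.sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
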