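"""Rarefaction and per-sample alpha-diversity indices.

Indices follow the usual definitions on proportions ``p_i = count_i/total``:
observed OTU richness, Shannon entropy ``-sum p_i ln p_i`` (natural log),
and inverse Simpson ``1 / sum p_i^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tableio import CountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlphaRecord:
    sample_id: str
    observed_otus: int
    shannon: float
    invsimpson: float


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Uses multivariate hypergeometric draws, so the result is an exact
    uniform subsample of the reads. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= depth].tolist()
    if not keep:
        raise ValueError(
            f"rarefaction depth {depth} exceeds every sample total "
            f"(max {int(totals.max())})")
    dropped = totals.index.difference(keep).tolist()
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = np.empty((table.counts.shape[0], len(keep)), dtype=np.int64)
    for j, sid in enumerate(keep):
        col = table.counts[sid].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=keep)
    meta = None if table.sample_meta is None else table.sample_meta.loc[keep]
    return CountTable(counts, meta, table.taxonomy)


def auto_depth(table: CountTable) -> int:
    """Default rarefaction depth: the minimum sample total."""
    return int(table.counts.sum(axis=0).min())


def alpha_diversity(table: CountTable) -> list[AlphaRecord]:
    """Observed OTUs, Shannon (natural log) and inverse Simpson per sample."""
    records = []
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero total counts")
        p = col[col > 0] / total
        records.append(AlphaRecord(
            sample_id=sid,
            observed_otus=int((col > 0).sum()),
            shannon=float(-(p * np.log(p)).sum()),
            invsimpson=float(1.0 / (p ** 2).sum()),
        ))
    return records


def alpha_frame(records: list[AlphaRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
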