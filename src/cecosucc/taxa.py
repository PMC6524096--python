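"""Taxonomic agglomeration, abundance ratios and the pathway-presence filter.

Counts agglomerate by summing OTU rows sharing a rank label (phylum, family
or genus); empty labels pool into an explicit ``unassigned`` bucket so
column totals are conserved. Ratio trajectories (e.g. Firmicutes to
Bacteroidetes) are computed per sample and summarised per age. The pathway
filter retains pathways present in at least a fraction (default 1/3) of the
genomes of a taxon of interest, presence meaning completeness at or above a
cutoff (default 1.0, i.e. the whole pathway).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tableio import CountTable, TAXONOMY_RANKS

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RatioResult:
    per_sample: pd.DataFrame    # sample_id -> ratio (NaN when denominator 0)
    summary: pd.DataFrame | None  # per-age mean, sd, n (when ages known)
    n_zero_denominator: int


def agglomerate(table: CountTable, rank: str) -> pd.DataFrame:
    """Sum counts over OTUs sharing a rank label; empty -> ``unassigned``.

    Returns a taxon x sample frame whose column sums equal the input's.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {TAXONOMY_RANKS}")
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy attached")
    labels = table.taxonomy[rank].replace("", UNASSIGNED).fillna(UNASSIGNED)
    out = table.counts.groupby(labels.loc[table.counts.index]).sum()
    out.index.name = rank
    return out.sort_index()


def taxon_ratio(rank_table: pd.DataFrame, numerator: str, denominator: str,
                sample_ages: pd.Series | None = None) -> RatioResult:
    """Per-sample ratio of two taxa, with per-age mean +/- sd when ages given.

    Samples with a zero denominator get a NaN ratio and are excluded from
    the summaries (their number is reported and logged).
    """
    for name in (numerator, denominator):
        if name not in rank_table.index:
            raise ValueError(f"taxon {name!r} not in table")
    num = rank_table.loc[numerator].astype(float)
    den = rank_table.loc[denominator].astype(float)
    ratio = num.divide(den).where(den > 0, np.nan)
    n_zero = int((den == 0).sum())
    if n_zero:
        logger.warning("taxon_ratio: %d samples with zero %s excluded",
                       n_zero, denominator)
    ratio.name = f"{numerator}/{denominator}"
    summary = None
    if sample_ages is not None:
        df = pd.DataFrame({"ratio": ratio,
                           "age_days": sample_ages.loc[ratio.index]})
        summary = (df.dropna().groupby("age_days")["ratio"]
                   .agg(["mean", "std", "count"])
                   .rename(columns={"std": "sd", "count": "n"}))
    return RatioResult(per_sample=ratio.to_frame(), summary=summary,
                       n_zero_denominator=n_zero)


def pathway_presence_filter(completeness: pd.DataFrame,
                            min_presence: float = 1 / 3,
                            completeness_cutoff: float = 1.0) -> list[str]:
    """Pathways present in at least ``min_presence`` of the genomes.

    ``completeness`` is a pathway x genome frame of completeness scores in
    [0, 1]; a genome "contains" a pathway when its score is at or above
    ``completeness_cutoff``. Retention uses >= (a pathway in exactly 1 of 3
    genomes passes a 1/3 threshold).
    """
    if completeness.shape[1] < 1:
        raise ValueError("need at least one genome column")
    vals = completeness.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("completeness scores must be in [0, 1]")
    present = vals >= completeness_cutoff
    frac = present.mean(axis=1)
    return [p for p, f in zip(completeness.index, frac) if f >= min_presence]


def percent_contrast(value: float, others) -> float:
    """Percent excess of ``value`` over the mean of ``others``.

    E.g. early solid-feed intake of 7.8 g/d against groups at 6.4 and 6.2
    g/d is a +23.8% contrast.
    """
    base = float(np.mean(list(others)))
    if base == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (value - base) / base
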