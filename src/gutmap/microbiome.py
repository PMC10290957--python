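"""Post-ASV community-table processing.

Consumes an amplicon sequence variant (ASV) count table with taxonomic
lineages and sample metadata; provides sequencing-depth filtering,
rarefaction to a common depth (random subsampling without replacement,
equivalent to vegan's ``rrarefy``), aggregation to a taxonomic rank and
relative-abundance normalization.  Read denoising, classification and
chimera removal happen upstream and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "AsvTable",
    "filter_depth",
    "rarefy",
    "aggregate",
    "relative_abundance",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AsvTable:
    """Integer counts taxa x samples with lineage and sample metadata.

    ``lineage`` is indexed by taxon with the seven rank columns;
    ``samples`` is indexed by sample id (columns typically mouse,
    region, habitat).
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        missing = set(self.counts.index) - set(self.lineage.index)
        if missing:
            raise ValueError(f"lineage missing for taxa: {sorted(missing)[:5]}")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample index")

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, ids) -> "AsvTable":
        ids = list(ids)
        return AsvTable(self.counts[ids], self.lineage, self.samples.loc[ids])


def filter_depth(
    table: AsvTable, min_reads: int = 1000
) -> tuple[AsvTable, list[str]]:
    """Drop samples with fewer than ``min_reads`` total reads.

    The boundary is inclusive: a sample at exactly ``min_reads`` is
    retained.
    """
    if table.counts.shape[1] == 0:
        raise ValueError("empty table")
    depths = table.depths
    keep = depths.index[depths >= min_reads]
    dropped = [s for s in depths.index if s not in set(keep)]
    if len(keep) == 0:
        raise ValueError("all samples fall below the depth threshold")
    return table.subset_samples(keep), dropped


def rarefy(table: AsvTable, depth: int | None = None, seed: int = 0) -> AsvTable:
    """Subsample each sample without replacement to a common depth.

    ``depth=None`` uses the minimum sample sum (the common choice when
    normalizing sequencing effort after depth filtering).  Taxa that end
    up all-zero are retained.
    """
    depths = table.depths
    if depth is None:
        depth = int(depths.min())
    too_shallow = depths.index[depths < depth].tolist()
    if too_shallow:
        raise ValueError(
            f"samples below rarefaction depth {depth}: {too_shallow[:10]}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    counts = table.counts.to_numpy()
    for j in range(counts.shape[1]):
        col = counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AsvTable(rarefied, table.lineage, table.samples)


def aggregate(table: AsvTable, rank: str) -> pd.DataFrame:
    """Sum ASV counts sharing the same label at ``rank``.

    Taxa unannotated at the rank (empty/NaN label) are pooled as
    ``"unclassified <parent label>"`` using the nearest annotated
    ancestor rank.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    lineage = table.lineage.loc[table.counts.index]
    labels = lineage[rank].astype(object).copy()
    blank = labels.isna() | (labels.astype(str).str.len() == 0)
    if blank.any():
        upto = RANKS[: RANKS.index(rank)]
        for taxon in labels.index[blank]:
            parent = "root"
            for r in upto:
                val = lineage.at[taxon, r]
                if isinstance(val, str) and val:
                    parent = val
            labels.at[taxon] = f"unclassified {parent}"
    return table.counts.groupby(labels).sum()


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample (column) to proportions summing to 1."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum samples: {zero[:10]}")
    return counts / totals
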