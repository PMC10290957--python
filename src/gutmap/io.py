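"""Plain-text table readers/writers for the pipeline's interfaces.

Concentration matrices are written as wide CSV with explicit censoring
sentinels ("<LLOQ" below the linear range, ">ULOL" above) distinct from
missing (empty cell), alongside a long-format sample-metadata CSV.
Community tables use TSV (counts, 7-rank lineages, sample metadata), and
the network maps use the familiar one-pair-per-row TSV layouts
(taxon -> EC as emitted by functional prediction tools, metabolite -> EC,
and a host EC list).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .association import NetworkMaps
from .microbiome import AsvTable
from .quantify import (
    CENSOR_ABOVE,
    CENSOR_BELOW,
    CENSOR_MISSING,
    CENSOR_OK,
    ConcentrationMatrix,
)

__all__ = [
    "write_concentrations",
    "read_concentrations",
    "write_asv_table",
    "read_asv_table",
    "write_network_maps",
    "read_network_maps",
    "write_fits",
]

_BELOW = "<LLOQ"
_ABOVE = ">ULOL"


def write_concentrations(matrix: ConcentrationMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>_values.csv`` and ``<prefix>_samples.csv``."""
    prefix = Path(prefix)
    cells = matrix.values.astype(object)
    cells[matrix.mask == CENSOR_BELOW] = _BELOW
    cells[matrix.mask == CENSOR_ABOVE] = _ABOVE
    cells[matrix.mask == CENSOR_MISSING] = ""
    cells.to_csv(prefix.with_name(prefix.name + "_values.csv"))
    matrix.samples.to_csv(prefix.with_name(prefix.name + "_samples.csv"))


def read_concentrations(prefix: str | Path) -> ConcentrationMatrix:
    prefix = Path(prefix)
    raw = pd.read_csv(
        prefix.with_name(prefix.name + "_values.csv"), index_col=0, dtype=object,
        keep_default_na=False,
    )
    samples = pd.read_csv(prefix.with_name(prefix.name + "_samples.csv"), index_col=0)
    mask = np.full(raw.shape, CENSOR_OK, dtype=np.int8)
    values = np.full(raw.shape, np.nan)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j]
            if cell == _BELOW:
                mask[i, j] = CENSOR_BELOW
            elif cell == _ABOVE:
                mask[i, j] = CENSOR_ABOVE
            elif cell == "" or cell is None:
                mask[i, j] = CENSOR_MISSING
            else:
                values[i, j] = float(cell)
    return ConcentrationMatrix(
        pd.DataFrame(values, index=raw.index, columns=raw.columns),
        samples,
        pd.DataFrame(mask, index=raw.index, columns=raw.columns),
    )


def write_asv_table(table: AsvTable, prefix: str | Path) -> None:
    """Write ``<prefix>_counts.tsv``, ``_lineage.tsv`` and ``_samples.tsv``."""
    prefix = Path(prefix)
    table.counts.to_csv(prefix.with_name(prefix.name + "_counts.tsv"), sep="\t")
    table.lineage.to_csv(prefix.with_name(prefix.name + "_lineage.tsv"), sep="\t")
    table.samples.to_csv(prefix.with_name(prefix.name + "_samples.tsv"), sep="\t")


def read_asv_table(prefix: str | Path) -> AsvTable:
    prefix = Path(prefix)
    counts = pd.read_csv(
        prefix.with_name(prefix.name + "_counts.tsv"), sep="\t", index_col=0
    )
    lineage = pd.read_csv(
        prefix.with_name(prefix.name + "_lineage.tsv"), sep="\t", index_col=0,
        keep_default_na=False,
    )
    samples = pd.read_csv(
        prefix.with_name(prefix.name + "_samples.tsv"), sep="\t", index_col=0
    )
    return AsvTable(counts, lineage, samples)


def write_network_maps(maps: NetworkMaps, outdir: str | Path) -> None:
    """Write host_ecs.txt, taxon_ec.tsv (one EC per row), metabolite_ec.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "host_ecs.txt").write_text(
        "\n".join(sorted(maps.host_ecs)) + "\n"
    )
    with open(outdir / "taxon_ec.tsv", "w") as fh:
        fh.write("taxon\tec\n")
        for taxon in sorted(maps.taxon_ecs):
            for ec in sorted(maps.taxon_ecs[taxon]):
                fh.write(f"{taxon}\t{ec}\n")
    with open(outdir / "metabolite_ec.tsv", "w") as fh:
        fh.write("metabolite\tec\n")
        for met in sorted(maps.metabolite_ecs):
            for ec in sorted(maps.metabolite_ecs[met]):
                fh.write(f"{met}\t{ec}\n")


def read_network_maps(outdir: str | Path) -> NetworkMaps:
    outdir = Path(outdir)
    host = frozenset(
        line.strip()
        for line in (outdir / "host_ecs.txt").read_text().splitlines()
        if line.strip()
    )
    taxon_df = pd.read_csv(outdir / "taxon_ec.tsv", sep="\t")
    met_df = pd.read_csv(outdir / "metabolite_ec.tsv", sep="\t")
    taxon_ecs = {
        t: frozenset(g["ec"]) for t, g in taxon_df.groupby("taxon")
    }
    met_ecs = {
        m: frozenset(g["ec"]) for m, g in met_df.groupby("metabolite")
    }
    return NetworkMaps(host_ecs=host, taxon_ecs=taxon_ecs, metabolite_ecs=met_ecs)


def write_fits(fits: dict, chosen: dict, path: str | Path) -> None:
    """One row per metabolite x modification with all fit fields."""
    rows = []
    for met, mods in fits.items():
        for mod, f in mods.items():
            rows.append(
                dict(
                    metabolite=met, modification=mod, slope=f.slope,
                    intercept=f.intercept, r2=f.r2, removed_top=f.removed_top,
                    removed_bottom=f.removed_bottom, lloq=f.lloq, ulol=f.ulol,
                    n_retained=f.n_retained, chosen=(chosen.get(met) == mod),
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
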