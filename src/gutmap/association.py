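"""Metabolite origin classification and metabolite-microbe association.

Origin classification compares each metabolite's enzyme (EC number) set
against the host metabolic network and the predicted microbiome network
(union of per-taxon EC sets from functional prediction); a metabolite is
labelled host-only, microbe-only, both, or unmatched.

The association cascade aggregates the 15-site metabolome to the five
community-profiling regions, computes per-pair Spearman rank correlation
over matched (mouse, region, habitat) observations, and then applies the
sequential filter funnel: correlation P below threshold, colonized vs
germ-free fold change above threshold, enzyme possession by the paired
taxon, and positive correlation.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import MICROBIOME_REGIONS
from .quantify import ConcentrationMatrix

__all__ = [
    "NetworkMaps",
    "classify_origin",
    "spearman",
    "spatial_correlate",
    "filter_pairs",
    "summarize_pairs",
]

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def _check_ecs(ecs, where: str) -> frozenset[str]:
    ecs = frozenset(ecs)
    bad = [e for e in ecs if not _EC_RE.match(e)]
    if bad:
        raise ValueError(f"malformed EC numbers in {where}: {bad[:5]}")
    return ecs


@dataclass
class NetworkMaps:
    """Host EC set, per-taxon EC sets, and metabolite -> EC mapping."""

    host_ecs: frozenset[str]
    taxon_ecs: dict[str, frozenset[str]] = field(default_factory=dict)
    metabolite_ecs: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.host_ecs = _check_ecs(self.host_ecs, "host")
        self.taxon_ecs = {t: _check_ecs(e, t) for t, e in self.taxon_ecs.items()}
        self.metabolite_ecs = {
            m: _check_ecs(e, m) for m, e in self.metabolite_ecs.items()
        }

    @property
    def microbiome_ecs(self) -> frozenset[str]:
        out: set[str] = set()
        for ecs in self.taxon_ecs.values():
            out |= ecs
        return frozenset(out)


def classify_origin(metabolites, maps: NetworkMaps) -> pd.Series:
    """Label each metabolite host / microbe / both / unmatched.

    A metabolite maps to a network when its EC set intersects it; the
    four labels partition the metabolite list.  Metabolites without an
    EC entry are unmatched.
    """
    micro = maps.microbiome_ecs
    labels = {}
    for met in metabolites:
        ecs = maps.metabolite_ecs.get(met, frozenset())
        in_host = bool(ecs & maps.host_ecs)
        in_micro = bool(ecs & micro)
        if in_host and in_micro:
            labels[met] = "both"
        elif in_host:
            labels[met] = "host"
        elif in_micro:
            labels[met] = "microbe"
        else:
            labels[met] = "unmatched"
    return pd.Series(labels, name="origin")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation P for Spearman rho at small n."""
    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    n = len(rx)
    count = 0
    total = 0
    observed = abs(rho)
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx[list(perm)], ry)[0, 1]
        total += 1
        if abs(r) >= observed - 1e-12:
            count += 1
    return count / total


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with average ranks and a two-sided P value.

    Uses the t-approximation for n > ``exact_max_n`` and an exact
    permutation distribution for smaller samples, where the
    approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return math.nan, math.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    if n <= exact_max_n and not math.isnan(rho):
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def _region_profile(matrix: ConcentrationMatrix) -> pd.DataFrame:
    """Mean concentration per (mouse, region, habitat) observation.

    The 15 metabolome sites are reduced to the five community-profiling
    regions by averaging a region's sites within each mouse and habitat;
    the stomach has no community sample and is dropped.
    """
    meta = matrix.samples
    keep = meta["region"].isin(MICROBIOME_REGIONS)
    ids = meta.index[keep]
    values = matrix.values[ids]
    key = meta.loc[ids, ["mouse", "region", "habitat"]].apply(tuple, axis=1)
    grouped = values.T.groupby(key.values).mean().T
    grouped.columns = pd.MultiIndex.from_tuples(
        grouped.columns, names=["mouse", "region", "habitat"]
    )
    return grouped


def _abundance_profile(abundance: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean relative abundance per (mouse, region, habitat).

    Replicate community samples of the same stratum are averaged.
    """
    key = samples.loc[abundance.columns, ["mouse", "region", "habitat"]].apply(
        tuple, axis=1
    )
    grouped = abundance.T.groupby(key.values).mean().T
    grouped.columns = pd.MultiIndex.from_tuples(
        grouped.columns, names=["mouse", "region", "habitat"]
    )
    return grouped


def spatial_correlate(
    matrix: ConcentrationMatrix,
    abundance: pd.DataFrame,
    asv_samples: pd.DataFrame,
    habitat: str = "both",
    min_points: int = 3,
) -> pd.DataFrame:
    """Spearman correlation for every (metabolite, taxon) pair.

    Observation points are matched (mouse, region, habitat) strata
    present in both datasets; ``habitat`` may restrict to ``"lumen"``
    or ``"mucus"``.  Pairs with fewer than ``min_points`` paired
    non-missing observations get NaN rho/P (excluded from filtering).
    Returns one row per pair: metabolite, taxon, rho, p, n_obs.
    """
    met_prof = _region_profile(matrix)
    tax_prof = _abundance_profile(abundance, asv_samples)
    if habitat in ("lumen", "mucus"):
        met_prof = met_prof.loc[:, met_prof.columns.get_level_values("habitat") == habitat]
        tax_prof = tax_prof.loc[:, tax_prof.columns.get_level_values("habitat") == habitat]
    shared = met_prof.columns.intersection(tax_prof.columns)
    if len(shared) == 0:
        raise ValueError("no matched (mouse, region, habitat) observations")
    M = met_prof[shared].to_numpy()
    T = tax_prof[shared].to_numpy()

    rows = []
    for i, met in enumerate(met_prof.index):
        for j, taxon in enumerate(tax_prof.index):
            x, y = M[i], T[j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < min_points:
                rho, p = math.nan, math.nan
            else:
                rho, p = spearman(x[ok], y[ok])
            rows.append((met, taxon, rho, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["metabolite", "taxon", "rho", "p", "n_obs"])


def filter_pairs(
    pairs: pd.DataFrame,
    fold_changes: pd.Series,
    maps: NetworkMaps,
    exclusive: pd.Series | None = None,
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    require_enzyme: bool = True,
    require_positive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the sequential association filter funnel.

    Stages: correlation P < ``p_threshold``; metabolite SPF/GF fold
    change > ``fc_threshold`` (metabolites exclusive to colonized mice
    pass by definition); the paired taxon possesses an enzyme acting on
    the metabolite; positive correlation.  Returns the annotated pair
    table (with per-stage flags and ``final_pass``) and the funnel table
    of survivor counts.
    """
    out = pairs.copy()
    fc = out["metabolite"].map(fold_changes)
    excl = (
        out["metabolite"].map(exclusive).fillna(False).astype(bool)
        if exclusive is not None
        else pd.Series(False, index=out.index)
    )
    out["spf_gf_fc"] = fc
    out["exclusive"] = excl.values

    defined = out["p"].notna()
    # BH-adjusted column for transparency; the gate itself uses raw P
    from .differential import bh_adjust

    out["q"] = np.nan
    if defined.any():
        out.loc[defined, "q"] = bh_adjust(out.loc[defined, "p"].to_numpy())
    out["pass_p"] = defined & (out["p"] < p_threshold)
    out["pass_fc"] = out["pass_p"] & ((fc > fc_threshold) | excl.values)
    enzyme = out.apply(
        lambda r: bool(
            maps.metabolite_ecs.get(r["metabolite"], frozenset())
            & maps.taxon_ecs.get(r["taxon"], frozenset())
        ),
        axis=1,
    )
    out["has_enzyme"] = enzyme
    out["pass_enzyme"] = out["pass_fc"] & (enzyme if require_enzyme else True)
    out["pass_positive"] = out["pass_enzyme"] & (
        (out["rho"] > 0) if require_positive else True
    )
    out["final_pass"] = out["pass_positive"]

    funnel = pd.DataFrame(
        {
            "stage": [
                "all_pairs",
                f"p<{p_threshold}",
                f"fc>{fc_threshold}",
                "enzyme",
                "rho>0",
            ],
            "n_pairs": [
                len(out),
                int(out["pass_p"].sum()),
                int(out["pass_fc"].sum()),
                int(out["pass_enzyme"].sum()),
                int(out["pass_positive"].sum()),
            ],
        }
    )
    return out, funnel


def summarize_pairs(pairs: pd.DataFrame, lineage: pd.DataFrame) -> pd.DataFrame:
    """Per-order counts of passing pairs plus unique metabolite/taxon totals.

    ``pairs`` should be the annotated table from :func:`filter_pairs`;
    only rows with ``final_pass`` are counted (all rows if the column is
    absent).  Returns a long table (order, n_pairs, n_metabolites,
    n_taxa) suitable for Sankey-style summaries.
    """
    if "final_pass" in pairs.columns:
        pairs = pairs[pairs["final_pass"]]
    if pairs.empty:
        return pd.DataFrame(columns=["order", "n_pairs", "n_metabolites", "n_taxa"])
    missing = set(pairs["taxon"]) - set(lineage.index)
    if missing:
        raise ValueError(f"lineage missing for taxa: {sorted(missing)[:5]}")
    order = pairs["taxon"].map(lineage["order"])
    grouped = pairs.assign(order=order.values).groupby("order")
    out = grouped.agg(
        n_pairs=("taxon", "size"),
        n_metabolites=("metabolite", "nunique"),
        n_taxa=("taxon", "nunique"),
    ).reset_index()
    return out.sort_values("n_pairs", ascending=False, ignore_index=True)
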