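"""Fold-change and significance analyses.

Covers the paired habitat and region contrasts (two-sided paired t-test
across mice with Benjamini-Hochberg correction), colonized (SPF) vs
germ-free (GF) fold-change cascades, microbial-origin calling with the
fourfold rule, subregion-specific calls, and the diet-composition share
screen.

Fold changes never use pseudo-counts: a metabolite detected in one
colonization group and fully undetected in the other is flagged as
exclusive (the categorical analogue of an infinite fold change) and its
log2 fold change is left NaN.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import LI_REGIONS, SI_REGIONS
from .quantify import CENSOR_BELOW, CENSOR_OK, ConcentrationMatrix

__all__ = [
    "bh_adjust",
    "paired_contrast",
    "group_mean",
    "colonization_fc",
    "call_origin",
    "diet_share",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mouse_means(sub: ConcentrationMatrix) -> pd.DataFrame:
    """Per-metabolite mean over each mouse's samples (NaN-excluded)."""
    key = sub.samples["mouse"]
    return sub.values.T.groupby(key.values).mean().T


def paired_contrast(
    matrix: ConcentrationMatrix,
    group_col: str,
    groups: tuple[str, str],
    pairing: str = "mouse",
    fc_threshold_log2: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group paired differential analysis per metabolite.

    Values are averaged within each pairing unit (mouse) per group, a
    two-sided paired t-test is run across units, and P values are
    BH-adjusted over all testable metabolites in the contrast.  The
    log2 fold change is log2(mean A / mean B) of the unit-averaged
    group means; positive values mean higher in group A.

    Metabolites with fewer than two complete pairs are reported as
    untestable (NaN P) and excluded from the BH family.  Zero-variance
    zero-difference pairs get P = 1.  A group counts as undetected only
    when every value is censored below the LLOQ; such one-sided
    metabolites carry the exclusivity marker instead of a fold change.
    """
    a_label, b_label = groups
    sub_a = matrix.select(**{group_col: a_label})
    sub_b = matrix.select(**{group_col: b_label})
    mean_a = _mouse_means(sub_a)
    mean_b = _mouse_means(sub_b)
    units = mean_a.columns.intersection(mean_b.columns)

    rows = []
    for met in matrix.metabolites:
        xa = mean_a.loc[met, units]
        xb = mean_b.loc[met, units]
        a_undet = _all_censored_below(sub_a, met)
        b_undet = _all_censored_below(sub_b, met)
        if a_undet != b_undet and (a_undet or b_undet):
            rows.append(
                dict(metabolite=met, log2fc=np.nan, p=np.nan, n_pairs=0,
                     exclusivity=f"{b_label}_only" if a_undet else f"{a_label}_only")
            )
            continue
        ok = xa.notna() & xb.notna()
        n = int(ok.sum())
        if n < 2:
            rows.append(dict(metabolite=met, log2fc=np.nan, p=np.nan,
                             n_pairs=n, exclusivity=None))
            continue
        va, vb = xa[ok].to_numpy(), xb[ok].to_numpy()
        ma, mb = va.mean(), vb.mean()
        log2fc = np.log2(ma / mb) if ma > 0 and mb > 0 else np.nan
        diffs = va - vb
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(va, vb).pvalue)
        rows.append(dict(metabolite=met, log2fc=log2fc, p=p, n_pairs=n,
                         exclusivity=None))

    out = pd.DataFrame(rows).set_index("metabolite")
    testable = out["p"].notna()
    out["q"] = np.nan
    if testable.any():
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["significant"] = (
        testable
        & (out["log2fc"].abs() >= fc_threshold_log2)
        & (out["q"] <= alpha)
    )
    out["contrast"] = f"{group_col}:{a_label}_vs_{b_label}"
    return out


def welch_contrast(
    a: ConcentrationMatrix,
    b: ConcentrationMatrix,
    labels: tuple[str, str] = ("SPF", "GF"),
    fc_threshold_log2: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Unpaired two-sided Welch test between two colonization groups.

    Different animals cannot be paired, so colonization comparisons use
    Welch's unequal-variance t-test on mouse-averaged values where a P
    value is wanted; fold-change thresholds remain the primary
    criterion.  Exclusivity handling mirrors :func:`paired_contrast`.
    """
    mean_a = _mouse_means(a)
    mean_b = _mouse_means(b)
    rows = []
    for met in a.metabolites:
        xa = mean_a.loc[met].dropna()
        xb = mean_b.loc[met].dropna() if met in mean_b.index else pd.Series(dtype=float)
        a_undet = _all_censored_below(a, met)
        b_undet = _all_censored_below(b, met)
        if a_undet != b_undet and (a_undet or b_undet):
            rows.append(dict(metabolite=met, log2fc=np.nan, p=np.nan,
                             n_a=len(xa), n_b=len(xb),
                             exclusivity=f"{labels[1]}_only" if a_undet
                             else f"{labels[0]}_only"))
            continue
        if len(xa) < 2 or len(xb) < 2:
            rows.append(dict(metabolite=met, log2fc=np.nan, p=np.nan,
                             n_a=len(xa), n_b=len(xb), exclusivity=None))
            continue
        ma, mb = xa.mean(), xb.mean()
        log2fc = np.log2(ma / mb) if ma > 0 and mb > 0 else np.nan
        if np.allclose(xa.to_numpy().std(), 0) and np.allclose(
            xb.to_numpy().std(), 0
        ) and np.isclose(ma, mb):
            p = 1.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append(dict(metabolite=met, log2fc=log2fc, p=p,
                         n_a=len(xa), n_b=len(xb), exclusivity=None))
    out = pd.DataFrame(rows).set_index("metabolite")
    testable = out["p"].notna()
    out["q"] = np.nan
    if testable.any():
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["significant"] = (
        testable & (out["log2fc"].abs() >= fc_threshold_log2) & (out["q"] <= alpha)
    )
    out["contrast"] = f"colonization:{labels[0]}_vs_{labels[1]}"
    return out


def _all_censored_below(sub: ConcentrationMatrix, metabolite: str) -> bool:
    codes = sub.mask.loc[metabolite]
    measured = codes != 2  # ignore missing
    if not measured.any():
        return False
    return bool((codes[measured] == CENSOR_BELOW).all())


def _detected_any(sub: ConcentrationMatrix, metabolite: str) -> bool:
    return bool((sub.mask.loc[metabolite] == CENSOR_OK).any())


def group_mean(sub: ConcentrationMatrix) -> pd.Series:
    """Per-metabolite mean over all non-censored values (NaN if none)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sub.values.mean(axis=1)


def colonization_fc(
    spf: ConcentrationMatrix,
    gf: ConcentrationMatrix,
    regions: Sequence[str] | None = None,
    habitat: str | None = None,
    granularity: str = "site",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SPF vs GF fold-change points and per-metabolite summary.

    At ``granularity="site"`` the fold-change point for SPF mouse m at
    site s is value(m, s) / mean over GF mice at s — the four large
    intestinal sites with five mice give 20 points per metabolite and
    habitat, the ten small intestinal sites give 50.  At
    ``granularity="region"`` each mouse's values are first averaged over
    the subset's sites, giving one point per mouse.

    Returns (points, summary); the summary has the median log2 fold
    change, mean fold change of group means, and exclusivity flags
    (detected in SPF with GF fully undetected, or zero GF mean).
    """
    if granularity not in ("site", "region"):
        raise ValueError("granularity must be 'site' or 'region'")
    crit: dict = {}
    if regions is not None:
        crit["region"] = tuple(regions)
    if habitat is not None:
        crit["habitat"] = habitat
    s = spf.select(**crit) if crit else spf
    g = gf.select(**crit) if crit else gf

    spf_sites = set(s.samples["site_index"])
    gf_sites = set(g.samples["site_index"])
    shared = sorted(spf_sites & gf_sites)
    skipped = sorted(spf_sites ^ gf_sites)
    if skipped:
        warnings.warn(f"sites absent in one group skipped: {skipped}", stacklevel=2)
    s = s.select(site_index=shared)
    g = g.select(site_index=shared)

    if granularity == "site":
        cols = s.samples[["mouse", "site_index"]].apply(tuple, axis=1)
        spf_units = s.values.T.groupby(cols.values).mean().T
        gf_site_mean = g.values.T.groupby(g.samples["site_index"].values).mean().T
        denom = spf_units.columns.map(lambda mc: mc[1])
        ref = gf_site_mean.reindex(columns=denom)
        ref.columns = spf_units.columns
    else:
        spf_units = _mouse_means(s)
        gm = group_mean(g)
        ref = pd.DataFrame(
            np.tile(gm.to_numpy()[:, None], (1, spf_units.shape[1])),
            index=spf_units.index, columns=spf_units.columns,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = spf_units / ref
    fc[ref <= 0] = np.nan

    points = fc.stack(future_stack=True).rename("fc").reset_index()
    points.columns = ["metabolite", "unit", "fc"]

    spf_mean = group_mean(s)
    gf_mean = group_mean(g)
    gf_undetected = pd.Series(
        {m: _all_censored_below(g, m) or not (gf_mean[m] > 0) for m in s.metabolites}
    )
    spf_detected = pd.Series(
        {m: _detected_any(s, m) or (spf_mean[m] > 0) for m in s.metabolites}
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_fc = spf_mean / gf_mean
    mean_fc[~(gf_mean > 0)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_log2 = np.log2(fc.where(fc > 0)).median(axis=1)
    summary = pd.DataFrame(
        {
            "median_log2fc": median_log2,
            "mean_fc": mean_fc,
            "n_points": fc.notna().sum(axis=1),
            "exclusive_spf": gf_undetected & spf_detected,
        }
    )
    return points, summary


def _region_mean(matrix: ConcentrationMatrix, regions, habitat) -> pd.Series:
    sub = matrix.select(region=tuple(regions), habitat=habitat)
    return group_mean(sub)


def _safe_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r[~(den > 0)] = np.nan
    return r


def call_origin(
    spf: ConcentrationMatrix,
    gf: ConcentrationMatrix,
    fold_threshold: float = 4.0,
    habitats: Sequence[str] = ("lumen", "mucus"),
) -> pd.DataFrame:
    """Two-stage microbial-origin calling plus subregion-specific calls.

    Stage 1: mean concentration at least ``fold_threshold`` higher in
    the large than the small intestine in either habitat (high
    bacterial load implicates microbial activity).  Stage 2, evaluated
    on stage-1 metabolites: SPF mean at least ``fold_threshold`` times
    the GF mean within the large intestine (SPF-exclusive metabolites
    pass by definition).  Independently, a subregion call fires when the
    SPF/GF ratio reaches the threshold within the duodenum, jejunum or
    ileum while the whole-small-intestine ratio stays below it.

    Final labels: stage 1 + stage 2 -> "supported_microbial"; stage 1
    without stage 2, or a subregion-only call -> "candidate"; pooled
    SPF/GF ratio at or below 1/threshold (enriched in germ-free mice,
    pointing at diet or host) -> "host_diet"; otherwise "unclassified".
    """
    mets = spf.metabolites
    out = pd.DataFrame(index=mets)

    stage1 = pd.Series(False, index=mets)
    stage2 = pd.Series(False, index=mets)
    exclusive = pd.Series(False, index=mets)
    for habitat in habitats:
        si = _region_mean(spf, SI_REGIONS, habitat)
        li = _region_mean(spf, LI_REGIONS, habitat)
        stage1 |= (_safe_ratio(li, si) >= fold_threshold).fillna(
            (li > 0) & ~(si > 0)
        )
        li_spf = li
        li_gf = _region_mean(gf, LI_REGIONS, habitat)
        gf_sub = gf.select(region=tuple(LI_REGIONS), habitat=habitat)
        excl_h = pd.Series(
            {
                m: (li_spf[m] > 0)
                and (_all_censored_below(gf_sub, m) or not (li_gf[m] > 0))
                for m in mets
            }
        )
        exclusive |= excl_h
        stage2 |= (_safe_ratio(li_spf, li_gf) >= fold_threshold).fillna(False) | excl_h

    subregion_flags = {}
    subregion_any = pd.Series(False, index=mets)
    for habitat in habitats:
        si_fc = _safe_ratio(
            _region_mean(spf, SI_REGIONS, habitat), _region_mean(gf, SI_REGIONS, habitat)
        )
        for region in SI_REGIONS:
            r_fc = _safe_ratio(
                _region_mean(spf, [region], habitat),
                _region_mean(gf, [region], habitat),
            )
            flag = (r_fc >= fold_threshold).fillna(False) & ~(
                (si_fc >= fold_threshold).fillna(False)
            )
            key = region
            subregion_flags[key] = subregion_flags.get(key, pd.Series(False, index=mets)) | flag
            subregion_any |= flag

    pooled_fc = _safe_ratio(group_mean(spf), group_mean(gf))

    out["stage1_li_enriched"] = stage1
    out["stage2_spf_supported"] = stage1 & stage2
    for region in SI_REGIONS:
        out[f"subregion_{region}"] = subregion_flags[region]
    out["exclusive_spf"] = exclusive
    out["pooled_spf_gf_fc"] = pooled_fc

    labels = pd.Series("unclassified", index=mets)
    labels[(pooled_fc <= 1.0 / fold_threshold).fillna(False)] = "host_diet"
    labels[subregion_any] = "candidate"
    labels[stage1] = "candidate"
    labels[stage1 & stage2] = "supported_microbial"
    out["label"] = labels
    return out


def diet_share(
    intensities: pd.Series,
    query: Sequence[str] | None = None,
    coverage: float = 0.5,
    dominance_threshold: float = 0.0005,
) -> tuple[pd.DataFrame, int, pd.DataFrame]:
    """Rank diet ion intensities and screen compounds' diet share.

    Returns (ranked table with fraction and cumulative fraction, size of
    the minimal prefix reaching ``coverage`` of the total signal, and —
    when ``query`` is given — each queried compound's fraction with a
    flag at the ``dominance_threshold`` (default 0.05%)).
    """
    s = pd.Series(intensities, dtype=float)
    if s.empty:
        raise ValueError("empty intensity table")
    if (s < 0).any():
        raise ValueError("intensities must be >= 0")
    total = s.sum()
    if total <= 0:
        raise ValueError("intensities must not be all zero")
    ranked = s.sort_values(ascending=False).to_frame("intensity")
    ranked["fraction"] = ranked["intensity"] / total
    ranked["cumulative"] = ranked["fraction"].cumsum()
    n_cover = int(np.searchsorted(ranked["cumulative"].to_numpy(), coverage) + 1)
    if query is None:
        query_table = pd.DataFrame(columns=["fraction", "above_threshold"])
    else:
        fractions = pd.Series(
            {q: float(s.get(q, 0.0)) / total for q in query}, name="fraction"
        )
        query_table = fractions.to_frame()
        query_table["above_threshold"] = query_table["fraction"] > dominance_threshold
    return ranked, n_cover, query_table
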