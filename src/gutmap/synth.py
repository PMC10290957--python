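"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here: dilution-series
standard measurements with a saturating, noise-floored log-log ion
response; spatially structured concentration landscapes for colonized
(SPF) and germ-free (GF) mice over 15 gut sites, two habitats and five
mice; ASV community tables with taxonomic lineages, planted producer
taxa and per-taxon enzyme annotations; and the host/microbiome network
maps used for origin classification.

The default panel mirrors the scale of a targeted gut metabolomics
study: 138 targeted metabolites of which 128 pass calibration QC, with
planted large-intestine enrichment (31 metabolites, 24 of them
microbially supported, 3 SPF-exclusive), subregion-specific effects,
habitat effects, and a 7/13/81/27 host/microbe/both/unmatched origin
partition.  All effect sizes, sample counts and noise levels are
configurable; planted effects are exactly recoverable at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import NetworkMaps
from .calibration import make_dilution_series
from .design import (
    CONCENTRATION_REGIONS,
    MICROBIOME_REGIONS,
    SI_REGIONS,
    MetaboliteSpec,
    ResponseModel,
    StudyDesign,
    nmol_per_mg_to_molar,
)
from .microbiome import RANKS, AsvTable
from .quantify import ConcentrationMatrix

__all__ = [
    "make_dilution_series",
    "simulate_ion_counts",
    "generate_landscape",
    "simulate_sample_counts",
    "simulate_standards",
    "Panel",
    "default_panel",
    "AsvStudy",
    "generate_asv_study",
]


def simulate_ion_counts(
    concentrations, model: ResponseModel, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Ion counts for a concentration series under the response model.

    Mid-range points follow the log-log line with multiplicative noise;
    the count saturates at the ceiling, and where the line falls below
    the noise floor the detector reports floor-level noise instead.
    Zero-concentration (blank) measurements read clearly below the
    noise shoulder of a real low-signal sample: they are reported at a
    third of the floor (times noise), or 0 when there is no floor.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    eps = rng.normal(0.0, model.noise_sd, size=c.shape) if model.noise_sd > 0 else 0.0
    with np.errstate(divide="ignore"):
        log_line = model.intercept + model.slope * np.log10(
            np.where(c > 0, c, np.nan)
        )
    line = np.where(c > 0, 10.0 ** log_line, 0.0)
    counts = np.where(c > 0, 10.0 ** (np.where(c > 0, log_line, 0.0) + eps), 0.0)
    if model.floor > 0:
        floor_eps = (
            rng.normal(0.0, model.noise_sd, size=c.shape)
            if model.noise_sd > 0
            else 0.0
        )
        floor_noise = model.floor * 10.0 ** floor_eps
        counts = np.where(line < model.floor, floor_noise, counts)
        counts = np.where(c == 0, floor_noise / 3.0, counts)
    return np.minimum(counts, model.ceiling)


def simulate_standards(
    models: dict[str, dict[str, ResponseModel]],
    top_concentration: float = 150e-6,
    n_points: int = 24,
    dilution_factor: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dilution-series measurements for every (metabolite, modification).

    Returns a long table (metabolite, modification, concentration_molar,
    ion_count) sorted by descending concentration within each series.
    """
    rng = np.random.default_rng(seed)
    series = make_dilution_series(top_concentration, n_points, dilution_factor)
    rows = []
    for met in sorted(models):
        for mod in sorted(models[met]):
            counts = simulate_ion_counts(series, models[met][mod], rng)
            for c, y in zip(series, counts):
                rows.append((met, mod, c, y))
    return pd.DataFrame(
        rows, columns=["metabolite", "modification", "concentration_molar", "ion_count"]
    )


def generate_landscape(
    design: StudyDesign,
    specs: list[MetaboliteSpec],
    seed: int = 0,
) -> dict[str, ConcentrationMatrix]:
    """True concentration matrices (nmol/mg) per colonization group.

    One column per (mouse, site, habitat); values are drawn log-normally
    around the region x habitat x colonization mean with each spec's
    noise CV, using a mean-one multiplicative factor so that zero CV
    reproduces the means exactly and the expectation is unbiased at any
    CV.  Exclusive metabolites are exactly 0 in germ-free mice.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, ConcentrationMatrix] = {}
    names = [s.name for s in specs]
    for colonization in design.colonizations:
        samples = design.sample_index(colonization)
        values = np.empty((len(specs), len(samples)))
        regions = samples["region"].to_numpy()
        habitats = samples["habitat"].to_numpy()
        for i, spec in enumerate(specs):
            means = np.array(
                [
                    spec.true_mean(r, h, colonization)
                    for r, h in zip(regions, habitats)
                ]
            )
            if spec.noise_cv > 0:
                sigma = np.sqrt(np.log1p(spec.noise_cv**2))
                factor = rng.lognormal(-sigma**2 / 2.0, sigma, size=means.shape)
            else:
                factor = 1.0
            values[i] = means * factor
        out[colonization] = ConcentrationMatrix(
            pd.DataFrame(values, index=pd.Index(names, name="metabolite"),
                         columns=samples.index),
            samples,
        )
    return out


def simulate_sample_counts(
    matrix: ConcentrationMatrix,
    models: dict[str, ResponseModel],
    seed: int = 0,
) -> pd.DataFrame:
    """Ion counts for a true concentration matrix (nmol/mg -> counts)."""
    rng = np.random.default_rng(seed)
    counts = np.empty(matrix.values.shape)
    for i, met in enumerate(matrix.metabolites):
        c_molar = nmol_per_mg_to_molar(matrix.values.loc[met].to_numpy())
        counts[i] = simulate_ion_counts(c_molar, models[met], rng)
    return pd.DataFrame(counts, index=matrix.values.index, columns=matrix.values.columns)


# ---------------------------------------------------------------------------
# Default panel with planted structure
# ---------------------------------------------------------------------------

CLASS_LABELS = (
    "amino acids",
    "organic acids",
    "vitamins",
    "nucleotides",
    "carbon sources",
    "bile acids",
)

_PRIMARY_MOD = "protonated_cation"
_SECONDARY_MOD = "sodium_adduct_cation"


@dataclass
class Panel:
    """A metabolite panel with ground truth and ion-response models."""

    specs: list[MetaboliteSpec]
    response_models: dict[str, dict[str, ResponseModel]]
    qc_fail: list[str] = field(default_factory=list)
    origin_class: dict[str, str] = field(default_factory=dict)
    li_enriched: list[str] = field(default_factory=list)
    supported: list[str] = field(default_factory=list)
    exclusive: list[str] = field(default_factory=list)
    subregion_specific: dict[str, str] = field(default_factory=dict)
    lumen_enriched: list[str] = field(default_factory=list)
    mucus_enriched: list[str] = field(default_factory=list)
    gf_enriched: list[str] = field(default_factory=list)
    producer_metabolites: list[str] = field(default_factory=list)

    @property
    def quantifiable(self) -> list[MetaboliteSpec]:
        fail = set(self.qc_fail)
        return [s for s in self.specs if s.name not in fail]


def _region_profile_li(scale: float) -> dict[str, float]:
    # graded over SI, strongly large-intestine enriched (LI/SI mean > 4)
    return {
        "stomach": 0.2 * scale,
        "duodenum": 1.0 * scale,
        "jejunum": 1.5 * scale,
        "ileum": 2.0 * scale,
        "caecum": 10.0 * scale,
        "colon": 9.0 * scale,
    }


_ARCHETYPES = {
    "stomach_high": {"stomach": 8.0, "duodenum": 1.0, "jejunum": 1.0,
                     "ileum": 1.0, "caecum": 1.0, "colon": 1.0},
    "si_high": {"stomach": 1.0, "duodenum": 5.0, "jejunum": 5.0,
                "ileum": 5.0, "caecum": 1.0, "colon": 1.0},
    "li_mild": {"stomach": 1.0, "duodenum": 1.0, "jejunum": 1.0,
                "ileum": 1.0, "caecum": 3.0, "colon": 3.0},
}


def default_panel(
    n_total: int = 138,
    n_qc_fail: int = 10,
    n_li_enriched: int = 31,
    n_supported: int = 24,
    n_exclusive: int = 3,
    n_subregion: int = 10,
    n_lumen_enriched: int = 8,
    n_mucus_enriched: int = 3,
    n_gf_enriched: int = 8,
    origin_counts: tuple[int, int, int, int] = (7, 13, 81, 27),
    li_fold: float = 8.0,
    habitat_fold: float = 8.0,
    subregion_fold: float = 8.0,
    noise_cv: float = 0.2,
    measurement_noise_sd: float = 0.05,
    n_producers: int = 12,
    seed: int = 0,
) -> Panel:
    """Construct the default planted-structure metabolite panel.

    ``origin_counts`` is the (host, microbe, both, unmatched) partition
    of the quantifiable metabolites.  Effects are planted
    deterministically by index; concentration scales are drawn
    log-uniformly so the panel spans several orders of magnitude while
    staying inside the calibration linear range.
    """
    n_pass = n_total - n_qc_fail
    n_host, n_microbe, n_both, n_unmatched = origin_counts
    if n_host + n_microbe + n_both + n_unmatched != n_pass:
        raise ValueError("origin_counts must sum to the QC-passing count")
    if not (n_exclusive <= n_supported <= n_li_enriched <= n_pass):
        raise ValueError("need n_exclusive <= n_supported <= n_li_enriched <= panel")

    rng = np.random.default_rng(seed)
    names = [f"met_{i:03d}" for i in range(n_total)]
    # log-uniform base scales chosen so every stratum mean — including
    # mucus / germ-free attenuation — stays inside the default
    # calibration linear range (about 5e-5 to 6 nmol/mg) with headroom
    # for a few noise-driven trim steps at either end of the curve
    scales = 10.0 ** rng.uniform(-2.5, -1.4, size=n_total)

    # origin classes by index over the QC-passing metabolites
    origin_class: dict[str, str] = {}
    bounds = np.cumsum([n_microbe, n_both, n_host, n_unmatched])
    for i in range(n_pass):
        if i < bounds[0]:
            cls = "microbe"
        elif i < bounds[1]:
            cls = "both"
        elif i < bounds[2]:
            cls = "host"
        else:
            cls = "unmatched"
        origin_class[names[i]] = cls

    def ec_for(i: int) -> frozenset[str]:
        cls = origin_class[names[i]]
        prefix = {"microbe": "2.7.1", "both": "3.5.1",
                  "host": "1.1.1", "unmatched": "6.3.2"}[cls]
        return frozenset({f"{prefix}.{i + 1}"})

    specs: list[MetaboliteSpec] = []
    panel = Panel(specs=specs, response_models={})
    arch_names = list(_ARCHETYPES)
    for i in range(n_total):
        name = names[i]
        s = scales[i]
        region_means: dict[str, float]
        lm_ratio = 1.0
        spf_gf: dict[str, float] | float = 1.0
        exclusive = False

        if i < n_li_enriched:
            region_means = _region_profile_li(s)
            panel.li_enriched.append(name)
            if i < n_supported:
                spf_gf = {r: li_fold for r in ("caecum", "colon")}
                panel.supported.append(name)
                if i < n_exclusive:
                    exclusive = True
                    panel.exclusive.append(name)
        elif i < n_li_enriched + n_subregion:
            region_means = {r: s for r in CONCENTRATION_REGIONS}
            target = SI_REGIONS[(i - n_li_enriched) % 3]
            spf_gf = {target: subregion_fold}
            panel.subregion_specific[name] = target
        elif i < n_li_enriched + n_subregion + n_lumen_enriched:
            region_means = {r: s for r in CONCENTRATION_REGIONS}
            lm_ratio = habitat_fold
            panel.lumen_enriched.append(name)
        elif i < n_li_enriched + n_subregion + n_lumen_enriched + n_mucus_enriched:
            region_means = {r: s for r in CONCENTRATION_REGIONS}
            lm_ratio = 1.0 / habitat_fold
            panel.mucus_enriched.append(name)
        elif i < (n_li_enriched + n_subregion + n_lumen_enriched
                  + n_mucus_enriched + n_gf_enriched):
            region_means = {r: s for r in CONCENTRATION_REGIONS}
            spf_gf = 1.0 / li_fold
            panel.gf_enriched.append(name)
        else:
            arch = _ARCHETYPES[arch_names[i % 3]]
            region_means = {r: v * s for r, v in arch.items()}

        specs.append(
            MetaboliteSpec(
                name=name,
                class_label=CLASS_LABELS[i % len(CLASS_LABELS)],
                region_means=region_means,
                lumen_mucus_ratio=lm_ratio,
                spf_gf_ratio=spf_gf,
                exclusive=exclusive,
                noise_cv=noise_cv,
                ec_set=ec_for(i) if i < n_pass else frozenset(),
            )
        )

    # ion response: a good primary modification, a noisier secondary one;
    # QC failures get a near-flat, noisy response for both
    for i, name in enumerate(names):
        if i < n_pass:
            panel.response_models[name] = {
                # floors are placed so the line crosses them midway
                # between two dilution steps of the default series: the
                # boundary step then sits clearly off the line (trimmed)
                # and true zeros invert clearly below the LLOQ
                _PRIMARY_MOD: ResponseModel(
                    slope=1.0, intercept=10.0, ceiling=5e6, floor=8.1,
                    noise_sd=measurement_noise_sd,
                ),
                _SECONDARY_MOD: ResponseModel(
                    slope=0.9, intercept=9.0, ceiling=1e6, floor=42.7,
                    noise_sd=1.5 * measurement_noise_sd,
                ),
            }
        else:
            panel.qc_fail.append(name)
            bad = ResponseModel(slope=0.02, intercept=3.0, ceiling=1e6,
                                floor=10.0, noise_sd=0.4)
            panel.response_models[name] = {_PRIMARY_MOD: bad, _SECONDARY_MOD: bad}

    panel.origin_class = origin_class
    # planted producers come from the microbially supported metabolites,
    # which sit inside the microbe/both origin classes
    lo = n_exclusive  # skip exclusives: their GF-zero profile is categorical
    panel.producer_metabolites = names[lo: lo + n_producers]
    return panel


# ---------------------------------------------------------------------------
# ASV study
# ---------------------------------------------------------------------------

ORDER_POOL = (
    "Lachnospirales", "Oscillospirales", "Lactobacillales", "Bacteroidales",
    "Erysipelotrichales", "Clostridiales", "Verrucomicrobiales",
    "Bifidobacteriales", "Burkholderiales", "Desulfovibrionales",
    "Peptostreptococcales", "Monoglobales", "Enterobacterales",
    "Rhodospirillales",
)

_ORDER_TAXONOMY = {
    "Lachnospirales": ("Firmicutes", "Clostridia"),
    "Oscillospirales": ("Firmicutes", "Clostridia"),
    "Clostridiales": ("Firmicutes", "Clostridia"),
    "Peptostreptococcales": ("Firmicutes", "Clostridia"),
    "Monoglobales": ("Firmicutes", "Clostridia"),
    "Lactobacillales": ("Firmicutes", "Bacilli"),
    "Erysipelotrichales": ("Firmicutes", "Bacilli"),
    "Bacteroidales": ("Bacteroidota", "Bacteroidia"),
    "Verrucomicrobiales": ("Verrucomicrobiota", "Verrucomicrobiae"),
    "Bifidobacteriales": ("Actinobacteriota", "Actinobacteria"),
    "Burkholderiales": ("Proteobacteria", "Gammaproteobacteria"),
    "Enterobacterales": ("Proteobacteria", "Gammaproteobacteria"),
    "Desulfovibrionales": ("Desulfobacterota", "Desulfovibrionia"),
    "Rhodospirillales": ("Proteobacteria", "Alphaproteobacteria"),
}


@dataclass
class AsvStudy:
    """Generated community study: counts, networks, planted truth."""

    table: AsvTable
    maps: NetworkMaps
    producers: list[tuple[str, str]]  # (taxon, metabolite)
    low_depth_samples: list[str]


def generate_asv_study(
    design: StudyDesign,
    specs: list[MetaboliteSpec],
    n_taxa: int = 120,
    planted_producers: list[str] | list[tuple[int, str]] | None = None,
    origin_class: dict[str, str] | None = None,
    n_samples: int = 72,
    n_low_depth: int = 9,
    min_depth: int = 6000,
    max_depth: int = 60000,
    abundance_noise_sd: float = 0.3,
    habitat_effect_sd: float = 0.5,
    mouse_effect_sd: float = 0.5,
    ec_carriers_per_metabolite: int = 3,
    host_filler_ecs: int = 40,
    taxon_filler_ec_pool: int = 200,
    seed: int = 0,
) -> AsvStudy:
    """Generate an ASV study with planted producer taxa and networks.

    Samples cover the full (mouse, region, habitat) factorial of the
    five community regions, padded with replicate columns up to
    ``n_samples``; ``n_low_depth`` samples are planted below 1,000
    reads, and the minimum depth among the remainder is exactly
    ``min_depth``.  Each taxon additionally carries a log-normal
    lumen:mucus preference (``habitat_effect_sd``) and per-mouse
    carriage differences (``mouse_effect_sd``), as real communities do.
    Planted producer taxa have regional abundance proportional to the
    paired metabolite's region means (hence spatially monotone with it)
    and carry an enzyme from the metabolite's EC set.  The emitted host network, taxon EC sets and
    metabolite EC map reproduce the requested origin partition exactly
    when classified downstream.
    """
    rng = np.random.default_rng(seed)
    spec_by_name = {s.name: s for s in specs}

    # --- samples -----------------------------------------------------------
    strata = [
        (m, r, h)
        for m in range(1, design.n_mice + 1)
        for r in MICROBIOME_REGIONS
        for h in design.habitats
    ]
    if n_samples < len(strata):
        raise ValueError(f"n_samples must be >= the factorial size {len(strata)}")
    rows = []
    for m, r, h in strata:
        rows.append((f"16S_{h}_m{m}_{r}", m, r, h))
    for k in range(n_samples - len(strata)):
        m, r, h = strata[k % len(strata)]
        rows.append((f"16S_{h}_m{m}_{r}_rep{k // len(strata) + 2}", m, r, h))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "mouse", "region", "habitat"]
    ).set_index("sample_id")

    # --- taxa and lineages -------------------------------------------------
    taxa = [f"ASV_{i + 1:04d}" for i in range(n_taxa)]
    orders = [ORDER_POOL[i % len(ORDER_POOL)] for i in range(n_taxa)]
    lineage = pd.DataFrame(index=pd.Index(taxa, name="taxon"), columns=list(RANKS))
    for i, t in enumerate(taxa):
        phylum, klass = _ORDER_TAXONOMY[orders[i]]
        lineage.loc[t] = [
            "Bacteria", phylum, klass, orders[i],
            f"{orders[i][:-2]}ceae", f"Genus_{i + 1:03d}", "",
        ]

    # --- planted producers -------------------------------------------------
    if planted_producers is None:
        planted_producers = []
    pairs: list[tuple[str, str]] = []
    for k, entry in enumerate(planted_producers):
        if isinstance(entry, tuple):
            idx, met = entry
        else:
            idx, met = k, entry
        if not 0 <= idx < n_taxa:
            raise ValueError(f"producer taxon index {idx} out of range")
        if met not in spec_by_name:
            raise ValueError(f"producer metabolite {met!r} not in specs")
        pairs.append((taxa[idx], met))
    producer_taxa = {t: m for t, m in pairs}

    # --- abundance weights -------------------------------------------------
    region_idx = {r: i for i, r in enumerate(MICROBIOME_REGIONS)}
    weights = rng.lognormal(0.0, 1.0, size=(n_taxa, len(MICROBIOME_REGIONS)))
    for t, met in producer_taxa.items():
        means = np.array(
            [spec_by_name[met].region_means.get(r, 0.0) for r in MICROBIOME_REGIONS]
        )
        if means.sum() <= 0:
            raise ValueError(f"producer metabolite {met!r} has no regional signal")
        profile = means / means.mean()
        size = rng.lognormal(0.0, 0.5)
        weights[taxa.index(t)] = profile * size

    # --- sequencing depths -------------------------------------------------
    depths = rng.integers(min_depth, max_depth + 1, size=n_samples)
    special = rng.choice(n_samples, size=n_low_depth + 1, replace=False)
    depths[special[0]] = min_depth  # the post-filter minimum is exact
    if n_low_depth > 0:
        depths[special[1:]] = rng.integers(200, 1000, size=n_low_depth)
    low_ids = [samples.index[i] for i in special[1:]]

    # --- counts ------------------------------------------------------------
    habitat_factor = (
        rng.lognormal(0.0, habitat_effect_sd, size=n_taxa)
        if habitat_effect_sd > 0 else np.ones(n_taxa)
    )
    mouse_factor = (
        rng.lognormal(0.0, mouse_effect_sd, size=(n_taxa, design.n_mice))
        if mouse_effect_sd > 0 else np.ones((n_taxa, design.n_mice))
    )
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j, (sid, meta) in enumerate(samples.iterrows()):
        w = weights[:, region_idx[meta["region"]]].copy()
        w = w * mouse_factor[:, int(meta["mouse"]) - 1]
        if meta["habitat"] == "mucus":
            w = w * habitat_factor
        if abundance_noise_sd > 0:
            w = w * rng.lognormal(0.0, abundance_noise_sd, size=n_taxa)
        counts[:, j] = rng.multinomial(depths[j], w / w.sum())
    table = AsvTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"),
                     columns=samples.index),
        lineage,
        samples,
    )

    # --- networks ----------------------------------------------------------
    if origin_class is None:
        origin_class = {}
    host_ecs: set[str] = {f"1.2.3.{k + 1}" for k in range(host_filler_ecs)}
    taxon_ecs: dict[str, set[str]] = {t: set() for t in taxa}
    filler_pool = [f"2.3.4.{k + 1}" for k in range(taxon_filler_ec_pool)]
    for t in taxa:
        picks = rng.choice(len(filler_pool), size=8, replace=False)
        taxon_ecs[t].update(filler_pool[p] for p in picks)

    metabolite_ecs: dict[str, frozenset[str]] = {}
    for s in specs:
        if not s.ec_set:
            continue
        metabolite_ecs[s.name] = s.ec_set
        cls = origin_class.get(s.name, "unmatched")
        if cls in ("host", "both"):
            host_ecs |= set(s.ec_set)
        if cls in ("microbe", "both"):
            carriers = set(
                rng.choice(n_taxa, size=min(ec_carriers_per_metabolite, n_taxa),
                           replace=False)
            )
            for idx in carriers:
                taxon_ecs[taxa[idx]] |= set(s.ec_set)
    for t, met in producer_taxa.items():
        taxon_ecs[t] |= set(spec_by_name[met].ec_set)

    maps = NetworkMaps(
        host_ecs=frozenset(host_ecs),
        taxon_ecs={t: frozenset(e) for t, e in taxon_ecs.items()},
        metabolite_ecs=metabolite_ecs,
    )
    return AsvStudy(table=table, maps=maps, producers=pairs,
                    low_depth_samples=low_ids)
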