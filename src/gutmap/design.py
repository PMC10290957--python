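"""Study design: sites, regions, habitats and the synthetic ground-truth types.

The sampling scheme covers 15 discrete sites along the mouse gut: the
stomach (site 1), ten small-intestinal sites (2-11, partitioned into
duodenum / jejunum / ileum), the caecum (12) and three colonic sites
(13-15).  Two habitats (luminal content and mucus) are sampled at every
site in each mouse, for both colonized (SPF) and germ-free (GF) animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

HABITATS = ("lumen", "mucus")
COLONIZATIONS = ("SPF", "GF")

#: the five community-profiling regions (stomach is not sampled for 16S)
MICROBIOME_REGIONS = ("duodenum", "jejunum", "ileum", "caecum", "colon")

#: the six concentration regions used for ground-truth means
CONCENTRATION_REGIONS = ("stomach",) + MICROBIOME_REGIONS

SI_REGIONS = ("duodenum", "jejunum", "ileum")
LI_REGIONS = ("caecum", "colon")


@dataclass(frozen=True)
class Site:
    index: int          # 1-based, ordered stomach -> distal colon
    region: str         # one of CONCENTRATION_REGIONS
    compartment: str    # stomach | small_intestine | large_intestine


def build_sites(si_partition: Sequence[int] = (3, 4, 3)) -> tuple[Site, ...]:
    """Lay out the 15 sites.

    ``si_partition`` splits the ten small-intestinal sites into
    duodenum/jejunum/ileum; the default 3/4/3 split is configurable.
    """
    if len(si_partition) != 3 or sum(si_partition) != 10:
        raise ValueError("si_partition must be three counts summing to 10")
    sites = [Site(1, "stomach", "stomach")]
    idx = 2
    for region, n in zip(SI_REGIONS, si_partition):
        for _ in range(n):
            sites.append(Site(idx, region, "small_intestine"))
            idx += 1
    sites.append(Site(12, "caecum", "large_intestine"))
    for i in (13, 14, 15):
        sites.append(Site(i, "colon", "large_intestine"))
    return tuple(sites)


@dataclass(frozen=True)
class StudyDesign:
    """Full-factorial sampling design: sites x habitats x mice per group."""

    n_mice: int = 5
    si_partition: tuple[int, int, int] = (3, 4, 3)
    habitats: tuple[str, ...] = HABITATS
    colonizations: tuple[str, ...] = COLONIZATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        build_sites(self.si_partition)  # validates

    @property
    def sites(self) -> tuple[Site, ...]:
        return build_sites(self.si_partition)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples_per_colonization(self) -> int:
        return self.n_sites * len(self.habitats) * self.n_mice

    def sample_index(self, colonization: str):
        """Long-format sample metadata for one colonization group.

        Returns a :class:`pandas.DataFrame` indexed by sample id with
        columns mouse, site_index, region, compartment, habitat,
        colonization.
        """
        import pandas as pd

        rows = []
        for mouse in range(1, self.n_mice + 1):
            for site in self.sites:
                for habitat in self.habitats:
                    sid = f"{colonization}_{habitat}_m{mouse}_s{site.index:02d}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "mouse": mouse,
                            "site_index": site.index,
                            "region": site.region,
                            "compartment": site.compartment,
                            "habitat": habitat,
                            "colonization": colonization,
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class MetaboliteSpec:
    """Ground truth for one synthetic metabolite.

    ``region_means`` are SPF luminal concentrations in nmol/mg per
    concentration region; the mucus mean is the luminal mean divided by
    ``lumen_mucus_ratio`` and the GF mean is the SPF mean divided by the
    per-region ``spf_gf_ratio``.  ``exclusive`` marks compounds present
    only in colonized animals (GF concentration exactly 0).
    """

    name: str
    class_label: str = "unclassified"
    region_means: Mapping[str, float] = field(default_factory=dict)
    lumen_mucus_ratio: float = 1.0
    spf_gf_ratio: Mapping[str, float] | float = 1.0
    exclusive: bool = False
    noise_cv: float = 0.2
    ec_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for region, mean in self.region_means.items():
            if region not in CONCENTRATION_REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if mean < 0:
                raise ValueError("concentrations must be >= 0")
        if self.lumen_mucus_ratio <= 0:
            raise ValueError("lumen_mucus_ratio must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def gf_ratio(self, region: str) -> float:
        if isinstance(self.spf_gf_ratio, Mapping):
            return float(self.spf_gf_ratio.get(region, 1.0))
        return float(self.spf_gf_ratio)

    def true_mean(self, region: str, habitat: str, colonization: str) -> float:
        """Expected concentration (nmol/mg) for one stratum."""
        mean = float(self.region_means.get(region, 0.0))
        if habitat == "mucus":
            mean /= self.lumen_mucus_ratio
        if colonization == "GF":
            if self.exclusive:
                return 0.0
            mean /= self.gf_ratio(region)
        return mean


@dataclass(frozen=True)
class ResponseModel:
    """Log-log-linear ion response with saturation ceiling and noise floor.

    ``slope`` and ``intercept`` relate log10(ion count) to
    log10(concentration in molar).  Counts saturate at ``ceiling``; below
    the floor the detector reports floor-level noise instead of signal.
    ``noise_sd`` is multiplicative noise on the log10 scale.
    """

    slope: float = 1.0
    intercept: float = 10.0
    ceiling: float = np.inf
    floor: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.floor < 0 or not self.ceiling > self.floor:
            raise ValueError("need ceiling > floor >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: nmol/mg per molar of injected solution: a 1:1 mobile-phase dilution
#: before injection (x2) and an extraction of 20 uL water per mg sample;
#: 1 mol/L = 1000 nmol/uL.
INJECTION_DILUTION = 2.0
EXTRACTION_UL_PER_MG = 20.0


def molar_to_nmol_per_mg(
    c_molar: float | np.ndarray,
    injection_dilution: float = INJECTION_DILUTION,
    extraction_ul_per_mg: float = EXTRACTION_UL_PER_MG,
) -> float | np.ndarray:
    return np.asarray(c_molar) * injection_dilution * extraction_ul_per_mg * 1000.0


def nmol_per_mg_to_molar(
    c_nmol_mg: float | np.ndarray,
    injection_dilution: float = INJECTION_DILUTION,
    extraction_ul_per_mg: float = EXTRACTION_UL_PER_MG,
) -> float | np.ndarray:
    return np.asarray(c_nmol_mg) / (injection_dilution * extraction_ul_per_mg * 1000.0)
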