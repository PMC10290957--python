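"""End-to-end workflow: synthetic study -> quantification -> analyses.

Ties the modules together in the order a real study would run them:
simulate standards and sample ion counts, fit calibration curves with
trimming, select the modification per metabolite, quantify with
linear-range censoring, then run the spatial, differential,
origin-calling, community and association analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .association import classify_origin, filter_pairs, spatial_correlate
from .calibration import CalibrationError, CalibrationFit, fit_calibration, select_modification
from .design import StudyDesign
from .differential import call_origin, colonization_fc, paired_contrast
from .microbiome import filter_depth, rarefy, relative_abundance
from .quantify import CENSOR_OK, ConcentrationMatrix, invert_counts, quantify_matrix
from .synth import (
    AsvStudy,
    Panel,
    default_panel,
    generate_asv_study,
    generate_landscape,
    simulate_sample_counts,
    simulate_standards,
)

__all__ = ["QuantificationResult", "StudyResult", "run_quantification", "run_study"]


@dataclass
class QuantificationResult:
    fits: dict[str, dict[str, CalibrationFit]]      # metabolite -> modification -> fit
    chosen: dict[str, str]                          # metabolite -> modification
    matrices: dict[str, ConcentrationMatrix]        # colonization -> quantified matrix
    truth: dict[str, ConcentrationMatrix]           # colonization -> true landscape
    dropped: list[str]                              # failed calibration QC

    @property
    def n_quantified(self) -> int:
        return len(self.matrices["SPF"].metabolites)


def run_quantification(
    panel: Panel,
    design: StudyDesign,
    seed: int = 0,
    r2_min: float = 0.99,
    min_points: int = 5,
) -> QuantificationResult:
    """Simulate standards + samples, calibrate, select and quantify."""
    truth = generate_landscape(design, panel.specs, seed=seed)
    standards = simulate_standards(panel.response_models, seed=seed + 1)

    fits: dict[str, dict[str, CalibrationFit]] = {}
    for (met, mod), grp in standards.groupby(["metabolite", "modification"]):
        grp = grp.sort_values("concentration_molar", ascending=False)
        try:
            fit = fit_calibration(
                grp["concentration_molar"].to_numpy(),
                grp["ion_count"].to_numpy(),
                min_points=min_points,
            )
        except CalibrationError:
            continue
        if fit.slope <= 0:  # not an invertible response
            continue
        fits.setdefault(met, {})[mod] = fit

    # ion counts per modification over all samples, used both for
    # coverage (detected-sample counts) and for the final matrices
    counts_by_mod: dict[str, dict[str, pd.DataFrame]] = {}
    offset = 2
    for mod in sorted({m for mods in panel.response_models.values() for m in mods}):
        models = {met: mods[mod] for met, mods in panel.response_models.items()
                  if mod in mods}
        counts_by_mod[mod] = {
            col: simulate_sample_counts(
                truth[col], models, seed=seed + offset + i
            )
            for i, col in enumerate(design.colonizations)
        }
        offset += len(design.colonizations)

    chosen: dict[str, str] = {}
    for met, mods in fits.items():
        coverage = {}
        for mod, fit in mods.items():
            n_det = 0
            for col in design.colonizations:
                _, code = invert_counts(
                    counts_by_mod[mod][col].loc[met].to_numpy(), fit
                )
                n_det += int((code == CENSOR_OK).sum())
            coverage[mod] = n_det
        chosen[met] = select_modification(mods, coverage)

    selected_fits = {met: fits[met][mod] for met, mod in chosen.items()}
    no_fit = [m for m in panel.response_models if m not in selected_fits]
    matrices: dict[str, ConcentrationMatrix] = {}
    dropped: list[str] = []
    for col in design.colonizations:
        counts = pd.DataFrame(
            {  # columns = samples; build metabolite x sample frame
                met: counts_by_mod[chosen[met]][col].loc[met]
                for met in selected_fits
            }
        ).T
        counts.index.name = "metabolite"
        matrices[col], dropped = quantify_matrix(
            counts, selected_fits, truth[col].samples,
            r2_min=r2_min, min_points=min_points,
        )
    return QuantificationResult(
        fits=fits, chosen=chosen, matrices=matrices, truth=truth,
        dropped=sorted(set(dropped) | set(no_fit)),
    )


@dataclass
class StudyResult:
    quant: QuantificationResult
    habitat_contrast: pd.DataFrame
    origin_calls: pd.DataFrame
    asv: AsvStudy
    retained_samples: int
    origin_labels: pd.Series
    pairs: pd.DataFrame
    funnel: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_study(
    panel: Panel | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
    rarefaction_depth: int | None = None,
) -> StudyResult:
    """Run the full synthetic study end to end with one seed."""
    if panel is None:
        panel = default_panel(seed=seed)
    if design is None:
        design = StudyDesign(seed=seed)

    quant = run_quantification(panel, design, seed=seed)
    spf = quant.matrices["SPF"]
    gf = quant.matrices["GF"]

    habitat_contrast = paired_contrast(
        spf, "habitat", ("lumen", "mucus"), fc_threshold_log2=1.5
    )
    origin_calls = call_origin(spf, gf)

    asv = generate_asv_study(
        design,
        panel.specs,
        planted_producers=panel.producer_metabolites,
        origin_class=panel.origin_class,
        seed=seed + 100,
    )
    filtered, _ = filter_depth(asv.table, min_reads=1000)
    rarefied = rarefy(filtered, depth=rarefaction_depth, seed=seed + 101)
    relabund = relative_abundance(rarefied.counts)

    origin_labels = classify_origin(spf.metabolites, asv.maps)

    _, fc_summary = colonization_fc(spf, gf, granularity="region")
    pairs = spatial_correlate(spf, relabund, rarefied.samples)
    pairs, funnel = filter_pairs(
        pairs,
        fold_changes=fc_summary["mean_fc"],
        maps=asv.maps,
        exclusive=fc_summary["exclusive_spf"],
    )
    return StudyResult(
        quant=quant,
        habitat_contrast=habitat_contrast,
        origin_calls=origin_calls,
        asv=asv,
        retained_samples=filtered.counts.shape[1],
        origin_labels=origin_labels,
        pairs=pairs,
        funnel=funnel,
    )
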