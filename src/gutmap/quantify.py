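"""Ion counts -> absolute concentrations (nmol per mg sample).

Given a fitted calibration curve, a measured ion count is back-calculated
to the injected molar concentration via log10 c = (log10 count -
intercept) / slope.  Values outside the retained linear range are
censored (below LLOQ / above ULOL) rather than extrapolated.  In-range
molar concentrations are scaled to nmol per mg of sample using the
injection dilution (1:1 in mobile phase, factor 2) and the extraction
ratio (20 uL water per mg sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationFit
from .design import INJECTION_DILUTION, EXTRACTION_UL_PER_MG, molar_to_nmol_per_mg

__all__ = [
    "CENSOR_OK",
    "CENSOR_BELOW",
    "CENSOR_ABOVE",
    "CENSOR_MISSING",
    "ConcentrationMatrix",
    "invert_counts",
    "quantify_count",
    "quantify_matrix",
]

CENSOR_OK = 0        # quantified within the linear range
CENSOR_BELOW = -1    # below LLOQ ("not detected")
CENSOR_ABOVE = 1     # above ULOL
CENSOR_MISSING = 2   # no measurement at all


@dataclass
class ConcentrationMatrix:
    """Metabolites x samples in nmol/mg with censoring mask and metadata.

    ``values`` holds NaN wherever ``mask`` is non-zero; ``samples`` is
    indexed by sample id with columns mouse, site_index, region,
    compartment, habitat, colonization.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = pd.DataFrame(
                np.where(self.values.isna(), CENSOR_MISSING, CENSOR_OK),
                index=self.values.index,
                columns=self.values.columns,
                dtype=np.int8,
            )
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("value columns must match sample index")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")

    @property
    def metabolites(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select(self, **criteria) -> "ConcentrationMatrix":
        """Subset samples by metadata equality, e.g. habitat="lumen".

        Values may be scalars or collections (membership test).
        """
        keep = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                keep &= self.samples[col].isin(val)
            else:
                keep &= self.samples[col] == val
        ids = self.samples.index[keep]
        return ConcentrationMatrix(
            self.values[ids], self.samples.loc[ids], self.mask[ids]
        )

    def detected(self) -> pd.DataFrame:
        """Boolean frame: quantified within the linear range."""
        return self.mask == CENSOR_OK


def invert_counts(
    counts: np.ndarray, fit: CalibrationFit
) -> tuple[np.ndarray, np.ndarray]:
    """Back-calculate molar concentrations; censor outside [LLOQ, ULOL].

    Returns ``(conc_molar, censor_code)``; censored and missing entries
    carry NaN concentrations.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be > 0 to invert")
    counts = np.asarray(counts, dtype=float)
    code = np.full(counts.shape, CENSOR_OK, dtype=np.int8)
    conc = np.full(counts.shape, np.nan)

    missing = np.isnan(counts)
    with np.errstate(divide="ignore"):
        log_c = (np.log10(counts, where=~missing & (counts > 0),
                          out=np.full(counts.shape, -np.inf)) - fit.intercept) / fit.slope
    c = 10.0 ** log_c
    below = ~missing & (c < fit.lloq)
    above = ~missing & (c > fit.ulol)
    ok = ~missing & ~below & ~above
    conc[ok] = c[ok]
    code[below] = CENSOR_BELOW
    code[above] = CENSOR_ABOVE
    code[missing] = CENSOR_MISSING
    return conc, code


def quantify_count(
    count: float,
    fit: CalibrationFit,
    injection_dilution: float = INJECTION_DILUTION,
    extraction_ul_per_mg: float = EXTRACTION_UL_PER_MG,
) -> tuple[float, int]:
    """Quantify a single ion count.

    Returns ``(nmol_per_mg, censor_code)``; the concentration is NaN
    when the code is non-zero.
    """
    if count < 0:
        raise ValueError("ion count must be >= 0")
    conc, code = invert_counts(np.asarray([count]), fit)
    value = molar_to_nmol_per_mg(conc[0], injection_dilution, extraction_ul_per_mg)
    return float(value), int(code[0])


def quantify_matrix(
    counts: pd.DataFrame,
    fits: Mapping[str, CalibrationFit],
    samples: pd.DataFrame,
    r2_min: float = 0.99,
    min_points: int = 5,
    injection_dilution: float = INJECTION_DILUTION,
    extraction_ul_per_mg: float = EXTRACTION_UL_PER_MG,
) -> tuple[ConcentrationMatrix, list[str]]:
    """Quantify a metabolite x sample ion-count matrix.

    Metabolites whose selected calibration fails QC (R^2 below
    ``r2_min`` or fewer than ``min_points`` retained) are dropped and
    returned in the second element.  All-censored rows are retained with
    their mask.
    """
    missing_fits = [m for m in counts.index if m not in fits]
    if missing_fits:
        raise KeyError(f"no calibration fit for metabolites: {missing_fits[:5]}")

    dropped: list[str] = []
    kept: list[str] = []
    for met in counts.index:
        f = fits[met]
        if f.r2 < r2_min or f.n_retained < min_points or f.slope <= 0:
            dropped.append(met)
        else:
            kept.append(met)

    values = np.full((len(kept), counts.shape[1]), np.nan)
    mask = np.full((len(kept), counts.shape[1]), CENSOR_MISSING, dtype=np.int8)
    for i, met in enumerate(kept):
        conc, code = invert_counts(counts.loc[met].to_numpy(dtype=float), fits[met])
        values[i] = molar_to_nmol_per_mg(conc, injection_dilution, extraction_ul_per_mg)
        mask[i] = code

    matrix = ConcentrationMatrix(
        pd.DataFrame(values, index=pd.Index(kept, name=counts.index.name),
                     columns=counts.columns),
        samples.loc[counts.columns],
        pd.DataFrame(mask, index=pd.Index(kept, name=counts.index.name),
                     columns=counts.columns),
    )
    if dropped:
        warnings.warn(
            f"{len(dropped)} metabolite(s) failed calibration QC and were dropped",
            stacklevel=2,
        )
    return matrix, dropped
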