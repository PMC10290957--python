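"""Shared fixtures: seeded synthetic studies at two problem sizes."""

import warnings

import pytest

from gutmap.design import StudyDesign
from gutmap.pipeline import run_study
from gutmap.synth import default_panel

STUDY_SEED = 11


def small_panel(seed=0, noise_cv=0.2, measurement_noise_sd=0.05, n_producers=8):
    """A reduced panel for simulation-heavy tests: 30 metabolites, no
    QC failures, 12 large-intestine-enriched (all colonization-supported)."""
    return default_panel(
        n_total=30, n_qc_fail=0, n_li_enriched=12, n_supported=12,
        n_exclusive=0, n_subregion=0, n_lumen_enriched=0,
        n_mucus_enriched=0, n_gf_enriched=0,
        origin_counts=(2, 6, 12, 10), n_producers=n_producers,
        noise_cv=noise_cv, measurement_noise_sd=measurement_noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def panel():
    return default_panel(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def design():
    return StudyDesign(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(panel, design):
    """One full end-to-end study run shared across the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(panel=panel, design=design, seed=STUDY_SEED)
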