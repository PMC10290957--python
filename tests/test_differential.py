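"""Differential analyses: paired contrasts, fold-change cascades, diet share."""

import math

import numpy as np
import pandas as pd
import pytest

from gutmap.design import CONCENTRATION_REGIONS, MetaboliteSpec, StudyDesign
from gutmap.differential import (
    bh_adjust,
    call_origin,
    colonization_fc,
    diet_share,
    paired_contrast,
)
from gutmap.quantify import ConcentrationMatrix
from gutmap.synth import generate_landscape

from conftest import small_panel


def bh_oracle(pvals):
    """Independent step-up implementation from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.1] * 7), 0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_in_unit_interval(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def toy_matrix(values, habitats, mice, mask=None):
    """Tiny ConcentrationMatrix: one site, two habitats, paired mice."""
    n = len(mice)
    samples = pd.DataFrame(
        {
            "mouse": mice,
            "site_index": [1] * n,
            "region": ["caecum"] * n,
            "compartment": ["large_intestine"] * n,
            "habitat": habitats,
            "colonization": ["SPF"] * n,
        },
        index=[f"s{i}" for i in range(n)],
    )
    vals = pd.DataFrame(values, index=pd.Index(["m"], name="metabolite"),
                        columns=samples.index)
    return ConcentrationMatrix(vals, samples, mask)


class TestPairedContrast:
    def test_identical_groups_p_one_fc_zero(self):
        matrix = toy_matrix(
            [[2.0, 2.0, 3.0, 3.0]], ["lumen", "mucus", "lumen", "mucus"], [1, 1, 2, 2]
        )
        res = paired_contrast(matrix, "habitat", ("lumen", "mucus"))
        assert res.loc["m", "p"] == 1.0
        assert res.loc["m", "log2fc"] == 0.0
        assert not res.loc["m", "significant"]

    def test_three_pair_toy_matches_textbook_t(self):
        matrix = toy_matrix(
            [[2.0, 1.0, 4.0, 2.0, 8.0, 3.0]],
            ["lumen", "mucus"] * 3, [1, 1, 2, 2, 3, 3],
        )
        res = paired_contrast(matrix, "habitat", ("lumen", "mucus"))
        diffs = np.array([1.0, 2.0, 5.0])
        t_expected = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(3))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t_expected), df=2)
        assert res.loc["m", "p"] == pytest.approx(p_expected, rel=1e-9)
        assert res.loc["m", "log2fc"] == pytest.approx(
            math.log2((14 / 3) / (6 / 3)), rel=1e-12
        )
        assert res.loc["m", "n_pairs"] == 3

    def test_planted_habitat_enrichment_detected(self, study):
        """Metabolites planted with an 8-fold lumen:mucus ratio come out
        significant with log2 fold change near 3."""
        hc = study.habitat_contrast
        from conftest import STUDY_SEED
        from gutmap.synth import default_panel

        panel = default_panel(seed=STUDY_SEED)
        for met in panel.lumen_enriched:
            assert hc.loc[met, "significant"]
            assert hc.loc[met, "log2fc"] == pytest.approx(3.0, abs=0.7)
        for met in panel.mucus_enriched:
            assert hc.loc[met, "significant"]
            assert hc.loc[met, "log2fc"] == pytest.approx(-3.0, abs=0.7)

    def test_antisymmetry_under_group_swap(self, study):
        spf = study.quant.matrices["SPF"]
        fwd = paired_contrast(spf, "habitat", ("lumen", "mucus"))
        rev = paired_contrast(spf, "habitat", ("mucus", "lumen"))
        both = fwd["log2fc"].notna() & rev["log2fc"].notna()
        np.testing.assert_allclose(
            fwd.loc[both, "log2fc"], -rev.loc[both, "log2fc"], atol=1e-10
        )
        np.testing.assert_allclose(fwd.loc[both, "p"], rev.loc[both, "p"], atol=1e-12)

    def test_insufficient_pairs_untestable_excluded_from_family(self):
        matrix = toy_matrix([[2.0, 1.0]], ["lumen", "mucus"], [1, 1])
        res = paired_contrast(matrix, "habitat", ("lumen", "mucus"))
        assert np.isnan(res.loc["m", "p"])
        assert np.isnan(res.loc["m", "q"])


@pytest.fixture(scope="module")
def matrices():
    panel = small_panel(noise_cv=0.1)
    truth = generate_landscape(StudyDesign(), panel.specs, seed=8)
    return truth["SPF"], truth["GF"], panel


class TestColonizationFc:
    def test_li_sites_give_20_points_per_habitat(self, matrices):
        spf, gf, _ = matrices
        points, _ = colonization_fc(
            spf, gf, regions=("caecum", "colon"), habitat="lumen"
        )
        per_met = points.dropna(subset=["fc"]).groupby("metabolite").size()
        assert (per_met == 20).all()

    def test_si_sites_give_50_points_per_habitat(self, matrices):
        spf, gf, _ = matrices
        points, _ = colonization_fc(
            spf, gf, regions=("duodenum", "jejunum", "ileum"), habitat="lumen"
        )
        per_met = points.dropna(subset=["fc"]).groupby("metabolite").size()
        assert (per_met == 50).all()

    def test_identical_groups_unit_fc(self):
        panel = small_panel(noise_cv=0.0)
        flat = MetaboliteSpec(
            name="m", region_means={r: 1.0 for r in CONCENTRATION_REGIONS},
            noise_cv=0.0,
        )
        truth = generate_landscape(StudyDesign(), [flat], seed=0)
        points, summary = colonization_fc(truth["SPF"], truth["SPF"])
        np.testing.assert_allclose(points["fc"], 1.0)
        assert summary.loc["m", "median_log2fc"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_ratio_recovered_exactly_at_zero_noise(self):
        panel = small_panel(noise_cv=0.0, measurement_noise_sd=0.0)
        truth = generate_landscape(StudyDesign(), panel.specs, seed=0)
        _, summary = colonization_fc(
            truth["SPF"], truth["GF"], regions=("caecum", "colon"),
            habitat="lumen", granularity="region",
        )
        for name in panel.supported:
            assert summary.loc[name, "mean_fc"] == pytest.approx(8.0, rel=1e-12)

    def test_exclusive_flagged_not_numeric(self):
        spec = MetaboliteSpec(name="x", region_means={"caecum": 2.0},
                              exclusive=True, noise_cv=0.0)
        truth = generate_landscape(StudyDesign(), [spec], seed=0)
        _, summary = colonization_fc(truth["SPF"], truth["GF"],
                                     regions=("caecum",))
        assert bool(summary.loc["x", "exclusive_spf"])
        assert np.isnan(summary.loc["x", "mean_fc"])


class TestWelchContrast:
    def test_planted_colonization_effect_detected(self, matrices):
        from gutmap.differential import welch_contrast

        spf, gf, panel = matrices
        res = welch_contrast(
            spf.select(region=("caecum", "colon")),
            gf.select(region=("caecum", "colon")),
        )
        for met in panel.supported:
            assert res.loc[met, "significant"]
            assert res.loc[met, "log2fc"] == pytest.approx(3.0, abs=0.5)

    def test_identical_groups_not_significant(self, matrices):
        from gutmap.differential import welch_contrast

        spf, _, _ = matrices
        res = welch_contrast(spf, spf)
        assert not res["significant"].any()
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)


class TestCallOrigin:
    def test_planted_counts_recovered(self, study, panel):
        oc = study.origin_calls
        assert set(oc.index[oc["stage1_li_enriched"]]) == set(panel.li_enriched)
        assert set(oc.index[oc["stage2_spf_supported"]]) == set(panel.supported)
        assert set(oc.index[oc["exclusive_spf"]]) == set(panel.exclusive)
        assert (oc.loc[panel.supported, "label"] == "supported_microbial").all()

    def test_subregion_specific_calls(self, study, panel):
        oc = study.origin_calls
        for met, region in panel.subregion_specific.items():
            assert oc.loc[met, f"subregion_{region}"], (met, region)
            assert oc.loc[met, "label"] == "candidate"
            others = [r for r in ("duodenum", "jejunum", "ileum") if r != region]
            for r in others:
                assert not oc.loc[met, f"subregion_{r}"]

    def test_gf_enriched_labelled_host_diet(self, study, panel):
        oc = study.origin_calls
        assert (oc.loc[panel.gf_enriched, "label"] == "host_diet").all()

    def test_all_equal_data_no_calls(self):
        flat = MetaboliteSpec(
            name="m", region_means={r: 1.0 for r in CONCENTRATION_REGIONS},
            noise_cv=0.0,
        )
        truth = generate_landscape(StudyDesign(), [flat], seed=0)
        oc = call_origin(truth["SPF"], truth["GF"])
        assert not oc["stage1_li_enriched"].any()
        assert not oc["stage2_spf_supported"].any()
        assert (oc["label"] == "unclassified").all()


class TestDietShare:
    def test_simple_shares(self):
        ranked, n_cover, _ = diet_share(pd.Series({"a": 50.0, "b": 30.0, "c": 20.0}))
        assert n_cover == 1
        np.testing.assert_allclose(ranked["fraction"], [0.5, 0.3, 0.2])
        np.testing.assert_allclose(ranked["cumulative"], [0.5, 0.8, 1.0])

    def test_uniform_thousand_ions_prefix_500(self):
        s = pd.Series(1.0, index=[f"ion{i}" for i in range(1000)])
        _, n_cover, _ = diet_share(s)
        assert n_cover == 500

    def test_dominant_compound_fraction(self):
        rng = np.random.default_rng(0)
        rest = pd.Series(rng.uniform(0.5, 1.5, 99), index=[f"i{k}" for k in range(99)])
        total_rest = rest.sum()
        # one compound at exactly 14% of the total signal
        dom = 0.14 / 0.86 * total_rest
        s = pd.concat([pd.Series({"disaccharide": dom}), rest])
        ranked, _, query = diet_share(s, query=["disaccharide", "i0", "absent"])
        assert ranked["fraction"].iloc[0] == pytest.approx(0.14)
        assert query.loc["disaccharide", "fraction"] == pytest.approx(0.14)
        assert query.loc["disaccharide", "above_threshold"]
        assert query.loc["absent", "fraction"] == 0.0
        assert not query.loc["absent", "above_threshold"]

    def test_empty_or_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            diet_share(pd.Series(dtype=float))
        with pytest.raises(ValueError):
            diet_share(pd.Series({"a": 0.0}))
        with pytest.raises(ValueError):
            diet_share(pd.Series({"a": -1.0, "b": 2.0}))
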