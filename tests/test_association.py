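"""Origin classification and the metabolite-microbe filter funnel."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutmap.association import (
    NetworkMaps,
    classify_origin,
    filter_pairs,
    spatial_correlate,
    spearman,
    summarize_pairs,
)
from gutmap.design import StudyDesign
from gutmap.microbiome import filter_depth, rarefy, relative_abundance
from gutmap.synth import generate_asv_study, generate_landscape

from conftest import small_panel


class TestClassifyOrigin:
    def test_planted_partition_recovered(self, study):
        counts = study.origin_labels.value_counts()
        assert counts["host"] == 7
        assert counts["microbe"] == 13
        assert counts["both"] == 81
        assert counts["unmatched"] == 27
        assert counts.sum() == 128

    def test_labels_partition_any_input(self, study):
        labels = study.origin_labels
        assert set(labels.unique()) <= {"host", "microbe", "both", "unmatched"}
        assert len(labels) == len(study.quant.matrices["SPF"].metabolites)

    def test_empty_microbiome_union_never_microbe(self):
        maps = NetworkMaps(
            host_ecs=frozenset({"1.1.1.1"}),
            taxon_ecs={},
            metabolite_ecs={"a": frozenset({"1.1.1.1"}), "b": frozenset({"2.2.2.2"})},
        )
        labels = classify_origin(["a", "b"], maps)
        assert labels["a"] == "host"
        assert labels["b"] == "unmatched"

    def test_shared_ec_labelled_both(self):
        maps = NetworkMaps(
            host_ecs=frozenset({"3.5.1.2"}),
            taxon_ecs={"t": frozenset({"3.5.1.2"})},
            metabolite_ecs={"m": frozenset({"3.5.1.2"})},
        )
        assert classify_origin(["m"], maps)["m"] == "both"

    def test_metabolite_without_entry_unmatched(self):
        maps = NetworkMaps(host_ecs=frozenset({"1.1.1.1"}))
        assert classify_origin(["m"], maps)["m"] == "unmatched"

    def test_malformed_ec_rejected(self):
        with pytest.raises(ValueError):
            NetworkMaps(host_ecs=frozenset({"not-an-ec"}))


class TestSpearman:
    def test_perfectly_opposed_vectors(self):
        rho, p = spearman([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_self_correlation(self):
        x = np.array([0.3, 1.2, 0.7, 2.2, 5.0, 0.1, 3.3, 2.0, 0.9])
        rho, _ = spearman(x, x)
        assert rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        x = np.array([0.5, 1.5, 2.5, 4.0, 9.0, 20.0, 21.0, 30.0, 44.0, 50.0])
        rho, _ = spearman(x, np.log(x) + 3)
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_pearson_on_average_ranks(self, seed):
        """Oracle: Spearman's rho is Pearson correlation of the average
        ranks, with or without ties."""
        rng = np.random.default_rng(seed)
        n = 30
        x = rng.integers(0, 10, n).astype(float)  # ties likely
        y = rng.normal(size=n)
        rho, _ = spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        """For n=5 the two-sided P of a perfect ranking is the share of
        permutations with |rho| = 1: exactly 2/120."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_degenerate_inputs_give_nan(self):
        rho, p = spearman([1.0, 2.0], [1.0, 2.0])
        assert np.isnan(rho)
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho)


@pytest.fixture(scope="module")
def assoc_fixture():
    """Reduced study: truth matrices + rarefied community + networks."""
    panel = small_panel(noise_cv=0.2, n_producers=8)
    design = StudyDesign()
    truth = generate_landscape(design, panel.specs, seed=21)
    asv = generate_asv_study(
        design, panel.specs, n_taxa=40,
        planted_producers=panel.producer_metabolites,
        origin_class=panel.origin_class, seed=22,
    )
    kept, _ = filter_depth(asv.table)
    rarefied = rarefy(kept, seed=23)
    relabund = relative_abundance(rarefied.counts)
    return panel, truth, asv, rarefied, relabund


class TestSpatialCorrelate:
    def test_pair_count_and_observation_counts(self, assoc_fixture):
        panel, truth, asv, rarefied, relabund = assoc_fixture
        pairs = spatial_correlate(truth["SPF"], relabund, rarefied.samples)
        assert len(pairs) == 30 * 40
        # 5 regions x 2 habitats x 5 mice strata, minus the few lost
        # entirely to the sequencing-depth filter
        assert 40 <= pairs["n_obs"].max() <= 50

    def test_planted_producer_strongly_positive(self, assoc_fixture):
        panel, truth, asv, rarefied, relabund = assoc_fixture
        pairs = spatial_correlate(truth["SPF"], relabund, rarefied.samples)
        keyed = pairs.set_index(["taxon", "metabolite"])
        for taxon, met in asv.producers:
            assert keyed.loc[(taxon, met), "rho"] > 0.5
            assert keyed.loc[(taxon, met), "p"] < 1e-4

    def test_metabolite_against_its_own_profile(self):
        """A 'taxon' whose abundance IS the metabolite's regional profile
        correlates at rho = 1 (monotone invariance of rank correlation)."""
        from gutmap.design import MICROBIOME_REGIONS

        zero_noise_panel = small_panel(noise_cv=0.0)
        truth0 = generate_landscape(StudyDesign(), zero_noise_panel.specs, seed=31)
        spec = zero_noise_panel.specs[0]
        rows = []
        for mouse in range(1, 6):
            for region in MICROBIOME_REGIONS:
                rows.append((f"x_m{mouse}_{region}", mouse, region, "lumen"))
        meta = pd.DataFrame(
            rows, columns=["sample_id", "mouse", "region", "habitat"]
        ).set_index("sample_id")
        abundance = pd.DataFrame(
            [[spec.region_means[r] for r in meta["region"]]],
            index=["self"], columns=meta.index,
        )
        pairs = spatial_correlate(truth0["SPF"], abundance, meta, habitat="lumen")
        row = pairs.set_index(["taxon", "metabolite"]).loc[("self", spec.name)]
        assert row["rho"] == pytest.approx(1.0)

    def test_lumen_only_mode_halves_observations(self, assoc_fixture):
        panel, truth, asv, rarefied, relabund = assoc_fixture
        both = spatial_correlate(truth["SPF"], relabund, rarefied.samples)
        lumen = spatial_correlate(
            truth["SPF"], relabund, rarefied.samples, habitat="lumen"
        )
        assert lumen["n_obs"].max() <= 25
        assert lumen["n_obs"].max() < both["n_obs"].max()


class TestFilterPairs:
    @staticmethod
    def synthetic_pairs(n_null=5000, n_planted=10, seed=0):
        rng = np.random.default_rng(seed)
        mets = [f"m{i}" for i in range(50)]
        taxa = [f"t{j}" for j in range((n_null + n_planted) // 50 + 1)]
        rows = []
        combos = itertools.product(mets, taxa)
        for k, (met, taxon) in enumerate(itertools.islice(combos, n_null)):
            rows.append((met, taxon, rng.uniform(-0.5, 0.5), rng.uniform(0.0, 1.0), 50))
        planted = [(f"pm{i}", f"pt{i}") for i in range(n_planted)]
        for met, taxon in planted:
            rows.append((met, taxon, 0.9, 1e-6, 50))
        pairs = pd.DataFrame(rows, columns=["metabolite", "taxon", "rho", "p", "n_obs"])
        fc = pd.Series(1.0, index=pairs["metabolite"].unique())
        fc[[m for m, _ in planted]] = 8.0
        maps = NetworkMaps(
            host_ecs=frozenset(),
            taxon_ecs={t: frozenset({f"2.7.1.{i + 1}"})
                       for i, (_, t) in enumerate(planted)},
            metabolite_ecs={m: frozenset({f"2.7.1.{i + 1}"})
                            for i, (m, _) in enumerate(planted)},
        )
        return pairs, fc, maps, set(planted)

    def test_planted_pairs_all_recovered(self):
        pairs, fc, maps, planted = self.synthetic_pairs()
        out, funnel = filter_pairs(pairs, fc, maps)
        passing = {(r["metabolite"], r["taxon"])
                   for _, r in out[out["final_pass"]].iterrows()}
        assert passing == planted
        assert (np.diff(funnel["n_pairs"]) <= 0).all()

    def test_degenerate_thresholds(self):
        pairs, fc, maps, planted = self.synthetic_pairs(n_null=200, n_planted=5)
        out, funnel = filter_pairs(
            pairs, fc, maps, p_threshold=np.inf, fc_threshold=-np.inf,
            require_enzyme=False, require_positive=False,
        )
        assert funnel["n_pairs"].iloc[-1] == len(pairs)
        out, funnel = filter_pairs(pairs, fc, maps, p_threshold=0.0)
        assert funnel["n_pairs"].iloc[-1] == 0

    def test_negative_rho_rejected_even_if_rest_passes(self):
        pairs = pd.DataFrame(
            [("m", "t", -0.9, 1e-8, 50)],
            columns=["metabolite", "taxon", "rho", "p", "n_obs"],
        )
        fc = pd.Series({"m": 10.0})
        maps = NetworkMaps(
            host_ecs=frozenset(), taxon_ecs={"t": frozenset({"2.7.1.1"})},
            metabolite_ecs={"m": frozenset({"2.7.1.1"})},
        )
        out, _ = filter_pairs(pairs, fc, maps)
        assert not out["final_pass"].any()

    def test_exclusive_metabolite_passes_fc_gate(self):
        pairs = pd.DataFrame(
            [("m", "t", 0.9, 1e-8, 50)],
            columns=["metabolite", "taxon", "rho", "p", "n_obs"],
        )
        fc = pd.Series({"m": np.nan})
        exclusive = pd.Series({"m": True})
        maps = NetworkMaps(
            host_ecs=frozenset(), taxon_ecs={"t": frozenset({"2.7.1.1"})},
            metabolite_ecs={"m": frozenset({"2.7.1.1"})},
        )
        out, _ = filter_pairs(pairs, fc, maps, exclusive=exclusive)
        assert out["final_pass"].all()

    def test_bh_column_emitted_alongside_raw_gate(self):
        pairs, fc, maps, planted = self.synthetic_pairs(n_null=200, n_planted=5)
        out, _ = filter_pairs(pairs, fc, maps)
        assert "q" in out.columns
        defined = out["p"].notna()
        assert (out.loc[defined, "q"] >= out.loc[defined, "p"] - 1e-15).all()

    def test_undefined_rho_excluded(self):
        pairs = pd.DataFrame(
            [("m", "t", np.nan, np.nan, 2)],
            columns=["metabolite", "taxon", "rho", "p", "n_obs"],
        )
        fc = pd.Series({"m": 10.0})
        maps = NetworkMaps(host_ecs=frozenset())
        out, funnel = filter_pairs(pairs, fc, maps)
        assert funnel["n_pairs"].iloc[-1] == 0


class TestStudyFunnel:
    def test_funnel_monotone_and_producers_recovered(self, study):
        counts = study.funnel["n_pairs"].to_numpy()
        assert counts[0] == 128 * 120
        assert (np.diff(counts) <= 0).all()
        passing = {(r["taxon"], r["metabolite"])
                   for _, r in study.pairs[study.pairs["final_pass"]].iterrows()}
        assert set(study.asv.producers) <= passing


class TestSummarizePairs:
    def test_single_order_holds_total(self):
        pairs = pd.DataFrame(
            {"metabolite": ["a", "b"], "taxon": ["t1", "t2"],
             "final_pass": [True, True]}
        )
        lineage = pd.DataFrame({"order": ["O1", "O1"]}, index=["t1", "t2"])
        out = summarize_pairs(pairs, lineage)
        assert len(out) == 1
        assert out.loc[0, "n_pairs"] == 2
        assert out.loc[0, "n_taxa"] == 2

    def test_study_totals_conserved(self, study):
        out = summarize_pairs(study.pairs, study.asv.table.lineage)
        assert out["n_pairs"].sum() == int(study.pairs["final_pass"].sum())
        producer_orders = {
            study.asv.table.lineage.loc[t, "order"] for t, _ in study.asv.producers
        }
        assert producer_orders <= set(out["order"])
        assert len(producer_orders) >= 3

    def test_empty_pass_set(self):
        pairs = pd.DataFrame(
            {"metabolite": [], "taxon": [], "final_pass": []}
        )
        out = summarize_pairs(pairs, pd.DataFrame(columns=["order"]))
        assert out.empty

    def test_missing_lineage_rejected(self):
        pairs = pd.DataFrame(
            {"metabolite": ["a"], "taxon": ["tX"], "final_pass": [True]}
        )
        with pytest.raises(ValueError):
            summarize_pairs(pairs, pd.DataFrame(columns=["order"]))
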