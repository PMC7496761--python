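"""Predictor screening: correlations, contributions, jackknife, selection rules."""

import numpy as np
import pandas as pd
import pytest

from stacksdm.models import ModelSpec, fit, sample_background
from stacksdm.screening import (
    apply_selection_rules,
    contribution_scores,
    correlation_matrix,
    jackknife_test,
    select_predictors,
)
from stacksdm.synthetic import TruthNiche, sample_occurrences


class TestCorrelationMatrix:
    def test_structure(self, small_present):
        c = correlation_matrix(small_present, ["sst", "depth", "iron"], seed=0)
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c.values, c.values.T)
        assert c.values.min() >= -1.0 and c.values.max() <= 1.0

    def test_self_and_negation(self, small_present):
        from stacksdm.grid import EnvStack, Layer

        sst = small_present.layers["sst"]
        neg = Layer(sst.grid, np.where(sst.nodata_mask, np.nan, -sst.values),
                    sst.nodata_mask)
        stack = EnvStack(
            layers={"sst": sst, "neg_sst": neg}, scenario="present",
            sea_mask=small_present.sea_mask,
        )
        c = correlation_matrix(stack, ["sst", "neg_sst"], seed=0)
        assert c.loc["sst", "sst"] == 1.0
        assert c.loc["sst", "neg_sst"] == pytest.approx(-1.0)

    def test_noise_attenuation_closed_form(self, small_present):
        # r(X, X + eps) with sd(eps) = 0.1 sd(X) is 1/sqrt(1.01) ~ 0.995
        from stacksdm.grid import EnvStack, Layer

        sst = small_present.layers["sst"]
        rng = np.random.default_rng(0)
        sd = np.nanstd(sst.values)
        noisy_vals = sst.values + rng.normal(0, 0.1 * sd, sst.values.shape)
        noisy = Layer(sst.grid, np.where(sst.nodata_mask, np.nan, noisy_vals),
                      sst.nodata_mask)
        stack = EnvStack(layers={"sst": sst, "noisy": noisy}, scenario="present",
                         sea_mask=small_present.sea_mask)
        c = correlation_matrix(stack, ["sst", "noisy"], seed=0, n_sample=10_000)
        assert c.loc["sst", "noisy"] == pytest.approx(1 / np.sqrt(1.01), abs=0.005)

    def test_zero_variance_predictor_warns_r_zero(self, small_present):
        from stacksdm.grid import EnvStack, Layer

        sst = small_present.layers["sst"]
        flat = Layer(sst.grid, np.where(sst.nodata_mask, np.nan, 3.0), sst.nodata_mask)
        stack = EnvStack(layers={"sst": sst, "flat": flat}, scenario="present",
                         sea_mask=small_present.sea_mask)
        with pytest.warns(UserWarning, match="zero-variance"):
            c = correlation_matrix(stack, ["sst", "flat"], seed=0)
        assert c.loc["sst", "flat"] == 0.0
        assert c.loc["flat", "flat"] == 1.0


@pytest.fixture(scope="module")
def screened_species(small_present):
    niche = TruthNiche("sp", "phytoplankton", {"sst": ("window", 6.0, 14.0, 4.0)})
    occ = sample_occurrences(niche, small_present, 150, seed=31, jitter_fraction=0.0)
    background = sample_background(small_present, 1000, seed=13)
    return niche, occ, background


class TestContributions:
    def test_single_predictor_gets_everything(self, small_present, screened_species):
        _, occ, bg = screened_species
        rep = fit(ModelSpec("maxent_hinge", seed=1), occ.cells, bg, small_present,
                  ["sst"], seed=1)
        scores = contribution_scores(rep.estimator, rep.train_presences,
                                     rep.train_contrast, small_present, ["sst"], seed=0)
        assert scores == {"sst": 100.0}

    def test_scores_sum_to_hundred(self, small_present, screened_species):
        _, occ, bg = screened_species
        preds = ["sst", "surface_salinity", "land_distance"]
        rep = fit(ModelSpec("maxent_hinge", seed=2), occ.cells, bg, small_present,
                  preds, seed=2)
        scores = contribution_scores(rep.estimator, rep.train_presences,
                                     rep.train_contrast, small_present, preds, seed=0)
        assert sum(scores.values()) == pytest.approx(100.0, abs=1e-6)

    def test_pure_noise_predictor_scores_below_threshold(self, small_present,
                                                         screened_species):
        """A predictor carrying no signal stays under the 4% rule in >= 9/10 runs."""
        _, occ, bg = screened_species
        preds = ["sst", "bottom_salinity"]  # bottom salinity is pure noise here
        hits = 0
        for s in range(10):
            rep = fit(ModelSpec("maxent_hinge", seed=s), occ.cells, bg, small_present,
                      preds, seed=s)
            scores = contribution_scores(rep.estimator, rep.train_presences,
                                         rep.train_contrast, small_present, preds,
                                         seed=s)
            hits += scores["bottom_salinity"] < 4.0
        assert hits >= 9


class TestJackknife:
    def test_driving_predictor_alone_is_informative(self, small_present,
                                                    screened_species):
        _, occ, bg = screened_species
        jk = jackknife_test(occ.cells, bg, small_present,
                            ["sst", "surface_salinity"], seed=5)
        with_only_sst, _ = jk["sst"]
        assert with_only_sst >= 0.8

    def test_removing_noise_predictor_changes_little(self, small_present,
                                                     screened_species):
        _, occ, bg = screened_species
        preds = ["sst", "bottom_salinity"]
        rep = fit(ModelSpec("maxent_hinge", seed=3), occ.cells, bg, small_present,
                  preds, seed=3)
        jk = jackknife_test(occ.cells, bg, small_present, preds, seed=3)
        _, without_noise = jk["bottom_salinity"]
        assert abs(without_noise - rep.report.auc) < 0.02

    def test_constant_layer_alone_is_random(self, small_present, screened_species):
        from stacksdm.grid import EnvStack, Layer

        _, occ, bg = screened_species
        sst = small_present.layers["sst"]
        flat = Layer(sst.grid, np.where(sst.nodata_mask, np.nan, 1.0), sst.nodata_mask)
        stack = EnvStack(
            layers={**small_present.layers, "flat": flat}, scenario="present",
            sea_mask=small_present.sea_mask,
        )
        jk = jackknife_test(occ.cells, bg, stack, ["sst", "flat"], seed=7)
        with_only_flat, _ = jk["flat"]
        assert with_only_flat == pytest.approx(0.5, abs=0.02)


def _corr_frame(names, pairs):
    c = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b, r in pairs:
        c.loc[a, b] = c.loc[b, a] = r
    return c


class TestSelectionRules:
    def test_hand_traced_example(self):
        contributions = {"SST": 60.0, "BotTemp": 30.0, "Ice": 8.0, "Noise": 2.0}
        corr = _corr_frame(["SST", "BotTemp", "Ice", "Noise"],
                           [("SST", "BotTemp", 0.9)])
        selected, dropped = apply_selection_rules(contributions, corr)
        # Noise fails the 4% rule, BotTemp loses the collinear pair to SST;
        # the three-predictor floor restores the best non-collinear candidate
        assert selected == ["SST", "Ice", "Noise"]
        assert dropped == {"BotTemp": "correlated_with:SST"}

    def test_no_rule_fires(self):
        contributions = {"a": 40.0, "b": 35.0, "c": 25.0}
        corr = _corr_frame(["a", "b", "c"], [])
        selected, dropped = apply_selection_rules(contributions, corr)
        assert set(selected) == {"a", "b", "c"} and not dropped

    def test_highest_r_pair_resolved_first(self):
        contributions = {"a": 50.0, "b": 30.0, "c": 20.0, "d": 10.0}
        corr = _corr_frame(["a", "b", "c", "d"],
                           [("a", "b", 0.95), ("b", "c", 0.75)])
        selected, _ = apply_selection_rules(contributions, corr)
        # b lost to a on the 0.95 pair; (b, c) then no longer applies
        assert "a" in selected and "c" in selected and "d" in selected

    def test_floor_outranks_correlation_when_unavoidable(self):
        contributions = {"a": 50.0, "b": 30.0, "c": 20.0}
        corr = _corr_frame(["a", "b", "c"],
                           [("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", 0.9)])
        selected, dropped = apply_selection_rules(contributions, corr)
        assert len(selected) == 3 and not dropped

    def test_insertion_order_never_matters(self, rng):
        for _ in range(50):
            names = [f"p{i}" for i in range(int(rng.integers(3, 8)))]
            contributions = dict(zip(names, 100 * rng.dirichlet(np.ones(len(names)))))
            corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    r = float(rng.uniform(-1, 1))
                    corr.iloc[i, j] = corr.iloc[j, i] = r
            base_sel, base_drop = apply_selection_rules(contributions, corr)
            perm = list(rng.permutation(names))
            shuffled = {k: contributions[k] for k in perm}
            sel2, drop2 = apply_selection_rules(shuffled, corr.loc[perm, perm])
            assert sel2 == base_sel and drop2 == base_drop
            # invariants
            assert len(base_sel) >= 3
            assert not set(base_sel) & set(base_drop)


class TestSelectPredictors:
    def test_fewer_than_three_candidates_errors(self, small_present, screened_species):
        _, occ, _ = screened_species
        with pytest.raises(ValueError):
            select_predictors(["sst", "iron"], occ.cells, small_present, seed=0)

    def test_adversarial_stacks_still_yield_three(self, small_present):
        """Duplicated and pure-noise layers never drive selection below three."""
        from stacksdm.grid import EnvStack, Layer

        rng = np.random.default_rng(0)
        sst = small_present.layers["sst"]
        dup = Layer(sst.grid, sst.values.copy(), sst.nodata_mask.copy())
        noise_vals = np.where(sst.nodata_mask, np.nan,
                              rng.normal(size=sst.values.shape))
        noise = Layer(sst.grid, noise_vals, sst.nodata_mask.copy())
        stack = EnvStack(
            layers={"sst": sst, "sst_copy": dup, "noise": noise,
                    "depth": small_present.layers["depth"]},
            scenario="present", sea_mask=small_present.sea_mask,
        )
        niche = TruthNiche("adv", "phytoplankton", {"sst": ("window", 6.0, 14.0, 4.0)})
        occ = sample_occurrences(niche, small_present, 120, seed=17)
        report = select_predictors(["sst", "sst_copy", "noise", "depth"], occ.cells,
                                   stack, seed=2, n_background=800,
                                   with_jackknife=False)
        assert len(report.selected) >= 3
        assert not set(report.selected) & set(report.dropped)

    def test_full_report_consistency(self, small_present, screened_species):
        _, occ, bg = screened_species
        report = select_predictors(
            ["sst", "surface_salinity", "land_distance", "ice_thickness"],
            occ.cells, small_present, seed=4, background=bg,
        )
        assert sum(report.contributions.values()) == pytest.approx(100.0, abs=1e-6)
        assert len(report.selected) >= 3
        frame = report.to_frame()
        assert set(frame.predictor) == {"sst", "surface_salinity", "land_distance",
                                        "ice_thickness"}
        assert frame.selected.sum() == len(report.selected)
        assert set(report.response_shape) == set(report.contributions)
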