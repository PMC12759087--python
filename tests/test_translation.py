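"""Translation pipeline: bounds, summarising, objective, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiotrans.drugs import DrugSpec
from cardiotrans.synthetic import generate_drug_effect_dataset
from cardiotrans.transients import ALL_BIOMARKERS, DrugEffectTable
from cardiotrans.translation import (
    InferenceSpec,
    RatEffectDataset,
    infer_potencies,
    inference_objective,
    pic50_bounds,
    predict_human_effects,
    summarise_rat_effects,
)


class TestBounds:
    def test_standard_series(self):
        lo, hi = pic50_bounds([0.1, 1.0, 10.0, 30.0])
        assert lo == pytest.approx(6 - math.log10(3000.0))
        assert hi == pytest.approx(6 - math.log10(0.001))
        assert (lo, hi) == pytest.approx((2.523, 9.0), abs=1e-3)

    def test_single_concentration(self):
        assert pic50_bounds([1.0]) == pytest.approx((4.0, 8.0))

    def test_invalid_concentrations(self):
        with pytest.raises(ValueError):
            pic50_bounds([0.0, 1.0])


def table_from(effects_by_conc, species="rat"):
    return DrugEffectTable.from_effects(
        {c: dict(zip(ALL_BIOMARKERS, vals)) for c, vals in effects_by_conc.items()},
        species=species,
    )


class TestSummarise:
    def test_single_cell_is_identity(self):
        t = table_from({1.0: range(14)})
        ds = summarise_rat_effects([t])
        assert ds.effects.loc["SLRes", 1.0] == 0.0
        assert ds.effects.loc["dCaMin", 1.0] == 13.0

    def test_median_across_cells(self):
        cells = [table_from({1.0: [v] * 14}) for v in (-10.0, -20.0, -30.0)]
        ds = summarise_rat_effects(cells)
        assert (ds.effects[1.0] == -20.0).all()

    def test_out_of_range_cell_excluded_before_median(self):
        cells = [table_from({1.0: [v] * 14}) for v in (-10.0, -20.0, 600.0)]
        ds = summarise_rat_effects(cells)
        assert (ds.effects[1.0] == -15.0).all()  # median of the included pair

    def test_empty_cell_after_exclusion_raises(self):
        cells = [table_from({1.0: [600.0] * 14})]
        with pytest.raises(ValueError, match="no included data"):
            summarise_rat_effects(cells)


@pytest.fixture(scope="module")
def truth_setup(desk_study):
    truth = {"RyR2": 5.4, "SERCA2": 5.7, "NCX1": 5.9}
    ds = generate_drug_effect_dataset(DrugSpec("t", truth), [0.1, 1.0], desk_study)
    return truth, RatEffectDataset.from_table(ds["rat"])


class TestObjective:
    def test_near_zero_at_ground_truth(self, desk_study, truth_setup):
        truth, rat = truth_setup
        obj = inference_objective(
            np.array(list(truth.values())), rat, desk_study, tuple(truth)
        )
        # the residual is exactly zero; only the finite-beat periodicity
        # penalty of the clean transients remains
        assert obj < 1.0

    def test_no_block_limit_equals_squared_data_norm(self, desk_study, truth_setup):
        truth, rat = truth_setup
        weak = np.full(3, 2.6)  # s ~ 1 at every concentration
        obj = inference_objective(weak, rat, desk_study, tuple(truth))
        data_norm = float(np.nansum(rat.effects.to_numpy() ** 2))
        assert obj == pytest.approx(data_norm, rel=0.05)

    def test_nonnegative_everywhere(self, desk_study, truth_setup):
        truth, rat = truth_setup
        rng = np.random.default_rng(4)
        for _ in range(3):
            x = rng.uniform(4.5, 6.5, 3)
            assert inference_objective(x, rat, desk_study, tuple(truth)) >= 0.0


class TestInferAndPredict:
    def test_restart_determinism(self, desk_study):
        truth = {"SERCA2": 5.6}
        ds = generate_drug_effect_dataset(DrugSpec("t", truth), [1.0], desk_study)
        rat = RatEffectDataset.from_table(ds["rat"])
        spec = InferenceSpec(targets=("SERCA2",), restarts=2, maxiter=6, popsize=4)
        a = infer_potencies(rat, spec, desk_study, seed=9)
        b = infer_potencies(rat, spec, desk_study, seed=9)
        assert a.potencies == b.potencies
        assert a.restart_objectives == b.restart_objectives

    def test_single_target_recovery(self, desk_study):
        truth = {"SERCA2": 5.6}
        ds = generate_drug_effect_dataset(DrugSpec("t", truth), [1.0], desk_study)
        rat = RatEffectDataset.from_table(ds["rat"])
        spec = InferenceSpec(targets=("SERCA2",), restarts=1, maxiter=10, popsize=5)
        res = infer_potencies(rat, spec, desk_study, seed=9)
        assert res.potencies.potencies["SERCA2"] == pytest.approx(5.6, abs=0.05)

    def test_zero_block_predicts_no_human_effects(self, desk_study):
        # potencies at the weak end of the bounds: s ~ 1 everywhere
        weak = DrugSpec("weak", {t: 2.6 for t in ("RyR2", "SERCA2", "NCX1")})
        table, abnormal = predict_human_effects(weak, [0.1, 1.0], desk_study)
        assert not abnormal
        mat = table.matrix()
        assert np.nanmax(np.abs(mat.to_numpy())) < 2.0  # percent

    def test_dataset_generation_deterministic(self, desk_study):
        drug = DrugSpec("d", {"RyR2": 5.5})
        a = generate_drug_effect_dataset(drug, [1.0], desk_study)
        b = generate_drug_effect_dataset(drug, [1.0], desk_study)
        pd.testing.assert_frame_equal(a["rat"].table, b["rat"].table)
        pd.testing.assert_frame_equal(a["human"].table, b["human"].table)
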