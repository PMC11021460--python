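from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phbcascade.calibrate import (FitSpec, TimeCourseDataset, compare, fit,
                                  objective, read_dataset, write_dataset)
from phbcascade.kinetics import ScenarioSpec
from phbcascade.synth import DesignSpec, NoiseModel, generate_timecourse

TOY_DESIGN = DesignSpec(label="toy", times_h=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0))
NOISELESS = NoiseModel(cv=0.0, floor=0.0)


@pytest.fixture(scope="module")
def toy_truth_data(toy_cascade):
    net, params, scenario = toy_cascade
    ds = generate_timecourse(net, params, scenario, TOY_DESIGN, NOISELESS, seed=1)
    return net, params, scenario, ds


class TestObjective:
    def test_zero_on_generating_parameters(self, toy_truth_data):
        net, params, _, ds = toy_truth_data
        assert objective(net, params, [ds]) == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_scaling(self, toy_cascade):
        net, params, scenario = toy_cascade
        from phbcascade.kinetics import simulate
        import pandas as pd
        sim = simulate(net, params, scenario)
        times = (0.5, 1.0, 2.0)
        model = [sim.at("PHB", t * 60) for t in times]

        # residuals d on the two smaller points; the maximum point (the
        # normalization scale) is left exact so doubling every residual
        # must exactly quadruple the loss
        def dataset(d):
            rows = [{"time_h": t, "observable": "PHB", "replicate": 1,
                     "value_mM": v - (d if v < max(model) else 0.0)}
                    for t, v in zip(times, model)]
            return TimeCourseDataset("scaled", scenario, pd.DataFrame(rows))

        l1 = objective(net, params, [dataset(0.02)])
        l2 = objective(net, params, [dataset(0.04)])
        assert l2 / l1 == pytest.approx(4.0, rel=1e-6)

    def test_hand_computed_toy_loss(self, toy_cascade):
        net, params, scenario = toy_cascade
        # 3 PHB points with known model values and means differing by 1, 2, 3
        from phbcascade.kinetics import simulate
        sim = simulate(net, params, scenario)
        times = (1.0, 2.0, 4.0)
        model = [sim.at("PHB", t * 60) for t in times]
        means = [m - d for m, d in zip(model, (0.05, 0.1, 0.15))]
        rows = [{"time_h": t, "observable": "PHB", "replicate": 1, "value_mM": v}
                for t, v in zip(times, means)]
        ds = TimeCourseDataset("hand", scenario, pd.DataFrame(rows))
        scale = max(means)
        expected = sum((d / scale) ** 2 for d in (0.05, 0.1, 0.15))
        assert objective(net, params, [ds]) == pytest.approx(expected, rel=1e-6)


class TestFit:
    def test_start_at_truth_returns_truth(self, toy_truth_data):
        net, params, _, ds = toy_truth_data
        spec = FitSpec(free={("km", "E1", "MD"): (1.0, 300.0),
                             ("km", "E2", "X"): (0.1, 100.0)})
        res = fit(net, [ds], spec, params, n_starts=1, seed=0)
        assert res.loss <= res.start_loss
        assert res.loss == pytest.approx(0.0, abs=1e-8)
        for addr in spec.free:
            assert res.values[addr] == pytest.approx(spec.get(params, addr), rel=1e-3)

    def test_recovery_from_2x_perturbed_start_noise_free(self, toy_truth_data):
        net, params, _, ds = toy_truth_data
        spec = FitSpec(free={("km", "E1", "MD"): (1.0, 300.0),
                             ("km", "E2", "X"): (0.1, 100.0)})
        start = spec.apply(params, [2.0 * spec.get(params, a) for a in spec.free])
        res = fit(net, [ds], spec, start, n_starts=1, seed=0)
        for addr in spec.free:
            truth = spec.get(params, addr)
            assert abs(res.values[addr] - truth) / truth <= 0.01, addr

    def test_recovery_with_default_noise(self, toy_cascade):
        net, params, scenario = toy_cascade
        ds = generate_timecourse(net, params, scenario, TOY_DESIGN,
                                 NoiseModel(cv=0.02, floor=0.01), seed=11)
        spec = FitSpec(free={("km", "E1", "MD"): (1.0, 300.0),
                             ("km", "E2", "X"): (0.1, 100.0)})
        start = spec.apply(params, [2.0 * spec.get(params, a) for a in spec.free])
        res = fit(net, [ds], spec, start, n_starts=1, seed=0)
        for addr in spec.free:
            truth = spec.get(params, addr)
            assert abs(res.values[addr] - truth) / truth <= 0.05, addr

    def test_seed_reproducibility(self, toy_truth_data):
        net, params, _, ds = toy_truth_data
        spec = FitSpec(free={("km", "E1", "MD"): (1.0, 300.0)})
        start = spec.apply(params, [90.0])
        a = fit(net, [ds], spec, start, n_starts=3, seed=42)
        b = fit(net, [ds], spec, start, n_starts=3, seed=42)
        assert a.values == b.values and a.loss == b.loss

    def test_empty_free_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            FitSpec(free={})

    def test_round1_emulation_improves_on_model0(self, full_net):
        """Freeing the phosphoketolase/transketolase/PTA/PhaB Km entries and
        the PhaC binding parameters strictly improves the fit of the
        unfitted parameter set to 1x and 5x loading time courses."""
        from phbcascade.kinetics import ScenarioSpec, shipped_params
        from phbcascade.pipeline import ROUND1_FREE

        truth = shipped_params("model1")
        datasets = []
        for label, level in (("1x", 1.0), ("5x", 5.0)):
            vm = {rid: level for rid in truth.reactions}
            vm["FPK"] = 0.12 * level
            datasets.append(generate_timecourse(
                full_net, truth.with_vmax(vm),
                ScenarioSpec(t_end=240.0, label=label),
                DesignSpec(label=label, times_h=(0.0, 1.0, 2.0, 4.0)),
                NoiseModel(), seed=5))
        start = shipped_params("model0")
        res = fit(full_net, datasets, FitSpec(free=ROUND1_FREE), start,
                  n_starts=1, seed=0, max_nfev=15)
        assert res.loss < res.start_loss


class TestCompare:
    def test_perfect_fit_zero_rmse(self, toy_truth_data):
        net, params, _, ds = toy_truth_data
        spec = FitSpec(free={("km", "E1", "MD"): (1.0, 300.0)})
        res = fit(net, [ds], spec, params, n_starts=1, seed=0)
        assert (res.per_dataset_rmse["rmse_mM"] < 1e-5).all()

    def test_rmse_matches_direct_recomputation(self, toy_truth_data):
        net, params, scenario, ds = toy_truth_data
        from phbcascade.calibrate import FitResult
        from phbcascade.kinetics import simulate
        res = FitResult(params=params, values={}, loss=0.0, start_loss=0.0,
                        converged=True, n_starts=1)
        table = compare(res, net, [ds])
        sim = simulate(net, params, replace(scenario, t_end=4 * 60.0))
        means = ds.means()
        sub = means[means["observable"] == "PHB"]
        err = [sim.at("PHB", t * 60.0) - m
               for t, m in zip(sub["time_h"], sub["mean_mM"])]
        expected = float(np.sqrt(np.mean(np.square(err))))
        got = float(table.loc[table["observable"] == "PHB", "rmse_mM"].iloc[0])
        assert got == pytest.approx(expected, abs=1e-9)


class TestDatasetIO:
    def test_roundtrip(self, toy_truth_data, tmp_path):
        _, _, scenario, ds = toy_truth_data
        path = tmp_path / "toy.csv"
        write_dataset(ds, path)
        back = read_dataset(path, label="toy", scenario=scenario)
        pd.testing.assert_frame_equal(back.measurements, ds.measurements)

    def test_invalid_measurements_rejected(self, toy_cascade):
        _, _, scenario = toy_cascade
        bad = pd.DataFrame([{"time_h": 1.0, "observable": "PHB",
                             "replicate": 1, "value_mM": -2.0}])
        with pytest.raises(ValueError, match=">= 0"):
            TimeCourseDataset("bad", scenario, bad)
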