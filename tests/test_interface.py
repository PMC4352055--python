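"""Round-trips of the on-disk formats, config loading, CLI contracts."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cogmap.bold import PredictedCurve
from cogmap.cli import main
from cogmap.config import MappingParams, RunConfig
from cogmap.glm import VolumeGrid
from cogmap.io import (
    load_roi,
    load_volume,
    read_curves,
    read_events,
    read_trace,
    save_roi,
    save_volume,
    write_curves,
    write_events,
    write_trace,
)
from cogmap.roi import ROIMask
from cogmap.task_models import (
    DemandTrace,
    MultitaskParams,
    TrialSpec,
    generate_multitask_trace,
)


class TestRoundTrips:
    def test_trace_tsv(self, tmp_path):
        trace = generate_multitask_trace("nback+count", MultitaskParams(),
                                         np.random.default_rng(3))
        p = tmp_path / "trace.tsv"
        write_trace(trace, p)
        back = read_trace(p)
        for m in trace.active_modules():
            np.testing.assert_allclose(back.module_intervals(m),
                                       trace.module_intervals(m), atol=1e-6)
        header = p.read_text().splitlines()[0]
        assert header.split("\t") == ["module", "trial", "onset", "offset"]

    def test_events_tsv(self, tmp_path):
        trials = [TrialSpec("a", 0.0, 30.0), TrialSpec("b", 40.0, 30.0)]
        p = tmp_path / "events.tsv"
        write_events(trials, p, rts=np.array([1.25, 2.5]),
                     correct=np.array([1, 0]))
        back = read_events(p)
        assert [(t.condition, t.onset) for t in back] == [("a", 0.0), ("b", 40.0)]
        df = pd.read_csv(p, sep="\t")
        assert list(df.columns) == ["onset", "duration", "condition", "rt",
                                    "correct"]

    def test_curves_tsv(self, tmp_path):
        curves = {
            "a": PredictedCurve(module="visual", condition="a",
                                values=[0.0, 0.5, 1.0]),
            "b": PredictedCurve(module="visual", condition="b",
                                values=[0.0, -0.25, 0.75]),
        }
        p = tmp_path / "curves.tsv"
        write_curves(curves, p)
        back = {c.condition: c for c in read_curves(p)}
        np.testing.assert_allclose(back["b"].values, [0.0, -0.25, 0.75],
                                   atol=1e-6)

    def test_volume_float32(self, tmp_path, small_grid, rng):
        data = rng.normal(size=(*small_grid.dims, 5))
        p = tmp_path / "vol.nii"
        save_volume(data, small_grid, p)
        back, grid = load_volume(p)
        assert grid.matches(small_grid)
        np.testing.assert_allclose(back, data.astype(np.float32), atol=1e-6)

    def test_roi_mask_exact_with_sidecar(self, tmp_path, small_grid):
        mask = np.zeros(small_grid.dims, bool)
        mask[2:5, 3:6, 4:7] = True
        roi = ROIMask(grid=small_grid, mask=mask, seed=(3, 4, 5),
                      module="visual", hemisphere="left")
        p = tmp_path / "roi_visual.nii"
        save_roi(roi, p)
        back = load_roi(p)
        np.testing.assert_array_equal(back.mask, roi.mask)
        assert back.module == "visual" and back.seed == (3, 4, 5)
        meta = json.loads((tmp_path / "roi_visual.json").read_text())
        assert meta["size_voxels"] == roi.size

    def test_malformed_trace_names_file(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("module\tonset\n")
        with pytest.raises(ValueError, match="bad.tsv"):
            read_trace(p)


class TestRunConfig:
    def test_defaults_match_published_procedure(self):
        cfg = RunConfig()
        assert cfg.mapping.p_thresh == 1e-7
        assert cfg.mapping.min_extent == 250
        assert cfg.mapping.target_size == 100

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "seed: 7\n"
            "hrf: {peak_shape: 6, undershoot_shape: 16}\n"
            "scans: {tr: 2.0, n_scans: 100}\n"
            "mapping: {p_thresh: 1.0e-5, min_extent: 50, target_size: 80,"
            " connectivity: 18}\n"
        )
        cfg = RunConfig.from_yaml(p)
        assert cfg.seed == 7
        assert cfg.mapping.min_extent == 50
        assert cfg.scans.n_scans == 100

    def test_missing_path_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("paths: {data: /does/not/exist.nii}\n")
        with pytest.raises(FileNotFoundError):
            RunConfig.from_yaml(p)

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            MappingParams(connectivity=7)


class TestCLI:
    def test_predict_writes_outputs_and_provenance(self, tmp_path):
        trace = generate_multitask_trace("nback", MultitaskParams(),
                                         np.random.default_rng(0))
        tpath = tmp_path / "trace.tsv"
        write_trace(trace, tpath)
        write_events([TrialSpec("nback", 0.0, 30.0)], tmp_path / "events.tsv")
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("scans: {tr: 2.0, n_scans: 30}\nevaluation: {window: 10}\n")
        runner = CliRunner()
        res = runner.invoke(main, [
            "predict", str(tpath), "--config", str(cfg),
            "--events", str(tmp_path / "events.tsv"),
            "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "regressors.tsv").exists()
        assert (tmp_path / "out" / "predicted_curves.tsv").exists()
        prov = json.loads((tmp_path / "out" / "provenance.json").read_text())
        assert prov["command"] == "predict"

    def test_predict_deterministic_outputs(self, tmp_path):
        trace = generate_multitask_trace("count", MultitaskParams(),
                                         np.random.default_rng(0))
        tpath = tmp_path / "trace.tsv"
        write_trace(trace, tpath)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("scans: {tr: 2.0, n_scans: 30}\n")
        runner = CliRunner()
        for out in ("o1", "o2"):
            res = runner.invoke(main, ["predict", str(tpath), "--config",
                                       str(cfg), "--out", str(tmp_path / out)])
            assert res.exit_code == 0, res.output
        a = (tmp_path / "o1" / "regressors.tsv").read_bytes()
        b = (tmp_path / "o2" / "regressors.tsv").read_bytes()
        assert a == b

    def test_missing_input_errors_nonzero(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, ["predict", str(tmp_path / "nope.tsv"),
                                   "--out", str(tmp_path / "out")])
        assert res.exit_code != 0


class TestCLIWorkflows:
    """End-to-end create-mapping and evaluate workflows through the CLI."""

    def make_dataset(self, tmp_path):
        from cogmap.bold import HRFSpec, ScanGrid
        from cogmap.synthetic import NoiseModel, iter_group, make_truth

        affine = np.array([[4.0, 0, 0, -30.0], [0, 4.0, 0, -30.0],
                           [0, 0, 4.0, -30.0], [0, 0, 0, 1.0]])
        grid = VolumeGrid((16, 16, 16), affine)
        truth = make_truth(grid, centers={"visual": (-14.0, -14.0, 0.0),
                                          "declarative": (14.0, 14.0, 0.0)},
                           radius_mm=7.0)
        scans = ScanGrid(tr=2.0, n_scans=136)
        data_files, trace_files, event_files = [], [], []
        for sub in iter_group(n_subjects=5, truth=truth, scans=scans,
                              noise=NoiseModel(sigma=0.3), seed=4,
                              n_per_condition=1):
            d = tmp_path / f"{sub.subject}_bold.nii"
            save_volume(sub.data, grid, d)
            t = tmp_path / f"{sub.subject}_trace.tsv"
            write_trace(sub.trace, t)
            e = tmp_path / f"{sub.subject}_events.tsv"
            write_events(sub.trials, e)
            data_files.append(str(d))
            trace_files.append(str(t))
            event_files.append(str(e))
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("scans: {tr: 2.0, n_scans: 136}\n"
                       "evaluation: {window: 12}\n")
        return truth, cfg, data_files, trace_files, event_files

    def test_map_then_evaluate(self, tmp_path):
        truth, cfg, data_files, trace_files, event_files = \
            self.make_dataset(tmp_path)
        runner = CliRunner()
        args = ["map", "--config", str(cfg), "--out", str(tmp_path / "mapping"),
                "--p-thresh", "1e-3", "--min-extent", "10",
                "--target-size", "15"]
        for d in data_files:
            args += ["--data", d]
        for t in trace_files:
            args += ["--trace", t]
        res = runner.invoke(main, args)
        assert res.exit_code == 0, res.output
        roi_path = tmp_path / "mapping" / "roi_visual.nii"
        assert roi_path.exists()
        roi = load_roi(roi_path)
        assert roi.size == 15
        assert np.all(truth.regions["visual"].mask[roi.mask])

        # model curves for the evaluate step: predictions for both modules
        from cogmap.bold import HRFSpec, ScanGrid, condition_average, predict_module
        from cogmap.io import read_events as _read_events

        trace = read_trace(trace_files[0])
        trials = _read_events(event_files[0])
        scans = ScanGrid(tr=2.0, n_scans=136)
        curves = []
        for m in ("visual", "declarative"):
            pred = predict_module(trace, m, HRFSpec(), scans)
            curves.extend(condition_average(pred, trials, scans, 12,
                                            module=m).values())
        write_curves(curves, tmp_path / "model_curves.tsv")

        args = ["evaluate", "--config", str(cfg),
                "--model-curves", str(tmp_path / "model_curves.tsv"),
                "--out", str(tmp_path / "fits"),
                "--roi", str(roi_path),
                "--roi", str(tmp_path / "mapping" / "roi_declarative.nii")]
        for d in data_files:
            args += ["--data", d]
        for e in event_files:
            args += ["--events", e]
        res = runner.invoke(main, args)
        assert res.exit_code == 0, res.output
        table = pd.read_csv(tmp_path / "fits" / "fit_report.tsv", sep="\t")
        assert set(table["module"]) == {"visual", "declarative"}
        # strong signal, weak noise: the model should fit its own region well
        assert (table["tcc_aggregate"] > 0.8).all()

    def test_evaluate_grid_mismatch_fails_cleanly(self, tmp_path):
        truth, cfg, data_files, trace_files, event_files = \
            self.make_dataset(tmp_path)
        runner = CliRunner()
        args = ["map", "--config", str(cfg), "--out", str(tmp_path / "m"),
                "--p-thresh", "1e-3", "--min-extent", "10",
                "--target-size", "15", "--data", data_files[0],
                "--trace", trace_files[0]]
        # single subject: group stats need >= 3, must exit nonzero
        res = runner.invoke(main, args)
        assert res.exit_code != 0
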