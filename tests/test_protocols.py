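"""Experiment orchestration: sweeps, regime boundaries, DMS tasks, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from corrgate.cli import main as cli_main
from corrgate.protocols import (
    MonteCarloDesign,
    dms_two_unit_trial,
    dms_wta_trial,
    loading_curve,
    regime_boundaries,
    regime_map,
    run_blocking_protocol,
    run_dms_two_unit,
    run_erasing_protocol,
)

TINY = MonteCarloDesign(n_connectivity=2, n_noise=5)


class TestSweeps:
    def test_erasing_sweep_layout_and_reproducibility(self):
        table = run_erasing_protocol([0.0, 0.8], design=TINY, seed=4)
        assert list(table["lambda"]) == [0.0, 0.8]
        assert ((table["P_e"] >= 0) & (table["P_e"] <= 1)).all()
        assert (table["n_trials"] == TINY.n_trials).all()
        again = run_erasing_protocol([0.0, 0.8], design=TINY, seed=4)
        pd.testing.assert_frame_equal(table, again)

    def test_blocking_sweep_monotone_direction(self):
        table = run_blocking_protocol(
            [0.0, 0.8], design=MonteCarloDesign(2, 12), seed=4
        )
        p = table.set_index("lambda")["P_b"]
        # strong-correlation arm blocks at least as often (allow MC slack)
        assert p[0.8] >= p[0.0] - 0.1

    def test_loading_curve_columns(self):
        table = loading_curve([20.0, 56.0], lams=[0.4], js=[0.26],
                              design=TINY, seed=2)
        assert set(table.columns) >= {"nu1", "lambda", "J", "P_load", "SE"}
        assert ((table["P_load"] >= 0) & (table["P_load"] <= 1)).all()


class TestRegimeBoundaries:
    def _synthetic_map(self, lam_b=0.04, lam_e=0.11, width=0.02):
        lam = np.linspace(0, 0.2, 21)
        p_b = 1 / (1 + np.exp(-(lam - lam_b) / width))
        p_e = 1 / (1 + np.exp(-(lam - lam_e) / width))
        return pd.DataFrame({
            "lambda": lam,
            "P_gi": (1 - p_e) * (1 - p_b),
            "P_sg": (1 - p_e) * p_b,
            "P_go": p_e * p_b,
        }), lam, p_b, p_e

    def test_crossovers_recovered_from_synthetic_sigmoids(self):
        df, lam, p_b, p_e = self._synthetic_map()
        bounds = regime_boundaries(df)
        # independent oracle: crossings located on a fine grid
        fine = np.linspace(0, 0.2, 20001)
        pb_f = 1 / (1 + np.exp(-(fine - 0.04) / 0.02))
        pe_f = 1 / (1 + np.exp(-(fine - 0.11) / 0.02))
        gi = (1 - pe_f) * (1 - pb_f)
        sg = (1 - pe_f) * pb_f
        go = pe_f * pb_f
        gi_end = fine[np.argmax(gi < np.maximum(sg, go))]
        sg_end = fine[::-1][np.argmax((sg > np.maximum(gi, go))[::-1])]
        assert bounds["gate_in_end"] == pytest.approx(gi_end, abs=0.005)
        assert bounds["selective_gate_end"] == pytest.approx(sg_end, abs=0.005)
        sg_max = fine[np.argmax(sg)]
        assert bounds["p_sg_max"] == pytest.approx(sg_max, abs=0.01)

    def test_no_crossing_returns_none(self):
        lam = np.array([0.0, 0.1, 0.2])
        df = pd.DataFrame({"lambda": lam, "P_gi": [0.9, 0.8, 0.7],
                           "P_sg": [0.05, 0.1, 0.2], "P_go": [0.0, 0.0, 0.0]})
        bounds = regime_boundaries(df)
        assert bounds["gate_in_end"] is None
        assert bounds["selective_gate_end"] is None


class TestDmsTrials:
    def test_wta_trial_returns_three_operations(self):
        out = dms_wta_trial(4.8, correlated=True, seed=1, conn_seed=2)
        assert set(out) == {"load", "protect", "clear"}
        assert all(isinstance(v, (bool, np.bool_)) for v in out.values())

    def test_two_unit_trial_reports_sub_operations(self):
        out = dms_two_unit_trial(seed=1, conn_seed=2)
        assert set(out) == {"load", "protect", "clear", "maintain", "block"}

    def test_two_unit_driver_reports_all_operations(self):
        table = run_dms_two_unit(design=MonteCarloDesign(1, 3), seed=2)
        assert set(table["operation"]) == {"load", "maintain", "block", "clear"}
        assert ((table["success_rate"] >= 0) & (table["success_rate"] <= 1)).all()

    def test_wta_correlations_protect_against_strong_distractor(self):
        # strong distractors: the correlated arm protects far more often
        hits = {True: 0, False: 0}
        for correlated in (True, False):
            for seed in range(10):
                out = dms_wta_trial(9.0, correlated=correlated, seed=seed,
                                    conn_seed=3)
                hits[correlated] += out["protect"]
        assert hits[True] > hits[False]


class TestCli:
    def test_simulate_command_writes_raster_and_meta(self, tmp_path):
        cfg = {
            "network": {"family": "single_unit",
                        "overrides": {"n": 30, "c": 0.2, "j": 0.26}},
            "schedule": {
                "duration": 200.0,
                "lam": {"E": [[0.0, 0.3]]},
                "stimuli": [{"population": "E", "t_on": 50.0, "t_off": 100.0,
                             "nu1": 56.0, "j1": 1.5}],
            },
        }
        cfg_path = tmp_path / "run.json"
        cfg_path.write_text(json.dumps(cfg))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                       "--seed", "3", "--out",
                                       str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        raster = (tmp_path / "out" / "raster.tsv").read_text().splitlines()
        assert raster[0].startswith("#")
        meta = json.loads((tmp_path / "out" / "run_meta.json").read_text())
        assert meta["seed"] == 3

    def test_run_command_writes_csv(self, tmp_path):
        cfg = {"lambdas": [0.0, 0.6], "N": 50, "n_connectivity": 1, "n_noise": 4}
        cfg_path = tmp_path / "exp.json"
        cfg_path.write_text(json.dumps(cfg))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["run", "blocking", "--config",
                                       str(cfg_path), "--seed", "1",
                                       "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(tmp_path / "out" / "blocking.csv")
        assert {"lambda", "P_b"} <= set(table.columns)
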