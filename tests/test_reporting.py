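"""Run configuration, scenario fixtures, reports, manifests and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from pydantic import ValidationError

from todo_design import RunConfig, builtin_scenarios, manifest, run_scenarios
from todo_design.cli import main as cli_main
from todo_design.reporting import wl_sweep


BASE = {"design": {"p0": 0.2, "pA": 0.4, "delta1": 0.05, "delta2": 0.2,
                   "n_min": 20, "n_max": 40}}


@pytest.fixture()
def config():
    return RunConfig.model_validate(BASE)


def test_builtin_scenario_sets():
    t1 = builtin_scenarios("table1")
    assert len(t1) == 9
    assert (t1[0].p1, t1[0].p2) == (0.20, 0.20)
    assert (t1[4].p1, t1[4].p2) == (0.20, 0.40)
    t2 = builtin_scenarios("table2")
    assert len(t2) == 15
    assert (t2[13].q1, t2[13].p1, t2[13].q2, t2[13].p2) == \
        (0.20, 0.50, 0.45, 0.40)
    with pytest.raises(ValueError):
        builtin_scenarios("table9")


def test_config_validation():
    with pytest.raises(ValidationError):
        RunConfig.model_validate({"design": {"p0": 0.2, "pA": 0.4,
                                             "delta1": 0.2, "delta2": 0.05}})
    with pytest.raises(ValidationError):
        RunConfig.model_validate({"design": {"p0": 0.2, "pA": 0.4,
                                             "delta1": 0.05, "delta2": 0.2,
                                             "q0": 0.4}})   # partial toxicity


def test_manifest_reproducible(config):
    m1 = manifest(config)
    m2 = manifest(RunConfig.model_validate(BASE))
    assert m1["config_sha256"] == m2["config_sha256"]
    assert m1["version"]


def test_empty_scenario_set(config, example_design):
    report, m = run_scenarios(config, [], designs={"todo": example_design})
    assert len(report) == 0


def test_report_rows_per_method(config, example_design):
    scen = builtin_scenarios("table1")[:2]
    report, m = run_scenarios(config, scen,
                              methods=("todo", "dreamm2"),
                              designs={"todo": example_design})
    assert len(report) == 4
    assert set(report["method"]) == {"todo", "dreamm2"}
    sums = report[["sel_d1_pct", "sel_d2_pct", "sir_pct", "none_pct"]].sum(axis=1)
    assert np.allclose(sums, 100.0, atol=1e-6)
    # the comparator design never returns an inconclusive outcome
    assert (report.query("method == 'dreamm2'")["sir_pct"] == 0).all()
    assert "todo" in m["designs"]


def test_wl_sweep_gap_shrinks(config, example_design):
    scen = [builtin_scenarios("table1")[1]]
    table, _ = wl_sweep(config, wl_grid=[0.0, 0.5, 1.0],
                        design=example_design, scenario_set=scen)
    gaps = table.groupby("wl").first().eval("c2 - c1")
    assert gaps.loc[1.0] == 0.0
    assert (np.diff(gaps.to_numpy()) <= 1e-12).all()


class TestCli:

    def _cfg(self, tmp_path, extra=None):
        cfg = {"design": dict(BASE["design"]), "execution": {"seed": 1},
               "output": {"directory": str(tmp_path / "out")}}
        if extra:
            cfg["design"].update(extra)
        path = tmp_path / "config.json"
        path.write_text(json.dumps(cfg))
        return str(path)

    def test_calibrate_and_analyze(self, tmp_path):
        runner = CliRunner()
        cfg = self._cfg(tmp_path)
        res = runner.invoke(cli_main, ["calibrate", cfg])
        assert res.exit_code == 0, res.output
        out = tmp_path / "out"
        design = json.loads((out / "design.json").read_text())
        assert design["c1"] <= design["c2"]
        assert (out / "step1_trace.csv").exists()
        assert json.loads((out / "manifest.json").read_text())["seed"] == 1

        res = runner.invoke(cli_main, [
            "analyze", cfg, "--counts", "12,29,13,29",
            "--design-file", str(out / "design.json")])
        assert res.exit_code == 0, res.output
        result = json.loads(res.output)
        assert result["decision"] in {"none", "select_d1", "select_d2",
                                      "inconclusive"}

    def test_decision_table_command(self, tmp_path):
        runner = CliRunner()
        cfg = self._cfg(tmp_path)
        res = runner.invoke(cli_main, ["decision-table", cfg, "--no-plot"])
        assert res.exit_code == 0, res.output
        interim = pd.read_csv(tmp_path / "out" / "decision_interim.csv")
        assert {"y1", "y2", "continue_d1", "continue_d2"} <= set(interim)
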