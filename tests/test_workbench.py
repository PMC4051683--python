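"""Config validation, pipeline orchestration, CLI entry points."""

import filecmp
import json

import numpy as np
import pytest
from click.testing import CliRunner

from memdiff.cli import main as cli_main
from memdiff.config import ConfigError, config_errors, validate_config
from memdiff.io import write_curve, write_peak_table, write_profile
from memdiff.pipeline import STAGES, run_pipeline
from memdiff.synthetic import (
    analytic_form_factors,
    default_gel_model,
    simulate_intensity_curve,
)

from conftest import model_f0


def _minimal_config(tmp_path, **overrides):
    cfg = {
        "seed": 11,
        "sample": {"name": "minimal", "lipids": {"DMPC": 1.0}},
        "output_dir": str(tmp_path / "out"),
    }
    cfg.update(overrides)
    return cfg


class TestConfigValidation:
    def test_minimal_valid_config_accepted(self, tmp_path):
        cfg = validate_config(_minimal_config(tmp_path))
        assert cfg.seed == 11
        assert cfg.name == "minimal"

    def test_fraction_sum_flagged(self, tmp_path):
        raw = _minimal_config(tmp_path)
        raw["sample"]["lipids"] = {"DMPC": 0.97, "DMPS": 0.05}
        errs = config_errors(raw)
        assert any("sum" in e for e in errs)

    def test_unknown_species_without_formula_flagged(self, tmp_path):
        raw = _minimal_config(tmp_path)
        raw["sample"]["lipids"] = {"octanol": 1.0}
        errs = config_errors(raw)
        assert any("octanol" in e for e in errs)

    def test_custom_species_accepted(self, tmp_path):
        raw = _minimal_config(tmp_path)
        raw["sample"]["species"] = [{"name": "octanol", "formula": "C8H18O"}]
        raw["sample"]["lipids"] = {"octanol": 1.0}
        assert config_errors(raw) == []

    def test_missing_seed_flagged(self, tmp_path):
        raw = _minimal_config(tmp_path)
        del raw["seed"]
        errs = config_errors(raw)
        assert any("seed" in e for e in errs)

    def test_unknown_analysis_option_flagged(self, tmp_path):
        raw = _minimal_config(tmp_path, analysis={"wavelength": 1.54})
        errs = config_errors(raw)
        assert any("wavelength" in e for e in errs)

    def test_missing_file_flagged(self, tmp_path):
        raw = _minimal_config(tmp_path,
                              files={"reflectivity": str(tmp_path / "nope.txt")})
        errs = config_errors(raw)
        assert any("nope.txt" in e for e in errs)

    def test_validate_raises_structured_error(self, tmp_path):
        raw = _minimal_config(tmp_path)
        del raw["seed"]
        raw["sample"]["lipids"] = {"DMPC": 0.9}
        with pytest.raises(ConfigError) as err:
            validate_config(raw)
        assert len(err.value.errors) == 2

    def test_yaml_text_accepted(self, tmp_path):
        text = f"""
seed: 5
sample:
  name: yaml-sample
  lipids:
    DMPC: 1.0
output_dir: {tmp_path / "out"}
"""
        cfg = validate_config(text)
        assert cfg.name == "yaml-sample"

    def test_invalid_yaml_reported(self):
        errs = config_errors("seed: [unclosed")
        assert errs and "YAML" in errs[0]


@pytest.fixture(scope="module")
def e2e_setup(tmp_path_factory):
    """Synthetic end-to-end run with full ground truth.

    Sample = gel bilayer plus a mirrored Gaussian 'peptide' insertion at
    12 Å; reference = the gel bilayer alone, written as an absolute
    profile.  The composition is tuned so the electron budget and center
    density equal the model's true values, making the reconstruction
    comparable to the model on the absolute scale.
    """
    from memdiff.synthetic import BilayerModel

    tmp = tmp_path_factory.mktemp("e2e")
    gel = default_gel_model()
    d, A_L = gel.d_spacing, 40.95
    insertion = (12.0, 2.0, 0.06)
    sample = BilayerModel(d, gel.components + (insertion,))

    for name, dd, seed in (("primary.txt", d, 101), ("swell.txt", 60.0, 102)):
        ffs = analytic_form_factors(sample.with_d(dd), 10)
        write_curve(tmp / name,
                    simulate_intensity_curve(ffs, 0.01, (0.0, 50.0), seed))

    # reference profile: water level + periodized gel contrast
    z = np.linspace(-d / 2, d / 2, 1025)
    contrast = sum(gel.density(z + m * d) - gel.water_level for m in (-1, 0, 1))
    write_profile(tmp / "reference.tsv", z, gel.water_level + contrast,
                  {"d_spacing": d})

    # in-plane fixture + published-style peak tables
    from memdiff.synthetic import write_fixtures

    write_fixtures(tmp / "fx", seed=2024)
    import pandas as pd

    def table(chain, p110, p200):
        return pd.DataFrame({"label": ["chain", "[110]", "[200]"],
                             "position": [1.49, 1.19, 1.32],
                             "width": [0.05, 0.008, 0.008],
                             "amplitude": [1.0, 1.0, 1.0],
                             "area": [chain, p110, p200]})

    write_peak_table(tmp / "before.tsv", table(1216.0, 73.0, 98.0))
    write_peak_table(tmp / "after.tsv", table(552.0, 63.0, 158.0))

    budget = A_L * (gel.water_level * d + model_f0(sample)) / 2.0
    raw = {
        "seed": 314,
        "sample": {
            "name": "e2e", "lipids": {"DMPC": 1.0},
            "waters_per_lipid": (budget - 374.0) / 10.0,
            "area_per_lipid": A_L, "lamellar_spacing": d,
        },
        "analysis": {
            "center_density": float(sample.density(0.0)),
            "k_components": 1, "d_hint": d,
            "pose_angle_step": 90.0, "pose_z_step": 1.0,
        },
        "files": {
            "reflectivity": str(tmp / "primary.txt"),
            "swelling": [str(tmp / "swell.txt")],
            "inplane": str(tmp / "fx" / "inplane_gel.txt"),
            "reference_profile": str(tmp / "reference.tsv"),
            "pdb": str(tmp / "fx" / "helix_25_35.pdb"),
            "peak_table_before": str(tmp / "before.tsv"),
            "peak_table_after": str(tmp / "after.tsv"),
        },
        "output_dir": str(tmp / "out"),
    }
    return tmp, raw, sample, insertion, A_L


class TestPipelineEndToEnd:
    def test_full_run_reproduces_ground_truth(self, e2e_setup):
        tmp, raw, sample, insertion, A_L = e2e_setup
        summary = run_pipeline(validate_config(raw))

        assert summary["d_spacings"][0] == pytest.approx(55.07, abs=0.1)

        truth_ffs = analytic_form_factors(sample, 10)
        detected = summary["orders"][0]
        truth_signs = [int(truth_ffs.signs[n - 1]) for n in detected]
        assert summary["signs"] == truth_signs

        assert summary["head_peak_z"] == pytest.approx(22.0, abs=1.0)

        comp = summary["components"][0]
        assert comp["position"] == pytest.approx(insertion[0], abs=1.5)
        # per-leaflet count: mirrored partner belongs to the other leaflet
        true_electrons = A_L * insertion[2] * insertion[1] * np.sqrt(2 * np.pi)
        assert comp["electrons"] == pytest.approx(true_electrons, rel=0.25)
        assert summary["embedded_fraction"] == pytest.approx(100.0)

        assert np.isfinite(summary["pose"]["score"])
        assert 0.0 <= summary["pose"]["z_shift"] <= 55.07 / 2

        ip = summary["inplane"]
        assert ip["chain_q"] == pytest.approx(1.49, abs=0.01)
        assert ip["tail_spacing"] == pytest.approx(4.87, abs=0.02)
        assert ip["plaque_area_change_pct"] == pytest.approx(29.24, abs=0.01)
        assert ip["chain_area_change_pct"] == pytest.approx(-54.6, abs=0.1)
        assert ip["lattice"]["a"] == pytest.approx(9.76, abs=0.05)
        assert ip["lattice"]["b"] == pytest.approx(7.56, abs=0.05)

        out = tmp / "out"
        for artifact in ("bragg_peaks.tsv", "density_profile.tsv",
                         "components.tsv", "pose.json", "summary.json"):
            assert (out / artifact).exists()

    def test_rerun_is_byte_identical(self, e2e_setup):
        tmp, raw, *_ = e2e_setup
        raw_a = dict(raw, output_dir=str(tmp / "rerun_a"))
        raw_b = dict(raw, output_dir=str(tmp / "rerun_b"))
        run_pipeline(validate_config(raw_a), stages=("peaks", "phase",
                                                     "density", "diff"))
        run_pipeline(validate_config(raw_b), stages=("peaks", "phase",
                                                     "density", "diff"))
        names = sorted(p.name for p in (tmp / "rerun_a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp / "rerun_a", tmp / "rerun_b", names, shallow=False)
        assert mismatch == [] and errors == []


class TestStageDependencies:
    def _cfg(self, tmp_path):
        return validate_config(_minimal_config(tmp_path))

    @pytest.mark.parametrize("stage,needs", [
        ("phase", "peaks"),
        ("density", "phase"),
        ("locate", "diff"),
    ])
    def test_missing_upstream_named(self, tmp_path, stage, needs):
        with pytest.raises(RuntimeError, match=needs):
            run_pipeline(self._cfg(tmp_path), stages=(stage,))

    def test_unknown_stage_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown stage"):
            run_pipeline(self._cfg(tmp_path), stages=("peaks", "wavelets"))

    def test_stage_order_is_dependency_order(self):
        assert STAGES == ("peaks", "phase", "density", "diff", "locate",
                          "inplane")


class TestCli:
    def test_simulate_writes_fixture_pack(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--outdir",
                                       str(tmp_path / "fx"), "--seed", "9"])
        assert res.exit_code == 0, res.output
        manifest = json.loads(res.output)
        assert (tmp_path / "fx" / "gel_55.07.txt").exists()
        assert manifest["seed"] == 9

    def test_invalid_config_exits_2(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("sample:\n  lipids:\n    DMPC: 0.5\n")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["peaks", str(bad)])
        assert res.exit_code == 2

    def test_analysis_failure_exits_1(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "seed: 1\n"
            "sample:\n  name: x\n  lipids:\n    DMPC: 1.0\n"
            f"output_dir: {tmp_path / 'out'}\n")
        runner = CliRunner()
        # peaks stage without a reflectivity file -> analysis failure
        res = runner.invoke(cli_main, ["peaks", str(cfg)])
        assert res.exit_code == 1
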