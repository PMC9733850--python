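"""I/O round trips, configuration validation, pipeline and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import lamellaflex as lf
from lamellaflex import io as lio
from lamellaflex.cli import main
from lamellaflex.errors import DegenerateLipidError, FileFormatError
from lamellaflex.pipeline import RunConfig, run_pipeline


@pytest.fixture()
def small_config():
    spec = lf.UndulationSpec(amplitude=6.0, wavelength=80.0, angular_noise_sd=4.0, seed=5)
    return lf.generate_undulated_multilayer(4, 25, spec, beads_per_lipid=5)


class TestGroRoundTrip:
    def test_write_read_identical_within_format_precision(self, small_config, tmp_path):
        path = tmp_path / "stack.gro"
        lio.write_gro(small_config, path)
        back = lio.read_gro(path)
        # GRO stores nm to 3 decimals -> 0.01 A position precision
        assert np.abs(back.bead_positions - small_config.bead_positions).max() <= 0.0051
        assert np.array_equal(back.lipid_id, small_config.lipid_id)
        assert np.array_equal(back.layer_index, small_config.layer_index)
        assert np.array_equal(back.bead_role, small_config.bead_role)
        assert np.allclose(back.box, small_config.box, atol=0.01)

    def test_second_round_trip_bit_identical(self, small_config, tmp_path):
        p1, p2 = tmp_path / "a.gro", tmp_path / "b.gro"
        lio.write_gro(small_config, p1)
        lio.write_gro(lio.read_gro(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_missing_head_bead_rejected(self, small_config, tmp_path):
        path = tmp_path / "bad.gro"
        small_config.bead_role[small_config.lipid_id == 0] = "tail"
        lio.write_gro(small_config, path)
        with pytest.raises(DegenerateLipidError):
            lio.read_gro(path)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.gro"
        path.write_text("")
        with pytest.raises(FileFormatError):
            lio.read_gro(path)

    def test_malformed_coordinates_reported_with_line_number(self, small_config, tmp_path):
        path = tmp_path / "mangled.gro"
        lio.write_gro(small_config, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5][:20] + "  xx.xxx" + lines[5][28:]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FileFormatError, match="line 6"):
            lio.read_gro(path)


class TestXyzRoundTrip:
    def test_write_read_exact(self, small_config, tmp_path):
        path = tmp_path / "stack.xyz"
        lio.write_xyz(small_config, path)
        back = lio.read_xyz(path)
        assert np.abs(back.bead_positions - small_config.bead_positions).max() < 1e-5
        assert np.array_equal(back.bead_role, small_config.bead_role)
        assert np.array_equal(back.layer_index, small_config.layer_index)


class TestTableAndProfileIO:
    def test_scattering_profile_round_trip(self, tmp_path):
        q = np.linspace(1.2, 1.8, 64)
        prof = lf.generate_scattering_profile([(1.5, 0.05, 10.0)], (1.0, 0.0), q, label="demo")
        path = tmp_path / "profile.dat"
        lio.write_scattering_profile(prof, path)
        back = lio.read_scattering_profile(path)
        assert np.allclose(back.q, prof.q)
        assert np.allclose(back.intensity, prof.intensity)

    def test_buckle_table_round_trip(self, tmp_path):
        obs = lf.generate_buckle_dataset(6, 0.22, 42e6, rel_noise=0.05, seed=1)
        path = tmp_path / "buckles.tsv"
        lio.write_buckle_table(obs, path)
        back = lio.read_buckle_table(path)
        got = np.array([(o.lam, o.t, o.eps) for o in back])
        expected = np.array([(o.lam, o.t, o.eps) for o in obs])
        assert np.allclose(got, expected)

    def test_topography_csv_and_tiff_round_trip(self, tmp_path):
        topo = lf.generate_topography(32, 16, 10.0, wrinkle_amplitude=3.0,
                                      wrinkle_wavelength=80.0)
        csv_path, tif_path = tmp_path / "map.csv", tmp_path / "map.tif"
        lio.write_topography_csv(topo, csv_path)
        lio.write_topography_tiff(topo, tif_path)
        for back in (lio.read_topography_csv(csv_path), lio.read_topography_tiff(tif_path)):
            assert back.pixel_size == 10.0
            assert np.allclose(back.heights, topo.heights, atol=1e-4)


class TestRunConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception, match="extra|unexpected"):
            RunConfig.model_validate({"seed": 1, "bogus_stage": {}})

    def test_invalid_strain_rejected_before_computation(self):
        with pytest.raises(Exception, match="strain"):
            RunConfig.model_validate({"adhesion": {"strains": [0.05, 1.5]}})

    def test_pipeline_runs_and_is_deterministic(self, tmp_path):
        cfg = {
            "seed": 3,
            "out_dir": str(tmp_path / "run1"),
            "multilayer": {"lipids_per_layer": 100, "segments": 10},
            "scattering": {"orders": None},
            "adhesion": {"rel_noise": 0.1},
            "topography": {"nx": 128, "ny": 32},
        }
        bundle1 = run_pipeline(RunConfig.model_validate(cfg))
        cfg["out_dir"] = str(tmp_path / "run2")
        bundle2 = run_pipeline(RunConfig.model_validate(cfg))
        j1 = json.loads((tmp_path / "run1" / "results.json").read_text())
        j2 = json.loads((tmp_path / "run2" / "results.json").read_text())
        j1["provenance"]["config"].pop("out_dir")
        j2["provenance"]["config"].pop("out_dir")
        assert j1 == j2
        assert bundle1["adhesion"]["gamma_J_per_m2"] > 0
        assert bundle1["scattering"]["peaks"][0]["spacing_A"] == pytest.approx(4.15, abs=0.01)
        assert bundle2["multilayer"]["p2_lipid_director"] == pytest.approx(1.0)


class TestCli:
    def test_simulate_and_fit_adhesion(self, tmp_path):
        runner = CliRunner()
        table = tmp_path / "buckles.tsv"
        res = runner.invoke(main, ["simulate", "buckles", "--n", "12", "--rel-noise", "0.0",
                                   "--seed", "1", "--out", str(table)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "fit.json"
        res = runner.invoke(main, ["fit-adhesion", str(table), "--e-mpa", "42",
                                   "--out", str(out)])
        assert res.exit_code == 0, res.output
        record = json.loads(out.read_text())
        assert record["gamma_J_per_m2"] == pytest.approx(0.22, rel=1e-6)

    def test_simulate_profile_and_fit_scattering(self, tmp_path):
        runner = CliRunner()
        prof = tmp_path / "profile.dat"
        res = runner.invoke(main, ["simulate", "profile", "--peak", "1.5141,0.061003,100",
                                   "--background", "2,0", "--q-range", "1.2,1.8",
                                   "--n-points", "400", "--out", str(prof)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["fit-scattering", str(prof), "--window", "1.35,1.68"])
        assert res.exit_code == 0, res.output
        record = json.loads(res.output)
        assert record["spacing_A"] == pytest.approx(4.15, abs=0.01)
        assert record["xi_A"] == pytest.approx(103.0, abs=1.0)

    def test_multilayer_order_and_tilt_hist(self, tmp_path):
        runner = CliRunner()
        gro = tmp_path / "stack.gro"
        res = runner.invoke(main, ["simulate", "multilayer", "--n-layers", "2",
                                   "--lipids-per-layer", "100", "--beads-per-lipid", "5",
                                   "--out", str(gro)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["order", str(gro), "--reference", "director"])
        assert res.exit_code == 0, res.output
        # GRO stores 0.001-nm positions, so rigid rods are only as straight
        # as the format precision allows
        assert json.loads(res.output)["p2"] == pytest.approx(1.0, abs=1e-3)
        hist = tmp_path / "hist.txt"
        res = runner.invoke(main, ["tilt-hist", str(gro), "--out", str(hist)])
        assert res.exit_code == 0, res.output
        assert hist.exists()

    def test_topography_command(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "map.csv"
        res = runner.invoke(main, ["simulate", "topography", "--shape", "256,32",
                                   "--wrinkle-amplitude", "6.2225",
                                   "--wrinkle-wavelength", "640", "--out", str(csv)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["topography", str(csv)])
        assert res.exit_code == 0, res.output
        assert json.loads(res.output)["rms_roughness_nm"] == pytest.approx(4.4, abs=0.05)

    def test_run_subcommand_with_invalid_config_exits_nonzero(self, tmp_path):
        cfg = tmp_path / "bad.json"
        cfg.write_text(json.dumps({"adhesion": {"strains": [2.0]}}))
        runner = CliRunner()
        res = runner.invoke(main, ["run", str(cfg)])
        assert res.exit_code == 2
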