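"""Directors, tilt statistics, P2 order parameters, inter-layer correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lamellaflex as lf
from lamellaflex.errors import (
    DegenerateLipidError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from lamellaflex.synthetic import straight_chain_configuration

SLOPE_22_5 = math.tan(math.radians(22.5))


def _rotate_config_about_z(config, angle_deg):
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a), 0.0],
                  [math.sin(a), math.cos(a), 0.0],
                  [0.0, 0.0, 1.0]])
    return lf.LipidConfiguration(
        bead_positions=config.bead_positions @ R.T,
        lipid_id=config.lipid_id.copy(),
        layer_index=config.layer_index.copy(),
        bead_role=config.bead_role.copy(),
        box=config.box.copy(),
    )


class TestDirectors:
    def test_vertical_and_horizontal_chains(self):
        config = straight_chain_configuration(np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
                                              beads_per_lipid=3, bond_length=10.0)
        field = lf.compute_directors(config)
        assert np.allclose(field.vectors[0], [0, 0, 1])
        assert np.allclose(field.vectors[1], [1, 0, 0])
        angles = lf.tilt_angles(field)
        assert angles[0] == pytest.approx(0.0)
        assert angles[1] == pytest.approx(90.0)

    def test_downward_chain_folded_to_upper_hemisphere(self):
        config = straight_chain_configuration(np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]]))
        field = lf.compute_directors(config)
        assert np.allclose(field.vectors[:, 2], 1.0)

    def test_degenerate_lipid_reported_with_id(self):
        config = straight_chain_configuration(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]))
        # collapse the second lipid onto a point
        config.bead_positions[config.lipid_id == 1] = [5.0, 5.0, 5.0]
        with pytest.raises(DegenerateLipidError, match="1"):
            lf.compute_directors(config)

    def test_principal_axis_agrees_for_rigid_rods(self, undulated_multilayer):
        h2t = lf.compute_directors(undulated_multilayer)
        pa = lf.compute_directors(undulated_multilayer, method="principal_axis")
        assert np.abs(h2t.vectors - pa.vectors).max() < 1e-9


class TestTiltHistogram:
    def test_all_zero_angles_mode_in_first_bin(self):
        hist = lf.tilt_histogram(np.zeros(100))
        assert hist.modal_angle == pytest.approx(0.5)
        assert hist.counts[0] == 100

    def test_modal_bin_at_max_slope_of_undulation(self, undulated_multilayer):
        field = lf.compute_directors(undulated_multilayer)
        hist = lf.tilt_histogram(lf.tilt_angles(field), bin_width=1.0)
        assert abs(hist.modal_angle - 22.5) <= 1.0
        assert hist.n_lipids == 10000

    def test_uniform_angles_nearly_flat(self, rng):
        angles = rng.uniform(0.0, 90.0, size=1_000_000)
        hist = lf.tilt_histogram(angles, bin_width=1.0)
        assert hist.counts.max() / hist.counts.min() < 1.1

    def test_tie_broken_toward_smaller_angle(self):
        hist = lf.tilt_histogram([5.5, 10.5], bin_width=1.0)
        assert hist.modal_angle == pytest.approx(5.5)

    def test_invalid_bin_width(self):
        with pytest.raises(InvalidParameterError):
            lf.tilt_histogram([1.0], bin_width=0.0)


class TestOrderParameterP2:
    def test_bonds_along_normal_give_exactly_one(self):
        config = straight_chain_configuration(
            np.tile([0.0, 0.0, 1.0], (50, 1)), beads_per_lipid=4
        )
        assert lf.order_parameter_p2(config).p2 == 1.0

    def test_in_plane_bonds_give_exactly_minus_half(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * np.pi, size=50)
        directions = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(50)])
        config = straight_chain_configuration(directions, beads_per_lipid=4)
        assert lf.order_parameter_p2(config).p2 == -0.5

    def test_isotropic_bonds_give_zero_within_sampling_bound(self, rng):
        n = 100_000
        v = rng.normal(size=(n, 3))
        config = straight_chain_configuration(v, beads_per_lipid=3)
        result = lf.order_parameter_p2(config)
        assert abs(result.p2) < 3.0 / math.sqrt(n)
        assert result.n_bonds == n

    def test_undulation_p2_matches_quadrature_and_decreases_with_amplitude(self):
        # oracle: numeric quadrature of (3 cos^2 theta - 1)/2 over the sinusoid,
        # cos^2 theta = 1 / (1 + (A k cos(k x))^2)
        previous = 1.0
        for slope_max in (0.1, 0.3, SLOPE_22_5, 0.7):
            A = slope_max * 200.0 / (2 * math.pi)
            spec = lf.UndulationSpec(amplitude=A, wavelength=200.0, seed=0)
            config = lf.generate_undulated_multilayer(2, 2500, spec)
            p2 = lf.order_parameter_p2(config).p2
            x = np.linspace(0.0, 2 * math.pi, 400001)
            cos2 = 1.0 / (1.0 + (slope_max * np.cos(x)) ** 2)
            oracle = float(np.mean(1.5 * cos2 - 0.5))
            assert p2 == pytest.approx(oracle, abs=1e-3)
            assert p2 < previous
            previous = p2

    def test_renormalized_p2_is_one_for_rigid_rods_at_any_amplitude_and_noise(self):
        for amplitude, noise in ((0.0, 0.0), (5.0, 0.0), (13.18, 10.0), (25.0, 20.0)):
            spec = lf.UndulationSpec(amplitude=amplitude, wavelength=200.0,
                                     angular_noise_sd=noise, seed=9)
            config = lf.generate_undulated_multilayer(2, 100, spec)
            assert lf.order_parameter_p2(config, reference="lipid_director").p2 == pytest.approx(
                1.0, abs=1e-12
            )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_p2_bounds_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(64, 3))
        config = straight_chain_configuration(v, beads_per_lipid=3)
        for reference in ("membrane_normal", "lipid_director"):
            p2 = lf.order_parameter_p2(config, reference=reference).p2
            assert -0.5 <= p2 <= 1.0

    def test_rotation_about_z_leaves_outputs_unchanged(self, undulated_multilayer):
        rotated = _rotate_config_about_z(undulated_multilayer, 37.0)
        orig_angles = lf.tilt_angles(lf.compute_directors(undulated_multilayer))
        rot_angles = lf.tilt_angles(lf.compute_directors(rotated))
        assert np.abs(np.sort(orig_angles) - np.sort(rot_angles)).max() < 1e-9
        assert lf.order_parameter_p2(rotated).p2 == pytest.approx(
            lf.order_parameter_p2(undulated_multilayer).p2, abs=1e-9
        )
        assert lf.order_parameter_p2(rotated, reference="lipid_director").p2 == pytest.approx(
            1.0, abs=1e-9
        )


class TestInterlayerCorrelation:
    def test_duplicated_layer_gives_exactly_one(self, undulated_multilayer):
        field = lf.compute_directors(undulated_multilayer)
        corr = lf.interlayer_tilt_correlation(field, 0, 1, segments=50)
        assert corr == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_matches_monte_carlo_oracle(self):
        # amplitude 0, pure director noise: tilts are iid |N(0, sigma)|;
        # oracle = mean(theta)^2 / mean(theta^2) of that distribution by MC
        spec = lf.UndulationSpec(amplitude=0.0, wavelength=200.0,
                                 angular_noise_sd=10.0, seed=3)
        config = lf.generate_undulated_multilayer(2, 5000, spec)
        field = lf.compute_directors(config)
        corr = lf.interlayer_tilt_correlation(field, 0, 1, segments=71)
        rng = np.random.default_rng(12345)
        theta = np.abs(rng.normal(0.0, 10.0, size=2_000_000))
        oracle = theta.mean() ** 2 / np.mean(theta**2)
        assert corr == pytest.approx(oracle, abs=0.05)

    def test_correlation_increases_with_undulation_amplitude(self):
        corrs = []
        for amplitude in (2.0, 8.0, 20.0):
            spec = lf.UndulationSpec(amplitude=amplitude, wavelength=200.0,
                                     angular_noise_sd=6.0, seed=17)
            config = lf.generate_undulated_multilayer(2, 2500, spec)
            field = lf.compute_directors(config)
            corrs.append(lf.interlayer_tilt_correlation(field, 0, 1, segments=25))
        assert corrs[0] < corrs[1] < corrs[2]

    def test_flat_noiseless_layers_undefined(self, flat_multilayer):
        field = lf.compute_directors(flat_multilayer)
        with pytest.raises(UndefinedCorrelationError):
            lf.interlayer_tilt_correlation(field, 0, 1, segments=5)

    def test_missing_layer_rejected(self, flat_multilayer):
        field = lf.compute_directors(flat_multilayer)
        with pytest.raises(InvalidParameterError):
            lf.interlayer_tilt_correlation(field, 0, 9, segments=5)

    def test_pearson_variant_bounded(self):
        spec = lf.UndulationSpec(amplitude=10.0, wavelength=200.0,
                                 angular_noise_sd=5.0, seed=21)
        config = lf.generate_undulated_multilayer(2, 2500, spec)
        field = lf.compute_directors(config)
        r = lf.interlayer_tilt_correlation(field, 0, 1, segments=25, mode="pearson")
        assert -1.0 <= r <= 1.0
        assert r > 0.5  # in-phase undulation dominates the noise
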