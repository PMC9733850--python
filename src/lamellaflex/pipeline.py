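"""Config-driven pipeline: simulate → analyze → fit, with provenance.

A :class:`RunConfig` declares which stages to run and their parameters.
Unknown keys are rejected and numeric preconditions are validated at
load time, before any computation.  :func:`run_pipeline` executes the
requested stages in order, writes one JSON result record per stage plus
a provenance block (seed, parameters, package version), and preserves
partial results if a later stage fails.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .datatypes import UndulationSpec
from .errors import LamellaflexError

logger = logging.getLogger(__name__)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MultilayerStage(_Block):
    """Generate an undulated multilayer and run the order analysis."""

    n_layers: int = Field(4, ge=1)
    lipids_per_layer: int = Field(2500, ge=2)
    amplitude: float = Field(13.18, ge=0.0)        # A
    wavelength: float = Field(200.0, gt=0.0)       # A
    phase_per_layer: float = 0.0                   # rad
    layer_spacing: float = Field(56.0, gt=0.0)     # A
    angular_noise_sd: float = Field(0.0, ge=0.0)   # degrees
    beads_per_lipid: int = Field(12, ge=2)
    bond_length: float = Field(1.5, gt=0.0)        # A
    bin_width: float = Field(1.0, gt=0.0)          # degrees
    segments: int = Field(50, ge=1)
    correlate_layers: tuple[int, int] | None = (0, 1)
    write_gro: bool = False


class ScatteringStage(_Block):
    """Generate a synthetic profile, fit its peaks and convert them."""

    peaks: list[tuple[float, float, float]] = [(1.5141, 0.061003, 100.0)]
    background: tuple[float, float] = (2.0, 0.0)
    q_min: float = 1.2
    q_max: float = 1.8
    n_points: int = Field(400, ge=8)
    noise_sd: float = Field(0.0, ge=0.0)
    window: tuple[float, float] | None = None
    orders: list[int] | None = None

    @field_validator("peaks")
    @classmethod
    def _positive_widths(cls, v):
        if any(f <= 0 for _, f, _ in v):
            raise ValueError("peak fwhm must be > 0")
        return v


class AdhesionStage(_Block):
    """Generate a buckle dataset and invert it for the adhesion energy."""

    n: int = Field(12, ge=2)
    gamma: float = Field(0.22, gt=0.0)             # J/m^2
    E_mpa: float = Field(42.0, gt=0.0)             # MPa
    thickness_range: tuple[float, float] = (70.0, 150.0)
    strains: tuple[float, ...] = (0.05, 0.10, 0.14)
    rel_noise: float = Field(0.10, ge=0.0, lt=1.0)

    @field_validator("strains")
    @classmethod
    def _strain_fraction(cls, v):
        if any(not (0 < s < 1) for s in v):
            raise ValueError("strains must be fractions in (0, 1)")
        return v


class TopographyStage(_Block):
    """Generate a wrinkled/buckled height map and measure it."""

    nx: int = Field(512, ge=4)
    ny: int = Field(512, ge=4)
    pixel_size: float = Field(10.0, gt=0.0)        # nm
    wrinkle_amplitude: float = 6.2225              # nm
    wrinkle_wavelength: float = Field(640.0, gt=0.0)
    buckles: list[tuple[float, float, float]] = []
    noise_sd: float = Field(0.0, ge=0.0)
    detrend: str = "none"

    @field_validator("detrend")
    @classmethod
    def _known_detrend(cls, v):
        if v not in ("none", "plane", "line"):
            raise ValueError(f"unknown detrend mode {v!r}")
        return v


class RunConfig(_Block):
    """Full pipeline configuration; omitted stages are skipped."""

    seed: int = 0
    out_dir: str = "results"
    verbosity: str = "info"
    multilayer: MultilayerStage | None = None
    scattering: ScatteringStage | None = None
    adhesion: AdhesionStage | None = None
    topography: TopographyStage | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a JSON (or YAML, if available) configuration file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)


def _run_multilayer(stage: MultilayerStage, seed: int, out: Path) -> dict:
    from . import io as lio
    from .order import compute_directors, interlayer_tilt_correlation, order_parameter_p2, tilt_angles, tilt_histogram
    from .synthetic import generate_undulated_multilayer

    spec = UndulationSpec(
        amplitude=stage.amplitude,
        wavelength=stage.wavelength,
        phase_per_layer=stage.phase_per_layer,
        layer_spacing=stage.layer_spacing,
        angular_noise_sd=stage.angular_noise_sd,
        seed=seed,
    )
    config = generate_undulated_multilayer(
        stage.n_layers, stage.lipids_per_layer, spec,
        beads_per_lipid=stage.beads_per_lipid, bond_length=stage.bond_length,
    )
    if stage.write_gro:
        lio.write_gro(config, out / "multilayer.gro")
    field = compute_directors(config)
    hist = tilt_histogram(tilt_angles(field), bin_width=stage.bin_width)
    p2_n = order_parameter_p2(config, reference="membrane_normal")
    p2_d = order_parameter_p2(config, reference="lipid_director")
    result = {
        "n_lipids": int(config.n_lipids),
        "modal_tilt_deg": hist.modal_angle,
        "p2_membrane_normal": p2_n.p2,
        "p2_lipid_director": p2_d.p2,
    }
    if stage.correlate_layers is not None and stage.n_layers > max(stage.correlate_layers):
        l1, l2 = stage.correlate_layers
        result["interlayer_tilt_correlation"] = interlayer_tilt_correlation(
            field, l1, l2, segments=stage.segments
        )
    (out / "tilt_histogram.txt").write_text(
        "\n".join(
            f"{0.5 * (hist.bin_edges[i] + hist.bin_edges[i + 1]):.3f} {int(c)}"
            for i, c in enumerate(hist.counts)
        )
        + "\n"
    )
    return result


def _run_scattering(stage: ScatteringStage, seed: int, out: Path) -> dict:
    import numpy as np

    from .scattering import (
        auto_window,
        correlation_length_from_peak,
        fit_lorentzian_peak,
        lamellar_d_spacing,
        spacing_from_peak,
    )
    from .synthetic import generate_scattering_profile

    q = np.linspace(stage.q_min, stage.q_max, stage.n_points)
    profile = generate_scattering_profile(
        list(stage.peaks), stage.background, q, noise_sd=stage.noise_sd, seed=seed
    )
    fits = []
    for q0, _, _ in stage.peaks:
        window = stage.window or auto_window(profile, q0)
        fits.append(fit_lorentzian_peak(profile, window))
    result = {
        "peaks": [
            {
                "q0_invA": f.q0,
                "fwhm_invA": f.fwhm,
                "spacing_A": spacing_from_peak(f),
                "xi_A": correlation_length_from_peak(f),
                "residual_ss": f.residual_ss,
            }
            for f in fits
        ]
    }
    if stage.orders:
        result["lamellar_d_A"] = lamellar_d_spacing(fits, orders=stage.orders)
    return result


def _run_adhesion(stage: AdhesionStage, seed: int, out: Path) -> dict:
    from . import io as lio
    from .ruga import fit_adhesion_energy
    from .synthetic import generate_buckle_dataset

    obs = generate_buckle_dataset(
        stage.n, stage.gamma, stage.E_mpa * 1e6,
        thickness_range=stage.thickness_range, strains=stage.strains,
        rel_noise=stage.rel_noise, seed=seed,
    )
    lio.write_buckle_table(obs, out / "buckles.tsv")
    fit = fit_adhesion_energy(obs, E_f=stage.E_mpa * 1e6)
    return {
        "gamma_J_per_m2": fit.gamma_hat,
        "gamma_se": fit.gamma_se,
        "slope": fit.slope_m,
        "n": fit.n_obs,
        "gamma_true": stage.gamma,
    }


def _run_topography(stage: TopographyStage, seed: int, out: Path) -> dict:
    from .ruga import extract_buckle_geometry, rms_roughness
    from .synthetic import generate_topography

    topo = generate_topography(
        stage.nx, stage.ny, stage.pixel_size,
        wrinkle_amplitude=stage.wrinkle_amplitude,
        wrinkle_wavelength=stage.wrinkle_wavelength,
        buckles=list(stage.buckles), noise_sd=stage.noise_sd, seed=seed,
    )
    result = {"rms_roughness_nm": rms_roughness(topo, detrend=stage.detrend)}
    if stage.buckles:
        mid = topo.heights[topo.heights.shape[0] // 2]
        widest = max(w for _, w, _ in stage.buckles)
        regions = extract_buckle_geometry(mid, topo.pixel_size, max_buckle_width=widest)
        result["buckles"] = [{"width_nm": w, "height_nm": h} for w, h in regions]
    return result


_STAGES = (
    ("multilayer", _run_multilayer),
    ("scattering", _run_scattering),
    ("adhesion", _run_adhesion),
    ("topography", _run_topography),
)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write ``results.json``.

    Returns the result bundle.  A stage failure raises after logging the
    stage name; results of completed stages are already on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "provenance": {
            "seed": config.seed,
            "version": __version__,
            "config": json.loads(config.model_dump_json()),
        }
    }
    results_path = out / "results.json"
    for name, runner in _STAGES:
        stage = getattr(config, name)
        if stage is None:
            continue
        try:
            bundle[name] = runner(stage, config.seed, out)
        except LamellaflexError:
            logger.error("stage %r failed", name)
            results_path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
            raise
        results_path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return bundle
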