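"""Seeded generators for every input the analysis pipeline consumes.

Four generators emulate the study's data sources:

* :func:`generate_undulated_multilayer` — stacked bilayers with a
  one-dimensional sinusoidal undulation and optional director noise,
  standing in for coarse-grained MD configurations;
* :func:`generate_scattering_profile` — Lorentzian diffraction peaks on a
  smooth background, emulating azimuthally integrated grazing-incidence
  scattering;
* :func:`generate_topography` — wrinkled/buckled height maps emulating
  AFM topography of a compressed film;
* :func:`generate_buckle_dataset` — noisy (λ, t, ε) buckle-geometry
  observations drawn from the delamination-width model.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
seeds and parameters give bit-identical outputs.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .datatypes import (
    BuckleObservation,
    LipidConfiguration,
    ScatteringProfile,
    TopographyMap,
    UndulationSpec,
)
from .errors import GeometryError, InvalidParameterError
from .ruga import buckle_width_forward
from .datatypes import MechanicsParams

logger = logging.getLogger(__name__)

#: Lateral lattice spacing of the generated lipid grid, Å.  64 Å² per
#: lipid is the gel-phase DPPC scale; exposed as a keyword for tests.
DEFAULT_GRID_SPACING = 8.0


def _undulation_surface(x: np.ndarray, layer: int, spec: UndulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Height and slope of layer ``layer`` at lateral positions ``x``."""
    k = 2.0 * math.pi / spec.wavelength
    phase = k * x + layer * spec.phase_per_layer
    z = layer * spec.layer_spacing + spec.amplitude * np.sin(phase)
    dz_dx = spec.amplitude * k * np.cos(phase)
    return z, dz_dx


def generate_undulated_multilayer(
    n_layers: int,
    lipids_per_layer: int,
    spec: UndulationSpec,
    beads_per_lipid: int = 12,
    bond_length: float = 1.5,
    grid_spacing: float = DEFAULT_GRID_SPACING,
) -> LipidConfiguration:
    """Build a stacked multilayer of rigid straight lipid chains.

    Each layer ``l`` follows the mid-surface
    ``z_l(x) = l*d + A*sin(2*pi*x/wavelength + l*phase_per_layer)``.
    Lipid bases sit on a uniform x–y grid; each lipid is a straight chain
    of ``beads_per_lipid`` beads spaced ``bond_length`` Å apart along the
    local surface normal.  Director noise tilts each chain by an angle
    ``|N(0, angular_noise_sd)|`` (truncated at 90°) about a uniformly
    random azimuth.

    Lipids are rigid rods by construction: conformational (intra-chain)
    disorder is deliberately absent, so any drop in bond order measured
    against the membrane normal is attributable purely to lipid tilt.

    Parameters
    ----------
    n_layers : number of stacked layers (>= 1)
    lipids_per_layer : lipids per layer (>= 2), placed on a near-square grid
    spec : undulation geometry, noise level and seed
    beads_per_lipid : beads per chain (>= 2); first bead is the head,
        last is the terminal bead
    bond_length : inter-bead spacing in Å
    grid_spacing : lateral lattice constant in Å
    """
    if n_layers < 1:
        raise InvalidParameterError("n_layers must be >= 1")
    if lipids_per_layer < 2:
        raise InvalidParameterError("lipids_per_layer must be >= 2")
    if beads_per_lipid < 2:
        raise InvalidParameterError("beads_per_lipid must be >= 2")
    if bond_length <= 0 or grid_spacing <= 0:
        raise InvalidParameterError("bond_length and grid_spacing must be > 0")

    nx = max(2, int(round(math.sqrt(lipids_per_layer))))
    ny = int(math.ceil(lipids_per_layer / nx))
    box_x = nx * grid_spacing
    box_y = ny * grid_spacing
    chain_len = (beads_per_lipid - 1) * bond_length
    if chain_len > min(box_x, box_y):
        raise GeometryError(
            f"lipid footprint ({chain_len:.1f} A) exceeds the lateral box "
            f"({box_x:.1f} x {box_y:.1f} A)"
        )
    box_z = n_layers * spec.layer_spacing + chain_len + 2.0 * spec.amplitude

    rng = np.random.default_rng(spec.seed)
    sigma_rad = math.radians(spec.angular_noise_sd)

    # Uniform sheared lattice, identical in every layer.  Each row is
    # offset along x by grid_spacing/ny so every lipid samples a distinct
    # undulation phase; a square lattice would alias the slope
    # distribution onto nx discrete phases and distort the tilt
    # histogram near its (arcsine-divergent) mode at maximum slope.
    idx = np.arange(lipids_per_layer)
    row = idx // nx
    gx = (idx % nx + (row + 0.5) / ny) * grid_spacing
    gy = (row + 0.5) * grid_spacing

    positions, lipid_ids, layer_ids, roles = [], [], [], []
    lid = 0
    for layer in range(n_layers):
        z0, slope = _undulation_surface(gx, layer, spec)
        # unit surface normal of z = f(x): (-f'(x), 0, 1)/sqrt(1 + f'^2)
        norm = np.sqrt(1.0 + slope**2)
        directors = np.column_stack([-slope / norm, np.zeros_like(slope), 1.0 / norm])

        if sigma_rad > 0:
            delta = np.abs(rng.normal(0.0, sigma_rad, size=lipids_per_layer))
            delta = np.minimum(delta, math.pi / 2)
            psi = rng.uniform(0.0, 2.0 * math.pi, size=lipids_per_layer)
            directors = _tilt_about_random_azimuth(directors, delta, psi)

        base = np.column_stack([gx, gy, z0])
        steps = np.arange(beads_per_lipid) * bond_length
        for i in range(lipids_per_layer):
            chain = base[i] + steps[:, None] * directors[i]
            positions.append(chain)
            lipid_ids.append(np.full(beads_per_lipid, lid))
            layer_ids.append(np.full(beads_per_lipid, layer))
            r = np.array(["tail"] * beads_per_lipid, dtype=object)
            r[0] = "head"
            r[-1] = "terminal"
            roles.append(r)
            lid += 1

    return LipidConfiguration(
        bead_positions=np.vstack(positions),
        lipid_id=np.concatenate(lipid_ids),
        layer_index=np.concatenate(layer_ids),
        bead_role=np.concatenate(roles),
        box=np.array([box_x, box_y, box_z]),
    )


def straight_chain_configuration(
    directions: np.ndarray,
    beads_per_lipid: int = 3,
    bond_length: float = 1.5,
    grid_spacing: float = 10.0,
) -> LipidConfiguration:
    """One straight rigid chain per row of ``directions``, heads on a grid.

    A small construction utility for controlled order-parameter inputs:
    every chain's bond vectors equal its (normalized) direction, so the
    bond-angle distribution is exactly the supplied direction set.
    """
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise InvalidParameterError("directions must be (n, 3)")
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidParameterError("directions must be nonzero")
    if beads_per_lipid < 2:
        raise InvalidParameterError("beads_per_lipid must be >= 2")
    d = d / norms[:, None]
    n = len(d)
    nx = max(2, int(math.ceil(math.sqrt(n))))
    chain_len = (beads_per_lipid - 1) * bond_length
    idx = np.arange(n)
    base = np.column_stack(
        [
            (idx % nx + 0.5) * grid_spacing,
            (idx // nx + 0.5) * grid_spacing,
            np.full(n, chain_len + 1.0),
        ]
    )
    steps = np.arange(beads_per_lipid) * bond_length
    positions = (base[:, None, :] + steps[None, :, None] * d[:, None, :]).reshape(-1, 3)
    roles = np.tile(
        np.array(["head"] + ["tail"] * (beads_per_lipid - 2) + ["terminal"], dtype=object), n
    )
    box_z = 2.0 * chain_len + 2.0
    return LipidConfiguration(
        bead_positions=positions,
        lipid_id=np.repeat(idx, beads_per_lipid),
        layer_index=np.zeros(n * beads_per_lipid, dtype=int),
        bead_role=roles,
        box=np.array([nx * grid_spacing, math.ceil(n / nx) * grid_spacing, box_z]),
    )


def _tilt_about_random_azimuth(directors: np.ndarray, delta: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Tilt each unit vector by angle ``delta`` toward azimuth ``psi``.

    For each director n, an orthonormal frame (e1, e2) perpendicular to n
    is built; the new director is cos(delta)*n + sin(delta)*(cos(psi)*e1 +
    sin(psi)*e2).  This realizes a rotation by delta about a uniformly
    random in-plane axis.
    """
    n = directors
    # a reference vector never parallel to n (n is within 90 deg of +z)
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(n), 1))
    ref[np.abs(n[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    tilt_dir = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
    out = np.cos(delta)[:, None] * n + np.sin(delta)[:, None] * tilt_dir
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def lorentzian(q: np.ndarray, q0: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Peak-normalized Lorentzian: amplitude * (Γ/2)² / ((q-q0)² + (Γ/2)²)."""
    hwhm = fwhm / 2.0
    return amplitude * hwhm**2 / ((q - q0) ** 2 + hwhm**2)


def generate_scattering_profile(
    peaks: list[tuple[float, float, float]],
    background: tuple[float, float],
    q_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> ScatteringProfile:
    """Sum of Lorentzian peaks on a linear background plus Gaussian noise.

    ``peaks`` is a list of (q0 [Å⁻¹], fwhm [Å⁻¹], amplitude) triples;
    the background is ``b0 + b1*q``.  Intensity is clipped at zero after
    adding noise so the profile satisfies the nonnegativity invariant.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or len(q) < 8 or np.any(np.diff(q) <= 0):
        raise InvalidParameterError("q_grid must be strictly increasing with >= 8 points")
    b0, b1 = background
    intensity = b0 + b1 * q
    for q0, fwhm, amp in peaks:
        if fwhm <= 0:
            raise InvalidParameterError("peak fwhm must be > 0")
        if not (q[0] <= q0 <= q[-1]):
            logger.warning("peak position %.4f outside q grid [%.4f, %.4f]", q0, q[0], q[-1])
        intensity = intensity + lorentzian(q, q0, fwhm, amp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(q))
    return ScatteringProfile(q=q, intensity=np.clip(intensity, 0.0, None), label=label)


def generate_topography(
    nx: int,
    ny: int,
    pixel_size: float,
    wrinkle_amplitude: float = 0.0,
    wrinkle_wavelength: float = 1000.0,
    buckles: list[tuple[float, float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TopographyMap:
    """Synthetic height map: sinusoidal wrinkles plus delamination buckles.

    The wrinkle field varies along x only (ridges run along y, i.e.
    perpendicular to the compression axis, as in uniaxially compressed
    films).  Each buckle is a raised-cosine ridge of the given
    (center [nm], width [nm], height [nm]) with support exactly equal to
    its width.  Heights are in nm.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    if wrinkle_wavelength <= 0:
        raise InvalidParameterError("wrinkle_wavelength must be > 0")
    x = np.arange(nx) * pixel_size
    row = np.zeros(nx)
    if wrinkle_amplitude != 0.0:
        row = row + wrinkle_amplitude * np.sin(2.0 * math.pi * x / wrinkle_wavelength)
    for center, width, height in buckles or []:
        if width <= 0:
            raise InvalidParameterError("buckle width must be > 0")
        if width < 2 * pixel_size:
            raise InvalidParameterError(
                f"buckle width {width} nm is below 2 pixels ({2 * pixel_size} nm)"
            )
        u = (x - center) / width
        inside = np.abs(u) < 0.5
        bump = np.zeros(nx)
        bump[inside] = 0.5 * height * (1.0 + np.cos(2.0 * math.pi * u[inside]))
        row = row + bump
    heights = np.tile(row, (ny, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, noise_sd, size=heights.shape)
    return TopographyMap(heights=heights, pixel_size=pixel_size)


def generate_buckle_dataset(
    n: int,
    gamma: float,
    E: float,
    thickness_range: tuple[float, float] = (70.0, 150.0),
    strains: tuple[float, ...] = (0.05, 0.10, 0.14),
    rel_noise: float = 0.0,
    seed: int = 0,
) -> list[BuckleObservation]:
    """Draw (λ, t, ε) observations from the buckle-delamination model.

    Thicknesses are uniform over ``thickness_range`` (nm); strains cycle
    round-robin through ``strains`` so every strain level is represented,
    mirroring the balanced multi-strain design of buckle surveys.  The
    measured width carries multiplicative Gaussian noise,
    ``λ = λ_model * (1 + N(0, rel_noise))``, redrawn if nonpositive.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if rel_noise >= 1:
        raise InvalidParameterError("rel_noise must be < 1")
    if rel_noise < 0:
        raise InvalidParameterError("rel_noise must be >= 0")
    if not all(0 < s < 1 for s in strains):
        raise InvalidParameterError("strains must be fractions in (0, 1)")
    params = MechanicsParams(E_f=E, gamma=gamma)
    rng = np.random.default_rng(seed)
    obs = []
    for i in range(n):
        t = rng.uniform(*thickness_range)
        eps = strains[i % len(strains)]
        lam_model = buckle_width_forward(t, eps, params)
        lam = lam_model
        if rel_noise > 0:
            lam = lam_model * (1.0 + rng.normal(0.0, rel_noise))
            while lam <= 0:
                lam = lam_model * (1.0 + rng.normal(0.0, rel_noise))
        obs.append(BuckleObservation(lam=lam, t=t, eps=eps))
    return obs
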