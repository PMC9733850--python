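"""Core domain containers.

The containers are thin, validated dataclasses around numpy arrays.
Conventions used throughout the package:

* coordinates and box lengths in ångström (Å);
* scattering vectors q in Å⁻¹;
* topography heights and pixel sizes in nanometres (nm);
* buckle widths λ and film thicknesses t in nm, strains dimensionless;
* adhesion energies Γ in J/m², moduli in Pa;
* layer indices are 0-based with layer 0 at the bottom of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

BEAD_ROLES = ("head", "tail", "terminal")


@dataclass
class LipidConfiguration:
    """Bead coordinates of a stacked lipid multilayer.

    Attributes
    ----------
    bead_positions : (n_beads, 3) float array, Å
    lipid_id : (n_beads,) int array — which lipid each bead belongs to
    layer_index : (n_beads,) int array — 0-based layer of each bead
    bead_role : (n_beads,) array of {"head", "tail", "terminal"}
    box : (3,) positive box lengths in Å
    periodic : (3,) booleans
    """

    bead_positions: np.ndarray
    lipid_id: np.ndarray
    layer_index: np.ndarray
    bead_role: np.ndarray
    box: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self):
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        self.lipid_id = np.asarray(self.lipid_id, dtype=int)
        self.layer_index = np.asarray(self.layer_index, dtype=int)
        self.bead_role = np.asarray(self.bead_role, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.bead_positions)
        if self.bead_positions.shape != (n, 3):
            raise InvalidParameterError("bead_positions must be (n, 3)")
        for name in ("lipid_id", "layer_index", "bead_role"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"{name} length must match bead count")
        if not np.all(np.isfinite(self.bead_positions)):
            raise InvalidParameterError("bead coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InvalidParameterError("box must be three positive lengths")
        bad = set(self.bead_role) - set(BEAD_ROLES)
        if bad:
            raise InvalidParameterError(f"unknown bead roles: {sorted(bad)}")

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def n_lipids(self) -> int:
        return len(np.unique(self.lipid_id))

    @property
    def n_layers(self) -> int:
        return len(np.unique(self.layer_index))

    def validate_lipids(self) -> None:
        """Check per-lipid invariants: one head, >=1 terminal, one layer.

        Raises :class:`~lamellaflex.errors.DegenerateLipidError` on the
        first violating lipid.
        """
        from .errors import DegenerateLipidError

        lids, inverse = np.unique(self.lipid_id, return_inverse=True)
        n_heads = np.bincount(inverse, weights=(self.bead_role == "head")).astype(int)
        if np.any(n_heads != 1):
            bad = lids[np.argmax(n_heads != 1)]
            raise DegenerateLipidError(f"lipid {bad} must have exactly one head bead")
        n_term = np.bincount(inverse, weights=(self.bead_role == "terminal")).astype(int)
        if np.any(n_term < 1):
            bad = lids[np.argmax(n_term < 1)]
            raise DegenerateLipidError(f"lipid {bad} must have at least one terminal bead")
        lo = np.full(len(lids), np.iinfo(int).max)
        hi = np.full(len(lids), np.iinfo(int).min)
        np.minimum.at(lo, inverse, self.layer_index)
        np.maximum.at(hi, inverse, self.layer_index)
        if np.any(lo != hi):
            bad = lids[np.argmax(lo != hi)]
            raise DegenerateLipidError(f"lipid {bad} spans multiple layers")
        layers = np.unique(self.layer_index)
        if not np.array_equal(layers, np.arange(len(layers))):
            raise DegenerateLipidError("layer indices must be contiguous from 0")


@dataclass
class UndulationSpec:
    """Sinusoidal undulation imposed on a stacked multilayer.

    The mid-surface of layer ``l`` is z_l(x) = l*d + A*sin(2πx/λ + l*φ);
    ``angular_noise_sd`` adds per-lipid director noise (degrees).
    """

    amplitude: float = 0.0          # Å
    wavelength: float = 200.0       # Å
    phase_per_layer: float = 0.0    # rad; 0 = in-phase stack
    layer_spacing: float = 56.0     # Å, inter-bilayer repeat d
    angular_noise_sd: float = 0.0   # degrees
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        if self.wavelength <= 0:
            raise InvalidParameterError("wavelength must be > 0")
        if self.layer_spacing <= 0:
            raise InvalidParameterError("layer spacing must be > 0")
        if self.angular_noise_sd < 0:
            raise InvalidParameterError("angular noise SD must be >= 0")


@dataclass
class ScatteringProfile:
    """1D scattering intensity vs momentum transfer q (Å⁻¹)."""

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.q) != len(self.intensity) or len(self.q) < 8:
            raise InvalidParameterError("q and intensity must have equal length >= 8")
        if np.any(np.diff(self.q) <= 0):
            raise InvalidParameterError("q must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InvalidParameterError("intensity must be nonnegative")


@dataclass
class PeakFit:
    """Fitted Lorentzian peak: position, width, amplitude, background."""

    q0: float                     # Å⁻¹
    fwhm: float                   # Å⁻¹
    amplitude: float
    background: tuple[float, float]   # (b0, b1), I_bg = b0 + b1*(q - q0)
    residual_ss: float
    window: tuple[float, float]

    def __post_init__(self):
        if not (self.window[0] < self.q0 < self.window[1]):
            raise InvalidParameterError("q0 must lie inside the fit window")
        if self.fwhm <= 0:
            raise InvalidParameterError("fwhm must be > 0")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be > 0")


@dataclass
class BuckleObservation:
    """One delamination buckle: width λ (nm), film thickness t (nm), strain ε."""

    lam: float
    t: float
    eps: float

    def __post_init__(self):
        if self.lam <= 0 or self.t <= 0:
            raise InvalidParameterError("lambda and t must be > 0")
        if not (0 < self.eps < 1):
            raise InvalidParameterError("strain must be a fraction in (0, 1)")


@dataclass
class MechanicsParams:
    """Film mechanics: in-plane Young's modulus E_f (Pa), adhesion Γ (J/m²)."""

    E_f: float
    gamma: float

    def __post_init__(self):
        if self.E_f <= 0:
            raise InvalidParameterError("E_f must be > 0")
        if self.gamma <= 0:
            raise InvalidParameterError("gamma must be > 0")


@dataclass
class AdhesionFit:
    """Result of inverting the buckle-width model for adhesion energy."""

    gamma_hat: float    # J/m²
    gamma_se: float     # J/m²
    slope_m: float      # m^(-1/2): slope of λ/t^1.5 vs sqrt(ε), SI
    n_obs: int


@dataclass
class TopographyMap:
    """Height grid (nm) with a physical pixel size (nm)."""

    heights: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise InvalidParameterError("heights must be a 2D grid")
        if not np.all(np.isfinite(self.heights)):
            raise InvalidParameterError("heights must be finite")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")


@dataclass
class DirectorField:
    """Per-lipid unit orientation vectors with base positions and labels."""

    vectors: np.ndarray        # (n_lipids, 3), unit norm
    base_positions: np.ndarray  # (n_lipids, 3), Å (head bead position)
    layer_index: np.ndarray    # (n_lipids,)
    lipid_id: np.ndarray       # (n_lipids,)
    box: np.ndarray | None = None  # lateral box for segment binning, Å

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.base_positions = np.asarray(self.base_positions, dtype=float)
        self.layer_index = np.asarray(self.layer_index, dtype=int)
        self.lipid_id = np.asarray(self.lipid_id, dtype=int)
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidParameterError("director vectors must be unit norm")

    @property
    def n_lipids(self) -> int:
        return len(self.vectors)


@dataclass
class TiltHistogram:
    """Histogram of lipid tilt angles on [0°, 90°]."""

    bin_edges: np.ndarray    # degrees, len = n_bins + 1
    counts: np.ndarray       # nonnegative ints
    modal_angle: float       # degrees, center of the maximal bin
    n_lipids: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if int(self.counts.sum()) != self.n_lipids:
            raise InvalidParameterError("histogram counts must sum to n_lipids")


@dataclass
class OrderParameterResult:
    """Second-rank (P2) bond order parameter and its reference axis."""

    p2: float
    reference: str            # "membrane_normal" | "lipid_director"
    n_bonds: int

    def __post_init__(self):
        if not (-0.5 - 1e-12 <= self.p2 <= 1.0 + 1e-12):
            raise InvalidParameterError("P2 must lie in [-0.5, 1]")
        if self.reference not in ("membrane_normal", "lipid_director"):
            raise InvalidParameterError(f"unknown reference {self.reference!r}")
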