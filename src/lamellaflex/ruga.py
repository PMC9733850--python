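"""Buckle-delamination mechanics and topography statistics.

A stiff film compressed on a compliant substrate relieves strain through
"ruga" morphologies — wrinkles and delamination buckles.  For a
delaminated buckle, balancing bending, compression and adhesion energy
gives the width law

    λ / t^{3/2} = π · sqrt(2 · E̅_f · ε / Γ)

with buckle width λ, film thickness t, in-plane film modulus E̅_f,
substrate compressive strain ε, and film–substrate adhesion energy Γ.
The law is linear in sqrt(ε) once widths are normalized by t^{3/2}, so a
through-origin regression of λ/t^{3/2} on sqrt(ε) yields a slope
m = π·sqrt(2·E̅_f/Γ) from which Γ = 2π²·E̅_f/m².

This module implements the forward law, its inversion with a
delta-method standard error, and the topography side: RMS roughness and
buckle-geometry extraction from height profiles.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import ndimage

from .datatypes import AdhesionFit, BuckleObservation, MechanicsParams, TopographyMap
from .errors import InvalidParameterError, UnderdeterminedError

logger = logging.getLogger(__name__)

NM = 1e-9

#: Film-thickness band (nm) within which width measurements are
#: considered comparable; outside it a warning is issued, not an error.
THICKNESS_VALIDITY_NM = (70.0, 150.0)


def buckle_width_forward(t: float, eps: float, params: MechanicsParams) -> float:
    """Buckle width λ (nm) predicted for thickness t (nm) and strain eps.

    Evaluates λ = t^{3/2} · π · sqrt(2·E_f·ε/Γ) in SI internally and
    returns nm.  eps = 0 returns exactly 0 (no compression, no buckle).
    """
    if t <= 0:
        raise InvalidParameterError("thickness must be > 0")
    if not (0 <= eps < 1):
        raise InvalidParameterError("strain must lie in [0, 1)")
    if eps == 0:
        return 0.0
    t_m = t * NM
    lam_m = t_m**1.5 * math.pi * math.sqrt(2.0 * params.E_f * eps / params.gamma)
    return lam_m / NM


def fit_adhesion_energy(
    obs: list[BuckleObservation],
    E_f: float,
    poisson_ratio: float | None = None,
) -> AdhesionFit:
    """Invert the buckle-width law for the adhesion energy Γ.

    Performs an unweighted through-origin least-squares fit of
    y = λ/t^{3/2} (SI) on x = sqrt(ε) and converts the slope m to
    Γ̂ = 2π²·E_f/m².  The standard error is first-order (delta-method)
    propagation from the slope SE: σ_Γ = 2·Γ̂·σ_m/m.

    Parameters
    ----------
    obs : buckle observations (λ, t in nm; ε a fraction)
    E_f : in-plane Young's modulus of the film, Pa
    poisson_ratio : if given, E_f is replaced by the plane-strain modulus
        E_f/(1−ν²) — a sensitivity knob; by default the modulus is used
        as supplied.
    """
    if len(obs) < 2:
        raise UnderdeterminedError("need at least 2 observations")
    if E_f <= 0:
        raise InvalidParameterError("E_f must be > 0")
    if poisson_ratio is not None:
        if not (0 <= poisson_ratio < 1):
            raise InvalidParameterError("poisson_ratio must be in [0, 1)")
        E_f = E_f / (1.0 - poisson_ratio**2)

    t_nm = np.array([o.t for o in obs])
    outside = (t_nm < THICKNESS_VALIDITY_NM[0]) | (t_nm > THICKNESS_VALIDITY_NM[1])
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} observation(s) outside the "
            f"{THICKNESS_VALIDITY_NM[0]:.0f}-{THICKNESS_VALIDITY_NM[1]:.0f} nm "
            "thickness validity band",
            stacklevel=2,
        )

    lam_m = np.array([o.lam for o in obs]) * NM
    t_m = t_nm * NM
    x = np.sqrt(np.array([o.eps for o in obs]))
    y = lam_m / t_m**1.5

    sxx = float(np.sum(x * x))
    m = float(np.sum(x * y)) / sxx
    gamma_hat = 2.0 * math.pi**2 * E_f / m**2

    n = len(obs)
    if n > 1:
        ss_res = float(np.sum((y - m * x) ** 2))
        sigma_m = math.sqrt(ss_res / (n - 1) / sxx)
    else:  # pragma: no cover - guarded above
        sigma_m = float("nan")
    gamma_se = 2.0 * gamma_hat * sigma_m / m

    return AdhesionFit(gamma_hat=gamma_hat, gamma_se=gamma_se, slope_m=m, n_obs=n)


def rms_roughness(topo: TopographyMap, detrend: str = "none") -> float:
    """Root-mean-square roughness (nm) of a height map.

    ``detrend`` selects the surface subtracted before the RMS:

    * ``"none"`` — heights minus their global mean;
    * ``"plane"`` — least-squares plane (removes sample tilt);
    * ``"line"`` — per-row least-squares line (AFM scan-line levelling).
    """
    h = topo.heights
    if h.shape[0] < 4 or h.shape[1] < 4:
        raise InvalidParameterError("topography grid must be at least 4x4")
    if detrend == "none":
        resid = h - h.mean()
    elif detrend == "plane":
        ny, nx = h.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        A = np.column_stack([xx.ravel(), yy.ravel(), np.ones(h.size)])
        coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
        resid = h - (A @ coef).reshape(h.shape)
    elif detrend == "line":
        nx = h.shape[1]
        xi = np.arange(nx)
        A = np.column_stack([xi, np.ones(nx)])
        coef, *_ = np.linalg.lstsq(A, h.T, rcond=None)
        resid = h - (A @ coef).T
    else:
        raise InvalidParameterError(f"unknown detrend mode {detrend!r}")
    return float(np.sqrt(np.mean(resid**2)))


def extract_buckle_geometry(
    profile: np.ndarray,
    pixel_size: float,
    max_buckle_width: float | None = None,
    h_min: float = 2.0,
    merge_gap_px: int = 3,
) -> list[tuple[float, float]]:
    """Detect delamination buckles in a 1D height profile.

    The baseline is a running median whose window is five times the
    largest expected buckle width (or the whole profile if none is
    given).  Pixels rising above the baseline by more than
    ``max(3 * 1.4826 * MAD, h_min)`` seed candidate regions; regions
    closer than ``merge_gap_px`` pixels are merged; each region is then
    widened to where the height recrosses the baseline, and its width
    and peak height above baseline are reported.

    Parameters
    ----------
    profile : 1D heights in nm (length >= 16)
    pixel_size : nm per pixel
    max_buckle_width : largest expected buckle width in nm; sets the
        running-median window (5x this width)
    h_min : minimum detection height in nm (default 2 nm, above typical
        film roughness)
    merge_gap_px : regions separated by fewer pixels are merged

    Returns
    -------
    list of (width λ in nm, height in nm), ordered along the profile;
    empty if nothing rises above the threshold.
    """
    h = np.asarray(profile, dtype=float)
    if h.ndim != 1 or len(h) < 16:
        raise InvalidParameterError("profile must be 1D with >= 16 samples")
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")

    if max_buckle_width is None:
        baseline = np.full_like(h, np.median(h))
    else:
        win = int(round(5.0 * max_buckle_width / pixel_size))
        win = max(3, min(win, len(h)))
        if win % 2 == 0:
            win += 1
        baseline = ndimage.median_filter(h, size=win, mode="nearest")

    resid = h - baseline
    mad = float(np.median(np.abs(resid - np.median(resid))))
    threshold = max(3.0 * 1.4826 * mad, h_min)

    core = resid > threshold
    if not np.any(core):
        return []

    # merge nearby cores: closing with a (merge_gap_px)-wide structure
    if merge_gap_px > 1:
        core = ndimage.binary_closing(core, structure=np.ones(merge_gap_px))
    labels, n_regions = ndimage.label(core)

    results: list[tuple[float, float]] = []
    for region in range(1, n_regions + 1):
        idx = np.where(labels == region)[0]
        lo, hi = int(idx[0]), int(idx[-1])
        # widen to the baseline-crossing level
        while lo > 0 and resid[lo - 1] > 0:
            lo -= 1
        while hi < len(h) - 1 and resid[hi + 1] > 0:
            hi += 1
        width = (hi - lo + 1) * pixel_size
        height = float(resid[lo : hi + 1].max())
        results.append((width, height))
    return results
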