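"""Lorentzian peak analysis of 1D grazing-incidence scattering profiles.

Azimuthally integrated GISAXS/GIWAXS intensity I(q) is modelled, within a
user-chosen window, as a single Lorentzian on a locally linear background:

    I(q) = A · (Γ/2)² / ((q − q0)² + (Γ/2)²) + b0 + b1·(q − q0)

The fitted peak position converts to a real-space spacing d = 2π/q0
(bilayer repeat for small-angle peaks, chain-packing spacing for
wide-angle peaks) and the full width at half maximum to an apparent
correlation length ξ = 2π/FWHM.  Lamellar stacks showing several orders
q_n = 2πn/d are indexed and reduced to a single repeat distance.
"""

from __future__ import annotations

import math

import numpy as np
from lmfit import Model

from .datatypes import PeakFit, ScatteringProfile
from .errors import FitFailureError, IndexingError, InvalidFitError, NoPeakError

_TWO_PI = 2.0 * math.pi


def _lorentzian_with_background(q, q0, fwhm, amplitude, b0, b1):
    hwhm = fwhm / 2.0
    return amplitude * hwhm**2 / ((q - q0) ** 2 + hwhm**2) + b0 + b1 * (q - q0)


def _initial_guess(q: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Initialize from the window maximum and its half-height crossings."""
    b0 = float(min(y[0], y[-1]))
    i_max = int(np.argmax(y))
    q0 = float(q[i_max])
    amp = float(y[i_max] - b0)
    half = b0 + amp / 2.0
    above = y >= half
    lo = i_max
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < len(y) - 1 and above[hi + 1]:
        hi += 1
    fwhm = float(q[hi] - q[lo])
    if fwhm <= 0:
        fwhm = float(q[1] - q[0])
    return {"q0": q0, "fwhm": fwhm, "amplitude": max(amp, 1e-12), "b0": b0, "b1": 0.0}


def fit_lorentzian_peak(
    profile: ScatteringProfile, window: tuple[float, float], max_restarts: int = 3
) -> PeakFit:
    """Least-squares Lorentzian fit of one peak inside ``window``.

    The window must contain at least 8 grid points and an interior
    maximum (the profile maximum must not sit on either window edge).
    Initialization comes from the window maximum and the half-height
    crossings; the optimizer is restarted with perturbed widths a
    bounded number of times before giving up.

    Raises
    ------
    NoPeakError : the window holds no interior maximum
    FitFailureError : the optimizer did not converge; carries diagnostics
    """
    q_lo, q_hi = window
    mask = (profile.q >= q_lo) & (profile.q <= q_hi)
    q = profile.q[mask]
    y = profile.intensity[mask]
    if len(q) < 8:
        raise NoPeakError(f"window [{q_lo}, {q_hi}] contains {len(q)} points (< 8)")
    i_max = int(np.argmax(y))
    if i_max in (0, len(q) - 1):
        raise NoPeakError(f"no interior maximum in window [{q_lo}, {q_hi}]")

    guess = _initial_guess(q, y)
    model = Model(_lorentzian_with_background)
    span = float(q[-1] - q[0])

    last_result = None
    for attempt in range(max_restarts + 1):
        params = model.make_params(**guess)
        params["q0"].set(min=q[0], max=q[-1])
        params["fwhm"].set(min=1e-6 * span, max=10.0 * span)
        params["amplitude"].set(min=1e-12)
        result = model.fit(y, params, q=q)
        if result.success and result.params["amplitude"].value > 0:
            return PeakFit(
                q0=float(result.params["q0"].value),
                fwhm=float(result.params["fwhm"].value),
                amplitude=float(result.params["amplitude"].value),
                background=(
                    float(result.params["b0"].value),
                    float(result.params["b1"].value),
                ),
                residual_ss=float(np.sum(result.residual**2)),
                window=(float(q_lo), float(q_hi)),
            )
        last_result = result
        guess = dict(guess, fwhm=guess["fwhm"] * (2.0 ** (attempt + 1)))

    raise FitFailureError(
        f"Lorentzian fit did not converge in window [{q_lo}, {q_hi}]",
        diagnostics={
            "message": getattr(last_result, "message", ""),
            "nfev": getattr(last_result, "nfev", None),
            "window": (q_lo, q_hi),
        },
    )


def auto_window(
    profile: ScatteringProfile, q_near: float, hwhm_factor: float = 5.0
) -> tuple[float, float]:
    """Convenience window around the local maximum nearest ``q_near``.

    Finds the local maximum closest to ``q_near`` and returns a window of
    plus/minus ``hwhm_factor`` times the initial half-width estimate from
    the half-height crossings.
    """
    y = profile.intensity
    interior = np.arange(1, len(y) - 1)
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1])
    candidates = interior[is_max]
    if len(candidates) == 0:
        raise NoPeakError("profile contains no local maximum")
    i_peak = int(candidates[np.argmin(np.abs(profile.q[candidates] - q_near))])
    guess = _initial_guess(profile.q, y)
    # re-estimate the half width around the chosen peak
    half = (y[i_peak] + min(y[0], y[-1])) / 2.0
    lo = i_peak
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = i_peak
    while hi < len(y) - 1 and y[hi + 1] >= half:
        hi += 1
    hwhm = max(float(profile.q[hi] - profile.q[lo]) / 2.0, float(profile.q[1] - profile.q[0]))
    del guess
    center = float(profile.q[i_peak])
    return (center - hwhm_factor * hwhm, center + hwhm_factor * hwhm)


def spacing_from_peak(fit: PeakFit, convention: str = "d") -> float:
    """Real-space spacing (Å) from a fitted peak position.

    ``convention="d"`` (default) returns the d-spacing 2π/q0.
    ``convention="hexagonal"`` returns the hexagonal lattice parameter
    a_hex = 4π/(√3·q0) for chain-packing peaks indexed on a 2D hexagonal
    lattice; reported spacings in the lipid literature usually quote the
    d-spacing, which is the default here.
    """
    if fit.q0 <= 0:
        raise InvalidFitError("q0 must be positive")
    if convention == "d":
        return _TWO_PI / fit.q0
    if convention == "hexagonal":
        return 2.0 * _TWO_PI / (math.sqrt(3.0) * fit.q0)
    raise InvalidFitError(f"unknown spacing convention {convention!r}")


def correlation_length_from_peak(fit: PeakFit) -> float:
    """Apparent correlation length ξ = 2π/FWHM (Å).

    No instrument-resolution deconvolution is applied; the result is the
    apparent (lower-bound) correlation length of the ordered domains.
    """
    if fit.fwhm <= 0:
        raise InvalidFitError("fwhm must be positive")
    return _TWO_PI / fit.fwhm


def lamellar_d_spacing(
    fits: list[PeakFit], orders: list[int] | None = None, max_rel_scatter: float = 0.10
) -> float:
    """Lamellar repeat distance (Å) from one or more diffraction orders.

    For peaks at q_n ≈ 2πn/d the repeat is the through-origin regression
    slope of q0 against the order index n, converted as d = 2π/slope.
    Orders default to 1..len(fits) in the given sequence.  If the
    per-peak ratios q0/n scatter by more than ``max_rel_scatter``
    relative to their mean, the indexing is rejected.
    """
    if len(fits) < 1:
        raise IndexingError("need at least one fitted peak")
    if orders is None:
        orders = list(range(1, len(fits) + 1))
    if len(orders) != len(fits) or any(n < 1 for n in orders):
        raise IndexingError("orders must be positive, one per fit")
    q0 = np.array([f.q0 for f in fits], dtype=float)
    n = np.array(orders, dtype=float)
    ratios = q0 / n
    if len(fits) > 1:
        scatter = (ratios.max() - ratios.min()) / ratios.mean()
        if scatter > max_rel_scatter:
            raise IndexingError(
                f"q0/n scatter {scatter:.1%} exceeds {max_rel_scatter:.0%}: "
                "order assignment inconsistent with peak positions"
            )
    slope = float(np.sum(n * q0) / np.sum(n * n))
    return _TWO_PI / slope
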