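"""Conventional CEST comparison arm.

QUASS quasi-steady-state correction (exact inversion of the transient
saturation model for the single unknown R1rho per offset), multi-pool
Lorentzian Z-spectrum fitting, fitted label/reference spectra and the
MTRRex / MTRAREX inverse-difference metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .signal_model import DEFAULT_B0_T, omega1_from_b1, ppm_to_rad


# ---------------------------------------------------------------------------
# QUASS
# ---------------------------------------------------------------------------

@dataclass
class QuassInput:
    """Transient Z-spectrum plus the saturation timing and relaxation
    knowledge needed to extrapolate it to steady state."""

    z: np.ndarray               # transient Z per offset
    offsets_ppm: np.ndarray
    tsat: float
    trec: float
    r1: float
    b1_ut: float
    b0: float = DEFAULT_B0_T
    z_end: Optional[np.ndarray] = None   # previous readout endpoint per offset

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        if self.tsat <= 0 or self.trec <= 0:
            raise ValueError("tsat and trec must be > 0")
        if self.r1 <= 0:
            raise ValueError("R1 must be > 0")
        if np.any(self.z < -0.1) or np.any(self.z > 1.1):
            raise ValueError("Z values outside the tolerated (-0.1, 1.1) band")


@dataclass
class QuassResult:
    z_ss: np.ndarray
    uncorrectable: np.ndarray   # bool mask of offsets left at input value


def quass_correct(q: QuassInput) -> QuassResult:
    """Per-offset steady-state extrapolation.

    Solves Ztrans = (frec - P2*R1/R1rho) * exp(-Tsat*R1rho) + P2*R1/R1rho
    for R1rho by bracketed root finding and returns Zss = P2*R1/R1rho.
    The recovered starting fraction is frec = 1 - (1 - Zend)*exp(-Trec*R1)
    with Zend the previous offset's readout endpoint (1 by default).
    """
    omega1 = omega1_from_b1(q.b1_ut)
    w = ppm_to_rad(q.offsets_ppm, q.b0)
    p2 = w**2 / (w**2 + omega1**2) if omega1 > 0 else np.ones_like(w)
    if q.z_end is None:
        z_end = np.ones_like(q.z)
    else:
        z_end = np.asarray(q.z_end, dtype=float)
    frec = 1.0 - (1.0 - z_end) * np.exp(-q.trec * q.r1)

    lo, hi = q.r1 * 1e-3, 1e3
    z_ss = q.z.copy()
    bad = np.zeros(q.z.size, dtype=bool)
    for i in range(q.z.size):
        def g(rr, i=i):
            zss = p2[i] * q.r1 / rr
            return (frec[i] - zss) * np.exp(-q.tsat * rr) + zss - q.z[i]
        try:
            if g(lo) * g(hi) > 0:
                raise ValueError
            rr = brentq(g, lo, hi, xtol=1e-12, rtol=1e-10)
            z_ss[i] = p2[i] * q.r1 / rr
        except ValueError:
            bad[i] = True
    return QuassResult(z_ss=z_ss, uncorrectable=bad)


# ---------------------------------------------------------------------------
# Lorentzian fitting
# ---------------------------------------------------------------------------

@dataclass
class LorentzianPoolSpec:
    """Fit template; pool 0 is water (centre 0 ppm)."""

    centers_ppm: Sequence[float] = (0.0, 4.2)
    center_tol_ppm: float = 0.6
    init_widths_ppm: Sequence[float] = (2.0, 1.0)
    init_amplitudes: Sequence[float] = (0.8, 0.01)
    width_bounds_ppm: tuple = (0.05, 20.0)
    max_nfev: int = 400

    @classmethod
    def two_pool(cls, cest_ppm: float = 4.2) -> "LorentzianPoolSpec":
        return cls(centers_ppm=(0.0, cest_ppm))

    @classmethod
    def four_pool(cls) -> "LorentzianPoolSpec":
        """In-vivo template: water, CEST +3.5, NOE -3.5, MT -2 ppm."""
        return cls(centers_ppm=(0.0, 3.5, -3.5, -2.0),
                   init_widths_ppm=(2.0, 1.0, 3.0, 10.0),
                   init_amplitudes=(0.8, 0.01, 0.01, 0.01))


@dataclass
class LorentzianPoolFit:
    z0: float
    amplitudes: np.ndarray
    widths_ppm: np.ndarray
    centers_ppm: np.ndarray
    residual_norm: float
    converged: bool

    def model(self, offsets_ppm) -> np.ndarray:
        return _lorentzian_model(np.asarray(offsets_ppm, dtype=float), self.z0,
                                 self.amplitudes, self.widths_ppm,
                                 self.centers_ppm)


def _lorentzian_model(offsets, z0, amps, widths, centers):
    out = np.full_like(np.asarray(offsets, dtype=float), z0)
    for a, g, c in zip(amps, widths, centers):
        out = out - a * (g**2 / 4.0) / (g**2 / 4.0 + (offsets - c) ** 2)
    return out


def fit_lorentzian(z: np.ndarray, offsets_ppm: np.ndarray,
                   spec: Optional[LorentzianPoolSpec] = None) -> LorentzianPoolFit:
    """Least-squares multi-pool Lorentzian fit of a Z-spectrum.

    Z(dw) = Z0 - sum_i A_i * (G_i^2/4) / (G_i^2/4 + (dw - d_i)^2), centres
    box-bounded near their nominal shifts.
    """
    spec = spec or LorentzianPoolSpec()
    z = np.asarray(z, dtype=float)
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    n_pools = len(spec.centers_ppm)
    if z.size < 2 * (1 + 3 * n_pools) / 2:
        raise ValueError("too few offsets for the requested pool count")

    # deterministic initialization from the data
    z0_init = float(np.max(z))
    amps = list(spec.init_amplitudes)
    amps[0] = max(z0_init - float(np.min(z)), 0.05)

    x0, lb, ub = [z0_init], [0.0], [1.5]
    for i, c in enumerate(spec.centers_ppm):
        x0 += [amps[i], spec.init_widths_ppm[i], c]
        lb += [0.0, spec.width_bounds_ppm[0], c - spec.center_tol_ppm]
        ub += [2.0, spec.width_bounds_ppm[1], c + spec.center_tol_ppm]

    def resid(p):
        return _lorentzian_model(offsets_ppm, p[0], p[1::3], p[2::3], p[3::3]) - z

    res = least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub),
                        method="trf", max_nfev=spec.max_nfev,
                        xtol=1e-12, ftol=1e-12)
    return LorentzianPoolFit(
        z0=float(res.x[0]), amplitudes=res.x[1::3].copy(),
        widths_ppm=res.x[2::3].copy(), centers_ppm=res.x[3::3].copy(),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0))


def label_reference_spectra(fit: LorentzianPoolFit, target_pool: int,
                            offsets_ppm) -> tuple:
    """(Zlab, Zref): full fitted model and the model with the target pool's
    amplitude zeroed.  Zref >= Zlab pointwise."""
    if not (0 <= target_pool < fit.amplitudes.size):
        raise IndexError("target pool not present in fit")
    zlab = fit.model(offsets_ppm)
    amps = fit.amplitudes.copy()
    amps[target_pool] = 0.0
    zref = _lorentzian_model(np.asarray(offsets_ppm, dtype=float), fit.z0,
                             amps, fit.widths_ppm, fit.centers_ppm)
    return zlab, zref


# ---------------------------------------------------------------------------
# Inverse-difference metrics
# ---------------------------------------------------------------------------

def mtr_rex(zlab, zref):
    """MTRRex = 1/Zlab - 1/Zref (spillover/T2-compensated CEST metric)."""
    zlab = np.asarray(zlab, dtype=float)
    zref = np.asarray(zref, dtype=float)
    out = np.full(np.broadcast_shapes(zlab.shape, zref.shape), np.nan)
    ok = (zlab > 0) & (zref > 0)
    out[ok] = 1.0 / zlab[ok] - 1.0 / zref[ok]
    return out


def mtr_arex(zlab, zref, r1):
    """MTRAREX = (1/Zlab - 1/Zref) * R1; equals Rex / cos^2(theta) at
    steady state."""
    return mtr_rex(zlab, zref) * np.asarray(r1, dtype=float)
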