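"""Closed-form CEST + Look-Locker signal model.

Analytic description of a saturation-inversion-Look-Locker experiment:
off-resonant continuous-wave saturation drives the water magnetization
towards a spin-lock steady state ``M0 * P2 * R1w / R1rho`` where the
rotating-frame rate R1rho collects water relaxation and the
exchange-dependent rates Rex of each solute pool (Lorentzian lineshapes).
An inversion pulse then mirrors the transient Z-spectrum, and a spoiled
FLASH train reads out the Look-Locker recovery towards its own driven
steady state.  Chaining the Look-Locker steady state into the next
saturation block closes the signal model for a whole multi-offset
acquisition without recovery delays.

All public interfaces use ppm for spectral quantities; conversion to
angular frequency uses the proton gyromagnetic ratio at the configured
static field (3 T default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Proton gyromagnetic ratio (Hz/T) and default static field (T).
GAMMA_HZ_PER_T = 42.577e6
DEFAULT_B0_T = 3.0


def ppm_to_rad(ppm, b0: float = DEFAULT_B0_T):
    """Convert a chemical-shift offset in ppm to rad/s at field ``b0``."""
    return 2.0 * np.pi * GAMMA_HZ_PER_T * b0 * 1e-6 * np.asarray(ppm, dtype=float)


def rad_to_ppm(rad, b0: float = DEFAULT_B0_T):
    return np.asarray(rad, dtype=float) / (2.0 * np.pi * GAMMA_HZ_PER_T * b0 * 1e-6)


def omega1_from_b1(b1_ut: float) -> float:
    """Saturation amplitude omega1 = gamma * B1 in rad/s for B1 in microtesla."""
    return 2.0 * np.pi * GAMMA_HZ_PER_T * b1_ut * 1e-6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExchangePool:
    """One solute pool exchanging with water.

    fs : relative proton fraction (dimensionless, 0 <= fs < 1)
    ks : exchange rate solute->water (1/s)
    r2s : transverse relaxation rate of the solute pool (1/s)
    delta_ppm : chemical shift of the pool relative to water (ppm, signed)
    r1s : longitudinal relaxation rate of the solute pool (1/s); only the
        numerical Bloch-McConnell simulation uses it.
    """

    fs: float
    ks: float
    r2s: float
    delta_ppm: float
    r1s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fs < 1.0):
            raise ValueError(f"pool fraction fs={self.fs} outside [0, 1)")
        if self.ks <= 0:
            raise ValueError("exchange rate ks must be > 0")
        if self.r2s < 0:
            raise ValueError("solute R2s must be >= 0")


@dataclass
class WaterPool:
    """Bulk water: observed R1 (1/s), R2 (1/s) and equilibrium magnetization."""

    r1: float
    r2: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("water R1 must be > 0")
        if self.m0 <= 0:
            raise ValueError("M0 must be > 0")


@dataclass
class SaturationSpec:
    """Continuous-wave-equivalent saturation block."""

    b1_ut: float
    tprep: float

    def __post_init__(self) -> None:
        if self.tprep <= 0:
            raise ValueError("saturation duration tprep must be > 0")
        if self.b1_ut < 0:
            raise ValueError("B1 amplitude must be >= 0")

    @property
    def omega1(self) -> float:
        return omega1_from_b1(self.b1_ut)


@dataclass
class ReadoutSpec:
    """Spoiled FLASH readout train after inversion.

    ``time_grid`` holds the sampled acquisition times relative to the
    inversion pulse (seconds, strictly increasing).  By convention spoke k
    of a continuous readout sits at (k + 0.5) * TR.
    """

    tr: float
    flip: float
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if not (0.0 < self.flip < np.pi / 2):
            raise ValueError("flip angle must lie in (0, pi/2)")
        if self.time_grid.ndim != 1 or self.time_grid.size < 1:
            raise ValueError("time_grid must be a non-empty 1-D array")
        if self.time_grid[0] < 0 or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be non-negative and increasing")

    @property
    def n_time(self) -> int:
        return int(self.time_grid.size)

    @property
    def r1_prime(self) -> float:
        """Readout-driven relaxation rate R1' = -ln(cos(flip))/TR >= 0."""
        return float(-np.log(np.cos(self.flip)) / self.tr)


def flash_time_grid(tr: float, n_readout: int, n_time: int,
                    spacing: str = "log") -> np.ndarray:
    """Sampled time points (k + 0.5)*TR for ``n_time`` spokes selected out of
    ``n_readout``, log-spaced by default to resolve the early recovery."""
    if spacing == "log":
        idx = np.unique(np.round(np.logspace(0, np.log10(n_readout), n_time)).astype(int)) - 1
        # top up in case rounding collapsed neighbours at the dense end
        k = 1
        while idx.size < n_time and k < n_readout:
            if k - 1 not in idx:
                idx = np.sort(np.append(idx, k - 1))
            k += 1
    elif spacing == "linear":
        idx = np.unique(np.linspace(0, n_readout - 1, n_time).astype(int))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return (idx + 0.5) * tr


@dataclass
class CombinedModelParams:
    """Parameter vector u = [M0, R1, R1', R2, omega0, a_i, Gamma_i].

    Pool entries are (amplitude a_i in 1/s, width Gamma_i in ppm,
    centre delta_i in ppm).  ``omega0_ppm`` absorbs a static B0 shift.
    """

    m0: float
    r1: float
    r1_prime: float
    r2: float
    omega0_ppm: float
    pools: Sequence[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.r1_prime < 0:
            raise ValueError("R1' must be >= 0")
        for a, g, _d in self.pools:
            if a < 0:
                raise ValueError("pool amplitude must be >= 0")
            if g <= 0:
                raise ValueError("pool width must be > 0")


@dataclass
class ZSpectrumStack:
    """Signal indexed by (offset, readout time point)."""

    signal: np.ndarray      # (n_offsets, n_time, ...)
    offsets_ppm: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.shape[:2] != (self.offsets_ppm.size, self.times.size):
            raise ValueError("signal shape inconsistent with offset/time axes")


@dataclass
class AcquisitionScheme:
    """Saturation + readout timing shared by simulation and fitting."""

    sat: SaturationSpec
    readout: ReadoutSpec
    offsets_ppm: np.ndarray
    b0: float = DEFAULT_B0_T

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)


# ---------------------------------------------------------------------------
# Elementary rates
# ---------------------------------------------------------------------------

def projection_factor(offset_rad, omega1: float):
    """cos^2(theta) and P2 for the effective-field tilt angle theta.

    cos(theta) = omega / sqrt(omega^2 + omega1^2); P2 = cos^2(theta).
    """
    offset_rad = np.asarray(offset_rad, dtype=float)
    if omega1 == 0.0:
        if np.any(offset_rad == 0.0):
            raise ValueError("projection undefined for offset = omega1 = 0")
        one = np.ones_like(offset_rad)
        return one, one.copy()
    cos2 = offset_rad**2 / (offset_rad**2 + omega1**2)
    return cos2, cos2.copy()


def rex_amplitude(fs, ks, r2s, omega1):
    """Peak exchange-dependent relaxation rate a = fs*ks*w1^2 / (ks*(ks+R2s)+w1^2)."""
    return fs * ks * omega1**2 / (ks * (ks + r2s) + omega1**2)


def rex_width(ks, r2s, omega1):
    """Lorentzian linewidth Gamma = 2*sqrt((R2s+ks)^2 + (R2s+ks)/ks * w1^2) (rad/s)."""
    s = r2s + ks
    return 2.0 * np.sqrt(s**2 + s / ks * omega1**2)


def lorentzian(offset_rad, amplitude, gamma_rad, delta_rad):
    """a * (G^2/4) / (G^2/4 + (w - d)^2)."""
    g24 = gamma_rad**2 / 4.0
    return amplitude * g24 / (g24 + (offset_rad - delta_rad) ** 2)


def rex_lorentzian(pool: ExchangePool, offset_rad, omega1: float,
                   b0: float = DEFAULT_B0_T):
    """Exchange-dependent relaxation rate Rex(offset) of one pool (1/s)."""
    a = rex_amplitude(pool.fs, pool.ks, pool.r2s, omega1)
    g = rex_width(pool.ks, pool.r2s, omega1)
    return lorentzian(np.asarray(offset_rad, dtype=float), a, g,
                      ppm_to_rad(pool.delta_ppm, b0))


def fraction_from_amplitude(a_fitted, ks: float, r2s: float, omega1: float):
    """Invert the Rex amplitude for the pool proton fraction.

    fs = a * (ks*(ks+R2s) + omega1^2) / (ks * omega1^2); exact algebraic
    inverse of :func:`rex_amplitude`.
    """
    if omega1 == 0.0:
        raise ZeroDivisionError("fraction unidentifiable at zero saturation amplitude")
    if ks <= 0:
        raise ValueError("ks must be > 0")
    return np.asarray(a_fitted) * (ks * (ks + r2s) + omega1**2) / (ks * omega1**2)


def _pools_as_triples(pools, omega1, b0):
    """Normalize ExchangePool objects / (a, Gamma_rad, delta_rad) triples."""
    out = []
    for p in pools:
        if isinstance(p, ExchangePool):
            out.append((rex_amplitude(p.fs, p.ks, p.r2s, omega1),
                        rex_width(p.ks, p.r2s, omega1),
                        ppm_to_rad(p.delta_ppm, b0)))
        else:
            out.append(tuple(p))
    return out


def r1rho(water: WaterPool, pools, offset_rad, omega1: float,
          b0: float = DEFAULT_B0_T):
    """Rotating-frame relaxation R1rho = R1w cos^2 + R2w sin^2 + sum Rex."""
    cos2, _ = projection_factor(offset_rad, omega1)
    rate = water.r1 * cos2 + water.r2 * (1.0 - cos2)
    for a, g, d in _pools_as_triples(pools, omega1, b0):
        rate = rate + lorentzian(np.asarray(offset_rad, dtype=float), a, g, d)
    return rate


def steady_state_fraction(water: WaterPool, pools, offset_rad, omega1: float,
                          b0: float = DEFAULT_B0_T):
    """Driven steady-state Z-value fss = P2 * R1w / R1rho, in [0, 1]."""
    _, p2 = projection_factor(offset_rad, omega1)
    return p2 * water.r1 / r1rho(water, pools, offset_rad, omega1, b0)


def transient_spectrum(water: WaterPool, pools, sat: SaturationSpec, frec,
                       offsets_ppm, b0: float = DEFAULT_B0_T):
    """Transient Z-spectrum magnetization after a saturation block.

    Mtrans(w) = M0 * [(frec - fss) * exp(-Tprep * R1rho) + fss]; ``frec`` is
    the starting Z-fraction (scalar or per-offset).
    """
    w = ppm_to_rad(np.asarray(offsets_ppm, dtype=float), b0)
    fss = steady_state_fraction(water, pools, w, sat.omega1, b0)
    rr = r1rho(water, pools, w, sat.omega1, b0)
    frec = np.broadcast_to(np.asarray(frec, dtype=float), fss.shape)
    return water.m0 * ((frec - fss) * np.exp(-sat.tprep * rr) + fss)


def look_locker(water: WaterPool, fss_ll, r1_prime: float, start_fraction,
                time_grid):
    """Look-Locker recovery M(t) = M0*[fss - (start + fss) * exp(-t*(R1+R1'))]."""
    t = np.asarray(time_grid, dtype=float)
    return water.m0 * (fss_ll - (np.asarray(start_fraction) + fss_ll)
                       * np.exp(-t * (water.r1 + r1_prime)))


def chain_recovery_fractions(fss_ll, n_offsets: int):
    """Starting Z-fraction per offset: 1 for the first, fss_LL afterwards."""
    if n_offsets < 1:
        raise ValueError("need at least one offset")
    frec = np.full(n_offsets, float(fss_ll))
    frec[0] = 1.0
    return frec


# ---------------------------------------------------------------------------
# Combined model
# ---------------------------------------------------------------------------

def combined_signal_arrays(m0, r1, r1_prime, r2, omega0_ppm, pools,
                           offsets_ppm, times, omega1: float, tprep: float,
                           b0: float = DEFAULT_B0_T,
                           frec_per_offset=None,
                           inversion_efficiency: float = 1.0):
    """Vectorized combined CEST + Look-Locker signal.

    Parameters may be scalars or arrays of a common batch shape ``B`` (one
    entry per voxel); ``pools`` is a sequence of (a [1/s], Gamma [ppm],
    delta [ppm]) triples whose entries broadcast with ``B``.  Returns an
    array of shape ``(n_offsets, n_times) + B``.

    The model: saturation drives the magnetization from frec (the chained
    Look-Locker steady state) towards fss_CEST at rate R1rho; inversion
    flips the transient Z-value; the FLASH train relaxes it towards
    fss_LL = R1/(R1+R1') at rate R1+R1'.
    """
    if tprep < 0:
        raise ValueError("saturation time must be >= 0")
    offsets_ppm = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    m0, r1, r1_prime, r2, omega0_ppm = (
        np.asarray(x, dtype=float) for x in (m0, r1, r1_prime, r2, omega0_ppm))
    batch = np.broadcast_shapes(m0.shape, r1.shape, r1_prime.shape, r2.shape,
                                omega0_ppm.shape)
    bax = (np.newaxis,) * len(batch)
    # offset axis first, batch axes trailing
    w = ppm_to_rad(offsets_ppm, b0)[(slice(None),) + bax] \
        - ppm_to_rad(omega0_ppm, b0)[np.newaxis]
    if omega1 > 0:
        cos2 = w**2 / (w**2 + omega1**2)
    else:
        cos2 = np.ones_like(w)
    rr = r1 * cos2 + r2 * (1.0 - cos2)
    for a, g_ppm, d_ppm in pools:
        a = np.asarray(a, dtype=float)
        g = ppm_to_rad(np.asarray(g_ppm, dtype=float), b0)
        d = ppm_to_rad(np.asarray(d_ppm, dtype=float), b0)
        rr = rr + lorentzian(w, a, g, d)
    fss_cest = cos2 * r1 / rr
    fss_ll = r1 / (r1 + r1_prime)
    if frec_per_offset is None:
        frec = np.broadcast_to(fss_ll, (offsets_ppm.size,) + batch).copy()
        frec[0] = 1.0
    else:
        frec = np.asarray(frec_per_offset, dtype=float)
        if frec.shape[0] != offsets_ppm.size:
            raise ValueError("frec_per_offset length must match offsets")
        frec = frec.reshape(frec.shape + (1,) * (len(batch) - (frec.ndim - 1)))
    ztrans = (frec - fss_cest) * np.exp(-tprep * rr) + fss_cest
    decay = np.exp(-times.reshape((times.size,) + (1,) * len(batch))
                   * (r1 + r1_prime))
    sig = m0 * (fss_ll - (inversion_efficiency * ztrans[:, np.newaxis] + fss_ll) * decay)
    return sig


def combined_signal(params: CombinedModelParams, sat: SaturationSpec,
                    readout: ReadoutSpec, offsets_ppm,
                    frec_per_offset=None, b0: float = DEFAULT_B0_T,
                    inversion_efficiency: float = 1.0) -> ZSpectrumStack:
    """Combined signal for a single parameter set; see combined_signal_arrays."""
    sig = combined_signal_arrays(
        params.m0, params.r1, params.r1_prime, params.r2, params.omega0_ppm,
        params.pools, offsets_ppm, readout.time_grid, sat.omega1, sat.tprep,
        b0=b0, frec_per_offset=frec_per_offset,
        inversion_efficiency=inversion_efficiency)
    return ZSpectrumStack(sig, np.atleast_1d(offsets_ppm), readout.time_grid)
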