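"""Numerical Bloch-McConnell integrator.

Ground-truth oracle for the analytic model and signal generator for the
numerical phantom.  All pools (water + solutes) carry full transverse and
longitudinal components; exchange follows a star topology (every solute
pool exchanges with water only).  Evolution under piecewise-constant RF is
propagated exactly with the matrix exponential of the homogenized
generator, so the integration is step-size free.

The FLASH readout is modeled as instantaneous rotations with perfect
spoiling: at each excitation the longitudinal magnetization is scaled by
cos(alpha), the transverse magnetization is discarded, and the recorded
signal is proportional to the pre-flip water Mz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.linalg import expm

from .signal_model import (DEFAULT_B0_T, ExchangePool, ReadoutSpec,
                           WaterPool, ZSpectrumStack, omega1_from_b1,
                           ppm_to_rad)


@dataclass
class BmcSystem:
    """Water plus solute pools at a given static field."""

    water: WaterPool
    pools: List[ExchangePool] = field(default_factory=list)
    b0: float = DEFAULT_B0_T

    def __post_init__(self) -> None:
        if sum(p.fs for p in self.pools) >= 1.0:
            raise ValueError("pool fractions must sum to < 1")

    @property
    def n_pools(self) -> int:
        return 1 + len(self.pools)

    def equilibrium(self) -> "MagState":
        m = np.zeros(3 * self.n_pools)
        m[2] = self.water.m0
        for i, p in enumerate(self.pools):
            m[3 * (i + 1) + 2] = p.fs * self.water.m0
        return MagState(m=m, time=0.0)


@dataclass
class PulseTrain:
    """Saturation pulse train; ``cw_block`` plays every pulse as a constant
    block at B1rms (the stand-in for the CW-like optimized pulses)."""

    n_pulses: int
    tp: float
    td: float
    b1_rms_ut: float
    shape: str = "cw_block"

    def __post_init__(self) -> None:
        if self.n_pulses < 1 or self.tp <= 0 or self.td < 0:
            raise ValueError("invalid pulse train timing")
        if self.shape not in ("cw_block", "gauss"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")

    @classmethod
    def cw(cls, b1_ut: float, tprep: float) -> "PulseTrain":
        """Single continuous block of duration tprep."""
        return cls(n_pulses=1, tp=tprep, td=0.0, b1_rms_ut=b1_ut)

    @property
    def duration(self) -> float:
        return self.n_pulses * self.tp + (self.n_pulses - 1) * self.td


@dataclass
class MagState:
    """Stacked (Mx, My, Mz) per pool, water first."""

    m: np.ndarray
    time: float = 0.0

    def mz_water(self) -> float:
        return float(self.m[2])


def _generator(system: BmcSystem, omega1: float, offset_rad: float) -> np.ndarray:
    """Homogenized Bloch-McConnell generator (3P+1 x 3P+1).

    RF along x with amplitude omega1; ``offset_rad`` is the RF frequency
    relative to water, so pool p precesses at delta_p - offset in the
    rotating frame.
    """
    n = system.n_pools
    size = 3 * n + 1
    a = np.zeros((size, size))
    r1 = [system.water.r1] + [p.r1s for p in system.pools]
    r2 = [system.water.r2] + [p.r2s for p in system.pools]
    m0 = [system.water.m0] + [p.fs * system.water.m0 for p in system.pools]
    delta = [0.0] + [ppm_to_rad(p.delta_ppm, system.b0) for p in system.pools]
    k_from_water = sum(p.fs * p.ks for p in system.pools)
    for p in range(n):
        i = 3 * p
        dw = delta[p] - offset_rad
        k_out = k_from_water if p == 0 else system.pools[p - 1].ks
        a[i, i] = -(r2[p] + k_out)
        a[i, i + 1] = dw
        a[i + 1, i] = -dw
        a[i + 1, i + 1] = -(r2[p] + k_out)
        a[i + 1, i + 2] = omega1
        a[i + 2, i + 1] = -omega1
        a[i + 2, i + 2] = -(r1[p] + k_out)
        a[i + 2, -1] = r1[p] * m0[p]
        if p == 0:
            for q, pool in enumerate(system.pools, start=1):
                for c in range(3):
                    a[i + c, 3 * q + c] = pool.ks           # gain from solute
        else:
            kw = system.pools[p - 1].fs * system.pools[p - 1].ks
            for c in range(3):
                a[i + c, c] = kw                            # gain from water
    return a


def _z_generator(system: BmcSystem) -> np.ndarray:
    """Longitudinal-only homogenized generator (P+1 x P+1), used between
    ideally spoiled FLASH pulses (transverse magnetization discarded)."""
    n = system.n_pools
    a = np.zeros((n + 1, n + 1))
    k_from_water = sum(p.fs * p.ks for p in system.pools)
    a[0, 0] = -(system.water.r1 + k_from_water)
    a[0, -1] = system.water.r1 * system.water.m0
    for q, p in enumerate(system.pools, start=1):
        a[0, q] = p.ks
        a[q, 0] = p.fs * p.ks
        a[q, q] = -(p.r1s + p.ks)
        a[q, -1] = p.r1s * p.fs * system.water.m0
    return a


def evolve(system: BmcSystem, state: MagState, b1_ut: float,
           offset_rad: float, duration: float) -> MagState:
    """Propagate the full Bloch-McConnell state under constant RF."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not np.all(np.isfinite(state.m)):
        raise ValueError("non-finite magnetization state")
    a = _generator(system, omega1_from_b1(b1_ut), offset_rad)
    vec = np.append(state.m, 1.0)
    out = expm(a * duration) @ vec
    return MagState(m=out[:-1], time=state.time + duration)


def inversion(state: MagState, efficiency: float = 1.0) -> MagState:
    """Ideal (crushed) inversion: Mz -> -efficiency * Mz, transverse spoiled."""
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("inversion efficiency must lie in [0, 1]")
    m = state.m.copy()
    for p in range(m.size // 3):
        m[3 * p] = 0.0
        m[3 * p + 1] = 0.0
        m[3 * p + 2] *= -efficiency
    return MagState(m=m, time=state.time)


def _saturation_propagator(system: BmcSystem, sat: PulseTrain,
                           offset_rad: float) -> np.ndarray:
    """Exact propagator of the whole saturation block at one offset."""
    p_pulse = expm(_generator(system, omega1_from_b1(sat.b1_rms_ut), offset_rad)
                   * sat.tp)
    if sat.n_pulses == 1:
        return p_pulse
    p_gap = expm(_generator(system, 0.0, offset_rad) * sat.td)
    step = p_gap @ p_pulse
    out = p_pulse.copy()
    for _ in range(sat.n_pulses - 1):
        out = step @ out
    return out


def run_sequence(system: BmcSystem, sat: PulseTrain, readout: ReadoutSpec,
                 offsets_ppm: Sequence[float],
                 inversion_efficiency: float = 1.0,
                 n_repeats: int = 1) -> ZSpectrumStack:
    """Full saturation -> inversion -> FLASH-train loop over all offsets.

    Magnetization chains across offsets with no recovery delay.  The
    recorded signal is the pre-flip water Mz at the times in
    ``readout.time_grid`` (spoke k at (k + 0.5) * TR).  ``n_repeats`` > 1
    replays the whole offset loop, keeping only the last pass, to probe the
    cyclic steady state.
    """
    offsets_ppm = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    if offsets_ppm.size == 0:
        raise ValueError("offsets must be non-empty")
    tr = readout.tr
    sample_idx = np.round(readout.time_grid / tr - 0.5).astype(int)
    if not np.allclose((sample_idx + 0.5) * tr, readout.time_grid, rtol=1e-6):
        raise ValueError("time_grid must sit on the (k + 0.5)*TR comb")
    n_readout = int(sample_idx[-1]) + 1
    n = system.n_pools
    cos_a = np.cos(readout.flip)

    az = _z_generator(system)
    p_half = expm(az * (tr / 2.0))
    p_tr = expm(az * tr)
    flip = np.diag([cos_a] * n + [1.0])
    step = p_tr @ flip                      # one TR: flip then relax
    gaps = np.diff(np.concatenate(([0], sample_idx)))
    step_powers = {g: np.linalg.matrix_power(step, g)
                   for g in np.unique(gaps) if g > 0}

    sat_props = [_saturation_propagator(system, sat, ppm_to_rad(o, system.b0))
                 for o in offsets_ppm]

    state = system.equilibrium()
    signal = np.zeros((offsets_ppm.size, sample_idx.size))
    for _ in range(max(1, n_repeats)):
        for io in range(offsets_ppm.size):
            vec = np.append(state.m, 1.0)
            vec = sat_props[io] @ vec
            state = inversion(MagState(m=vec[:-1]), inversion_efficiency)
            z = np.append(state.m[2::3], 1.0)
            z = p_half @ z                          # to first sample at TR/2
            prev = 0
            for j, k in enumerate(sample_idx):
                if k != prev:
                    z = step_powers[k - prev] @ z
                    prev = k
                signal[io, j] = z[0]
            # finish the block: flip at the last sample, then relax out
            remaining = n_readout - 1 - sample_idx[-1]
            z = flip @ z
            if remaining:
                z = np.linalg.matrix_power(step, remaining) @ z
            z = p_half @ z
            m = np.zeros(3 * n)
            m[2::3] = z[:-1]
            state = MagState(m=m)
    return ZSpectrumStack(signal, offsets_ppm, readout.time_grid)


def run_conventional(system: BmcSystem, sat: PulseTrain,
                     offsets_ppm: Sequence[float], trec: float) -> np.ndarray:
    """Conventional transient Z-spectrum: recovery Trec, saturation, then one
    instantaneous sample of water Mz per offset (centric readout).  Returns
    Z = Mz/M0 per offset."""
    offsets_ppm = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    relax = expm(_generator(system, 0.0, 0.0) * trec) if trec > 0 else None
    state = system.equilibrium()
    z = np.zeros(offsets_ppm.size)
    vec = np.append(state.m, 1.0)
    for io, o in enumerate(offsets_ppm):
        prop = _saturation_propagator(system, sat, ppm_to_rad(o, system.b0))
        vec = prop @ vec
        z[io] = vec[2] / system.water.m0
        # spoil transverse, then recover before the next offset
        for p in range(system.n_pools):
            vec[3 * p] = 0.0
            vec[3 * p + 1] = 0.0
        if relax is not None:
            vec = relax @ vec
    return z
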