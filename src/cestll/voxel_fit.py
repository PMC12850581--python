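"""Per-voxel nonlinear least-squares fitting of the combined model.

Image-space quantification: every voxel's (offset x time) signal is fitted
with the analytic CEST + Look-Locker model, parameter vector
u = [M0, R1, R1', R2, omega0, a_i, Gamma_i].  A staged initialization
(Look-Locker-only fit on the farthest offset block, then the full joint
fit) keeps the problem well-behaved without stochastic restarts, so the
fit is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .signal_model import (AcquisitionScheme, ReadoutSpec,
                           combined_signal_arrays)


@dataclass
class PoolTemplate:
    """Fixed pool centres (ppm) with initial width/amplitude guesses."""

    centers_ppm: Sequence[float] = (4.2,)
    init_width_ppm: float = 1.0
    init_amplitude: float = 0.1


@dataclass
class FitConfig:
    pool_template: PoolTemplate = field(default_factory=PoolTemplate)
    # bounds for [m0, r1, r1p, r2, omega0_ppm] and per-pool [a, gamma_ppm]
    m0_bounds: tuple = (1e-3, 20.0)
    r1_bounds: tuple = (0.05, 10.0)
    r1p_bounds: tuple = (0.0, 20.0)
    r2_bounds: tuple = (0.1, 100.0)
    omega0_bounds_ppm: tuple = (-0.3, 0.3)
    a_bounds: tuple = (0.0, 50.0)
    gamma_bounds_ppm: tuple = (0.1, 5.0)
    max_nfev: int = 200
    xtol: float = 1e-10
    ftol: float = 1e-10
    magnitude_data: bool = False


@dataclass
class VoxelFit:
    params: np.ndarray          # [m0, r1, r1p, r2, w0, (a, gamma)*pools]
    residual_norm: float
    converged: bool

    @property
    def t1_ms(self) -> float:
        return 1000.0 / self.params[1]


@dataclass
class ParameterMaps:
    """Co-registered fitted parameter maps."""

    maps: Dict[str, np.ndarray]
    mask: np.ndarray

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]


def restore_polarity(signal: np.ndarray) -> np.ndarray:
    """Sign restoration for magnitude inversion-recovery data: within each
    offset block, samples before the magnitude minimum are negated."""
    out = np.abs(np.asarray(signal, dtype=float)).copy()
    for row in out:
        k = int(np.argmin(row))
        row[:k] *= -1.0
        if row.size < 3:
            continue
        # the pivot sample's sign is ambiguous from magnitude alone; pick the
        # sign that best matches a local linear prediction from its neighbours
        if k == 0:
            pred = 2.0 * row[1] - row[2]
        elif k == row.size - 1:
            pred = 2.0 * row[k - 1] - row[k - 2]
        else:
            pred = 0.5 * (row[k - 1] + row[k + 1])
        if abs(-row[k] - pred) < abs(row[k] - pred):
            row[k] *= -1.0
    return out


def _pack_model(scheme: AcquisitionScheme, centers_ppm):
    offsets, times = scheme.offsets_ppm, scheme.readout.time_grid
    om1, tprep, b0 = scheme.sat.omega1, scheme.sat.tprep, scheme.b0

    def model(p):
        pools = [(p[5 + 2 * i], p[6 + 2 * i], c)
                 for i, c in enumerate(centers_ppm)]
        return combined_signal_arrays(p[0], p[1], p[2], p[3], p[4], pools,
                                      offsets, times, om1, tprep, b0=b0)
    return model


def fit_look_locker(signal: np.ndarray, readout: ReadoutSpec,
                    cfg: Optional[FitConfig] = None):
    """Three-parameter Look-Locker fit M(t) = M0*(fss - (1+fss)*exp(-t R1*)).

    Returns (m0, r1, r1_prime); T1 = 1/r1.
    """
    cfg = cfg or FitConfig()
    y = np.asarray(signal, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 time points")
    t = readout.time_grid

    def resid(p):
        m0, fss, rstar = p
        return m0 * (fss - (1 + fss) * np.exp(-t * rstar)) - y

    a_end = max(y[-1], 1e-3)
    r = least_squares(resid, [a_end / 0.4, 0.4, 2.0],
                      bounds=([1e-3, 1e-3, 0.01], [20.0, 1.0, 50.0]),
                      xtol=cfg.xtol, ftol=cfg.ftol, max_nfev=cfg.max_nfev)
    m0, fss, rstar = r.x
    return float(m0), float(fss * rstar), float((1 - fss) * rstar)


def fit_voxel(signal: np.ndarray, scheme: AcquisitionScheme,
              cfg: Optional[FitConfig] = None) -> VoxelFit:
    """Fit one voxel's (n_offsets, n_time) signal with the combined model."""
    cfg = cfg or FitConfig()
    sig = np.asarray(signal, dtype=float)
    if sig.shape[0] < 2 or sig.shape[1] < 3:
        raise ValueError("need >= 2 offsets and >= 3 time points")
    if cfg.magnitude_data:
        sig = restore_polarity(sig)

    # stage 1: Look-Locker on the farthest offset block
    far = int(np.argmax(np.abs(scheme.offsets_ppm)))
    m0_ll, r1_ll, r1p_ll = fit_look_locker(sig[far], scheme.readout, cfg)
    r1p_nominal = scheme.readout.r1_prime
    tmpl = cfg.pool_template
    centers = list(tmpl.centers_ppm)
    x0 = [m0_ll, r1_ll, max(r1p_ll, 0.5 * r1p_nominal), 10.0, 0.0]
    lb = [cfg.m0_bounds[0], cfg.r1_bounds[0], cfg.r1p_bounds[0],
          cfg.r2_bounds[0], cfg.omega0_bounds_ppm[0]]
    ub = [cfg.m0_bounds[1], cfg.r1_bounds[1], cfg.r1p_bounds[1],
          cfg.r2_bounds[1], cfg.omega0_bounds_ppm[1]]
    for _ in centers:
        x0 += [tmpl.init_amplitude, tmpl.init_width_ppm]
        lb += [cfg.a_bounds[0], cfg.gamma_bounds_ppm[0]]
        ub += [cfg.a_bounds[1], cfg.gamma_bounds_ppm[1]]
    x0 = np.clip(x0, lb, ub)

    model = _pack_model(scheme, centers)
    data = sig.ravel()
    res = least_squares(lambda p: model(p).ravel() - data, x0,
                        bounds=(lb, ub), method="trf",
                        xtol=cfg.xtol, ftol=cfg.ftol, max_nfev=cfg.max_nfev)
    return VoxelFit(params=res.x, residual_norm=float(np.linalg.norm(res.fun)),
                    converged=bool(res.status > 0))


def fit_map(series: np.ndarray, mask: np.ndarray, scheme: AcquisitionScheme,
            cfg: Optional[FitConfig] = None) -> ParameterMaps:
    """Voxel-wise fit of an (n_offsets, n_time, ny, nx) image series.

    Unmasked voxels are NaN in the output maps.
    """
    cfg = cfg or FitConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ny, nx = mask.shape
    n_pools = len(cfg.pool_template.centers_ppm)
    names = ["m0", "r1", "r1_prime", "r2", "omega0_ppm"]
    for i in range(n_pools):
        names += [f"a_{i}", f"gamma_ppm_{i}"]
    maps = {k: np.full((ny, nx), np.nan) for k in names}
    maps["t1_ms"] = np.full((ny, nx), np.nan)
    maps["residual"] = np.full((ny, nx), np.nan)
    maps["converged"] = np.zeros((ny, nx), dtype=bool)
    for iy, ix in zip(*np.nonzero(mask)):
        fit = fit_voxel(series[:, :, iy, ix], scheme, cfg)
        for j, k in enumerate(names):
            maps[k][iy, ix] = fit.params[j]
        maps["t1_ms"][iy, ix] = fit.t1_ms
        maps["residual"][iy, ix] = fit.residual_norm
        maps["converged"][iy, ix] = fit.converged
    return ParameterMaps(maps=maps, mask=mask)
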