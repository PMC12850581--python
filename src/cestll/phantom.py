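"""Numerical tube phantom: geometry, signal rendering, coil maps and
Cartesian / golden-angle radial k-space synthesis with additive noise.

The default layout emulates an eleven-tube ring inside a circular
background disk, each tube carrying one (water T1, CEST pool fraction)
combination; pixel signals are piecewise constant per region, so ROI-based
evaluation against ground truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, fftshift, ifft2, ifftshift

from .nufft import BatchedFrameNufft, KbNufft

GOLDEN_ANGLE_DEG = 111.246

# Default tube parameters: eleven fractions, ten T1 values with the last
# (1500 ms) reused for the eleventh tube.
DEFAULT_T1_MS = (500., 600., 700., 800., 900., 1000., 1100., 1200., 1300., 1500., 1500.)
DEFAULT_FRACTION = (0.0, 0.001, 0.002, 0.003, 0.004, 0.005, 0.006, 0.006,
                    0.007, 0.008, 0.009)
OUTSIDE = -1
BACKGROUND = 0


@dataclass
class TubeLayout:
    """Label image (-1 outside, 0 background disk, 1..n tubes) plus the
    per-label tissue parameters."""

    grid: int
    labels: np.ndarray          # (grid, grid) int
    t1_ms: np.ndarray           # (n_labels,) indexed by label
    fraction: np.ndarray        # (n_labels,)
    tube_radius: float
    centers: np.ndarray         # (n_tubes, 2)

    @property
    def n_labels(self) -> int:
        return int(self.t1_ms.size)

    def roi_masks(self, erode: int = 1) -> Dict[int, np.ndarray]:
        """Per-label boolean masks, eroded to avoid edge voxels."""
        out = {}
        for lab in range(self.n_labels):
            m = self.labels == lab
            if erode > 0:
                m = ndimage.binary_erosion(m, iterations=erode)
            out[lab] = m
        return out

    def support(self) -> np.ndarray:
        return self.labels >= 0

    def t1_map(self) -> np.ndarray:
        out = np.zeros(self.labels.shape)
        for lab in range(self.n_labels):
            out[self.labels == lab] = self.t1_ms[lab]
        return out

    def fraction_map(self) -> np.ndarray:
        out = np.zeros(self.labels.shape)
        for lab in range(self.n_labels):
            out[self.labels == lab] = self.fraction[lab]
        return out


def build_layout(grid: int = 64, t1_ms=DEFAULT_T1_MS, fraction=DEFAULT_FRACTION,
                 background_t1_ms: float = 1000.0,
                 disk_radius_frac: float = 0.45, ring_radius_frac: float = 0.30,
                 tube_radius_frac: float = 0.055) -> TubeLayout:
    """Eleven equal tubes on a ring inside a background disk.

    Label 0 is the pure-water background; labels 1..11 are the tubes in
    order of the parameter lists.  Deterministic for a fixed grid.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    if t1_ms.size != fraction.size:
        raise ValueError("t1 and fraction lists must have equal length")
    n_tubes = t1_ms.size
    c = (grid - 1) / 2.0
    yy, xx = np.mgrid[0:grid, 0:grid]
    rr = np.hypot(yy - c, xx - c)
    labels = np.full((grid, grid), OUTSIDE, dtype=int)
    labels[rr <= disk_radius_frac * grid] = BACKGROUND
    tube_r = tube_radius_frac * grid
    ring_r = ring_radius_frac * grid
    centers = []
    for i in range(n_tubes):
        phi = 2 * np.pi * i / n_tubes
        cy, cx = c + ring_r * np.sin(phi), c + ring_r * np.cos(phi)
        mask = np.hypot(yy - cy, xx - cx) <= tube_r
        if np.any(labels[mask] > 0):
            raise ValueError("tubes overlap; reduce tube_radius_frac")
        labels[mask] = i + 1
        centers.append((cy, cx))
    return TubeLayout(grid=grid, labels=labels,
                      t1_ms=np.concatenate(([background_t1_ms], t1_ms)),
                      fraction=np.concatenate(([0.0], fraction)),
                      tube_radius=tube_r, centers=np.asarray(centers))


def render_signal(layout: TubeLayout, signals: Dict[int, np.ndarray]) -> np.ndarray:
    """Piecewise-constant image series from per-label signal evolutions.

    ``signals[label]`` has any leading shape (e.g. (offsets, times)); the
    output appends the two spatial axes.  Pixels outside the disk are 0.
    """
    shapes = {np.asarray(s).shape for s in signals.values()}
    if len(shapes) != 1:
        raise ValueError("all label signals must share one shape")
    lead = shapes.pop()
    out = np.zeros(lead + layout.labels.shape, dtype=float)
    for lab in range(layout.n_labels):
        if lab not in signals:
            raise KeyError(f"missing signal for label {lab}")
        out[..., layout.labels == lab] = np.asarray(signals[lab])[..., None]
    return out


@dataclass
class CoilMaps:
    maps: np.ndarray            # (n_coils, grid, grid) complex

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))

    def combine(self, coil_images: np.ndarray) -> np.ndarray:
        """Ground-truth coil combination sum(conj(c) * img) / sum(|c|^2)."""
        num = (np.conj(self.maps) * coil_images).sum(axis=-3)
        den = np.maximum((np.abs(self.maps) ** 2).sum(axis=0), 1e-12)
        return num / den


def make_coil_maps(grid: int, n_coils: int = 4, seed: int = 0) -> CoilMaps:
    """Smooth synthetic sensitivities: Gaussian magnitude lobes centred at
    equispaced border positions with a low-order polynomial phase."""
    rng = np.random.default_rng(seed)
    c = (grid - 1) / 2.0
    yy, xx = np.mgrid[0:grid, 0:grid]
    maps = np.empty((n_coils, grid, grid), dtype=complex)
    for ic in range(n_coils):
        phi = 2 * np.pi * ic / n_coils + rng.uniform(-0.1, 0.1)
        cy, cx = c + 0.6 * grid * np.sin(phi), c + 0.6 * grid * np.cos(phi)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (0.7 * grid) ** 2))
        u, v = (yy - c) / grid, (xx - c) / grid
        coef = rng.uniform(-1.0, 1.0, size=4)
        phase = coef[0] + coef[1] * u + coef[2] * v + coef[3] * u * v
        maps[ic] = mag * np.exp(1j * phase)
    return CoilMaps(maps=maps)


def _noise_sigma(reference_images: np.ndarray, kspace: np.ndarray,
                 noise_level: float, interpretation: str) -> float:
    """Noise std per real/imaginary k-space component.

    'image-amplitude' (default): sigma = noise_level * max|image|, expressed
    in the orthonormal-DFT-matched data units, i.e. the image-domain noise
    amplitude is noise_level times the peak signal.  'image-variance' reads
    the level as a variance; 'kspace-amplitude' scales by the k-space peak.
    """
    if interpretation == "image-amplitude":
        return noise_level * float(np.abs(reference_images).max())
    if interpretation == "image-variance":
        return float(np.sqrt(noise_level * np.abs(reference_images).max()))
    if interpretation == "kspace-amplitude":
        return noise_level * float(np.abs(kspace).max())
    raise ValueError(f"unknown noise interpretation {interpretation!r}")


def synthesize_cartesian(series: np.ndarray, coils: CoilMaps,
                         noise_level: float = 0.05, seed: int = 0,
                         noise_interpretation: str = "image-amplitude"):
    """Fully sampled multi-coil Cartesian k-space of an image series.

    series : (n_frames, grid, grid) real or complex.
    Returns (kspace (n_frames, n_coils, grid, grid), sigma).
    Orthonormal centered DFT; i.i.d. Gaussian noise on real and imaginary
    parts with std sigma derived from ``noise_level``.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    coil_imgs = series[:, None, :, :] * coils.maps[None]
    k = fftshift(fft2(ifftshift(coil_imgs, axes=(-2, -1)), axes=(-2, -1),
                      norm="ortho"), axes=(-2, -1))
    sigma = _noise_sigma(series, k, noise_level, noise_interpretation)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        k = k + sigma * (rng.standard_normal(k.shape)
                         + 1j * rng.standard_normal(k.shape))
    return k, sigma


def reconstruct_cartesian(kspace: np.ndarray, coils: CoilMaps) -> np.ndarray:
    """IFFT + ground-truth coil combination; returns the real (signed)
    image series."""
    imgs = fftshift(ifft2(ifftshift(kspace, axes=(-2, -1)), axes=(-2, -1),
                          norm="ortho"), axes=(-2, -1))
    return np.real(coils.combine(imgs))


def golden_angle_trajectory(n_frames: int, spokes_per_frame: int, grid: int,
                            readout_os: int = 2) -> np.ndarray:
    """(n_frames, spokes_per_frame * n_samples, 2) golden-angle radial
    trajectory in cycles/FOV; the angle sequence continues across frames."""
    n_samples = readout_os * grid
    r = (np.arange(n_samples) - n_samples // 2) / readout_os   # [-N/2, N/2)
    angles = np.deg2rad(GOLDEN_ANGLE_DEG) * np.arange(n_frames * spokes_per_frame)
    traj = np.empty((n_frames, spokes_per_frame * n_samples, 2))
    for f in range(n_frames):
        a = angles[f * spokes_per_frame:(f + 1) * spokes_per_frame]
        kx = np.outer(np.cos(a), r).ravel()
        ky = np.outer(np.sin(a), r).ravel()
        traj[f] = np.stack([kx, ky], axis=1)
    return traj


def nominal_undersampling(n_spokes: int, grid: int) -> float:
    """Nyquist spoke count (pi/2 * grid) over the used spoke count."""
    return (np.pi / 2.0) * grid / n_spokes


@dataclass
class RadialKSpace:
    """Multi-coil radial samples with trajectory and timing metadata."""

    data: np.ndarray            # (n_coils, n_frames, n_samples) complex
    traj: np.ndarray            # (n_frames, n_samples, 2) cycles/FOV
    times: np.ndarray           # (n_frames,) seconds from inversion
    offsets_ppm: np.ndarray     # (n_frames,)
    frame_offset_idx: np.ndarray
    frame_time_idx: np.ndarray
    grid: int
    sigma: float = 0.0
    coils: Optional[CoilMaps] = None


def synthesize_radial(series: np.ndarray, coils: CoilMaps,
                      offsets_ppm: np.ndarray, times: np.ndarray,
                      spokes_per_frame: int = 3, seed: int = 0,
                      noise_level: float = 0.05,
                      noise_interpretation: str = "image-amplitude",
                      readout_os: int = 2) -> RadialKSpace:
    """Golden-angle radial k-space of a (n_offsets, n_time, grid, grid)
    series; each (offset, time) image becomes one frame with
    ``spokes_per_frame`` spokes, sharing that frame's time stamp."""
    n_off, n_time, grid, _ = series.shape
    n_frames = n_off * n_time
    flat = series.reshape(n_frames, grid, grid)
    traj = golden_angle_trajectory(n_frames, spokes_per_frame, grid, readout_os)
    op = BatchedFrameNufft(grid, traj, os=2.0, width=8, dtype=np.complex128)
    data = op.forward(flat[None] * coils.maps[:, None])
    sigma = _noise_sigma(series, data, noise_level, noise_interpretation)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + sigma * (rng.standard_normal(data.shape)
                               + 1j * rng.standard_normal(data.shape))
    off_idx, t_idx = np.divmod(np.arange(n_frames), n_time)
    return RadialKSpace(
        data=data, traj=traj,
        times=np.asarray(times)[t_idx],
        offsets_ppm=np.asarray(offsets_ppm)[off_idx],
        frame_offset_idx=off_idx, frame_time_idx=t_idx,
        grid=grid, sigma=sigma, coils=coils)


def compress_coils(coils: CoilMaps, n_virtual: int):
    """SVD coil compression: returns (virtual CoilMaps, basis U) with
    ``virtual_maps = U^H @ maps``.  Applying ``U^H`` to multi-coil data keeps
    white noise white (unitary rows)."""
    nc = coils.n_coils
    if not (1 <= n_virtual <= nc):
        raise ValueError("n_virtual out of range")
    mat = coils.maps.reshape(nc, -1)
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    basis = u[:, :n_virtual].conj().T            # (n_virtual, nc)
    vmaps = (basis @ mat).reshape((n_virtual,) + coils.maps.shape[1:])
    return CoilMaps(maps=vmaps), basis


def noisy_cartesian_recon(series: np.ndarray, coils: CoilMaps,
                          noise_level: float = 0.05, seed: int = 0,
                          noise_interpretation: str = "image-amplitude",
                          chunk: int = 32) -> np.ndarray:
    """Streaming Cartesian synthesize + noise + coil-combined reconstruction.

    Equivalent to synthesize_cartesian followed by reconstruct_cartesian but
    processed in frame chunks to bound memory for many-coil phantoms.
    """
    if noise_interpretation not in ("image-amplitude", "image-variance"):
        raise ValueError("streaming path supports image-referenced noise only")
    sigma = _noise_sigma(series, None, noise_level, noise_interpretation)
    rng = np.random.default_rng(seed)
    out = np.empty_like(series, dtype=float)
    for lo in range(0, series.shape[0], chunk):
        sl = slice(lo, min(lo + chunk, series.shape[0]))
        coil_imgs = (series[sl, None, :, :] * coils.maps[None]).astype(np.complex64)
        k = fftshift(fft2(ifftshift(coil_imgs, axes=(-2, -1)), axes=(-2, -1),
                          norm="ortho"), axes=(-2, -1))
        if sigma > 0:
            k = k + sigma * (rng.standard_normal(k.shape)
                             + 1j * rng.standard_normal(k.shape)).astype(np.complex64)
        imgs = fftshift(ifft2(ifftshift(k, axes=(-2, -1)), axes=(-2, -1),
                              norm="ortho"), axes=(-2, -1))
        out[sl] = np.real(coils.combine(imgs))
    return out
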