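"""Topographic brain maps.

Each EEG segment becomes a 28×28×3 image: per-channel θ/α/β band power is
projected to the plane by an azimuthal equidistant projection (pole at the
vertex) and interpolated over a square pixel grid with a piecewise-cubic
scattered interpolant, then the three band images are stacked.

Conventions
-----------
* Band edges are half-open ``[lo, hi)`` — the 8 Hz bin belongs to α only,
  the 13 Hz bin to β only, so the bands tile 4–30 Hz without double
  counting.
* Band power of a window ≤ 1 s is the rectangular-window periodogram
  integrated over the band (at 1 s the 1 Hz bin spacing tiles the band
  edges 4/8/13/30 exactly); longer windows use Welch (0.5 s segments,
  50 % overlap).
* The projection maps an electrode at colatitude φ, azimuth λ (measured
  from the nasion direction toward the right ear) to
  (u, v) = (φ·sin λ, φ·cos λ): +v is anterior, so image row 0 is the
  front of the head.  Planar distance from the origin equals great-circle
  distance from the vertex.
* Pixels outside the electrode convex hull hold the fill value (0 by
  default); normalization statistics are computed over in-hull pixels of
  the *training* maps only and are carried as metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import QhullError

from .io import Montage
from .preprocessing import Segment

logger = logging.getLogger("topogru")


class BandDefinition(NamedTuple):
    name: str
    lo: float
    hi: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass
class Layout2D:
    """Planar electrode layout produced by the azimuthal projection."""

    channel_names: list[str]
    uv: np.ndarray          # (n, 2)
    r_max: float            # largest planar radius

    def __len__(self) -> int:
        return len(self.channel_names)


@dataclass
class BrainMap:
    """One 28×28×3 stacked θ/α/β power image."""

    grid: np.ndarray            # (grid, grid, 3), band order θ, α, β
    mask: np.ndarray            # (grid, grid) bool, True inside the hull
    band_names: tuple[str, ...] = ("theta", "alpha", "beta")
    norm: dict = field(default_factory=dict)


@dataclass
class BrainMapSequence:
    """Ordered frames of one segment, the unit fed to the recurrent model."""

    frames: np.ndarray          # (n_frames, grid, grid, 3)
    mask: np.ndarray
    subject_id: str
    segment_index: int
    norm: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def band_power(data: np.ndarray | Segment, band: BandDefinition,
               fs: float | None = None) -> np.ndarray:
    """Per-channel power (µV²) in ``[band.lo, band.hi)``.

    ``data`` may be a :class:`Segment` or a channels × samples array with
    an explicit sampling rate.
    """
    if isinstance(data, Segment):
        fs = data.fs
        x = data.data
    else:
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        x = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if band.lo >= fs / 2:
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) above Nyquist ({fs / 2} Hz)")
    n = x.shape[1]
    if n <= int(round(fs)) + 1:  # windows up to ~1 s: plain periodogram
        freqs, psd = sps.periodogram(x, fs=fs, window="boxcar", axis=1)
    else:
        nper = max(8, int(round(0.5 * fs)))
        freqs, psd = sps.welch(x, fs=fs, nperseg=min(nper, n),
                               noverlap=min(nper, n) // 2, axis=1)
    df = freqs[1] - freqs[0]
    sel = (freqs >= band.lo) & (freqs < band.hi)
    return psd[:, sel].sum(axis=1) * df


def total_power(data: np.ndarray | Segment, fs: float | None = None) -> np.ndarray:
    """Per-channel total power (variance about the mean, µV²)."""
    x = data.data if isinstance(data, Segment) else np.atleast_2d(data)
    return x.var(axis=1)


def aep_project(montage: Montage) -> Layout2D:
    """Azimuthal equidistant projection of a montage, pole at the vertex.

    An electrode at colatitude φ = arccos z and azimuth λ maps to
    (u, v) = (φ·sin λ, φ·cos λ); radial distances from the pole are
    preserved exactly.  The antipode (φ = π) is singular and rejected.
    """
    xyz = montage.coords
    phi = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    if np.any(phi >= np.pi - 1e-9):
        bad = [montage.channel_names[i]
               for i in np.nonzero(phi >= np.pi - 1e-9)[0]]
        raise ValueError(f"projection singular at the antipode: {bad}")
    lam = np.arctan2(xyz[:, 0], xyz[:, 1])  # 0 at nasion, +π/2 at right ear
    uv = np.column_stack([phi * np.sin(lam), phi * np.cos(lam)])
    return Layout2D(list(montage.channel_names), uv, float(phi.max()))


def _grid_axes(layout: Layout2D, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    r = 1.05 * layout.r_max  # margin keeps every electrode strictly inside
    u = np.linspace(-r, r, grid_size)
    v = np.linspace(r, -r, grid_size)  # row 0 = anterior (v > 0)
    return u, v


def interpolate_topomap(values: Sequence[float], layout: Layout2D,
                        grid_size: int = 28, fill: float = 0.0) -> np.ndarray:
    """Scatter-to-grid piecewise-cubic interpolation of electrode values.

    Uses a Clough–Tocher C1 cubic interpolant over the projected layout;
    it is node-exact and reproduces linear fields.  Pixels outside the
    electrode convex hull receive ``fill``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (len(layout),):
        raise ValueError("need exactly one value per laid-out electrode")
    if len(layout) < 4:
        raise ValueError("at least 4 electrodes required for interpolation")
    try:
        interp = CloughTocher2DInterpolator(layout.uv, values)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) electrode layout") from exc
    u, v = _grid_axes(layout, grid_size)
    uu, vv = np.meshgrid(u, v)
    grid = interp(uu, vv)
    grid[np.isnan(grid)] = fill
    return grid


def hull_mask(layout: Layout2D, grid_size: int = 28) -> np.ndarray:
    """Boolean in-hull mask for the pixel grid of ``interpolate_topomap``."""
    probe = interpolate_topomap(np.ones(len(layout)), layout, grid_size,
                                fill=np.nan)
    return ~np.isnan(probe)


def make_brainmap(segment: Segment, layout: Layout2D,
                  bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                  grid_size: int = 28, fill: float = 0.0) -> BrainMap:
    """Render one segment as a stacked per-band power image."""
    if segment.channel_names and segment.channel_names != layout.channel_names:
        raise ValueError("segment channels do not match the layout")
    if segment.data.shape[0] != len(layout):
        raise ValueError("channel count does not match the layout")
    planes = [interpolate_topomap(band_power(segment, b), layout, grid_size, fill)
              for b in bands]
    return BrainMap(np.stack(planes, axis=-1), hull_mask(layout, grid_size),
                    tuple(b.name for b in bands))


def make_sequence(segment: Segment, layout: Layout2D,
                  frame_len: float = 0.5, frame_step: float = 0.25,
                  bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                  grid_size: int = 28, fill: float = 0.0) -> BrainMapSequence:
    """Render sliding sub-windows of a segment as an ordered frame stack.

    Defaults (0.5 s frames, 0.25 s step) give 3 frames per 1 s segment.
    Frames shorter than two cycles of the lowest band's centre frequency
    are rejected; frames that undercut two full cycles of the band's lower
    edge are allowed with a logged notice (a documented low-θ bias).
    """
    T = segment.duration
    if frame_len > T + 1e-9:
        raise ValueError(f"frame_len {frame_len} s exceeds segment length {T} s")
    lo = min(b.lo for b in bands)
    centre = min((b.lo + b.hi) / 2 for b in bands)
    if frame_len < 2.0 / centre:
        raise ValueError(
            f"frame_len {frame_len} s shorter than 2 cycles of the lowest "
            f"band centre ({centre} Hz)")
    if frame_len * lo <= 2.0:
        logger.info("frame_len %.3g s holds only ~%.1f cycles at %.3g Hz; "
                    "low-band power is biased", frame_len, frame_len * lo, lo)
    win = int(round(frame_len * segment.fs))
    step = max(1, int(round(frame_step * segment.fs)))
    n_frames = (segment.data.shape[1] - win) // step + 1
    frames = []
    for k in range(n_frames):
        sub = Segment(segment.data[:, k * step: k * step + win], segment.fs,
                      segment.subject_id, segment.index,
                      list(segment.channel_names))
        frames.append(make_brainmap(sub, layout, bands, grid_size, fill).grid)
    return BrainMapSequence(np.stack(frames), hull_mask(layout, grid_size),
                            segment.subject_id, segment.index)


def save_png(bmap: BrainMap, path, dpi: int = 100) -> None:
    """Render a brain map's three band planes side by side (needs
    matplotlib; inspection aid only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, k, name in zip(axes, range(3), bmap.band_names):
        ax.imshow(bmap.grid[:, :, k], cmap="viridis")
        ax.set_title(name)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def normalize_maps(maps: np.ndarray, mask: np.ndarray,
                   mode: str = "per_band_z",
                   stats: dict | None = None) -> tuple[np.ndarray, dict]:
    """Normalize stacked maps; returns (normalized, statistics).

    ``maps`` has shape (..., grid, grid, 3).  Statistics are computed over
    in-hull pixels only; pass the ``stats`` of the training set to apply
    the same transform to held-out data (no recomputation).  Out-of-hull
    pixels are left at the fill value.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if mode == "none":
        return maps, {"mode": "none"}
    flat = maps.reshape(-1, *maps.shape[-3:])
    out = flat.copy()
    if mode == "log_per_band_z":
        # dB-like scale: band power is heavy-tailed and class effects are
        # multiplicative, so z-scoring log-power is the natural transform
        flat = flat.copy()
        flat[:, mask, :] = np.log10(np.clip(flat[:, mask, :], 0, None) + 1e-6)
        out = flat.copy()
        mode_inner = "per_band_z"
        if stats is None:
            mean = flat[:, mask, :].mean(axis=(0, 1))
            sd = flat[:, mask, :].std(axis=(0, 1))
            sd = np.where(sd > 0, sd, 1.0)
            stats = {"mode": "log_per_band_z", "mean": mean.tolist(),
                     "sd": sd.tolist()}
        mean = np.asarray(stats["mean"])
        sd = np.asarray(stats["sd"])
        out[:, mask, :] = (flat[:, mask, :] - mean) / sd
    elif mode == "per_band_z":
        if stats is None:
            mean = flat[:, mask, :].mean(axis=(0, 1))
            sd = flat[:, mask, :].std(axis=(0, 1))
            sd = np.where(sd > 0, sd, 1.0)
            stats = {"mode": mode, "mean": mean.tolist(), "sd": sd.tolist()}
        mean = np.asarray(stats["mean"])
        sd = np.asarray(stats["sd"])
        out[:, mask, :] = (flat[:, mask, :] - mean) / sd
    elif mode == "global_max":
        if stats is None:
            peak = np.abs(flat[:, mask, :]).max()
            stats = {"mode": mode, "max": float(peak if peak > 0 else 1.0)}
        out[:, mask, :] = flat[:, mask, :] / stats["max"]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out.reshape(maps.shape), stats
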