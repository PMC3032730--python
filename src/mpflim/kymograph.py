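"""Intensity and average-lifetime kymograms along a path.

A kymogram displays photon counts (or a fitted lifetime) as a function of
position along a user-drawn path and acquisition time, the standard way to
visualize organelle transport along a neuronal process.  Photons are
assigned to the nearest path sample within a transverse corridor and to
acquisition-time frames; each (position, frame) bin keeps its micro-time
histogram so a per-bin amplitude fit (lifetimes fixed from the global
analysis) yields an average-lifetime kymogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .decay_model import Kernels, average_lifetime, normalized_amplitudes
from .global_fit import fit_amplitudes_batch
from .io import CHANNEL_BY_NAME, PhotonList, TimeAxis, DEFAULT_TIME_AXIS

__all__ = ["KymographSpec", "Kymograph", "extract_kymograph", "lifetime_kymograph"]


@dataclass
class KymographSpec:
    """Path, corridor width, frame duration and channel of a kymogram."""

    path: np.ndarray  # (K, 2) pixel coordinates (x, y)
    frame_duration_s: float
    channel: str
    width: float = 3.0
    min_photons: float = 30.0

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[0] < 2 or self.path.shape[1] != 2:
            raise ValueError("path must be a polyline of >= 2 (x, y) points")
        if self.width < 1:
            raise ValueError("corridor width must be >= 1 pixel")
        if not self.frame_duration_s > 0:
            raise ValueError("frame duration must be positive")
        if self.channel not in CHANNEL_BY_NAME:
            raise ValueError(f"unknown channel {self.channel!r}")

    def sample_positions(self) -> np.ndarray:
        """Path resampled at 1-pixel arc-length steps."""
        pts = self.path
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        arc = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = arc[-1]
        if total <= 0:
            raise ValueError("degenerate path of zero length")
        s = np.arange(0.0, total + 0.5, 1.0)
        x = np.interp(s, arc, pts[:, 0])
        y = np.interp(s, arc, pts[:, 1])
        return np.column_stack([x, y])


@dataclass
class Kymograph:
    """Position-along-path x frame matrices."""

    intensity: np.ndarray  # (S, F) photon counts
    lifetime: np.ndarray | None  # (S, F) tau_av in ps, NaN below the floor
    spec: KymographSpec
    positions: np.ndarray  # (S, 2) sampled path points


def _assign(photons: PhotonList, spec: KymographSpec):
    """Bin photons of the requested channel to (position, frame)."""
    if not photons.has_macrotime:
        raise ValueError(
            "photon list lacks the macrotime_s column required for kymograms"
        )
    f = photons.frame
    ch = CHANNEL_BY_NAME[spec.channel]
    in_channel = (
        (f["excitation"].to_numpy() == ch.excitation_nm)
        & (f["spectral"].to_numpy() == ch.emission_band)
    )
    sub = f.loc[in_channel]
    positions = spec.sample_positions()
    tree = cKDTree(positions)
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    if len(xy):
        dist, pos_idx = tree.query(xy)
        inside = dist <= spec.width / 2.0
    else:
        pos_idx = np.empty(0, dtype=int)
        inside = np.empty(0, dtype=bool)
    frames = np.floor(
        sub["macrotime_s"].to_numpy(dtype=float) / spec.frame_duration_s
    ).astype(int)
    n_frames = int(frames.max()) + 1 if len(frames) else 0
    return sub, positions, pos_idx, inside, frames, n_frames


def extract_kymograph(photons: PhotonList, spec: KymographSpec) -> Kymograph:
    """Intensity kymogram: photon counts per (path position, frame).

    Photons farther than ``width/2`` from the path are excluded; photons in
    the corridor are conserved (column sums equal the corridor counts per
    frame).  Empty bins are zero, not an error.
    """
    sub, positions, pos_idx, inside, frames, n_frames = _assign(photons, spec)
    S = len(positions)
    intensity = np.zeros((S, max(n_frames, 1)))
    if inside.any():
        np.add.at(intensity, (pos_idx[inside], frames[inside]), 1.0)
    return Kymograph(intensity, None, spec, positions)


def lifetime_kymograph(
    photons: PhotonList,
    spec: KymographSpec,
    kernels: Kernels,
    time_axis: TimeAxis = DEFAULT_TIME_AXIS,
) -> Kymograph:
    """Average-lifetime kymogram by per-bin amplitude fits.

    Component lifetimes must already be fixed (global analysis); every
    (position, frame) bin with at least ``spec.min_photons`` photons gets a
    multinomial-deviance amplitude fit and the intensity-weighted average
    lifetime.  Bins below the floor are NaN.
    """
    sub, positions, pos_idx, inside, frames, n_frames = _assign(photons, spec)
    S = len(positions)
    F = max(n_frames, 1)
    T = time_axis.n_channels
    hist = np.zeros((S * F, T))
    if inside.any():
        tch = np.floor(
            (sub["microtime_ps"].to_numpy(dtype=float)[inside] - time_axis.origin)
            / time_axis.channel_width
        ).astype(int)
        ok = (tch >= 0) & (tch < T)
        flat_bin = pos_idx[inside][ok] * F + frames[inside][ok]
        np.add.at(hist, (flat_bin, tch[ok]), 1.0)

    intensity = hist.sum(axis=1).reshape(S, F)
    lifetime = np.full(S * F, np.nan)
    n_per_bin = hist.sum(axis=1)
    fit_mask = n_per_bin >= spec.min_photons
    if fit_mask.any():
        alpha, _, fitted = fit_amplitudes_batch(hist[fit_mask], kernels)
        rows = np.flatnonzero(fit_mask)
        for k, row in enumerate(rows):
            if fitted[k]:
                a = normalized_amplitudes(alpha[k])
                lifetime[row] = average_lifetime(a, kernels.taus)
    return Kymograph(intensity, lifetime.reshape(S, F), spec, positions)
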