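"""Foreground segmentation and temporal quantification of well images.

Phase-contrast images of cultured cells show a dominant mid-grey
background with cells appearing as locally darker *and* brighter texture.
Segmentation therefore brackets the background mode with an adaptive
intensity interval [lo, hi]: the median intensity mu_b estimates the
background level, and Otsu's threshold is applied separately to the
sub-mu_b and supra-mu_b pixel populations to find the two interval ends.
Pixels outside the interval are foreground.

Two per-well temporal readouts are derived from the segmented frames:

* confluence change  dC(t_i) = (c(t_i) - c(t_0)) / c(t_0), with c the
  foreground area fraction, and
* morphology change  dM(t_i) = ||h(t_i) - h(t_0)||_1 / ||h(t_0)||_1,
  with h the hierarchical pixel histogram (PHHC) of foreground
  intensities over a multi-resolution pyramid.

Both are relative to the first recorded frame, which normalizes out
differences in cell seeding between wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import downscale_local_mean


@dataclass(frozen=True)
class PHHCParams:
    """Hierarchical pixel histogram parameters.

    ``n_levels`` pyramid levels, downsampled by ``scale_reduction`` per
    level; ``n_bins`` fixed-range intensity bins per level.  ``bin_range``
    should be held fixed across the wells of a plate so histograms are
    comparable between wells.
    """

    n_levels: int = 3
    scale_reduction: int = 2
    n_bins: int = 16
    bin_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        if self.n_levels < 1 or self.n_bins < 2 or self.scale_reduction <= 1:
            raise ValueError("require n_levels >= 1, n_bins >= 2, scale_reduction > 1")


@dataclass
class BackgroundInterval:
    lo: float
    hi: float
    mu_b: float

    def __post_init__(self):
        if not (self.lo <= self.mu_b <= self.hi):
            raise ValueError("require lo <= mu_b <= hi")


@dataclass
class WellProfile:
    """All temporal readouts of one well, on a shared time axis."""

    well_id: str
    times_h: np.ndarray
    delta_confluence: np.ndarray
    delta_morphology: np.ndarray
    object_counts: np.ndarray | None = None
    survival_index: float | None = None
    confluence: np.ndarray | None = None


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    return frame


def estimate_background_level(frame: np.ndarray) -> float:
    """Global background intensity estimate: the median pixel intensity.

    The background dominates phase-contrast frames at sub-confluent
    densities, so the median is a robust level estimate.
    """
    return float(np.median(_check_frame(frame)))


def adaptive_background_interval(frame: np.ndarray) -> BackgroundInterval:
    """Adaptive background interval via double one-sided Otsu thresholding.

    Pixels are split at mu_b; Otsu's method applied to the sub-mu_b
    population yields ``lo`` and to the supra-mu_b population yields
    ``hi``.  A constant image degenerates to [v, v] with a warning; a side
    with fewer than two distinct intensities contributes its extreme value
    (empty foreground on that side).
    """
    frame = _check_frame(frame)
    mu_b = float(np.median(frame))
    lower = frame[frame < mu_b]
    upper = frame[frame > mu_b]
    if lower.size == 0 and upper.size == 0:
        warnings.warn("constant image: degenerate background interval", stacklevel=2)
        return BackgroundInterval(lo=mu_b, hi=mu_b, mu_b=mu_b)
    lo = _one_sided_otsu(lower, fallback=mu_b, side="low")
    hi = _one_sided_otsu(upper, fallback=mu_b, side="high")
    return BackgroundInterval(lo=min(lo, mu_b), hi=max(hi, mu_b), mu_b=mu_b)


def _one_sided_otsu(values: np.ndarray, fallback: float, side: str) -> float:
    if np.unique(values).size < 2:
        if values.size == 0:
            return fallback
        return float(values.min()) if side == "low" else float(values.max())
    return float(threshold_otsu(values))


def segment_foreground(frame: np.ndarray, interval: BackgroundInterval) -> np.ndarray:
    """Binary foreground mask: intensity below ``lo`` or above ``hi``."""
    frame = _check_frame(frame)
    return (frame < interval.lo) | (frame > interval.hi)


def confluence(mask: np.ndarray) -> float:
    """Foreground area fraction of a binary mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(mask) / mask.size)


def delta_confluence(series: np.ndarray) -> np.ndarray:
    """Relative change in confluence versus the first time point."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty confluence series")
    c0 = series[0]
    if c0 == 0:
        raise ZeroDivisionError("confluence at t0 is zero; cannot form relative change")
    return (series - c0) / c0


def phhc_features(
    frame: np.ndarray, mask: np.ndarray, params: PHHCParams = PHHCParams()
) -> np.ndarray:
    """Hierarchical pixel histogram of the foreground over an image pyramid.

    Level 0 is the full-resolution frame; each further level downsamples
    frame (local averaging) and mask (nearest neighbor) by
    ``scale_reduction``.  Foreground intensities at each level are binned
    into ``n_bins`` fixed-range bins and the level histograms are
    concatenated.
    """
    frame = _check_frame(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")
    blocks = []
    level_frame, level_mask = frame, mask
    for level in range(params.n_levels):
        if level > 0:
            f = params.scale_reduction
            level_frame = downscale_local_mean(level_frame, (f, f))
            level_mask = level_mask[::f, ::f]
            # local averaging can leave a ragged trailing block; align shapes
            level_mask = level_mask[: level_frame.shape[0], : level_frame.shape[1]]
            if level_mask.shape != level_frame.shape:
                pad = [(0, level_frame.shape[i] - level_mask.shape[i]) for i in (0, 1)]
                level_mask = np.pad(level_mask, pad, mode="edge")
        fg = level_frame[level_mask]
        hist, _ = np.histogram(fg, bins=params.n_bins, range=params.bin_range)
        blocks.append(hist.astype(float))
    h = np.concatenate(blocks)
    if not h.any():
        warnings.warn("empty foreground at all pyramid levels; zero PHHC vector", stacklevel=2)
    return h


def delta_morphology(features: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Relative L1 change of the PHHC vector versus the first time point."""
    feats = [np.asarray(h, dtype=float) for h in features]
    if not feats:
        raise ValueError("empty feature series")
    h0 = feats[0]
    norm0 = np.abs(h0).sum()
    if norm0 == 0:
        raise ZeroDivisionError("reference histogram has zero mass")
    return np.array([np.abs(h - h0).sum() / norm0 for h in feats])


def well_profile_from_frames(
    well_id: str,
    frames: list[np.ndarray],
    times_h: np.ndarray | None = None,
    params: PHHCParams = PHHCParams(),
) -> WellProfile:
    """Segment every frame of a well and build its temporal profile.

    Each frame is segmented with its own adaptive background interval
    (frames are independent; processing order does not matter), then the
    per-frame confluences and PHHC vectors are reduced to dC and dM
    series relative to the first frame.
    """
    if not frames:
        raise ValueError("no frames for well")
    confl = np.empty(len(frames))
    hists = []
    for i, frame in enumerate(frames):
        interval = adaptive_background_interval(frame)
        mask = segment_foreground(frame, interval)
        confl[i] = confluence(mask)
        hists.append(phhc_features(frame, mask, params))
    if times_h is None:
        times_h = 4.0 * np.arange(len(frames))
    return WellProfile(
        well_id=well_id,
        times_h=np.asarray(times_h, dtype=float),
        delta_confluence=delta_confluence(confl),
        delta_morphology=delta_morphology(hists),
        confluence=confl,
    )
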