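"""Matched-filter detection and counting of apoptotic-like objects.

A user-selected prototype patch ``s`` (an apoptotic-like cell cut from a
raw frame, ~33x32 px in practice) defines a linear matched filter with
coefficient patch ``w = s - b``, where ``b`` is a scalar background level
broadcast over the patch and the noise covariance is taken as the
identity.  Sliding the filter over a frame gives the response map
``y(p) = sum(w * r_p)`` over all fully contained patches; the response
peaks where prototype-like objects occur.

Two counting algorithms convert a thresholded response map into an object
count: *taboo-based* counting greedily accepts the largest remaining
response, then masks a patch-sized neighborhood around it; *position-based*
counting projects the supra-threshold set onto columns, splits it into
maximal column intervals, and counts maximal row intervals within each.
The per-frame count is the mean of the two.

The detection threshold is tuned by supervised learning on annotated
training images: the loss is the mean absolute difference between observed
and predicted counts, minimized over a set of starting thresholds followed
by interval refinement, inside a repeated k-fold cross-validation whose
median leave-out loss guards against overfitting.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate2d


class NotTunedError(RuntimeError):
    """Counting was requested before a detection threshold was available."""


class OverfitError(RuntimeError):
    """Cross-validated tuning failed its generalization check.

    Raised when the median leave-out loss exceeds the overfit cutoff;
    the remedy is more (or more consistent) annotated training images.
    """

    def __init__(self, median_test_loss: float, cutoff: float):
        self.median_test_loss = median_test_loss
        self.cutoff = cutoff
        super().__init__(
            f"median cross-validation test loss {median_test_loss:.2f} exceeds "
            f"{cutoff:g}; re-train with more annotated images"
        )


@dataclass(frozen=True)
class Prototype:
    """The signal prototype patch and where it came from."""

    patch: np.ndarray
    well: str = ""
    frame_index: int = -1
    corner: tuple[int, int] = (-1, -1)

    def __post_init__(self):
        patch = np.asarray(self.patch, dtype=float)
        if patch.ndim != 2 or min(patch.shape) < 3:
            raise ValueError("prototype patch must be 2-D with both dimensions >= 3")
        if not np.all(np.isfinite(patch)):
            raise ValueError("prototype patch contains non-finite values")
        object.__setattr__(self, "patch", patch)

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape


@dataclass
class TuningReport:
    fold_optima: list[float] = field(default_factory=list)
    test_losses: list[float] = field(default_factory=list)
    median_test_loss: float = float("nan")


@dataclass
class MatchedFilterModel:
    s: np.ndarray
    b: float
    w: np.ndarray
    threshold: float | None = None
    tuning: TuningReport | None = None

    @property
    def patch_shape(self) -> tuple[int, int]:
        return self.w.shape


@dataclass
class CountResult:
    taboo_count: int
    position_count: int
    mean_count: float
    centers: list[tuple[int, int]] = field(default_factory=list)


def build_filter(prototype: Prototype, background_level: float) -> MatchedFilterModel:
    """Matched filter coefficients for identity noise covariance: w = s - b."""
    if not np.isfinite(background_level):
        raise ValueError("background level must be finite")
    w = prototype.patch - background_level
    if not w.any():
        warnings.warn("prototype equals background everywhere; zero filter", stacklevel=2)
    return MatchedFilterModel(s=prototype.patch.copy(), b=float(background_level), w=w)


def filter_response(frame: np.ndarray, model: MatchedFilterModel) -> np.ndarray:
    """Response map over all valid (fully contained) patch positions.

    y(p) = sum(w * r_p); output shape (H - N_r + 1, W - N_c + 1).
    """
    frame = np.asarray(frame, dtype=float)
    nr, nc = model.patch_shape
    if frame.ndim != 2 or frame.shape[0] < nr or frame.shape[1] < nc:
        raise ValueError("frame smaller than the filter patch")
    return correlate2d(frame, model.w, mode="valid")


def _center_offsets(patch_shape: tuple[int, int]) -> tuple[int, int, int, int]:
    # footprint extents around the center; even dimensions put the center
    # toward the top-left
    nr, nc = patch_shape
    top, bottom = (nr - 1) // 2, nr // 2
    left, right = (nc - 1) // 2, nc // 2
    return top, bottom, left, right


def taboo_count(
    resp: np.ndarray, tau: float, patch_shape: tuple[int, int]
) -> tuple[int, list[tuple[int, int]]]:
    """Greedy peak picking with a patch-sized taboo neighborhood.

    Repeatedly accept the largest non-tabooed response if it reaches
    ``tau``, recording its position and masking the patch footprint
    centered there, until no response remains at or above ``tau``.
    """
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    work = np.array(resp, dtype=float, copy=True)
    top, bottom, left, right = _center_offsets(patch_shape)
    centers: list[tuple[int, int]] = []
    while True:
        idx = int(np.argmax(work))
        r, c = np.unravel_index(idx, work.shape)
        if work[r, c] < tau:
            break
        centers.append((int(r), int(c)))
        r0, r1 = max(0, r - top), min(work.shape[0], r + bottom + 1)
        c0, c1 = max(0, c - left), min(work.shape[1], c + right + 1)
        work[r0:r1, c0:c1] = -np.inf
    return len(centers), centers


def _runs(occupied: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True runs as half-open (start, stop) intervals."""
    idx = np.flatnonzero(occupied)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def position_count(resp: np.ndarray, tau: float) -> int:
    """Interval-projection counting of the supra-threshold response set.

    Horizontal pass: maximal contiguous column intervals containing any
    supra-threshold pixel.  Vertical pass: within each column interval,
    maximal contiguous row intervals of supra-threshold pixels.  The count
    is the sum over column intervals of their row-interval counts.
    """
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    above = np.asarray(resp) >= tau
    total = 0
    for c0, c1 in _runs(above.any(axis=0)):
        total += len(_runs(above[:, c0:c1].any(axis=1)))
    return total


def frame_count(frame: np.ndarray, model: MatchedFilterModel, tau: float | None = None) -> CountResult:
    """Count objects in one frame with both algorithms and average them."""
    if tau is None:
        tau = model.threshold
    if tau is None:
        raise NotTunedError("no detection threshold: tune the model or pass tau")
    resp = filter_response(frame, model)
    n_taboo, centers = taboo_count(resp, tau, model.patch_shape)
    n_pos = position_count(resp, tau)
    # response-map coordinates are patch top-left corners; report detections
    # at the patch center in frame coordinates
    top, _, left, _ = _center_offsets(model.patch_shape)
    centers = [(r + top, c + left) for r, c in centers]
    return CountResult(
        taboo_count=n_taboo,
        position_count=n_pos,
        mean_count=(n_taboo + n_pos) / 2.0,
        centers=centers,
    )


def well_counts(frames: list[np.ndarray], model: MatchedFilterModel) -> np.ndarray:
    """Per-time-point mean counts for one well's ordered frames.

    Frames are independent, so any processing order yields the same
    result; the output preserves the input time order.
    """
    if not frames:
        raise ValueError("no frames for well")
    shape = np.asarray(frames[0]).shape
    for f in frames:
        if np.asarray(f).shape != shape:
            raise ValueError("inconsistent frame sizes within well")
    return np.array([frame_count(f, model).mean_count for f in frames])


# --- threshold tuning -------------------------------------------------------

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _counts_at(responses: list[np.ndarray], tau: float, patch_shape) -> np.ndarray:
    out = np.empty(len(responses))
    for i, resp in enumerate(responses):
        n_taboo, _ = taboo_count(resp, tau, patch_shape)
        out[i] = (n_taboo + position_count(resp, tau)) / 2.0
    return out


def _loss(responses, observed, tau, patch_shape) -> float:
    predicted = _counts_at(responses, tau, patch_shape)
    return float(np.mean(np.abs(np.asarray(observed, dtype=float) - predicted)))


def _optimize_threshold(
    responses: list[np.ndarray],
    observed: list[float],
    patch_shape: tuple[int, int],
    background_response: float,
    n_starts: int = 11,
    n_refine: int = 20,
) -> float:
    """Interval optimization of the counting loss over the threshold.

    Candidate starting points are the deciles of the pooled supra-background
    response values; the best start (ties toward the larger threshold,
    which detects less) is refined by golden-section iterations on the
    bracketing interval between its neighboring starting points.
    """
    pooled = np.concatenate([r.ravel() for r in responses])
    supra = pooled[pooled > background_response]
    if supra.size == 0:
        supra = pooled
    starts = np.unique(np.percentile(supra, np.linspace(0, 100, n_starts)))
    losses = np.array([_loss(responses, observed, t, patch_shape) for t in starts])
    best = losses.min()
    # tie-break toward the larger threshold
    i_best = int(np.flatnonzero(losses == best)[-1])
    lo = starts[i_best - 1] if i_best > 0 else starts[i_best]
    hi = starts[i_best + 1] if i_best < len(starts) - 1 else starts[i_best]
    best_tau, best_loss = float(starts[i_best]), float(best)
    a, b = float(lo), float(hi)
    for _ in range(n_refine):
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = _loss(responses, observed, c, patch_shape)
        fd = _loss(responses, observed, d, patch_shape)
        # probe points improve or tie the incumbent; ties go to larger tau
        for tau_cand, f_cand in ((c, fc), (d, fd)):
            if f_cand < best_loss or (f_cand == best_loss and tau_cand > best_tau):
                best_tau, best_loss = float(tau_cand), float(f_cand)
        if fc < fd:
            b = d
        else:
            a = c
    return best_tau


def tune_threshold(
    training: list[tuple[np.ndarray, float]],
    model: MatchedFilterModel,
    folds: int = 4,
    repeats: int = 2,
    overfit_cutoff: float = 5.0,
    seed: int = 0,
) -> MatchedFilterModel:
    """Cross-validated supervised tuning of the detection threshold.

    ``training`` pairs each image with its manually observed object count.
    For each of ``folds * repeats`` cross-validation partitions the loss
    (mean |observed - predicted| with predicted the two-algorithm mean
    count) is minimized over the threshold on the held-in images, and the
    leave-out loss of the per-fold optimum is recorded.  If the median
    leave-out loss exceeds ``overfit_cutoff`` tuning aborts; otherwise the
    final threshold is the median of the per-fold optima.

    Returns the model with ``threshold`` and ``tuning`` set (in place).
    """
    if len(training) < folds:
        raise ValueError(f"need at least {folds} training images for {folds}-fold CV")
    responses = [filter_response(frame, model) for frame, _ in training]
    observed = [float(n) for _, n in training]
    background_response = float(model.w.sum() * model.b)
    rng = np.random.default_rng(seed)
    report = TuningReport()
    n = len(training)
    for _rep in range(repeats):
        order = rng.permutation(n)
        fold_ids = np.arange(n) % folds
        for j in range(folds):
            test_idx = order[fold_ids == j]
            train_idx = order[fold_ids != j]
            tau_j = _optimize_threshold(
                [responses[i] for i in train_idx],
                [observed[i] for i in train_idx],
                model.patch_shape,
                background_response,
            )
            test_loss = _loss(
                [responses[i] for i in test_idx],
                [observed[i] for i in test_idx],
                tau_j,
                model.patch_shape,
            )
            report.fold_optima.append(tau_j)
            report.test_losses.append(test_loss)
    report.median_test_loss = float(statistics.median(report.test_losses))
    if report.median_test_loss > overfit_cutoff:
        raise OverfitError(report.median_test_loss, overfit_cutoff)
    model.threshold = float(statistics.median(report.fold_optima))
    model.tuning = report
    return model
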