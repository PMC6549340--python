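"""Plate quality control: intra-plate well exclusion and inter-plate outlier rejection.

Intra-plate QC checks that at the earliest (ideally pre-effect) frame all
wells of a plate look alike: wells whose morphology histograms deviate
from the rest contain artifacts (debris, focus failures, empty wells) and
are excluded from every downstream analysis.

Inter-plate QC decides which conditions may have their replicate growth
curves merged.  The variability of a condition across replicate plates is
the area between its replicate curves,

    V_w = sum_t ( max_r dC_w^(r)(t) - min_r dC_w^(r)(t) ),

and a resampling null distribution — drawing one untreated well per plate
with replacement, many times — supplies a percentile threshold above
which the observed variability is atypical and the condition is flagged
as a non-mergeable outlier.  At the default 95th percentile the false
alarm probability on well-behaved conditions is 5% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VariabilityNull:
    """Resampled null distribution of inter-plate variability."""

    samples: np.ndarray
    n_sims: int
    percentile: float
    threshold: float


@dataclass
class QCFlags:
    """Pass/fail bookkeeping for wells (intra-plate) and conditions (inter-plate)."""

    intra_failed: set[str] = field(default_factory=set)
    inter_outliers: set[str] = field(default_factory=set)
    variabilities: dict[str, float] = field(default_factory=dict)
    details: dict[str, str] = field(default_factory=dict)

    def passes_intra(self, well: str) -> bool:
        return well not in self.intra_failed

    def passes_inter(self, condition: str) -> bool:
        return condition not in self.inter_outliers


def _relative_l1(a: np.ndarray, b: np.ndarray) -> float:
    denom = 0.5 * (np.abs(a).sum() + np.abs(b).sum())
    if denom == 0:
        return 0.0
    return float(np.abs(a - b).sum() / denom)


def intra_plate_qc(
    features_t0: dict[str, np.ndarray],
    mad_factor: float = 3.0,
    min_distance: float = 0.5,
) -> QCFlags:
    """Exclude wells whose first-frame morphology histogram deviates.

    Computes pairwise relative L1 distances between well histograms
    (normalized by the mean histogram mass, so identical-shape histograms
    score ~0 and disjoint-support ones score 2) and flags wells whose
    median distance to all others exceeds median + ``mad_factor`` * MAD of
    the per-well median distances.  ``min_distance`` is an absolute floor
    on the cutoff: on a homogeneous plate the MAD collapses and the pure
    rule would flag ordinary extremes, so a well is only excluded when its
    deviation is also materially large (0.5 means histograms differing by
    a quarter of their mass).
    """
    wells = sorted(features_t0)
    if len(wells) < 3:
        raise ValueError("intra-plate QC needs at least 3 wells")
    feats = [np.asarray(features_t0[w], dtype=float) for w in wells]
    n = len(wells)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _relative_l1(feats[i], feats[j])
    med_to_others = np.array(
        [np.median(np.delete(dist[i], i)) for i in range(n)]
    )
    center = np.median(med_to_others)
    mad = np.median(np.abs(med_to_others - center))
    cutoff = max(center + mad_factor * mad, min_distance)
    flags = QCFlags()
    for well, d in zip(wells, med_to_others):
        if d > cutoff:
            flags.intra_failed.add(well)
            flags.details[well] = f"median pairwise distance {d:.3g} > cutoff {cutoff:.3g}"
    return flags


def inter_plate_variability(curves: np.ndarray) -> float:
    """Area between replicate growth curves: summed per-time-point span."""
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need >= 2 replicate curves on a shared time axis")
    return float((curves.max(axis=0) - curves.min(axis=0)).sum())


def null_variability_distribution(
    untreated_curves: list[np.ndarray],
    n_sims: int = 10000,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> VariabilityNull:
    """Resampling null for inter-plate variability from untreated wells.

    ``untreated_curves[p]`` holds the growth curves (rows) of the eligible
    untreated wells of plate ``p``.  Each simulation draws one untreated
    well per plate with replacement and computes the variability of the
    drawn set; the stated percentile of the collected samples is the QC
    threshold.
    """
    plates = [np.atleast_2d(np.asarray(c, dtype=float)) for c in untreated_curves]
    if len(plates) < 2:
        raise ValueError("need untreated curves from >= 2 plates")
    n_time = plates[0].shape[1]
    for p, c in enumerate(plates):
        if c.shape[0] < 1:
            raise ValueError(f"plate {p} has no eligible untreated wells")
        if c.shape[1] != n_time:
            raise ValueError("mismatched time axes across plates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # vectorized: draw an (n_sims,) well index per plate, stack the picked
    # curves to shape (n_plates, n_sims, n_time) and reduce over plates
    picked = np.stack(
        [c[rng.integers(0, c.shape[0], size=n_sims)] for c in plates], axis=0
    )
    samples = (picked.max(axis=0) - picked.min(axis=0)).sum(axis=1)
    threshold = float(np.percentile(samples, percentile))
    return VariabilityNull(
        samples=samples, n_sims=n_sims, percentile=percentile, threshold=threshold
    )


def inter_plate_qc(
    variabilities: dict[str, float],
    null: VariabilityNull,
    flags: QCFlags | None = None,
) -> QCFlags:
    """Flag conditions whose variability strictly exceeds the null threshold."""
    if flags is None:
        flags = QCFlags()
    for condition, v in variabilities.items():
        flags.variabilities[condition] = float(v)
        if v > null.threshold:
            flags.inter_outliers.add(condition)
            flags.details[condition] = (
                f"V={v:.4g} > tau_{null.percentile:g}={null.threshold:.4g}"
            )
    return flags


def merge_replicates(
    curves: np.ndarray, excluded: set[int] | None = None
) -> tuple[np.ndarray, np.ndarray, int] | None:
    """Per-time mean and standard deviation over surviving replicates.

    Returns (mean, sd, n_used), or None when every replicate is excluded
    (the condition is dropped, not an error).
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    keep = [i for i in range(curves.shape[0]) if not excluded or i not in excluded]
    if not keep:
        return None
    surviving = curves[keep]
    return surviving.mean(axis=0), surviving.std(axis=0, ddof=0), len(keep)
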