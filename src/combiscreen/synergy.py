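"""End-point survival index and higher-order Bliss synergy scoring.

The survival index of a combination c_n is the background-corrected,
control-normalized end-point signal

    S(c_n) = (f(c_n) - median f_blank) / (median f_control - median f_blank),

so S = 0 at blank level and S = 1 at untreated level; growth-inhibiting
treatments fall in [0, 1] but S is deliberately not clamped (stimulated
wells can exceed 1 and are reported with a warning flag).

Bliss independence generalizes to any order: the expected survival of an
n-drug combination is the product of the single-drug survivals, and the
Bliss index is

    B(c_n) = prod_i S(c_i) - S(c_n),

positive for synergy, negative for antagonism, in [-1, 1] for inputs in
[0, 1].  B is ambiguous — many (expected, observed) pairs share one B —
so the scaled index

    B_S(c_n) = B(c_n) * (1 - min{expected, observed})

suppresses synergy scores achieved at high observed survival and
antagonism scores at high expected survival, disambiguating such pairs
while preserving B's sign and never exceeding its magnitude.

Significance is assessed by replicate resampling: a percentile bootstrap
CI on B_S plus a null ensemble in which the observed combination survival
is replaced by products of independently resampled single-drug replicate
draws (Bliss independence holds by construction in the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from combiscreen.design import Combination, PlateLayout


@dataclass
class SynergyScore:
    combination: Combination
    expected: float
    observed: float
    bliss: float
    scaled_bliss: float
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    qc_excluded: bool = False
    out_of_range: bool = False  # any survival input outside [0, 1]


def survival_index(f: float, blanks: np.ndarray, controls: np.ndarray) -> float:
    """Blank-corrected, control-normalized survival index (not clamped)."""
    blank = float(np.median(blanks))
    control = float(np.median(controls))
    if control == blank:
        raise ValueError("degenerate normalization: median(controls) == median(blanks)")
    return (float(f) - blank) / (control - blank)


def bliss_index(single_S, combo_S: float) -> float:
    """Higher-order Bliss index: expected product minus observed survival."""
    singles = np.asarray(single_S, dtype=float)
    if singles.size == 0:
        raise ValueError("need at least one single-drug survival value")
    return float(np.prod(singles) - combo_S)


def scaled_bliss(single_S, combo_S: float) -> float:
    """Scaled Bliss index: B times (1 - min{expected, observed}).

    Equivalent piecewise form: B*(1 - observed) for B > 0, 0 for B = 0,
    B*(1 - expected) for B < 0.
    """
    singles = np.asarray(single_S, dtype=float)
    if singles.size == 0:
        raise ValueError("need at least one single-drug survival value")
    expected = float(np.prod(singles))
    b = expected - float(combo_S)
    return b * (1.0 - min(expected, float(combo_S)))


def synergy_significance(
    single_reps: list[np.ndarray],
    combo_reps: np.ndarray,
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
    ci: float = 95.0,
) -> tuple[float, tuple[float, float]]:
    """Resampling p-value and percentile bootstrap CI for the scaled Bliss index.

    The bootstrap resamples replicates with replacement within each
    condition and recomputes B_S from the resampled means.  The null
    ensemble substitutes the combination's survival with the product of
    independently drawn single-drug replicate values, so its B_S scatter
    reflects replicate noise under exact Bliss independence; the two-sided
    p is the fraction of null |B_S| at or above the observed |B_S|.
    """
    singles = [np.asarray(s, dtype=float) for s in single_reps]
    combo = np.asarray(combo_reps, dtype=float)
    if combo.size < 2 or any(s.size < 2 for s in singles):
        raise ValueError("need >= 2 replicates per condition for resampling")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed_bs = scaled_bliss([s.mean() for s in singles], combo.mean())

    boot = np.empty(n_boot)
    for i in range(n_boot):
        s_means = [s[rng.integers(0, s.size, s.size)].mean() for s in singles]
        c_mean = combo[rng.integers(0, combo.size, combo.size)].mean()
        boot[i] = scaled_bliss(s_means, c_mean)
    alpha = (100.0 - ci) / 2.0
    ci_low, ci_high = np.percentile(boot, [alpha, 100.0 - alpha])

    null = np.empty(n_boot)
    for i in range(n_boot):
        s_means = [s[rng.integers(0, s.size, s.size)].mean() for s in singles]
        # combination survival implied by independence of resampled singles
        c_null = np.prod([s[rng.integers(0, s.size)] for s in singles])
        null[i] = scaled_bliss(s_means, c_null)
    p = float((np.sum(np.abs(null) >= abs(observed_bs)) + 1) / (n_boot + 1))
    return p, (float(ci_low), float(ci_high))


def plate_synergy_table(
    layout_conditions: list[Combination],
    survival: dict[str, float],
    excluded: set[str] | None = None,
    replicate_survival: dict[str, np.ndarray] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every combination of order >= 2 against its single-drug wells.

    ``survival`` maps a combination label to its (replicate-merged)
    survival index; every member drug of every scored combination must be
    present as a single.  When per-replicate survivals are supplied a
    resampling p-value is computed per combination and Benjamini-Hochberg
    FDR is reported across the family.
    """
    excluded = excluded or set()
    singles = {c.members[0]: c for c in layout_conditions if c.order == 1}
    rows = []
    rng = np.random.default_rng(seed)
    for combo in layout_conditions:
        if combo.order < 2:
            continue
        for drug in combo.members:
            if drug not in singles or singles[drug].label() not in survival:
                raise KeyError(f"missing single-drug well for {drug!r}")
        single_S = [survival[singles[d].label()] for d in combo.members]
        combo_S = survival[combo.label()]
        expected = float(np.prod(single_S))
        b = bliss_index(single_S, combo_S)
        bs = scaled_bliss(single_S, combo_S)
        p = ci_low = ci_high = None
        if replicate_survival is not None:
            reps_s = [replicate_survival[singles[d].label()] for d in combo.members]
            reps_c = replicate_survival[combo.label()]
            p, (ci_low, ci_high) = synergy_significance(
                reps_s, reps_c, n_boot=n_boot, seed=rng
            )
        out_of_range = any(not 0 <= s <= 1 for s in single_S + [combo_S])
        rows.append(
            {
                "combination": combo.label(),
                "order": combo.order,
                "expected": expected,
                "observed": combo_S,
                "bliss": b,
                "scaled_bliss": bs,
                "p": p,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "qc_excluded": combo.label() in excluded,
                "out_of_range": out_of_range,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty and replicate_survival is not None:
        table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
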