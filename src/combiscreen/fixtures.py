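"""Seeded synthetic data generators for every stage of the pipeline.

The generators emulate the data a label-free time-lapse screen produces —
textured grayscale frames with a dominant mid-grey background, cell-like
foreground texture whose area grows over time, planted bright-ring
"apoptotic-like" objects at known positions, end-point fluorescence
values, and replicate plates with independent noise — together with full
ground truth, so every analysis module can be scored without external
data.

Treatment effects are expressed as an :class:`EffectModel` per drug; a
combination inherits the elementwise maximum of its members' effects
unless an explicit higher-order boost is configured.  This creates the
"single drug explains the group" structure that the representative-subset
search is designed to detect.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from combiscreen.design import BLANK, UNTREATED, Combination, PlateLayout

INTENSITY_RANGE = (0.0, 255.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic plate model.

    Frames are much smaller than a real microscope's field of view; the
    analysis algorithms are size-agnostic and the smaller frames keep the
    generated plates fast to process.
    """

    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 17
    frame_interval_h: float = 4.0
    bg_level: float = 100.0
    bg_noise_sd: float = 0.75
    fg_amplitude: float = 45.0
    initial_confluence: float = 0.08
    template_shape: tuple[int, int] = (33, 32)
    template_amplitude: float = 60.0
    template_core_depth: float = 25.0
    fmca_blank_level: float = 500.0
    fmca_control_level: float = 30000.0
    fmca_noise_sd: float = 0.03  # sd of the multiplicative log-normal noise
    confluence_noise_sd: float = 0.0


@dataclass(frozen=True)
class EffectModel:
    """Phenotypic effect of one treatment, relative to untreated cells.

    ``growth_inhibition`` 0..1 scales down the untreated growth rate;
    ``morphology_drift`` >= 0 shifts the foreground intensity mixture over
    time; ``apoptosis_count`` is the number of planted apoptotic-like
    objects at the final frame (ramped linearly from zero);
    ``viability`` is the terminal survival index the end-point assay
    should report.
    """

    growth_inhibition: float = 0.0
    morphology_drift: float = 0.0
    apoptosis_count: int = 0
    viability: float = 1.0


UNTREATED_EFFECT = EffectModel()


def combine_effects(effects: list[EffectModel]) -> EffectModel:
    """Combination effect: elementwise maximum of the member effects.

    Viability combines through the kill fraction (1 - viability), so the
    combined viability is the minimum of the members'.
    """
    if not effects:
        return UNTREATED_EFFECT
    return EffectModel(
        growth_inhibition=max(e.growth_inhibition for e in effects),
        morphology_drift=max(e.morphology_drift for e in effects),
        apoptosis_count=max(e.apoptosis_count for e in effects),
        viability=1.0 - max(1.0 - e.viability for e in effects),
    )


def make_background(
    shape: tuple[int, int], level: float, noise_sd: float, seed, quantize: bool = True
) -> np.ndarray:
    """Flat background with seeded Gaussian texture, clipped to intensity range.

    By default intensities are rounded to integer grey levels, as a camera
    would deliver them; the dominant background mode is then a narrow
    spike, which is what the double-Otsu interval expects.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = level + rng.normal(0.0, noise_sd, size=shape)
    if quantize:
        frame = np.round(frame)
    return np.clip(frame, *INTENSITY_RANGE)


def ring_template(
    shape: tuple[int, int] = (33, 32),
    amplitude: float = 60.0,
    core_depth: float = 25.0,
) -> np.ndarray:
    """Additive template of an apoptotic-like object.

    A bright elliptical ring with a darker core, zero outside the object;
    added on top of the background it mimics the halo-and-core appearance
    of rounded dying cells in phase contrast.
    """
    nr, nc = shape
    r = (np.arange(nr) - (nr - 1) / 2.0) / (nr / 2.0)
    c = (np.arange(nc) - (nc - 1) / 2.0) / (nc / 2.0)
    rho = np.sqrt(r[:, None] ** 2 + c[None, :] ** 2)
    ring = amplitude * np.exp(-(((rho - 0.62) / 0.16) ** 2))
    core = -core_depth * np.exp(-((rho / 0.35) ** 2))
    template = ring + core
    template[rho > 1.0] = 0.0
    return template


def plant_objects(
    frame: np.ndarray,
    template: np.ndarray,
    positions: list[tuple[int, int]],
) -> tuple[np.ndarray, dict]:
    """Additively blend the template at each center position.

    Positions are template centers (even dimensions round the center
    toward the top-left, matching the detector's convention).  Returns
    the new frame and a ground-truth table with exact centers, the count,
    and a record of overlapping placements.
    """
    frame = np.array(frame, dtype=float, copy=True)
    nr, nc = template.shape
    top, left = (nr - 1) // 2, (nc - 1) // 2
    occupied = np.zeros(frame.shape, dtype=bool)
    overlaps = []
    for r, c in positions:
        r0, c0 = r - top, c - left
        if r0 < 0 or c0 < 0 or r0 + nr > frame.shape[0] or c0 + nc > frame.shape[1]:
            raise ValueError(f"template at ({r}, {c}) does not fit inside the frame")
        footprint = template != 0
        if (occupied[r0 : r0 + nr, c0 : c0 + nc] & footprint).any():
            overlaps.append((r, c))
        occupied[r0 : r0 + nr, c0 : c0 + nc] |= footprint
        frame[r0 : r0 + nr, c0 : c0 + nc] += template
    frame = np.clip(frame, *INTENSITY_RANGE)
    truth = {"centers": list(positions), "count": len(positions), "overlaps": overlaps}
    return frame, truth


def random_positions(
    n: int,
    frame_shape: tuple[int, int],
    template_shape: tuple[int, int],
    rng: np.random.Generator,
    min_separation: float | None = None,
    max_tries: int = 2000,
    forbidden: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Rejection-sample template centers with a pairwise minimum separation.

    By default the separation is the template diagonal plus a small
    margin, the regime where both counting algorithms resolve every
    object.  Centers falling on a True pixel of ``forbidden`` are
    rejected (used to keep planted objects off the cell region).
    """
    nr, nc = template_shape
    top, left = (nr - 1) // 2, (nc - 1) // 2
    bottom, right = nr - 1 - top, nc - 1 - left
    if min_separation is None:
        min_separation = float(np.hypot(nr, nc)) + 2.0
    positions: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(positions) == n:
            break
        r = int(rng.integers(top, frame_shape[0] - bottom))
        c = int(rng.integers(left, frame_shape[1] - right))
        if forbidden is not None and forbidden[r, c]:
            continue
        if all(np.hypot(r - pr, c - pc) > min_separation for pr, pc in positions):
            positions.append((r, c))
    if len(positions) < n:
        raise RuntimeError(
            f"could only place {len(positions)}/{n} objects at separation "
            f"{min_separation:.1f} in frame {frame_shape}"
        )
    return positions


def _confluence_schedule(spec: FixtureSpec, effect: EffectModel) -> np.ndarray:
    # untreated cells roughly triple their area over the recording
    t = np.arange(spec.n_frames) * spec.frame_interval_h
    growth_rate = np.log(3.0) / max(t[-1], 1.0)
    rate = growth_rate * (1.0 - effect.growth_inhibition)
    return np.minimum(spec.initial_confluence * np.exp(rate * t), 0.9)


def simulate_well_frames(
    effect: EffectModel, spec: FixtureSpec, seed
) -> tuple[list[np.ndarray], dict]:
    """Time-lapse frames of one well under one effect model.

    Foreground is a centered disk of cell-like texture (pixels offset
    from the background by +-fg_amplitude) whose area follows the growth
    schedule; morphology drift shifts the bright/dark mixture over time;
    apoptotic-like ring objects are planted on a linear count ramp.
    Ground truth records the confluence schedule and planted counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = spec.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.sqrt((yy - h / 2.0) ** 2 + (xx - w / 2.0) ** 2)
    confl = _confluence_schedule(spec, effect)
    if spec.confluence_noise_sd > 0:
        confl = confl * (1.0 + rng.normal(0.0, spec.confluence_noise_sd, confl.size))
        confl = np.clip(confl, 1e-3, 0.95)
    template = ring_template(
        spec.template_shape, spec.template_amplitude, spec.template_core_depth
    )
    frames: list[np.ndarray] = []
    counts: list[int] = []
    # planted objects stay off the (eventual) cell region: detached dying
    # cells lie in the open background, and their confluence contribution
    # is then consistent across replicate plates
    max_radius = np.sqrt(confl.max() * h * w / np.pi)
    cell_region = rho <= max_radius + 2.0
    for i in range(spec.n_frames):
        frame = make_background(spec.frame_shape, spec.bg_level, spec.bg_noise_sd, rng, quantize=False)
        radius = np.sqrt(confl[i] * h * w / np.pi)
        fg = rho <= radius
        # bright/dark texture; drift moves mass from the dark to the bright mode
        frac = i / max(spec.n_frames - 1, 1)
        p_bright = np.clip(0.3 + 0.5 * effect.morphology_drift * frac, 0.0, 1.0)
        signs = np.where(rng.random(int(fg.sum())) < p_bright, 1.0, -1.0)
        frame[fg] += signs * spec.fg_amplitude
        n_objects = int(round(effect.apoptosis_count * frac))
        if n_objects > 0:
            positions = random_positions(
                n_objects, spec.frame_shape, spec.template_shape, rng,
                forbidden=cell_region,
            )
            frame, _ = plant_objects(frame, template, positions)
        frames.append(np.clip(np.round(frame), *INTENSITY_RANGE))
        counts.append(n_objects)
    truth = {"confluence": confl, "planted_counts": np.array(counts)}
    return frames, truth


def simulate_untreated_delta_confluence(
    n_wells: int,
    n_frames: int = 17,
    frame_interval_h: float = 4.0,
    growth_rate: float = np.log(3.0) / 64.0,
    noise_sd: float = 0.05,
    seed=0,
) -> np.ndarray:
    """Growth-curve matrix (wells x time) for untreated wells with i.i.d. noise.

    Each well's confluence follows the shared exponential growth model
    with independent multiplicative measurement noise per time point; the
    returned curves are relative changes versus each well's own first
    frame, so row ``w`` is dC_w(t) with dC_w(t_0) = 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval_h
    c = np.exp(growth_rate * t)[None, :] * (
        1.0 + rng.normal(0.0, noise_sd, size=(n_wells, n_frames))
    )
    return (c - c[:, :1]) / c[:, :1]


@dataclass
class PlateSimulation:
    """In-memory result of simulating one replicate plate."""

    layout: PlateLayout
    frames: dict[str, list[np.ndarray]]
    fmca: dict[str, float]
    truth: dict[str, dict]
    times_h: np.ndarray


def effect_for_condition(
    condition: Combination | str,
    effect_map: dict[str, EffectModel],
    boosts: dict[str, EffectModel] | None = None,
) -> EffectModel:
    if not isinstance(condition, Combination):
        return UNTREATED_EFFECT
    if boosts and condition.label() in boosts:
        return boosts[condition.label()]
    return combine_effects(
        [effect_map.get(d, UNTREATED_EFFECT) for d in condition.members]
    )


def simulate_plate(
    layout: PlateLayout,
    effect_map: dict[str, EffectModel],
    spec: FixtureSpec = FixtureSpec(),
    seed: int = 0,
    boosts: dict[str, EffectModel] | None = None,
    skip_blank_frames: bool = True,
) -> PlateSimulation:
    """Simulate every well of one replicate plate.

    Per well: a frame stack under the condition's (inherited) effect
    model, and an end-point fluorescence value proportional to the
    terminal viability with multiplicative log-normal noise.  Blank wells
    get blank-level fluorescence and, by default, no frames.  Replicate
    plates should be simulated with distinct seeds: effects are shared,
    noise is re-drawn.
    """
    rng = np.random.default_rng(seed)
    frames: dict[str, list[np.ndarray]] = {}
    fmca: dict[str, float] = {}
    truth: dict[str, dict] = {}
    span = spec.fmca_control_level - spec.fmca_blank_level
    for well, condition in sorted(layout.assignment.items()):
        if condition == BLANK:
            fmca[well] = spec.fmca_blank_level * float(
                np.exp(rng.normal(0.0, spec.fmca_noise_sd))
            )
            if not skip_blank_frames:
                frames[well], truth[well] = simulate_well_frames(
                    UNTREATED_EFFECT, spec, rng
                )
            continue
        effect = effect_for_condition(condition, effect_map, boosts)
        frames[well], truth[well] = simulate_well_frames(effect, spec, rng)
        truth[well]["viability"] = effect.viability
        fmca[well] = (spec.fmca_blank_level + span * effect.viability) * float(
            np.exp(rng.normal(0.0, spec.fmca_noise_sd))
        )
    times = np.arange(spec.n_frames) * spec.frame_interval_h
    return PlateSimulation(layout=layout, frames=frames, fmca=fmca, truth=truth, times_h=times)


def write_plate(sim: PlateSimulation, out_dir) -> None:
    """Write a simulated plate to disk in the pipeline's input formats.

    Frames as ``{plate}_{well}_{frame:02d}.tif``, the layout map CSV, the
    end-point fluorescence CSV, and a ground-truth CSV with the per-well
    terminal viability and planted counts.
    """
    from combiscreen.design import export_layout_map

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    plate = sim.layout.plate_id
    for well, stack in sim.frames.items():
        for i, frame in enumerate(stack):
            tifffile.imwrite(
                img_dir / f"{plate}_{well}_{i:02d}.tif",
                frame.astype(np.float32),
            )
    export_layout_map(sim.layout, out / f"{plate}_layout.csv")
    with (out / f"{plate}_fmca.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "signal"])
        for well in sorted(sim.fmca):
            writer.writerow([well, repr(sim.fmca[well])])
    with (out / f"{plate}_truth.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "viability", "final_planted_count"])
        for well in sorted(sim.truth):
            t = sim.truth[well]
            writer.writerow(
                [
                    well,
                    t.get("viability", ""),
                    int(t["planted_counts"][-1]) if "planted_counts" in t else "",
                ]
            )
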