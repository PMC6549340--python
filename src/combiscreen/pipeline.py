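"""End-to-end orchestration of a replicate-plate experiment.

Per replicate plate: intra-plate QC on the first frame's morphology
histograms, then per-well temporal feature extraction, matched-filter
object counting, and survival indices from the end-point assay.  Across
replicates: the resampling inter-plate QC on the growth curves, replicate
merging, Bliss synergy scoring, and multilevel response mining.

Per-frame and per-well computations are independent (a map step); the
per-well and per-condition reductions are deterministic, so results never
depend on processing order and the whole run reproduces bit-identically
from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from combiscreen import __version__
from combiscreen.design import BLANK, UNTREATED, Combination, read_layout_map
from combiscreen.imaging import (
    PHHCParams,
    adaptive_background_interval,
    phhc_features,
    segment_foreground,
    well_profile_from_frames,
)
from combiscreen.io import (
    load_frame,
    load_well_frames,
    read_fmca_csv,
    read_image_set,
    write_csv,
    write_profiles_csv,
)
from combiscreen.matched_filter import (
    MatchedFilterModel,
    Prototype,
    build_filter,
    well_counts,
)
from combiscreen.mining import fuse_profiles, group_report, multilevel_cluster
from combiscreen.qc import (
    QCFlags,
    inter_plate_qc,
    inter_plate_variability,
    intra_plate_qc,
    merge_replicates,
    null_variability_distribution,
)
from combiscreen.synergy import plate_synergy_table, survival_index


@dataclass
class PlateInput:
    plate_id: str
    images: Path
    layout: Path
    fmca: Path


@dataclass
class RunConfig:
    """Run parameters; every module's knobs are reachable from here."""

    plates: list[PlateInput]
    out_dir: Path
    prototype: Path | None = None
    mf_threshold: float | None = None
    phhc: PHHCParams = field(default_factory=PHHCParams)
    qc_n_sims: int = 10000
    qc_percentile: float = 95.0
    qc_mad_factor: float = 3.0
    mining_max_depth: int = 2
    mining_min_size: int = 8
    mining_repeats: int = 10
    mining_drop_pct: float = 20.0
    n_boot: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {
            "plates", "out_dir", "prototype", "mf_threshold", "phhc",
            "qc_n_sims", "qc_percentile", "qc_mad_factor", "mining_max_depth",
            "mining_min_size", "mining_repeats", "mining_drop_pct", "n_boot",
            "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        plates = [
            PlateInput(
                plate_id=p["plate_id"],
                images=Path(p["images"]),
                layout=Path(p["layout"]),
                fmca=Path(p["fmca"]),
            )
            for p in raw.pop("plates")
        ]
        if "phhc" in raw:
            raw["phhc"] = PHHCParams(**raw["phhc"])
        out_dir = Path(raw.pop("out_dir"))
        proto = raw.pop("prototype", None)
        return cls(
            plates=plates,
            out_dir=out_dir,
            prototype=Path(proto) if proto else None,
            **raw,
        )


@dataclass
class PlateResult:
    plate_id: str
    layout: object
    profiles: dict
    survival: dict[str, float]
    qc: QCFlags


@dataclass
class RunResult:
    plates: list[PlateResult]
    inter_qc: QCFlags
    merged: dict[str, dict]
    synergy: object
    tree: object
    report: list[dict]


def analyze_plate(
    plate: PlateInput,
    model: MatchedFilterModel | None,
    config: RunConfig,
) -> PlateResult:
    """Intra-plate stage: QC, temporal features, counts, survival indices."""
    layout = read_layout_map(plate.layout, plate_id=plate.plate_id)
    image_set = read_image_set(plate.images, plate=plate.plate_id)
    # intra-plate QC on the earliest frame's morphology histograms
    first_feats: dict[str, np.ndarray] = {}
    for well, paths in image_set.wells.items():
        frame = load_frame(paths[0])
        interval = adaptive_background_interval(frame)
        mask = segment_foreground(frame, interval)
        first_feats[well] = phhc_features(frame, mask, config.phhc)
    qc = intra_plate_qc(first_feats, mad_factor=config.qc_mad_factor)
    profiles = {}
    for well, paths in image_set.wells.items():
        if well in qc.intra_failed:
            continue
        frames = load_well_frames(paths)
        prof = well_profile_from_frames(well, frames, params=config.phhc)
        if model is not None and model.threshold is not None:
            prof.object_counts = well_counts(frames, model)
        profiles[well] = prof
    fmca = read_fmca_csv(plate.fmca)
    blanks = np.array([fmca[w] for w in layout.blank_wells() if w in fmca])
    controls = np.array(
        [
            fmca[w]
            for w in layout.untreated_wells()
            if w in fmca and w not in qc.intra_failed
        ]
    )
    survival: dict[str, float] = {}
    for well, cond in layout.assignment.items():
        if not isinstance(cond, Combination) or well not in fmca:
            continue
        if well in qc.intra_failed:
            continue
        s = survival_index(fmca[well], blanks, controls)
        survival[cond.label()] = s
        if well in profiles:
            profiles[well].survival_index = s
    return PlateResult(
        plate_id=plate.plate_id, layout=layout, profiles=profiles,
        survival=survival, qc=qc,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the whole experiment: per-plate analysis, QC, synergy, mining."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed

    model = None
    if config.prototype is not None:
        patch = load_frame(config.prototype)
        bg = float(np.median(patch))
        model = build_filter(Prototype(patch), bg)
        model.threshold = config.mf_threshold

    plate_results = [analyze_plate(p, model, config) for p in config.plates]
    for res in plate_results:
        write_profiles_csv(out / f"{res.plate_id}_profiles.csv", res.profiles)

    # condition -> per-plate curves, restricted to intra-QC survivors
    def curves_by_condition(attr: str) -> dict[str, list[np.ndarray]]:
        gathered: dict[str, list[np.ndarray]] = {}
        for res in plate_results:
            for well, prof in res.profiles.items():
                cond = res.layout.condition_of(well)
                if cond == BLANK:
                    continue
                label = cond.label() if isinstance(cond, Combination) else str(cond)
                vec = getattr(prof, attr)
                if vec is not None:
                    gathered.setdefault(label, []).append(np.asarray(vec))
        return gathered

    dC = curves_by_condition("delta_confluence")
    dM = curves_by_condition("delta_morphology")
    counts = curves_by_condition("object_counts")

    untreated_per_plate = []
    for res in plate_results:
        plate_untreated = [
            res.profiles[w].delta_confluence
            for w in res.layout.untreated_wells()
            if w in res.profiles
        ]
        untreated_per_plate.append(np.array(plate_untreated))
    null = null_variability_distribution(
        untreated_per_plate,
        n_sims=config.qc_n_sims,
        percentile=config.qc_percentile,
        seed=rng_seed,
    )
    variabilities = {
        label: inter_plate_variability(np.array(curves))
        for label, curves in dC.items()
        if len(curves) >= 2 and label != UNTREATED
    }
    inter = inter_plate_qc(variabilities, null)

    merged: dict[str, dict] = {}
    for label in dC:
        if label == UNTREATED or label in inter.inter_outliers:
            continue
        entry = {}
        m = merge_replicates(np.array(dC[label]))
        if m is None:
            continue
        entry["delta_confluence"], entry["dC_sd"], entry["n_replicates"] = m
        entry["delta_morphology"] = np.array(dM[label]).mean(axis=0)
        if label in counts and counts[label]:
            entry["counts"] = np.array(counts[label]).mean(axis=0)
        reps = [res.survival.get(label) for res in plate_results]
        reps = [s for s in reps if s is not None]
        if reps:
            entry["survival"] = float(np.mean(reps))
            entry["survival_reps"] = np.array(reps)
        merged[label] = entry

    write_csv(
        out / "qc_report.csv",
        ["item", "V", "tau", "flag", "reason"],
        [
            [
                label,
                inter.variabilities.get(label, ""),
                null.threshold,
                label in inter.inter_outliers,
                inter.details.get(label, ""),
            ]
            for label in sorted(variabilities)
        ]
        + [
            [f"{res.plate_id}:{w}", "", "", True, res.qc.details.get(w, "intra-plate QC")]
            for res in plate_results
            for w in sorted(res.qc.intra_failed)
        ],
    )

    conditions = sorted(
        {
            res.layout.condition_of(w)
            for res in plate_results
            for w in res.profiles
            if isinstance(res.layout.condition_of(w), Combination)
        },
        key=lambda c: (c.order, c.members),
    )
    replicate_survival = {
        label: entry["survival_reps"]
        for label, entry in merged.items()
        if "survival_reps" in entry and entry["survival_reps"].size >= 2
    }
    survival_means = {
        label: merged[label]["survival"] for label in merged if "survival" in merged[label]
    }
    scorable = [
        c
        for c in conditions
        if c.label() in survival_means
        and all(
            Combination((d,)).label() in survival_means for d in c.members
        )
    ]
    needed = {lab for c in scorable for lab in [c.label(), *c.members]}
    have_reps = needed <= set(replicate_survival)
    synergy = plate_synergy_table(
        scorable,
        survival_means,
        excluded=inter.inter_outliers,
        replicate_survival=replicate_survival if have_reps else None,
        n_boot=config.n_boot,
        seed=rng_seed,
    )
    synergy.to_csv(out / "synergy.csv", index=False)

    fused = []
    for label, entry in merged.items():
        if "counts" not in entry or "survival" not in entry:
            continue
        fused.append(
            fuse_profiles(
                entry["delta_confluence"],
                entry["delta_morphology"],
                entry["counts"],
                entry["survival"],
                condition=Combination.from_label(label),
            )
        )
    tree = None
    report = []
    if len(fused) >= 2:
        tree = multilevel_cluster(
            fused,
            max_depth=config.mining_max_depth,
            min_size=config.mining_min_size,
            repeats=config.mining_repeats,
            drop_pct=config.mining_drop_pct,
            seed=rng_seed,
        )
        report = group_report(tree, fused)
        write_csv(
            out / "mining_groups.csv",
            ["path", "depth", "n_members", "representatives", "members"],
            [
                [
                    r["path"],
                    r["depth"],
                    r["n_members"],
                    "|".join(r["representatives"]),
                    "|".join(r["members"]),
                ]
                for r in report
            ],
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_plates": len(config.plates),
        "qc_n_sims": config.qc_n_sims,
        "qc_percentile": config.qc_percentile,
        "tau_null": null.threshold,
        "intra_excluded": sorted(
            f"{res.plate_id}:{w}" for res in plate_results for w in res.qc.intra_failed
        ),
        "inter_outliers": sorted(inter.inter_outliers),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(
        plates=plate_results, inter_qc=inter, merged=merged,
        synergy=synergy, tree=tree, report=report,
    )
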