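"""Readers and writers for the pipeline's file formats.

Images are TIFF or PNG frames named ``{plate}_{well}_{frame}.tif``; all
tabular inputs and outputs are plain CSV.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png")

_FRAME_RE = re.compile(
    r"^(?P<plate>.+)_(?P<well>[A-P]\d{1,2})_(?P<frame>\d+)$"
)


@dataclass
class ImageSet:
    """Per-well ordered frame paths for one plate."""

    wells: dict[str, list[Path]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return sum(len(v) for v in self.wells.values())


def read_image_set(
    directory, expected_frames: int | None = None, plate: str | None = None
) -> ImageSet:
    """Group a directory of frames by well, sorted by frame index.

    Filenames must follow ``{plate}_{well}_{frame}``; files that do not
    parse are listed in ``skipped`` and ignored.  The grouping depends
    only on the parsed indices, never on listing order.  When ``plate``
    is given only that plate's frames are read (several plates may share
    a directory).  When ``expected_frames`` is given, wells with fewer
    frames are reported in ``missing``.
    """
    directory = Path(directory)
    per_well: dict[str, list[tuple[int, Path]]] = {}
    result = ImageSet()
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        m = _FRAME_RE.match(path.stem)
        if not m:
            result.skipped.append(path.name)
            continue
        if plate is not None and m.group("plate") != plate:
            continue
        per_well.setdefault(m.group("well"), []).append((int(m.group("frame")), path))
    for well, entries in sorted(per_well.items()):
        entries.sort(key=lambda e: e[0])
        result.wells[well] = [p for _, p in entries]
        if expected_frames is not None and len(entries) < expected_frames:
            result.missing.append(
                f"{well}: {len(entries)}/{expected_frames} frames"
            )
    return result


def load_frame(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    return np.asarray(iio.imread(path), dtype=float)


def load_well_frames(paths: list[Path]) -> list[np.ndarray]:
    return [load_frame(p) for p in paths]


def read_fmca_csv(path) -> dict[str, float]:
    """End-point fluorescence CSV: columns well, signal."""
    out: dict[str, float] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["well"]] = float(row["signal"])
    return out


def write_csv(path, header: list[str], rows: list[list]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def read_profiles_csv(path) -> dict:
    """Read a per-well profiles CSV back into :class:`WellProfile` objects."""
    from combiscreen.imaging import WellProfile

    per_well: dict[str, dict[str, list]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            d = per_well.setdefault(
                row["well"],
                {"time_h": [], "confluence": [], "dC": [], "dM": [], "count": []},
            )
            d["time_h"].append(float(row["time_h"]))
            d["confluence"].append(float(row["confluence"]) if row["confluence"] else np.nan)
            d["dC"].append(float(row["delta_confluence"]))
            d["dM"].append(float(row["delta_morphology"]))
            d["count"].append(float(row["mean_count"]) if row["mean_count"] else np.nan)
    out = {}
    for well, d in per_well.items():
        counts = np.array(d["count"])
        out[well] = WellProfile(
            well_id=well,
            times_h=np.array(d["time_h"]),
            delta_confluence=np.array(d["dC"]),
            delta_morphology=np.array(d["dM"]),
            object_counts=None if np.isnan(counts).all() else counts,
            confluence=np.array(d["confluence"]),
        )
    return out


def write_profiles_csv(path, profiles: dict) -> None:
    """Per-well temporal readouts, one row per (well, time point)."""
    rows = []
    for well, prof in sorted(profiles.items()):
        counts = prof.object_counts
        for i, t in enumerate(prof.times_h):
            rows.append(
                [
                    well,
                    float(t),
                    float(prof.confluence[i]) if prof.confluence is not None else "",
                    float(prof.delta_confluence[i]),
                    float(prof.delta_morphology[i]),
                    float(counts[i]) if counts is not None else "",
                ]
            )
    write_csv(
        path,
        ["well", "time_h", "confluence", "delta_confluence", "delta_morphology", "mean_count"],
        rows,
    )
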