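"""Randomized 384-well plate design for exhaustive drug combination experiments.

An *exhaustive* experiment evaluates every subset of a fixed drug panel up
to a chosen order, each drug at one fixed concentration.  With ``N_d``
drugs and maximum order ``c`` the number of treated wells is

    N_w(N_d, c) = sum_{i=1..c} C(N_d, i)

so a nine-drug panel screened up to order four needs 255 treated wells and
fits, together with >= 40 untreated control wells, on a single 384-well
plate.  Each replicate plate receives an independent random permutation of
the same condition multiset so that spatially correlated noise decorrelates
across replicates and can be averaged out.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _itercombos
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24

UNTREATED = "UNTREATED"
BLANK = "BLANK"

#: default number of untreated control wells placed when space allows
DEFAULT_UNTREATED_TARGET = 53


class LayoutInfeasibleError(ValueError):
    """Raised when a design cannot fit on a single plate."""

    def __init__(self, report: "FeasibilityReport"):
        self.report = report
        super().__init__(
            f"{report.n_treated} treated + {report.min_untreated} untreated "
            f"wells exceed {report.plate_wells}-well plate capacity; "
            f"suggest splitting over {report.suggested_plates} plates"
        )


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate coordinate like 'A01'."""
    if not (0 <= row < len(ROWS) and 0 <= col < N_COLS):
        raise ValueError(f"well ({row}, {col}) outside 16x24 plate")
    return f"{ROWS[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """Plate coordinate like 'A01' or 'A1' -> 0-based (row, col)."""
    name = name.strip().upper()
    row = ROWS.index(name[0])
    col = int(name[1:]) - 1
    if not 0 <= col < N_COLS:
        raise ValueError(f"column out of range in well {name!r}")
    return row, col


def all_wells(plate_wells: int = 384) -> list[str]:
    """Plate coordinates in row-major order (A01..A24, B01..)."""
    n_rows = plate_wells // N_COLS
    return [well_name(r, c) for r in range(n_rows) for c in range(N_COLS)]


@dataclass(frozen=True)
class DrugPanel:
    """The drug panel: unique names, one fixed concentration each."""

    drugs: tuple[tuple[str, float, str], ...]  # (name, concentration, unit)

    def __post_init__(self):
        names = [d[0] for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("drug names must be unique")
        for name, conc, _unit in self.drugs:
            if not conc > 0:
                raise ValueError(f"concentration of {name!r} must be > 0")

    @property
    def names(self) -> list[str]:
        return [d[0] for d in self.drugs]

    def concentration(self, name: str) -> tuple[float, str]:
        for n, c, u in self.drugs:
            if n == name:
                return c, u
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.drugs)


@dataclass(frozen=True, order=True)
class Combination:
    """An unordered set of panel drugs; the unit of design and analysis."""

    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("combination must have at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("combination members must be unique")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    @property
    def order(self) -> int:
        return len(self.members)

    def label(self) -> str:
        return "+".join(self.members)

    def contains(self, other: "Combination") -> bool:
        return set(other.members) <= set(self.members)

    @classmethod
    def from_label(cls, label: str) -> "Combination":
        return cls(tuple(label.split("+")))


@dataclass(frozen=True)
class DesignSpec:
    """Everything needed to generate one experiment's replicate layouts."""

    panel: DrugPanel
    max_order: int
    replicates: int = 1
    mode: str = "exhaustive"  # exhaustive | pairwise | explicit-list
    explicit: tuple[Combination, ...] = ()
    min_untreated: int = 40
    untreated_target: int = DEFAULT_UNTREATED_TARGET
    plate_wells: int = 384
    seed: int = 0
    edge_exclude: bool = False

    def __post_init__(self):
        if self.mode not in ("exhaustive", "pairwise", "explicit-list"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "explicit-list":
            if not 1 <= self.max_order <= len(self.panel):
                raise ValueError("max_order must satisfy 1 <= c <= N_d")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.min_untreated < 0:
            raise ValueError("min_untreated must be >= 0")

    def conditions(self) -> list[Combination]:
        if self.mode == "explicit-list":
            return list(self.explicit)
        order = 2 if self.mode == "pairwise" else self.max_order
        combos = enumerate_combinations(self.panel, order)
        if self.mode == "pairwise":
            combos = [c for c in combos if c.order == 2]
        return combos


@dataclass
class FeasibilityReport:
    feasible: bool
    n_treated: int
    min_untreated: int
    plate_wells: int
    usable_wells: int
    suggested_plates: int
    per_plate_conditions: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class PlateLayout:
    """Assignment of every plate well to a condition for one replicate."""

    replicate_id: int
    plate_id: str
    assignment: dict[str, Combination | str]  # well -> Combination/UNTREATED/BLANK

    def conditions(self) -> list[Combination]:
        return [c for c in self.assignment.values() if isinstance(c, Combination)]

    def wells_for(self, condition: Combination | str) -> list[str]:
        return sorted(w for w, c in self.assignment.items() if c == condition)

    def untreated_wells(self) -> list[str]:
        return self.wells_for(UNTREATED)

    def blank_wells(self) -> list[str]:
        return self.wells_for(BLANK)

    def condition_of(self, well: str) -> Combination | str:
        return self.assignment[well]


def n_wells(n_drugs: int, max_order: int) -> int:
    """Number of treated wells for an exhaustive design up to ``max_order``.

    Equals the number of non-empty subsets of the panel with at most
    ``max_order`` members: sum_{i=1..max_order} C(n_drugs, i).
    """
    if n_drugs < 1 or max_order < 1 or max_order > n_drugs:
        raise ValueError("require 1 <= max_order <= n_drugs")
    return sum(math.comb(n_drugs, i) for i in range(1, max_order + 1))


def enumerate_combinations(panel: DrugPanel, max_order: int) -> list[Combination]:
    """All subsets of the panel of size 1..max_order.

    Deterministic order: ascending combination order, then lexicographic by
    member names.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    if not 1 <= max_order <= len(panel):
        raise ValueError("require 1 <= max_order <= panel size")
    names = sorted(panel.names)
    out: list[Combination] = []
    for k in range(1, max_order + 1):
        for subset in _itercombos(names, k):
            out.append(Combination(subset))
    return out


def check_feasibility(spec: DesignSpec) -> FeasibilityReport:
    """Does the design fit on one plate with the required untreated floor?

    Infeasibility is reported, not raised; the report suggests the minimum
    number of plates over which a balanced split of the conditions fits.
    """
    conditions = spec.conditions()
    n_treated = len(conditions)
    usable = _usable_well_count(spec)
    feasible = n_treated + spec.min_untreated <= usable
    notes: list[str] = []
    if n_treated == 0:
        notes.append("design has no treated conditions")
    plates = 1
    if not feasible:
        while math.ceil(n_treated / plates) + spec.min_untreated > usable:
            plates += 1
    base, extra = divmod(n_treated, plates)
    per_plate = [base + (1 if i < extra else 0) for i in range(plates)]
    return FeasibilityReport(
        feasible=feasible,
        n_treated=n_treated,
        min_untreated=spec.min_untreated,
        plate_wells=spec.plate_wells,
        usable_wells=usable,
        suggested_plates=plates,
        per_plate_conditions=per_plate,
        warnings=notes,
    )


def _usable_well_count(spec: DesignSpec) -> int:
    if not spec.edge_exclude:
        return spec.plate_wells
    n_rows = spec.plate_wells // N_COLS
    return (n_rows - 2) * (N_COLS - 2)


def _usable_wells(spec: DesignSpec) -> list[str]:
    wells = all_wells(spec.plate_wells)
    if not spec.edge_exclude:
        return wells
    n_rows = spec.plate_wells // N_COLS
    keep = []
    for w in wells:
        r, c = parse_well(w)
        if 0 < r < n_rows - 1 and 0 < c < N_COLS - 1:
            keep.append(w)
    return keep


def randomize_layout(
    spec: DesignSpec, replicate_id: int, plate_id: str | None = None
) -> PlateLayout:
    """Uniform random assignment of conditions to wells for one replicate.

    The RNG stream is derived as ``spec.seed + replicate_id`` so the same
    spec reproduces byte-identical layouts while different replicates get
    independent permutations of the same condition multiset.
    """
    report = check_feasibility(spec)
    if not report.feasible:
        raise LayoutInfeasibleError(report)
    conditions = spec.conditions()
    usable = _usable_wells(spec)
    n_free = len(usable) - len(conditions)
    n_untreated = min(max(spec.min_untreated, spec.untreated_target), n_free)
    items: list[Combination | str] = list(conditions) + [UNTREATED] * n_untreated
    rng = np.random.default_rng(spec.seed + replicate_id)
    chosen = rng.permutation(len(usable))[: len(items)]
    assignment: dict[str, Combination | str] = {w: BLANK for w in all_wells(spec.plate_wells)}
    for item, idx in zip(items, chosen):
        assignment[usable[idx]] = item
    if plate_id is None:
        plate_id = f"R{replicate_id}"
    return PlateLayout(replicate_id=replicate_id, plate_id=plate_id, assignment=assignment)


def export_destination_csv(layout: PlateLayout, panel: DrugPanel, path) -> None:
    """Write the per-(well, compound) transfer list for liquid handling.

    One row per compound transfer; untreated and blank wells get a single
    marker row each so the file round-trips to the full layout.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plate_id", "destination_well", "compound", "final_concentration", "unit"])
        for well in sorted(layout.assignment, key=parse_well):
            cond = layout.assignment[well]
            if isinstance(cond, Combination):
                for drug in cond.members:
                    conc, unit = panel.concentration(drug)
                    writer.writerow([layout.plate_id, well, drug, repr(conc), unit])
            else:
                writer.writerow([layout.plate_id, well, cond, "", ""])


def read_destination_csv(path) -> PlateLayout:
    """Read a destination CSV back into a :class:`PlateLayout`."""
    per_well: dict[str, list[str]] = {}
    plate_id = ""
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            plate_id = row["plate_id"]
            per_well.setdefault(row["destination_well"], []).append(row["compound"])
    assignment: dict[str, Combination | str] = {}
    for well, compounds in per_well.items():
        if compounds == [UNTREATED] or compounds == [BLANK]:
            assignment[well] = compounds[0]
        else:
            assignment[well] = Combination(tuple(compounds))
    rep = int(plate_id[1:]) if plate_id.startswith("R") and plate_id[1:].isdigit() else 0
    return PlateLayout(replicate_id=rep, plate_id=plate_id, assignment=assignment)


def export_layout_map(layout: PlateLayout, path) -> None:
    """Human-readable map: one row per well with condition label and order."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "condition_label", "order"])
        for well in sorted(layout.assignment, key=parse_well):
            cond = layout.assignment[well]
            if isinstance(cond, Combination):
                writer.writerow([well, cond.label(), cond.order])
            else:
                writer.writerow([well, cond, 0])


def read_layout_map(path, replicate_id: int = 0, plate_id: str = "") -> PlateLayout:
    assignment: dict[str, Combination | str] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["condition_label"]
            if label in (UNTREATED, BLANK):
                assignment[row["well"]] = label
            else:
                assignment[row["well"]] = Combination.from_label(label)
    if not plate_id:
        plate_id = f"R{replicate_id}"
    return PlateLayout(replicate_id=replicate_id, plate_id=plate_id, assignment=assignment)


def read_design_spec(path_or_text) -> DesignSpec:
    """Parse the line-oriented experiment specification file.

    Dialect: ``key=value`` header lines (max_order, replicates, seed, mode,
    min_untreated, untreated_target) followed by one tab-separated
    ``drug<TAB>concentration<TAB>unit`` line per panel drug.  Blank lines
    and ``#`` comments are ignored.
    """
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    header: dict[str, str] = {}
    drugs: list[tuple[str, float, str]] = []
    for raw in io.StringIO(text):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line and "\t" not in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
        else:
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"bad drug line (need drug<TAB>conc<TAB>unit): {line!r}")
            drugs.append((parts[0], float(parts[1]), parts[2]))
    if not drugs:
        raise ValueError("specification contains no drugs")
    panel = DrugPanel(tuple(drugs))
    return DesignSpec(
        panel=panel,
        max_order=int(header.get("max_order", 1)),
        replicates=int(header.get("replicates", 1)),
        mode=header.get("mode", "exhaustive"),
        min_untreated=int(header.get("min_untreated", 40)),
        untreated_target=int(header.get("untreated_target", DEFAULT_UNTREATED_TARGET)),
        seed=int(header.get("seed", 0)),
    )


def write_design_spec(spec: DesignSpec, path) -> None:
    lines = [
        f"mode={spec.mode}",
        f"max_order={spec.max_order}",
        f"replicates={spec.replicates}",
        f"min_untreated={spec.min_untreated}",
        f"untreated_target={spec.untreated_target}",
        f"seed={spec.seed}",
    ]
    for name, conc, unit in spec.panel.drugs:
        lines.append(f"{name}\t{conc}\t{unit}")
    Path(path).write_text("\n".join(lines) + "\n")
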