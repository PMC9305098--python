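"""30-2 visual-field grid, perimetry ingest, and reliability filtering.

Field coordinates follow the tested eye's orientation: ``x_deg`` positive
temporal, ``y_deg`` positive superior.  Internally all downstream code works
in right-eye orientation; left-eye exams are mirrored at ingest.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VFLocation",
    "VFExam",
    "ReliabilityResult",
    "build_grid",
    "check_reliability",
    "analysis_locations",
    "read_vf_exam",
    "write_vf_exam",
    "FIXATION_LOSS_LIMIT",
    "FALSE_POSITIVE_LIMIT",
    "FALSE_NEGATIVE_LIMIT",
]

# QC limits; comparisons are strict ("<"), a value at the limit fails.
FIXATION_LOSS_LIMIT = 0.33
FALSE_POSITIVE_LIMIT = 0.20
FALSE_NEGATIVE_LIMIT = 0.20

# Half-width of each row of the 30-2 lattice, keyed by |y| (degrees).
# Rows hold 4/6/8/10/10 points; corner points are absent.
_ROW_MAX_X = {27: 9, 21: 15, 15: 21, 9: 27, 3: 27}

_TD_RANGE = (-40.0, 10.0)


@dataclass(frozen=True)
class VFLocation:
    """One 30-2 test location in field coordinates of the tested eye."""

    index: int
    x_deg: float
    y_deg: float
    is_blind_spot: bool = False


@dataclass
class VFExam:
    """A single 30-2 exam: per-location total deviations plus QC indices."""

    subject_id: str
    eye: str
    td: dict[int, float]
    md: float
    fixation_loss_frac: float
    fp_frac: float
    fn_frac: float

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")
        lo, hi = _TD_RANGE
        for idx, v in self.td.items():
            if not (lo <= v <= hi):
                raise ValueError(
                    f"total deviation {v} dB at location {idx} outside "
                    f"plausible range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class ReliabilityResult:
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def build_grid(eye: str = "right") -> list[VFLocation]:
    """Return the 76-point 30-2 lattice for the given eye.

    Indexing is 1..76 row-major starting at the superior row; within a row
    x ascends (nasal to temporal for a right eye).  The blind-spot pair sits
    on the temporal side at (+-15, +-3) depending on laterality.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    mirror = -1.0 if eye == "left" else 1.0
    blind_x = 15.0 * mirror
    locations: list[VFLocation] = []
    index = 1
    for y in (27, 21, 15, 9, 3, -3, -9, -15, -21, -27):
        max_x = _ROW_MAX_X[abs(y)]
        for x in range(-max_x, max_x + 1, 6):
            fx = float(x) * mirror
            blind = fx == blind_x and abs(y) == 3
            locations.append(VFLocation(index, fx, float(y), blind))
            index += 1
    return locations


def check_reliability(exam: VFExam) -> ReliabilityResult:
    """Apply the perimetry QC filter with strict-inequality thresholds."""
    for name in ("fixation_loss_frac", "fp_frac", "fn_frac"):
        value = getattr(exam, name)
        if value is None:
            raise ValueError(f"reliability index {name!r} is missing")
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"reliability index {name!r}={value} not in [0, 1]")
    reasons = []
    if not exam.fixation_loss_frac < FIXATION_LOSS_LIMIT:
        reasons.append("fixation losses")
    if not exam.fp_frac < FALSE_POSITIVE_LIMIT:
        reasons.append("false-positive")
    if not exam.fn_frac < FALSE_NEGATIVE_LIMIT:
        reasons.append("false-negative")
    return ReliabilityResult(passed=not reasons, reasons=tuple(reasons))


def analysis_locations(
    grid: Sequence[VFLocation],
    exclusions: Iterable[int] = (),
) -> list[VFLocation]:
    """Grid minus blind-spot points minus any configured extra exclusions."""
    exclusions = set(exclusions)
    indices = {loc.index for loc in grid}
    missing = exclusions - indices
    if missing:
        raise ValueError(f"exclusion indices not in grid: {sorted(missing)}")
    return [
        loc
        for loc in grid
        if not loc.is_blind_spot and loc.index not in exclusions
    ]


# ---------------------------------------------------------------------------
# ingest / export


def mirror_to_right(exam: VFExam, grid_left: Sequence[VFLocation] | None = None) -> VFExam:
    """Re-index a left-eye exam into right-eye orientation.

    Location indices are defined row-major on each eye's own grid, so the
    mirror maps index i at (x, y) to the right-eye index at (-x, y).
    """
    if exam.eye == "right":
        return exam
    left = grid_left if grid_left is not None else build_grid("left")
    right = build_grid("right")
    right_by_xy = {(loc.x_deg, loc.y_deg): loc.index for loc in right}
    left_by_index = {loc.index: loc for loc in left}
    td = {}
    for idx, v in exam.td.items():
        loc = left_by_index[idx]
        td[right_by_xy[(-loc.x_deg, loc.y_deg)]] = v
    return VFExam(
        subject_id=exam.subject_id,
        eye="right",
        td=td,
        md=exam.md,
        fixation_loss_frac=exam.fixation_loss_frac,
        fp_frac=exam.fp_frac,
        fn_frac=exam.fn_frac,
    )


def read_vf_exam(csv_path: str | Path, meta_path: str | Path) -> VFExam:
    """Read one exam from the CSV/JSON dialect written by :func:`write_vf_exam`."""
    csv_path, meta_path = Path(csv_path), Path(meta_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    td: dict[int, float] = {}
    subject_id = None
    eye = None
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            subject_id = row["subject_id"]
            eye = row["eye"]
            td[int(row["loc_index"])] = float(row["td_db"])
    if subject_id is None:
        raise ValueError(f"no rows in {csv_path}")
    return VFExam(
        subject_id=subject_id,
        eye=eye,
        td=td,
        md=float(meta["md"]),
        fixation_loss_frac=float(meta["fixation_loss"]),
        fp_frac=float(meta["fp"]),
        fn_frac=float(meta["fn"]),
    )


def write_vf_exam(
    exam: VFExam,
    csv_path: str | Path,
    meta_path: str | Path,
    grid: Sequence[VFLocation] | None = None,
) -> None:
    grid = grid if grid is not None else build_grid(exam.eye)
    by_index: Mapping[int, VFLocation] = {loc.index: loc for loc in grid}
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "eye", "loc_index", "x_deg", "y_deg", "td_db"])
        for idx in sorted(exam.td):
            loc = by_index[idx]
            writer.writerow(
                [exam.subject_id, exam.eye, idx, loc.x_deg, loc.y_deg,
                 f"{exam.td[idx]:.4f}"]
            )
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "subject_id": exam.subject_id,
                "eye": exam.eye,
                "md": exam.md,
                "fixation_loss": exam.fixation_loss_frac,
                "fp": exam.fp_frac,
                "fn": exam.fn_frac,
            },
            fh,
            indent=1,
        )
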