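"""Focal and global capillary density / RNFL thickness extraction."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .octa_preproc import BinaryPerfusionMap
from .trajectory import WedgeROI
from .vf_data import VFExam, VFLocation

__all__ = [
    "RNFLProfile",
    "FocalRecord",
    "MissingFocalValue",
    "focal_cd",
    "focal_rnflt",
    "global_metrics",
    "assemble_records",
    "read_rnfl_csv",
    "write_rnfl_csv",
    "records_to_frame",
]

log = logging.getLogger(__name__)


class MissingFocalValue(Exception):
    """A focal value could not be computed (e.g. empty denominator)."""


@dataclass(frozen=True)
class RNFLProfile:
    """Circumpapillary RNFL thickness sampled on the 3.5-mm ring.

    Angles are in the trajectory module's disc-polar convention (degrees,
    0 = along the fovea-disc axis pointing nasally, positive superior),
    covering [0, 360) without duplicates.
    """

    angles_deg: np.ndarray
    thickness_um: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, float)
        t = np.asarray(self.thickness_um, float)
        if a.shape != t.shape or a.ndim != 1 or a.size == 0:
            raise ValueError("angles and thickness must be matching 1D arrays")
        a_mod = np.mod(a, 360.0)
        if np.unique(a_mod).size != a.size:
            raise ValueError("duplicate ring angles")
        if np.any(t < 0):
            raise ValueError("negative thickness")

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.angles_deg).size)


@dataclass(frozen=True)
class FocalRecord:
    """Analysis-ready row: one subject at one VF location."""

    subject_id: str
    location_index: int
    fvfd_db: float
    fcd: float
    frnflt_um: float


def focal_cd(pmap: BinaryPerfusionMap, roi: WedgeROI) -> float:
    """Perfused fraction in the ROI, large-vessel pixels excluded from the
    denominator.  Raises :class:`MissingFocalValue` on an empty denominator
    rather than returning 0, which would masquerade as severe loss.
    """
    mask = roi.pixel_mask
    if mask.shape != pmap.perfused.shape:
        raise ValueError("ROI mask and perfusion map shapes differ")
    denom_mask = mask & ~pmap.large_vessel_mask
    denom = int(denom_mask.sum())
    if denom == 0:
        raise MissingFocalValue(
            f"location {roi.location_index}: ROI fully covered by large vessels"
        )
    return float((pmap.perfused & denom_mask).sum()) / denom


def _in_arc(angles_deg: np.ndarray, arc: tuple[float, float]) -> np.ndarray:
    """Half-open membership [lo, hi), unwrapped across 0/360."""
    lo, hi = arc
    width = hi - lo
    if width <= 0:
        raise ValueError("arc width must be positive")
    if width >= 360.0:
        return np.ones(np.shape(angles_deg), dtype=bool)
    return np.mod(np.asarray(angles_deg, float) - lo, 360.0) < width


def focal_rnflt(profile: RNFLProfile, arc: tuple[float, float]) -> float:
    """Mean thickness of the ring samples whose angle falls in the arc."""
    sel = _in_arc(profile.angles_deg, arc)
    if not sel.any():
        raise MissingFocalValue(
            f"no ring samples in arc [{arc[0]:.2f}, {arc[1]:.2f}) deg; "
            "arc narrower than the sampling step"
        )
    return float(np.mean(np.asarray(profile.thickness_um, float)[sel]))


def global_metrics(
    pmap: BinaryPerfusionMap,
    profile: RNFLProfile,
    disc_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """(global CD, global RNFL-T).

    Global CD is the perfused fraction over the normalized frame excluding
    the disc region and large-vessel pixels; global RNFL-T is the mean of
    the full ring profile.
    """
    excl = pmap.large_vessel_mask.copy()
    if disc_mask is not None:
        if disc_mask.shape != excl.shape:
            raise ValueError("disc_mask shape mismatch")
        excl |= np.asarray(disc_mask, bool)
    denom = int((~excl).sum())
    gcd = float((pmap.perfused & ~excl).sum()) / denom if denom else float("nan")
    return gcd, float(np.mean(np.asarray(profile.thickness_um, float)))


def assemble_records(
    exams: Mapping[str, VFExam],
    pmaps: Mapping[str, BinaryPerfusionMap],
    profiles: Mapping[str, RNFLProfile],
    rois: Mapping[str, Mapping[int, WedgeROI]],
    locations: Sequence[VFLocation],
) -> list[FocalRecord]:
    """One row per (subject, analysis location); incomplete rows are dropped
    and logged.  Raises if the input streams disagree on subjects.
    """
    keys = [set(m) for m in (exams, pmaps, profiles, rois)]
    union = set.union(*keys)
    mismatched = {
        sid for sid in union if any(sid not in m for m in (exams, pmaps, profiles, rois))
    }
    if mismatched:
        raise ValueError(f"subjects missing from some input streams: {sorted(mismatched)}")
    records: list[FocalRecord] = []
    for sid in sorted(union):
        exam, pmap, profile = exams[sid], pmaps[sid], profiles[sid]
        for loc in locations:
            roi = rois[sid].get(loc.index)
            if roi is None or loc.index not in exam.td:
                log.info("dropping (%s, %d): missing ROI or fVFD", sid, loc.index)
                continue
            try:
                fcd = focal_cd(pmap, roi)
                frnflt = focal_rnflt(profile, roi.ring_arc)
            except MissingFocalValue as exc:
                log.info("dropping (%s, %d): %s", sid, loc.index, exc)
                continue
            records.append(
                FocalRecord(sid, loc.index, exam.td[loc.index], fcd, frnflt)
            )
    return records


def records_to_frame(records: Iterable[FocalRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.subject_id, r.location_index, r.fvfd_db, r.fcd, r.frnflt_um)
            for r in records
        ],
        columns=["subject_id", "loc_index", "fVFD_db", "fCD", "fRNFLT_um"],
    )
    return df


# ---------------------------------------------------------------------------
# IO


def read_rnfl_csv(path: str | Path) -> RNFLProfile:
    angles, thickness = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            angles.append(float(row["angle_deg"]))
            thickness.append(float(row["thickness_um"]))
    return RNFLProfile(np.asarray(angles), np.asarray(thickness))


def write_rnfl_csv(profile: RNFLProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg", "thickness_um"])
        for a, t in zip(profile.angles_deg, profile.thickness_um):
            writer.writerow([f"{a:.4f}", f"{t:.3f}"])
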