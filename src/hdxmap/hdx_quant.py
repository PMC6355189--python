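"""Deuteration quantification from replicate centroid-mass measurements.

The measured quantity per peptide, state, exposure time and replicate is the
isotope-envelope centroid mass ``Mex``.  Two control experiments bound the
dynamic range: an in-exchange control (``Mex0``, minimal labelling) and an
out-exchange control (``Mex100``, maximal labelling after 24 h).  The
control-normalized deuteration level is

    %D = 100 * (Mex - Mex0) / (Mex100 - Mex0)

computed per replicate, then averaged (mean and sample SD) per
peptide/state/time.  Identification-level filters mirror the acquisition
software's criteria (minimum intensity, products per amino acid, score, and
MH+ mass error) with inclusive thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "APO", "COMPLEX", "IN_EXCHANGE_CONTROL", "OUT_EXCHANGE_CONTROL",
    "STATES", "EXCHANGE_CLASSES", "DEFAULT_CLASS_BINS",
    "UptakeRecord", "FilterCriteria", "IdentificationRecord",
    "DeuterationPoint", "TimeCourse", "DegenerateControlError",
    "filter_identifications", "percent_deuteration", "build_uptake_curves",
    "classify_exchange", "read_state_table", "write_state_table",
    "records_to_frame", "curves_to_frame", "write_curves", "read_curves",
]

APO = "apo"
COMPLEX = "complex"
IN_EXCHANGE_CONTROL = "in_exchange_control"
OUT_EXCHANGE_CONTROL = "out_exchange_control"
STATES = (APO, COMPLEX, IN_EXCHANGE_CONTROL, OUT_EXCHANGE_CONTROL)

EXCHANGE_CLASSES = ("very_slow", "slow", "intermediate", "fast", "very_fast")
# %D bin edges between the five classes; >70% is "very fast" per the
# exchanged-in-under-the-shortest-time reading of the heat map.
DEFAULT_CLASS_BINS = (20.0, 40.0, 60.0, 70.0)


class DegenerateControlError(ValueError):
    """Raised when Mex100 == Mex0 for a peptide (no dynamic range)."""


@dataclass(frozen=True)
class UptakeRecord:
    peptide_id: str
    state: str
    exposure_time: float  # seconds
    replicate: int
    centroid_mass: float  # Da
    intensity: float = float("nan")

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.exposure_time < 0:
            raise ValueError("exposure_time must be >= 0")
        if self.centroid_mass <= 0:
            raise ValueError("centroid_mass must be > 0")


@dataclass(frozen=True)
class FilterCriteria:
    """Identification filters; all thresholds are inclusive."""

    min_intensity: float = 3000.0
    min_products_per_aa: float = 0.3
    min_score: float = 7.0
    max_mh_error_ppm: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_intensity, self.min_products_per_aa,
               self.min_score, self.max_mh_error_ppm) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class IdentificationRecord:
    peptide_id: str
    intensity: float
    products_per_aa: float
    score: float
    mh_error_ppm: float


@dataclass(frozen=True)
class DeuterationPoint:
    peptide_id: str
    state: str
    exposure_time: float
    percent_deuteration_mean: float
    sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TimeCourse:
    times: tuple[float, ...] = (10.0, 60.0, 300.0, 1500.0, 7200.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")


def filter_identifications(
    records: Iterable[IdentificationRecord | dict],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[IdentificationRecord], list[tuple[IdentificationRecord | dict, str]]]:
    """Split identifications into kept and (record, reason) rejected lists.

    A record is kept iff intensity >= min_intensity, products_per_aa >=
    min_products_per_aa, score >= min_score and \\|mh_error_ppm\\| <=
    max_mh_error_ppm.  Records with missing fields are rejected with reason
    ``"incomplete"``.
    """
    kept: list[IdentificationRecord] = []
    rejected: list[tuple[IdentificationRecord | dict, str]] = []
    for rec in records:
        if isinstance(rec, dict):
            try:
                rec_obj = IdentificationRecord(**rec)
            except TypeError:
                rejected.append((rec, "incomplete"))
                continue
        else:
            rec_obj = rec
        vals = (rec_obj.intensity, rec_obj.products_per_aa,
                rec_obj.score, rec_obj.mh_error_ppm)
        if any(v is None or np.isnan(v) for v in vals):
            rejected.append((rec_obj, "incomplete"))
        elif rec_obj.intensity < criteria.min_intensity:
            rejected.append((rec_obj, "min_intensity"))
        elif rec_obj.products_per_aa < criteria.min_products_per_aa:
            rejected.append((rec_obj, "min_products_per_aa"))
        elif rec_obj.score < criteria.min_score:
            rejected.append((rec_obj, "min_score"))
        elif abs(rec_obj.mh_error_ppm) > criteria.max_mh_error_ppm:
            rejected.append((rec_obj, "max_mh_error_ppm"))
        else:
            kept.append(rec_obj)
    return kept, rejected


def percent_deuteration(
    mex: float, mex0: float, mex100: float, peptide_id: str = "?"
) -> float:
    """Control-normalized deuteration level in percent.

    Not clamped: noisy measurements may fall outside [0, 100]; values outside
    [-10, 110] trigger a warning but are preserved for downstream statistics.
    """
    if mex100 == mex0:
        raise DegenerateControlError(
            f"peptide {peptide_id}: Mex100 == Mex0 ({mex0}); no dynamic range"
        )
    pct = 100.0 * (mex - mex0) / (mex100 - mex0)
    if not -10.0 <= pct <= 110.0:
        warnings.warn(
            f"peptide {peptide_id}: %D {pct:.1f} outside [-10, 110]",
            stacklevel=2,
        )
    return pct


def build_uptake_curves(
    records: Iterable[UptakeRecord],
    timecourse: TimeCourse | None = None,
) -> list[DeuterationPoint]:
    """Normalize replicate centroids to %D and aggregate into uptake curves.

    Controls (Mex0/Mex100) are averaged over their replicates per peptide
    before normalization (pooled controls).  Peptides lacking either control
    are excluded with a warning.  Missing time points simply yield absent
    curve points; curves may be ragged.  Sample (n-1) SD is reported, 0.0
    for singleton points.
    """
    recs = list(records)
    by_pep: dict[str, list[UptakeRecord]] = {}
    for r in recs:
        by_pep.setdefault(r.peptide_id, []).append(r)

    allowed_times = set(timecourse.times) if timecourse is not None else None
    points: list[DeuterationPoint] = []
    for pep in sorted(by_pep):
        group = by_pep[pep]
        mex0_vals = [r.centroid_mass for r in group if r.state == IN_EXCHANGE_CONTROL]
        mex100_vals = [r.centroid_mass for r in group if r.state == OUT_EXCHANGE_CONTROL]
        if not mex0_vals or not mex100_vals:
            missing = "in-exchange" if not mex0_vals else "out-exchange"
            warnings.warn(
                f"peptide {pep}: missing {missing} control; excluded", stacklevel=2
            )
            continue
        mex0 = float(np.mean(mex0_vals))
        mex100 = float(np.mean(mex100_vals))

        by_state_time: dict[tuple[str, float], list[float]] = {}
        for r in group:
            if r.state in (IN_EXCHANGE_CONTROL, OUT_EXCHANGE_CONTROL):
                continue
            if allowed_times is not None and r.exposure_time not in allowed_times:
                continue
            by_state_time.setdefault((r.state, r.exposure_time), []).append(
                r.centroid_mass
            )
        for (state, t) in sorted(by_state_time):
            masses = by_state_time[(state, t)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # out-of-range flags batched below
                pd_vals = np.array(
                    [percent_deuteration(m, mex0, mex100, pep) for m in masses]
                )
            sd = float(np.std(pd_vals, ddof=1)) if len(pd_vals) > 1 else 0.0
            points.append(
                DeuterationPoint(
                    peptide_id=pep,
                    state=state,
                    exposure_time=t,
                    percent_deuteration_mean=float(pd_vals.mean()),
                    sd=sd,
                    n_replicates=len(pd_vals),
                )
            )
    return points


def classify_exchange(
    percent_d: float, bins: Sequence[float] = DEFAULT_CLASS_BINS
) -> str:
    """Map a %D value to one of the five exchange-speed classes.

    With the default bins (20, 40, 60, 70): %D <= 20 is very_slow, then
    slow, intermediate, fast, and > 70 very_fast.  Bin edges belong to the
    slower class.
    """
    if len(bins) != len(EXCHANGE_CLASSES) - 1:
        raise ValueError("need exactly four bin edges for five classes")
    idx = int(np.searchsorted(np.asarray(bins, dtype=float), percent_d, side="left"))
    return EXCHANGE_CLASSES[idx]


# ---------------------------------------------------------------------------
# Table I/O (state-data dialect)

STATE_TABLE_COLUMNS = [
    "peptide", "start", "end", "sequence", "state", "exposure", "replicate",
    "centroid", "intensity",
]


def records_to_frame(records: Iterable[UptakeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": r.peptide_id,
                "state": r.state,
                "exposure": r.exposure_time,
                "replicate": r.replicate,
                "centroid": r.centroid_mass,
                "intensity": r.intensity,
            }
            for r in records
        ]
    )


def read_state_table(path: str | Path) -> list[UptakeRecord]:
    """Read a delimited state-data table into uptake records.

    Required columns: peptide, state, exposure, replicate, centroid.
    Schema violations report the offending line number.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "state", "exposure", "replicate", "centroid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"state table missing columns: {sorted(missing)}")
    records: list[UptakeRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(
                UptakeRecord(
                    peptide_id=str(row["peptide"]),
                    state=str(row["state"]),
                    exposure_time=float(row["exposure"]),
                    replicate=int(row["replicate"]),
                    centroid_mass=float(row["centroid"]),
                    intensity=float(row.get("intensity", float("nan"))),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return records


def write_state_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def curves_to_frame(points: Iterable[DeuterationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": p.peptide_id,
                "state": p.state,
                "exposure": p.exposure_time,
                "percent_d": p.percent_deuteration_mean,
                "sd": p.sd,
                "n": p.n_replicates,
            }
            for p in points
        ]
    )


def write_curves(points: Iterable[DeuterationPoint], path: str | Path) -> None:
    curves_to_frame(points).to_csv(path, sep="\t", index=False)


def read_curves(path: str | Path) -> list[DeuterationPoint]:
    df = pd.read_csv(path, sep="\t")
    return [
        DeuterationPoint(
            peptide_id=str(r["peptide"]),
            state=str(r["state"]),
            exposure_time=float(r["exposure"]),
            percent_deuteration_mean=float(r["percent_d"]),
            sd=float(r["sd"]),
            n_replicates=int(r["n"]),
        )
        for _, r in df.iterrows()
    ]
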