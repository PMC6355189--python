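"""Differential exchange: apo vs complex comparison and protected regions.

Protection upon binding is read out per peptide as the difference in
fraction exchanged,

    dFE(t) = (%D_apo(t) - %D_complex(t)) / 100,

with uncertainty propagated as the square root of the sum of the two
variances.  Replicate-level significance uses the two-sample t-test for
unequal variances (Welch) with Satterthwaite degrees of freedom.  A peptide
is called protected when, at at least one exposure time, p <= alpha and
dFE >= min_delta; overlapping protected peptides are then condensed into
regions, by default as the shortest segment consistent with all overlapping
evidence (intersection mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hdx_quant import APO, COMPLEX, DeuterationPoint

__all__ = [
    "DifferentialPoint",
    "ProtectedRegion",
    "ResidueExchangeProfile",
    "delta_fraction_exchanged",
    "welch_t_test",
    "attach_welch",
    "differential_table",
    "call_significant_points",
    "benjamini_hochberg",
    "interval_jaccard",
    "protected_regions",
    "residue_profile",
    "regions_to_bed",
]


@dataclass(frozen=True)
class DifferentialPoint:
    peptide_id: str
    exposure_time: float
    delta_fraction_exchanged: float  # apo - complex, fraction units
    propagated_sd: float
    welch_t: float | None = None
    welch_df: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class ProtectedRegion:
    start: int
    end: int
    supporting_peptide_ids: tuple[str, ...]
    min_p: float
    mean_delta: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if not self.supporting_peptide_ids:
            raise ValueError("a region needs at least one supporting peptide")


@dataclass(frozen=True)
class ResidueExchangeProfile:
    """Per-residue exchange estimate (fraction) with coverage depth."""

    estimate: dict[int, float]
    depth: dict[int, int]


def delta_fraction_exchanged(
    apo: DeuterationPoint, complex_: DeuterationPoint
) -> DifferentialPoint:
    """dFE and propagated SD for one peptide at one exposure time.

    Statistics fields are left unset; use :func:`attach_welch` with the
    replicate values to fill them.
    """
    if apo.peptide_id != complex_.peptide_id:
        raise ValueError("peptide mismatch between states")
    if apo.exposure_time != complex_.exposure_time:
        raise ValueError("exposure-time mismatch between states")
    if apo.state != APO or complex_.state != COMPLEX:
        raise ValueError("expected one apo and one complex point")
    delta = (apo.percent_deuteration_mean - complex_.percent_deuteration_mean) / 100.0
    sd = math.sqrt(apo.sd**2 + complex_.sd**2) / 100.0
    return DifferentialPoint(
        peptide_id=apo.peptide_id,
        exposure_time=apo.exposure_time,
        delta_fraction_exchanged=delta,
        propagated_sd=sd,
    )


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (t, df, two-sided p).

    Degenerate inputs follow documented conventions: if both samples have
    zero variance the test is decided by the means alone (p = 1 when equal,
    p = 0 when different, t = ±inf, df = n_a + n_b - 2).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("welch_t_test requires at least two values per sample")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def attach_welch(
    point: DifferentialPoint,
    apo_replicates: Sequence[float],
    complex_replicates: Sequence[float],
) -> DifferentialPoint:
    t, df, p = welch_t_test(apo_replicates, complex_replicates)
    return replace(point, welch_t=t, welch_df=df, p_value=p)


def differential_table(
    apo_points: Iterable[DeuterationPoint],
    complex_points: Iterable[DeuterationPoint],
    replicate_values: Mapping[tuple[str, str, float], Sequence[float]] | None = None,
) -> list[DifferentialPoint]:
    """Pair apo and complex curve points and compute dFE per peptide/time.

    ``replicate_values`` optionally maps (peptide, state, time) to the
    per-replicate %D values; when given, Welch statistics are attached.
    Unpaired points are skipped.
    """
    apo_by_key = {(p.peptide_id, p.exposure_time): p for p in apo_points}
    out: list[DifferentialPoint] = []
    for cpx in complex_points:
        key = (cpx.peptide_id, cpx.exposure_time)
        apo = apo_by_key.get(key)
        if apo is None:
            continue
        dp = delta_fraction_exchanged(apo, cpx)
        if replicate_values is not None:
            a = replicate_values.get((cpx.peptide_id, APO, cpx.exposure_time))
            b = replicate_values.get((cpx.peptide_id, COMPLEX, cpx.exposure_time))
            if a is not None and b is not None and len(a) >= 2 and len(b) >= 2:
                dp = attach_welch(dp, a, b)
        out.append(dp)
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_significant_points(
    diffs: Iterable[DifferentialPoint],
    alpha: float = 0.05,
    min_delta: float = 0.02,
    adjust: bool = False,
) -> list[DifferentialPoint]:
    """Flag differential points showing significant protection.

    A point is flagged iff p <= alpha and dFE >= min_delta (protection
    only; deprotection is never flagged here).  With ``adjust=True``
    Benjamini–Hochberg adjusted p-values are used in place of raw ones.
    No correction is applied by default.
    """
    pts = [d for d in diffs if d.p_value is not None]
    if not pts:
        return []
    pvals = np.array([d.p_value for d in pts])
    if adjust:
        pvals = benjamini_hochberg(pvals)
    return [
        d
        for d, p in zip(pts, pvals)
        if p <= alpha and d.delta_fraction_exchanged >= min_delta
    ]


def interval_jaccard(
    intervals_a: Iterable[tuple[int, int]], intervals_b: Iterable[tuple[int, int]]
) -> float:
    """Residue-level Jaccard index between two sets of inclusive intervals."""
    set_a = {i for s, e in intervals_a for i in range(s, e + 1)}
    set_b = {i for s, e in intervals_b for i in range(s, e + 1)}
    if not set_a and not set_b:
        return 1.0
    return len(set_a & set_b) / len(set_a | set_b)


def protected_regions(
    flagged: Iterable[DifferentialPoint],
    peptide_intervals: Mapping[str, tuple[int, int]],
    mode: str = "intersection",
) -> list[ProtectedRegion]:
    """Condense flagged peptides into protected regions.

    ``intersection`` (default) reports the shortest regions consistent with
    the flagged evidence: flagged intervals are taken shortest-first, each
    reported as a region supported by every flagged peptide overlapping it,
    and the overlapping evidence is consumed before the next region is
    chosen.  When a short flagged fragment is nested in longer flagged
    peptides this reduces to the fragments' common segment — the "shortest
    region showing significant change" logic.  ``union`` reports the
    envelope of each connected component of flagged intervals instead.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    by_pep: dict[str, list[DifferentialPoint]] = {}
    for d in flagged:
        by_pep.setdefault(d.peptide_id, []).append(d)
    if not by_pep:
        return []
    intervals = []
    for pep in by_pep:
        if pep not in peptide_intervals:
            raise KeyError(f"no interval known for flagged peptide {pep!r}")
        s, e = peptide_intervals[pep]
        intervals.append((s, e, pep))

    groups: list[tuple[tuple[int, int], list[tuple[int, int, str]]]] = []
    if mode == "union":
        hi = None
        for iv in sorted(intervals):
            if hi is None or iv[0] > hi:
                groups.append(((iv[0], iv[1]), [iv]))
                hi = iv[1]
            else:
                (lo, _), members = groups[-1]
                hi = max(hi, iv[1])
                groups[-1] = ((lo, hi), members + [iv])
    else:
        pool = sorted(intervals, key=lambda iv: (iv[1] - iv[0], iv[0]))
        while pool:
            s, e, _ = pool[0]
            members = [iv for iv in pool if iv[0] <= e and iv[1] >= s]
            groups.append(((s, e), members))
            pool = [iv for iv in pool if iv[0] > e or iv[1] < s]
        groups.sort(key=lambda g: g[0])

    regions: list[ProtectedRegion] = []
    for (start, end), members in groups:
        peps = tuple(sorted({pep for _, _, pep in members}))
        pvals = [d.p_value for pep in peps for d in by_pep[pep]]
        deltas = [d.delta_fraction_exchanged for pep in peps for d in by_pep[pep]]
        regions.append(
            ProtectedRegion(
                start=start,
                end=end,
                supporting_peptide_ids=peps,
                min_p=float(min(pvals)),
                mean_delta=float(np.mean(deltas)),
            )
        )
    return regions


def residue_profile(
    points: Iterable[DeuterationPoint],
    peptide_intervals: Mapping[str, tuple[int, int]],
) -> ResidueExchangeProfile:
    """Depth-weighted per-residue exchange estimate at one state and time.

    Each covering peptide contributes its fraction exchanged with weight
    1/length (shorter peptides localize exchange better).  Residues covered
    by no peptide are absent from the profile, not zero.
    """
    pts = list(points)
    states = {p.state for p in pts}
    times = {p.exposure_time for p in pts}
    if len(states) > 1 or len(times) > 1:
        raise ValueError("residue_profile expects a single state and exposure time")
    num: dict[int, float] = {}
    den: dict[int, float] = {}
    depth: dict[int, int] = {}
    for p in pts:
        s, e = peptide_intervals[p.peptide_id]
        w = 1.0 / (e - s + 1)
        frac = p.percent_deuteration_mean / 100.0
        for i in range(s, e + 1):
            num[i] = num.get(i, 0.0) + w * frac
            den[i] = den.get(i, 0.0) + w
            depth[i] = depth.get(i, 0) + 1
    estimate = {i: num[i] / den[i] for i in num}
    return ResidueExchangeProfile(estimate=estimate, depth=depth)


def regions_to_bed(
    regions: Iterable[ProtectedRegion], parent_id: str, path: str | Path
) -> None:
    """Write regions as BED (0-based half-open, score = -log10 min p)."""
    rows = [
        {
            "chrom": parent_id,
            "start": r.start - 1,
            "end": r.end,
            "name": ",".join(r.supporting_peptide_ids),
            "score": -math.log10(r.min_p) if r.min_p > 0 else math.inf,
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
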