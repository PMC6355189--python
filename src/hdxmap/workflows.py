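"""End-to-end convenience workflows tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hdx_differential, hdx_quant, synthetic_data

__all__ = [
    "DifferentialResult",
    "frame_to_records",
    "replicate_percent_d",
    "differential_analysis",
    "simulate_and_call",
]


@dataclass(frozen=True)
class DifferentialResult:
    curves: list[hdx_quant.DeuterationPoint]
    diffs: list[hdx_differential.DifferentialPoint]
    flagged: list[hdx_differential.DifferentialPoint]
    regions: list[hdx_differential.ProtectedRegion]


def frame_to_records(frame: pd.DataFrame) -> list[hdx_quant.UptakeRecord]:
    return [
        hdx_quant.UptakeRecord(
            peptide_id=str(r.peptide),
            state=str(r.state),
            exposure_time=float(r.exposure),
            replicate=int(r.replicate),
            centroid_mass=float(r.centroid),
            intensity=float(getattr(r, "intensity", float("nan"))),
        )
        for r in frame.itertuples()
    ]


def replicate_percent_d(
    records: Iterable[hdx_quant.UptakeRecord],
) -> dict[tuple[str, str, float], list[float]]:
    """Per-replicate %D values keyed by (peptide, state, time).

    Controls are pooled (averaged over replicates) per peptide before
    normalization, matching :func:`hdx_quant.build_uptake_curves`.
    """
    by_pep: dict[str, list[hdx_quant.UptakeRecord]] = {}
    for r in records:
        by_pep.setdefault(r.peptide_id, []).append(r)
    out: dict[tuple[str, str, float], list[float]] = {}
    for pep, group in by_pep.items():
        m0 = [g.centroid_mass for g in group
              if g.state == hdx_quant.IN_EXCHANGE_CONTROL]
        m100 = [g.centroid_mass for g in group
                if g.state == hdx_quant.OUT_EXCHANGE_CONTROL]
        if not m0 or not m100:
            continue
        mex0 = float(np.mean(m0))
        mex100 = float(np.mean(m100))
        for g in group:
            if g.state in (hdx_quant.APO, hdx_quant.COMPLEX):
                out.setdefault((pep, g.state, g.exposure_time), []).append(
                    hdx_quant.percent_deuteration(
                        g.centroid_mass, mex0, mex100, pep
                    )
                )
    return out


def differential_analysis(
    records: Iterable[hdx_quant.UptakeRecord],
    peptide_intervals: Mapping[str, tuple[int, int]] | None = None,
    alpha: float = 0.05,
    min_delta: float = 0.02,
    adjust: bool = False,
    region_mode: str = "intersection",
) -> DifferentialResult:
    """Curves, differential statistics, significance calls and regions."""
    records = list(records)
    curves = hdx_quant.build_uptake_curves(records)
    repvals = replicate_percent_d(records)
    apo = [p for p in curves if p.state == hdx_quant.APO]
    cplx = [p for p in curves if p.state == hdx_quant.COMPLEX]
    diffs = hdx_differential.differential_table(apo, cplx, repvals)
    flagged = hdx_differential.call_significant_points(
        diffs, alpha=alpha, min_delta=min_delta, adjust=adjust
    )
    regions = []
    if peptide_intervals is not None and flagged:
        regions = hdx_differential.protected_regions(
            flagged, peptide_intervals, mode=region_mode
        )
    return DifferentialResult(
        curves=curves, diffs=diffs, flagged=flagged, regions=regions
    )


def simulate_and_call(
    config: synthetic_data.ScenarioConfig,
    peptides: Sequence[tuple[int, int]],
    seed: int,
    noise_sd: float = 0.1,
    n_replicates: int = 4,
    alpha: float = 0.05,
    min_delta: float = 0.02,
    region_mode: str = "intersection",
) -> tuple[synthetic_data.ScenarioTruth, DifferentialResult]:
    """Simulate one scenario and run the full differential analysis on it."""
    truth = synthetic_data.generate_truth(config, seed=seed)
    frame = synthetic_data.simulate_uptake(
        truth, peptides, n_replicates=n_replicates, noise_sd=noise_sd, seed=seed
    )
    intervals = {f"{s}-{e}": (s, e) for s, e in peptides}
    result = differential_analysis(
        frame_to_records(frame),
        peptide_intervals=intervals,
        alpha=alpha,
        min_delta=min_delta,
        region_mode=region_mode,
    )
    return truth, result
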