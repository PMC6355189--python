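"""Two-chain complex ensemble analysis: contacts, salt bridges, RMSD/RMSF.

The residue-residue contact score uses a dual-cutoff ramp: distances at or
below ``cutoff1`` (default 8 A) score 1, distances at or beyond ``cutoff2``
(default 10 A) score 0, with a linear ramp in between.  Distances are
measured between residue representative points — the heavy side-chain
centroid by default (Calpha for glycine), matching the side-chain-centre
convention of coarse-grained docking — and ensemble maps average the score
over models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import BACKBONE_ATOMS, Residue, StructureModel, kabsch, superpose

__all__ = [
    "ContactConfig",
    "ContactMap",
    "SaltBridge",
    "FluctuationProfile",
    "contact_score",
    "contact_map",
    "interface_residues",
    "salt_bridges",
    "hydrophobic_contacts",
    "superpose_rmsd",
    "rmsf",
    "contact_map_frame",
]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
HIS_BASIC_ATOMS = ("ND1", "NE2")
SALT_BRIDGE_MAX = 4.0  # A, charged O...N distance

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "PRO", "TYR"}
)
HYDROPHOBIC_MAX = 5.0  # A, side-chain centroid distance


@dataclass(frozen=True)
class ContactConfig:
    cutoff1: float = 8.0
    cutoff2: float = 10.0
    representative_point: str = "side_chain_centroid"  # or "c_alpha"
    ramp: bool = True  # False: step function at cutoff2

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff1 < self.cutoff2:
            raise ValueError("require 0 < cutoff1 < cutoff2")
        if self.representative_point not in ("side_chain_centroid", "c_alpha"):
            raise ValueError(
                f"unknown representative point {self.representative_point!r}"
            )


@dataclass(frozen=True)
class ContactMap:
    rows: tuple[int, ...]       # chain-A residue indices
    cols: tuple[int, ...]       # chain-B residue indices
    scores: np.ndarray          # shape (len(rows), len(cols)), values in [0,1]
    n_structures: int
    chain_a: str = "A"
    chain_b: str = "B"


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple[str, int, str]   # (chain, residue index, residue name)
    basic: tuple[str, int, str]
    min_distance: float
    occupancy: float


@dataclass(frozen=True)
class FluctuationProfile:
    rmsf: dict[int, float]  # residue index -> backbone RMSF (A)


def contact_score(distance: float, config: ContactConfig = ContactConfig()) -> float:
    """Graded contact score of a single residue-pair distance."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if not config.ramp:
        return 1.0 if distance <= config.cutoff2 else 0.0
    if distance <= config.cutoff1:
        return 1.0
    if distance >= config.cutoff2:
        return 0.0
    return (config.cutoff2 - distance) / (config.cutoff2 - config.cutoff1)


def _representative_point(res: Residue, mode: str) -> np.ndarray | None:
    if mode == "c_alpha":
        return res.atoms.get("CA")
    centroid = res.side_chain_centroid()
    if centroid is None:
        return res.atoms.get("CA")
    return centroid


def _rep_coords(
    model: StructureModel, chain_id: str, mode: str
) -> tuple[list[int], np.ndarray]:
    chain = model.chain(chain_id)
    idx, pts = [], []
    for res in chain.residues:
        p = _representative_point(res, mode)
        if p is None:
            continue
        idx.append(res.index)
        pts.append(p)
    return idx, np.asarray(pts)


def contact_map(
    ensemble: Sequence[StructureModel],
    chain_a: str,
    chain_b: str,
    config: ContactConfig = ContactConfig(),
) -> ContactMap:
    """Mean contact-score matrix between two chains over an ensemble."""
    if not ensemble:
        raise ValueError("contact_map requires at least one model")
    ref_rows: list[int] | None = None
    ref_cols: list[int] | None = None
    total: np.ndarray | None = None
    for model in ensemble:
        rows, pa = _rep_coords(model, chain_a, config.representative_point)
        cols, pb = _rep_coords(model, chain_b, config.representative_point)
        if ref_rows is None:
            ref_rows, ref_cols = rows, cols
            total = np.zeros((len(rows), len(cols)))
        elif rows != ref_rows or cols != ref_cols:
            raise ValueError(
                f"model {model.model_id}: residue numbering inconsistent "
                "across ensemble"
            )
        d = np.sqrt(
            np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=2)
        )
        if config.ramp:
            s = np.clip(
                (config.cutoff2 - d) / (config.cutoff2 - config.cutoff1), 0.0, 1.0
            )
        else:
            s = (d <= config.cutoff2).astype(float)
        total += s
    scores = total / len(ensemble)
    return ContactMap(
        rows=tuple(ref_rows),
        cols=tuple(ref_cols),
        scores=scores,
        n_structures=len(ensemble),
        chain_a=chain_a,
        chain_b=chain_b,
    )


def _merge_intervals(indices: Sequence[int]) -> list[tuple[int, int]]:
    if not indices:
        return []
    out = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
        else:
            out.append((start, prev))
            start = prev = i
    out.append((start, prev))
    return out


def interface_residues(
    cmap: ContactMap, threshold: float = 0.5
) -> dict[str, dict[str, object]]:
    """Residues whose best contact score reaches ``threshold``, per chain.

    Returns, per chain, the sorted residue indices and the merged
    consecutive intervals.
    """
    if cmap.scores.size == 0:
        a_idx: list[int] = []
        b_idx: list[int] = []
    else:
        a_mask = cmap.scores.max(axis=1) >= threshold
        b_mask = cmap.scores.max(axis=0) >= threshold
        a_idx = [i for i, m in zip(cmap.rows, a_mask) if m]
        b_idx = [j for j, m in zip(cmap.cols, b_mask) if m]
    return {
        cmap.chain_a: {"residues": a_idx, "intervals": _merge_intervals(a_idx)},
        cmap.chain_b: {"residues": b_idx, "intervals": _merge_intervals(b_idx)},
    }


def _charged_atoms(
    model: StructureModel, include_histidine: bool, chains: Sequence[str] | None
) -> tuple[list[tuple[tuple[str, int, str], np.ndarray]], list[tuple[tuple[str, int, str], np.ndarray]]]:
    acidic, basic = [], []
    basic_table = dict(BASIC_ATOMS)
    if include_histidine:
        basic_table["HIS"] = HIS_BASIC_ATOMS
    for cid, chain in model.chains.items():
        if chains is not None and cid not in chains:
            continue
        for res in chain.residues:
            for table, bucket in ((ACIDIC_ATOMS, acidic), (basic_table, basic)):
                names = table.get(res.name)
                if names is None:
                    continue
                pts = [res.atoms[a] for a in names if a in res.atoms]
                if not pts:
                    warnings.warn(
                        f"{cid} {res.name}{res.index}: charged side-chain atoms "
                        "missing; residue skipped",
                        stacklevel=3,
                    )
                    continue
                bucket.append(((cid, res.index, res.name), np.asarray(pts)))
    return acidic, basic


def salt_bridges(
    ensemble: StructureModel | Sequence[StructureModel],
    max_distance: float = SALT_BRIDGE_MAX,
    include_histidine: bool = False,
    inter_chain_only: bool = True,
    chains: Sequence[str] | None = None,
) -> list[SaltBridge]:
    """Detect salt bridges, with ensemble occupancy.

    A bridge exists in a frame when the minimum distance between any acidic
    side-chain oxygen and basic side-chain nitrogen of the pair is at most
    ``max_distance``.  Results are sorted by occupancy (descending), then
    by the ensemble-minimum distance.
    """
    models = [ensemble] if isinstance(ensemble, StructureModel) else list(ensemble)
    if not models:
        raise ValueError("salt_bridges requires at least one model")
    hits: dict[tuple, list[float]] = {}
    for model in models:
        acidic, basic = _charged_atoms(model, include_histidine, chains)
        for (a_key, a_pts) in acidic:
            for (b_key, b_pts) in basic:
                if inter_chain_only and a_key[0] == b_key[0]:
                    continue
                d = float(
                    np.sqrt(
                        np.min(
                            np.sum(
                                (a_pts[:, None, :] - b_pts[None, :, :]) ** 2, axis=2
                            )
                        )
                    )
                )
                hits.setdefault((a_key, b_key), []).append(d)
    bridges = []
    for (a_key, b_key), dists in hits.items():
        present = [d for d in dists if d <= max_distance]
        if not present:
            continue
        bridges.append(
            SaltBridge(
                acidic=a_key,
                basic=b_key,
                min_distance=min(dists),
                occupancy=len(present) / len(models),
            )
        )
    return sorted(bridges, key=lambda b: (-b.occupancy, b.min_distance))


def hydrophobic_contacts(
    ensemble: StructureModel | Sequence[StructureModel],
    chain_a: str,
    chain_b: str,
    max_distance: float = HYDROPHOBIC_MAX,
) -> list[tuple[tuple[int, str], tuple[int, str], float, float]]:
    """Cross-chain hydrophobic side-chain contacts (centroid distance).

    Returns (residue A, residue B, min distance, occupancy) tuples sorted
    by occupancy then distance.
    """
    models = [ensemble] if isinstance(ensemble, StructureModel) else list(ensemble)
    hits: dict[tuple, list[float]] = {}
    for model in models:
        for res_a in model.chain(chain_a).residues:
            if res_a.name not in HYDROPHOBIC_RESIDUES:
                continue
            ca_pt = res_a.side_chain_centroid()
            if ca_pt is None:
                continue
            for res_b in model.chain(chain_b).residues:
                if res_b.name not in HYDROPHOBIC_RESIDUES:
                    continue
                cb_pt = res_b.side_chain_centroid()
                if cb_pt is None:
                    continue
                d = float(np.linalg.norm(ca_pt - cb_pt))
                key = ((res_a.index, res_a.name), (res_b.index, res_b.name))
                hits.setdefault(key, []).append(d)
    out = []
    for (ka, kb), dists in hits.items():
        present = [d for d in dists if d <= max_distance]
        if present:
            out.append((ka, kb, min(dists), len(present) / len(models)))
    return sorted(out, key=lambda r: (-r[3], r[2]))


def _matched_atom_coords(
    mobile: StructureModel,
    reference: StructureModel,
    atom_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    mob, ref = [], []
    for cid, chain in reference.chains.items():
        if cid not in mobile.chains:
            raise ValueError(f"chain {cid!r} absent from mobile model")
        mob_map = mobile.chains[cid].residue_map()
        for res in chain.residues:
            mres = mob_map.get(res.index)
            for name in atom_names:
                if name in res.atoms:
                    if mres is None or name not in mres.atoms:
                        raise ValueError(
                            f"atom {cid}/{res.index}/{name} missing from mobile model"
                        )
                    ref.append(res.atoms[name])
                    mob.append(mres.atoms[name])
    if not ref:
        raise ValueError("no matched atoms in selection")
    return np.asarray(mob), np.asarray(ref)


def superpose_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    selection: str = "c_alpha",
) -> float:
    """Kabsch-minimized RMSD over the selection, A."""
    names = ("CA",) if selection == "c_alpha" else BACKBONE_ATOMS
    mob, ref = _matched_atom_coords(mobile, reference, names)
    _, _, value = kabsch(mob, ref)
    return value


def rmsf(
    trajectory: Sequence[StructureModel], selection: str = "backbone"
) -> FluctuationProfile:
    """Per-residue backbone RMSF across an ordered ensemble.

    Frames are rigid-fitted onto the first frame via Calphas; the RMSF of
    each selected atom is computed about its mean position and averaged per
    residue.
    """
    frames = list(trajectory)
    if len(frames) < 2:
        raise ValueError("rmsf requires at least two frames")
    names = ("CA",) if selection == "c_alpha" else BACKBONE_ATOMS
    ref = frames[0]

    # matched selected atoms, in a fixed order
    keys: list[tuple[str, int, str]] = []
    for cid, chain in ref.chains.items():
        for res in chain.residues:
            for name in names:
                if name in res.atoms:
                    keys.append((cid, res.index, name))
    if not keys:
        raise ValueError("no selected atoms in reference frame")

    stacks = np.empty((len(frames), len(keys), 3))
    for fi, frame in enumerate(frames):
        ca_mob, ca_ref = _matched_atom_coords(frame, ref, ("CA",))
        coords = []
        for cid, idx, name in keys:
            res = frame.chains[cid].residue_map().get(idx)
            if res is None or name not in res.atoms:
                raise ValueError(f"atom {cid}/{idx}/{name} missing from frame {fi}")
            coords.append(res.atoms[name])
        stacks[fi] = superpose(np.asarray(coords), ca_mob, ca_ref)

    mean_pos = stacks.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stacks - mean_pos) ** 2, axis=2), axis=0))
    per_res: dict[int, list[float]] = {}
    for (cid, idx, name), val in zip(keys, per_atom):
        per_res.setdefault(idx, []).append(float(val))
    return FluctuationProfile(
        rmsf={idx: float(np.mean(vals)) for idx, vals in per_res.items()}
    )


def contact_map_frame(cmap: ContactMap) -> pd.DataFrame:
    """Long-form table of the contact map (one row per residue pair)."""
    rows = []
    for i, ri in enumerate(cmap.rows):
        for j, cj in enumerate(cmap.cols):
            rows.append(
                {
                    "residue_a": ri,
                    "residue_b": cj,
                    "score": float(cmap.scores[i, j]),
                }
            )
    return pd.DataFrame(rows)
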