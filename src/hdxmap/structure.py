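"""Structure container, PDB I/O, and shared geometric primitives.

The in-memory model is deliberately small: chains of residues, each residue
a dict of named heavy atoms with coordinates in Angstrom.  PDB parsing and
writing delegate to gemmi; multi-MODEL files yield one
:class:`StructureModel` per MODEL block.  The module also hosts the two
geometry primitives shared by the scoring modules: Shrake–Rupley solvent
accessibility and Kabsch least-squares superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    SASA_N_POINTS,
    SASA_PROBE_RADIUS,
    VDW_DEFAULT,
    VDW_RADIUS,
)

__all__ = [
    "Residue",
    "Chain",
    "StructureModel",
    "read_structure",
    "read_structure_file",
    "write_pdb",
    "sphere_points",
    "shrake_rupley",
    "kabsch",
    "superpose",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    index: int
    name: str
    atoms: dict[str, np.ndarray]          # atom name -> xyz (A)
    elements: dict[str, str] = field(default_factory=dict)

    def element_of(self, atom_name: str) -> str:
        el = self.elements.get(atom_name)
        if el:
            return el
        # fall back on the PDB convention: first letter of the atom name
        return atom_name.strip("0123456789")[:1].upper() or "C"

    def side_chain_centroid(self) -> np.ndarray | None:
        """Heavy side-chain centroid; None if the residue has no side chain."""
        pts = [
            xyz
            for name, xyz in self.atoms.items()
            if name not in ("N", "CA", "C", "O", "OXT")
            and self.element_of(name) != "H"
        ]
        if not pts:
            return None
        return np.mean(pts, axis=0)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def residue(self, index: int) -> Residue | None:
        for r in self.residues:
            if r.index == index:
                return r
        return None

    def residue_map(self) -> dict[int, Residue]:
        return {r.index: r for r in self.residues}


@dataclass
class StructureModel:
    model_id: str
    chains: dict[str, Chain]

    def chain(self, chain_id: str) -> Chain:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in model {self.model_id}")
        return self.chains[chain_id]

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and vdW radii across the model."""
        coords, radii = [], []
        for chain in self.chains.values():
            for res in chain.residues:
                for name, xyz in res.atoms.items():
                    el = res.element_of(name)
                    if el == "H":
                        continue
                    coords.append(xyz)
                    radii.append(VDW_RADIUS.get(el, VDW_DEFAULT))
        return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def _from_gemmi_model(gmodel: gemmi.Model) -> StructureModel:
    chains: dict[str, Chain] = {}
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.seqid.icode not in (" ", "\x00", ""):
                raise ValueError(
                    f"insertion code {gres.seqid.icode!r} at {gchain.name} "
                    f"{gres.seqid.num} not supported"
                )
            atoms: dict[str, np.ndarray] = {}
            elements: dict[str, str] = {}
            for atom in gres:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(pos)):
                    raise ValueError(
                        f"non-finite coordinates at {gchain.name} {gres.seqid.num} "
                        f"{atom.name}"
                    )
                if atom.name in atoms:
                    raise ValueError(
                        f"duplicate atom {atom.name!r} in {gchain.name} "
                        f"{gres.seqid.num} (altloc not supported)"
                    )
                atoms[atom.name] = pos
                elements[atom.name] = atom.element.name.upper()
            residues.append(
                Residue(index=gres.seqid.num, name=gres.name.strip(),
                        atoms=atoms, elements=elements)
            )
        chains[gchain.name] = Chain(chain_id=gchain.name, residues=residues)
    mid = getattr(gmodel, "num", None)
    if mid is None:  # older gemmi exposes .name instead of .num
        mid = getattr(gmodel, "name", "1")
    return StructureModel(model_id=str(mid), chains=chains)


def read_structure(text: str) -> list[StructureModel]:
    """Parse PDB-format text into one StructureModel per MODEL block."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB input: {exc}") from exc
    st.setup_entities()
    return [_from_gemmi_model(m) for m in st]


def read_structure_file(path: str | Path) -> list[StructureModel]:
    return read_structure(Path(path).read_text())


def write_pdb(models: Sequence[StructureModel], path: str | Path | None = None) -> str:
    """Render models as (multi-MODEL) PDB text, optionally writing to a file."""
    st = gemmi.Structure()
    st.name = "hdxmap"
    for i, model in enumerate(models, start=1):
        gmodel = gemmi.Model(i)
        for chain in model.chains.values():
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.index, " ")
                for name, xyz in res.atoms.items():
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(res.element_of(name))
                    atom.pos = gemmi.Position(*map(float, xyz))
                    gres.add_atom(atom)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Geometry primitives


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = SASA_PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Each atom's extended sphere (vdW radius + probe) is sampled at
    ``n_points`` quadrature points; points inside any neighbour's extended
    sphere are occluded.  The accessible fraction times the extended-sphere
    area gives the atom's SASA.  When ``subset`` (atom indices) is given,
    areas are computed only for those atoms — every atom still occludes —
    and the returned array has zeros elsewhere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    targets = np.arange(n) if subset is None else np.asarray(subset, dtype=int)
    unit = sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    areas = np.zeros(n)
    for i in targets:
        pts = coords[i] + ext[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], r=max_reach):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points
    return areas


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix, translation, RMSD).  Proper rotations only
    (reflections are corrected by sign-flipping the smallest singular
    vector).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("coordinate sets must have the same shape")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    coords: np.ndarray, mobile_sel: np.ndarray, reference_sel: np.ndarray
) -> np.ndarray:
    """Apply to ``coords`` the rigid motion fitting mobile_sel onto reference_sel."""
    R, t, _ = kabsch(mobile_sel, reference_sel)
    return (R @ np.asarray(coords, dtype=float).T).T + t
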