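"""Ground-truth scenario generation for end-to-end pipeline testing.

No raw LC-MS or simulation outputs are deposited for this system, so every
pipeline stage is exercised against synthetic data with known truth:

* per-residue exchange kinetics in the EX2 limit — each backbone amide
  exchanges as a single exponential ``f_i(t) = 1 - exp(-(k_int,i / P_i) t)``
  with an intrinsic rate ``k_int`` drawn log-uniformly and a state-dependent
  protection factor ``P``; binding multiplies ``P`` by a fold factor inside
  the configured intervals;
* replicate centroid-mass tables in the same state-data dialect the
  quantification module reads, including in-/out-exchange control rows,
  Gaussian centroid noise, an in-exchange floor and a back-exchange loss
  that apply equally to samples and controls (so control normalization
  recovers the true exchanged fraction exactly on noise-free data);
* toy structural fixtures: two-chain complexes with planted interfaces and
  salt bridges, and decoy model sets in which exactly one selection
  criterion is degraded per decoy.

The default scenario mirrors the CD160 study conditions: a 141-residue
protein (the reconstructed 1-133 ectodomain sequence plus a synthetic
Gly/Ser tail), protected intervals 16-21 / 30-34 / 76-87, the fragment-panel
peptide map, five exposure times from 10 s to 2 h, and four replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import cd160
from .constants import DEUTERIUM_INCREMENT
from .peptide_chem import ModifiedPeptide, monoisotopic_mass
from .structure import Chain, Residue, StructureModel, sphere_points, write_pdb

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "generate_truth",
    "generate_peptide_map",
    "simulate_uptake",
    "generate_toy_complex",
    "generate_toy_complex_pdb",
    "generate_reference_model",
    "generate_model_decoys",
    "exchangeable_indices",
    "default_sequence",
]

# Synthetic Gly/Ser extension appended to the reconstructed 133-residue
# ectodomain sequence to reach the 141-residue scenario length.
SYNTHETIC_TAIL = "GSGSGSGS"

_AA = "ACDEFGHIKLMNPQRSTVWY"


def default_sequence(length: int, rng: np.random.Generator) -> str:
    """Scenario protein sequence of the requested length.

    Lengths up to 141 reuse the CD160 ectodomain sequence (with its
    synthetic tail); longer proteins are random draws over the canonical
    alphabet.
    """
    base = cd160.CD160_SEQUENCE_133 + SYNTHETIC_TAIL
    if length <= len(base):
        return base[:length]
    return "".join(rng.choice(list(_AA), size=length))


@dataclass(frozen=True)
class ScenarioConfig:
    length: int = 141
    sequence: str | None = None
    binding_intervals: tuple[tuple[int, int], ...] = cd160.PROTECTED_REGIONS
    fold: float = 10.0                      # P_complex / P_apo inside intervals
    k_int_range: tuple[float, float] = (1e-3, 1e1)   # 1/s, log-uniform
    p_apo_range: tuple[float, float] = (1.0, 100.0)  # log-uniform

    def __post_init__(self) -> None:
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        for s, e in self.binding_intervals:
            if not 1 <= s <= e <= self.length:
                raise ValueError(f"binding interval {s}-{e} outside protein")


@dataclass(frozen=True)
class ScenarioTruth:
    sequence: str
    k_int: np.ndarray        # 1/s, per residue (1-based index i -> k_int[i-1])
    p_apo: np.ndarray
    p_complex: np.ndarray
    binding_intervals: tuple[tuple[int, int], ...]
    seed: int

    def fraction_exchanged(self, state: str, t: float) -> np.ndarray:
        """Per-residue exchanged fraction at exposure time ``t`` (s)."""
        p = self.p_apo if state == "apo" else self.p_complex
        return 1.0 - np.exp(-(self.k_int / p) * t)

    def peptide_fraction(self, start: int, end: int, state: str, t: float) -> float:
        """Mean exchanged fraction over a peptide's exchangeable amides."""
        idx = exchangeable_indices(self.sequence, start, end)
        if not idx:
            raise ValueError(f"peptide {start}-{end} has no exchangeable amides")
        f = self.fraction_exchanged(state, t)
        return float(np.mean([f[i - 1] for i in idx]))


def exchangeable_indices(sequence: str, start: int, end: int) -> list[int]:
    """1-based residue indices carrying an exchangeable backbone amide.

    The peptide's first residue and all prolines are excluded.
    """
    return [
        i for i in range(start + 1, end + 1) if sequence[i - 1] != "P"
    ]


def generate_truth(config: ScenarioConfig = ScenarioConfig(), seed: int = 0) -> ScenarioTruth:
    """Draw a ground-truth scenario; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    seq = config.sequence or default_sequence(config.length, rng)
    if len(seq) != config.length:
        raise ValueError("sequence length does not match config.length")
    lo, hi = config.k_int_range
    k_int = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=config.length)
    plo, phi = config.p_apo_range
    p_apo = 10.0 ** rng.uniform(math.log10(plo), math.log10(phi), size=config.length)
    p_complex = p_apo.copy()
    for s, e in config.binding_intervals:
        p_complex[s - 1 : e] *= config.fold
    return ScenarioTruth(
        sequence=seq,
        k_int=k_int,
        p_apo=p_apo,
        p_complex=p_complex,
        binding_intervals=tuple(config.binding_intervals),
        seed=seed,
    )


def generate_peptide_map(
    protein_length: int,
    mean_length: int = 20,
    overlap: int = 8,
    mode: str = "tiling",
) -> list[tuple[int, int]]:
    """Peptide intervals covering the protein.

    ``tiling`` lays peptides of ``mean_length`` with the given overlap
    (deterministic ladder starting at residue 1); a final peptide is
    appended if needed so the tiling reaches the C-terminus.  ``panel_map``
    returns the fixed fragment-panel intervals; ``digest_map`` additionally
    includes the short HDX-resolved fragments.
    """
    if mode == "panel_map":
        return list(cd160.PANEL_MAP_INTERVALS)
    if mode == "digest_map":
        return list(cd160.DIGEST_MAP_INTERVALS)
    if mode != "tiling":
        raise ValueError(f"unknown mode {mode!r}")
    if mean_length >= protein_length:
        raise ValueError("mean_length must be smaller than the protein")
    step = mean_length - overlap
    if step < 1:
        raise ValueError("overlap must be smaller than mean_length")
    intervals = []
    s = 1
    while s + mean_length - 1 <= protein_length:
        intervals.append((s, s + mean_length - 1))
        s += step
    if intervals[-1][1] < protein_length:
        intervals.append((protein_length - mean_length + 1, protein_length))
    return intervals


def _peptide_base_mass(sequence: str, start: int, end: int) -> float:
    pep = ModifiedPeptide(
        parent_id="synthetic", start=start, end=end,
        sequence=sequence[start - 1 : end],
    )
    return monoisotopic_mass(pep)


def simulate_uptake(
    truth: ScenarioTruth,
    peptides: Sequence[tuple[int, int]],
    timecourse: Sequence[float] = cd160.TIME_COURSE_S,
    n_replicates: int = 4,
    noise_sd: float = 0.1,
    seed: int = 0,
    in_exchange_floor: float = 0.02,
    back_exchange: float = 0.15,
    intensity: float = 1e5,
) -> pd.DataFrame:
    """Simulate a replicate state-data table for apo and complex states.

    Per peptide, the exchangeable-site count N and the mean exchanged
    fraction f(t) give the centroid

        Mex(t) = M_base + N * m_D * (floor + f(t) * (retain - floor)) + noise

    with ``retain = 1 - back_exchange`` and m_D the deuterium mass
    increment.  The in-exchange control sits at the floor and the
    out-exchange control at full retention, so control-normalized %D equals
    ``100 * f(t)`` identically when ``noise_sd`` is zero.  Controls are
    simulated with the same replicate count and noise.
    """
    if not 0.0 <= in_exchange_floor < 1.0 - back_exchange:
        raise ValueError("in-exchange floor must lie below the retention level")
    rng = np.random.default_rng(seed)
    retain = 1.0 - back_exchange
    rows: list[dict] = []
    for start, end in peptides:
        pid = f"{start}-{end}"
        seq = truth.sequence[start - 1 : end]
        n_ex = len(exchangeable_indices(truth.sequence, start, end))
        if n_ex < 1:
            raise ValueError(f"peptide {pid} has no exchangeable amides")
        base = _peptide_base_mass(truth.sequence, start, end)
        full = n_ex * DEUTERIUM_INCREMENT

        def emit(state: str, exposure: float, value: float) -> None:
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "peptide": pid,
                        "start": start,
                        "end": end,
                        "sequence": seq,
                        "state": state,
                        "exposure": exposure,
                        "replicate": rep,
                        "centroid": value + noise,
                        "intensity": intensity,
                    }
                )

        emit("in_exchange_control", 0.0, base + full * in_exchange_floor)
        emit("out_exchange_control", 86400.0, base + full * retain)
        for state in ("apo", "complex"):
            for t in timecourse:
                f = truth.peptide_fraction(start, end, state, t)
                mex = base + full * (
                    in_exchange_floor + f * (retain - in_exchange_floor)
                )
                emit(state, t, mex)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structural fixtures

_CHAIN_SPACING = 3.8  # A, consecutive Calpha distance


def _ala_atoms(ca: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "N": ca + np.array([-1.2, 0.0, 0.4]),
        "CA": ca,
        "C": ca + np.array([1.2, 0.0, 0.4]),
        "O": ca + np.array([1.2, 0.0, 1.6]),
        "CB": ca + np.array([0.0, 0.0, -1.5]),
    }


def generate_toy_complex(
    seed: int = 0,
    chain_lengths: tuple[int, int] = (100, 80),
    planted_interface: tuple[tuple[int, int], tuple[int, int]] = ((20, 45), (17, 39)),
    planted_bridges: Sequence[
        tuple[tuple[str, int, str], tuple[str, int, str], float]
    ] = (
        (("A", 45, "GLU"), ("B", 27, "ARG"), 2.8),
        (("B", 35, "GLU"), ("A", 30, "ARG"), 2.8),
    ),
    n_models: int = 5,
    jitter_sd: float = 0.3,
    interface_gap: float = 6.0,
    far_offset: float = 50.0,
) -> list[StructureModel]:
    """Build a rigid two-chain toy complex ensemble with planted features.

    Interface residues of both chains face each other across a
    ``interface_gap`` slab (every planted residue pair sits well inside the
    inner contact cutoff); all other residues are displaced by
    ``far_offset`` so they score zero.  Planted salt bridges set the residue
    types and drop the charged side-chain atoms at the requested distance.
    The default bridge layout mimics the interface's reciprocal Glu/Arg
    pairing.  Each ensemble member applies a small rigid jitter to chain B.
    """
    (na, nb) = chain_lengths
    (a0, a1), (b0, b1) = planted_interface
    if not (1 <= a0 <= a1 <= na and 1 <= b0 <= b1 <= nb):
        raise ValueError("planted interface outside chain bounds")
    rng = np.random.default_rng(seed)

    span = _CHAIN_SPACING * (a1 - a0)

    def chain_coords(n: int, lo: int, hi: int, y_iface: float, y_far: float) -> np.ndarray:
        ca = np.empty((n, 3))
        width = max(hi - lo, 1)
        for i in range(1, n + 1):
            if lo <= i <= hi:
                x = span * (i - lo) / width
                y = y_iface
            else:
                x = _CHAIN_SPACING * (i - 1)
                y = y_far
            ca[i - 1] = (x, y, 0.0)
        return ca

    ca_a = chain_coords(na, a0, a1, 0.0, -far_offset)
    ca_b = chain_coords(nb, b0, b1, interface_gap, interface_gap + far_offset)

    names_a = {i: "ALA" for i in range(1, na + 1)}
    names_b = {i: "ALA" for i in range(1, nb + 1)}
    bridge_atoms: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for (acid, base, dist) in planted_bridges:
        for chain_id, idx, resname in (acid, base):
            n = na if chain_id == "A" else nb
            if not 1 <= idx <= n:
                raise ValueError(f"bridge residue {chain_id}{idx} outside chain")
            (names_a if chain_id == "A" else names_b)[idx] = resname
        ca_acid = (ca_a if acid[0] == "A" else ca_b)[acid[1] - 1]
        ca_base = (ca_a if base[0] == "A" else ca_b)[base[1] - 1]
        direction = ca_base - ca_acid
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("bridge partners coincide")
        u = direction / norm
        perp = np.array([0.0, 0.0, 1.0])
        o1 = ca_acid + u * max((norm - dist) / 2.0, 1.0)
        n1 = o1 + u * dist
        if acid[2] not in ("GLU", "ASP"):
            raise ValueError(f"{acid[2]} is not an acidic residue")
        if base[2] not in ("ARG", "LYS", "HIS"):
            raise ValueError(f"{base[2]} is not a basic residue")
        o_names = ("OE1", "OE2") if acid[2] == "GLU" else ("OD1", "OD2")
        n_names = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}[
            base[2]
        ]
        acid_atoms = {o_names[0]: o1, o_names[1]: o1 + perp * 1.0}
        base_atoms = {
            name: n1 + perp * (0.9 * k) for k, name in enumerate(n_names)
        }
        bridge_atoms.setdefault((acid[0], acid[1]), {}).update(acid_atoms)
        bridge_atoms.setdefault((base[0], base[1]), {}).update(base_atoms)

    def build_chain(chain_id: str, n: int, ca: np.ndarray, names: dict[int, str]) -> Chain:
        residues = []
        for i in range(1, n + 1):
            atoms = _ala_atoms(ca[i - 1])
            atoms.update(bridge_atoms.get((chain_id, i), {}))
            residues.append(Residue(index=i, name=names[i], atoms=atoms))
        return Chain(chain_id=chain_id, residues=residues)

    models = []
    for mi in range(1, n_models + 1):
        chain_a = build_chain("A", na, ca_a, names_a)
        chain_b = build_chain("B", nb, ca_b, names_b)
        if jitter_sd > 0:
            shift = rng.normal(0.0, jitter_sd, size=3)
            angle = rng.normal(0.0, jitter_sd / 60.0)
            c, s = math.cos(angle), math.sin(angle)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            centre = np.mean(
                [r.atoms["CA"] for r in chain_b.residues], axis=0
            )
            for res in chain_b.residues:
                for name in res.atoms:
                    res.atoms[name] = (
                        rot @ (res.atoms[name] - centre) + centre + shift
                    )
        models.append(
            StructureModel(model_id=str(mi), chains={"A": chain_a, "B": chain_b})
        )
    return models


def generate_toy_complex_pdb(**kwargs) -> str:
    """Toy complex ensemble rendered as multi-MODEL PDB text."""
    return write_pdb(generate_toy_complex(**kwargs))


def generate_reference_model(
    seed: int = 0,
    n_residues: int = 100,
    disulfide_pairs: Sequence[tuple[int, int]] = cd160.DISULFIDE_PAIRS,
    free_cysteines: Sequence[int] = cd160.FREE_CYSTEINES,
    model_id: str = "reference",
) -> StructureModel:
    """A fully exposed single-chain toy model with correct disulfides.

    Residues sit on a wide ring (all solvent-exposed, chain contiguous,
    no backbone hydrogen bonds); annotated cysteine pairs carry SG atoms at
    bonding distance and free cysteines carry an isolated SG.  The layout
    is a synthetic geometric fixture, not a protein fold.
    """
    rng = np.random.default_rng(seed)
    radius = n_residues * _CHAIN_SPACING / (2.0 * math.pi)
    cys = {i for pair in disulfide_pairs for i in pair} | set(free_cysteines)
    if cys and max(cys) > n_residues:
        raise ValueError("cysteine index outside chain")
    residues = []
    ca_pos: dict[int, np.ndarray] = {}
    for i in range(1, n_residues + 1):
        theta = 2.0 * math.pi * (i - 1) / n_residues
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        ca = radius * radial + rng.normal(0.0, 0.05, size=3)
        ca_pos[i] = ca
        atoms = {
            "N": ca - tangent * 1.2,
            "CA": ca,
            "C": ca + tangent * 1.2,
            "O": ca + tangent * 1.2 + radial * 1.23,
            "CB": ca + np.array([0.0, 0.0, 1.5]),
        }
        residues.append(
            Residue(index=i, name="CYS" if i in cys else "ALA", atoms=atoms)
        )
    res_map = {r.index: r for r in residues}
    for a, b in disulfide_pairs:
        mid = 0.5 * (ca_pos[a] + ca_pos[b])
        res_map[a].atoms["SG"] = mid + np.array([0.0, 0.0, 1.0])
        res_map[b].atoms["SG"] = mid + np.array([0.0, 0.0, -1.05])
    for i in free_cysteines:
        theta = 2.0 * math.pi * (i - 1) / n_residues
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        res_map[i].atoms["SG"] = ca_pos[i] + radial * 1.8
    return StructureModel(
        model_id=model_id, chains={"A": Chain(chain_id="A", residues=residues)}
    )


def _cage_chain(
    targets: Iterable[np.ndarray],
    start_index: int,
    radius: float = 4.0,
    n_points: int = 80,
    with_hbond_acceptor: Sequence[np.ndarray] = (),
) -> list[Residue]:
    """Occluding carbon shells around target points (synthetic burial).

    Optionally plants a carbonyl-like O/C acceptor pointing at each given
    amide-nitrogen position so the buried donor also reads as
    hydrogen-bonded.
    """
    unit = sphere_points(n_points)
    residues = []
    idx = start_index
    for centre in targets:
        atoms = {
            f"C{k + 1}": centre + radius * unit[k] for k in range(n_points)
        }
        residues.append(Residue(index=idx, name="CAG", atoms=atoms,
                                elements={f"C{k + 1}": "C" for k in range(n_points)}))
        idx += 1
    for n_xyz in with_hbond_acceptor:
        d = np.array([0.0, 0.0, 1.0])
        atoms = {"O": n_xyz + d * 3.0, "C": n_xyz + d * 4.23}
        residues.append(
            Residue(index=idx, name="CAG", atoms=atoms,
                    elements={"O": "O", "C": "C"})
        )
        idx += 1
    return residues


def _with_extra_chain(model: StructureModel, residues: list[Residue],
                      model_id: str) -> StructureModel:
    chains = {
        cid: Chain(chain_id=cid,
                   residues=[Residue(r.index, r.name, dict(r.atoms), dict(r.elements))
                             for r in ch.residues])
        for cid, ch in model.chains.items()
    }
    chains["X"] = Chain(chain_id="X", residues=residues)
    return StructureModel(model_id=model_id, chains=chains)


def generate_model_decoys(
    base: StructureModel,
    binding_regions: Sequence[tuple[int, int]],
    fast_residues: Sequence[int],
    disulfide_pairs: Sequence[tuple[int, int]] = cd160.DISULFIDE_PAIRS,
    modes: Sequence[str] = ("bury_binding_region", "break_disulfide",
                            "scramble_exposure"),
    n_decoys: int = 5,
    seed: int = 0,
    chain_id: str = "A",
) -> list[tuple[StructureModel, dict]]:
    """Decoy models, each degrading exactly one selection criterion.

    ``bury_binding_region`` cages one binding region behind an occluding
    shell; ``break_disulfide`` displaces one SG out of bonding range;
    ``scramble_exposure`` cages a subset of fast-exchanging residues and
    plants acceptors so they read as protected.  The manifest records the
    mode and the perturbed residues per decoy.
    """
    rng = np.random.default_rng(seed)
    chain = base.chain(chain_id)
    res_map = chain.residue_map()
    decoys: list[tuple[StructureModel, dict]] = []
    for k in range(n_decoys):
        mode = modes[k % len(modes)]
        model_id = f"decoy_{k + 1}_{mode}"
        if mode == "break_disulfide":
            pair = disulfide_pairs[rng.integers(len(disulfide_pairs))]
            moved = pair[rng.integers(2)]
            decoy = _with_extra_chain(base, [], model_id)
            decoy.chains.pop("X")
            sg = decoy.chain(chain_id).residue_map()[moved].atoms
            sg["SG"] = sg["SG"] + np.array([0.0, 0.0, 10.0])
            manifest = {"mode": mode, "residues": list(pair)}
        elif mode == "bury_binding_region":
            region = binding_regions[rng.integers(len(binding_regions))]
            targets = [
                res_map[i].atoms["CA"]
                for i in range(region[0], region[1] + 1)
                if i in res_map
            ]
            decoy = _with_extra_chain(
                base, _cage_chain(targets, start_index=1), model_id
            )
            manifest = {"mode": mode, "residues": list(range(region[0], region[1] + 1))}
        elif mode == "scramble_exposure":
            n_pick = max(1, len(fast_residues) // 3)
            picked = sorted(
                rng.choice(np.asarray(fast_residues), size=n_pick, replace=False)
            )
            targets = [res_map[i].atoms["CA"] for i in picked]
            acceptors = [res_map[i].atoms["N"] for i in picked if "N" in res_map[i].atoms]
            decoy = _with_extra_chain(
                base,
                _cage_chain(targets, start_index=1, with_hbond_acceptor=acceptors),
                model_id,
            )
            manifest = {"mode": mode, "residues": [int(i) for i in picked]}
        else:
            raise ValueError(f"unknown decoy mode {mode!r}")
        decoys.append((decoy, manifest))
    return decoys
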