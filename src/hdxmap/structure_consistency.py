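"""Score candidate structure models against HDX-derived evidence.

Model selection follows four experimental criteria: (1) fast-exchanging
residues must sit in solvent-exposed or hydrogen-bond-free parts of the
model, (2) the binding fragments must be exposed and mutually contiguous,
(3) disulfide bridges must be geometrically formed at the annotated
cysteine pairs (free cysteines unpaired), and (4) the overall fold must be
plausible.  Criterion (4) is approximated here by the Calpha-contiguity
requirement in (2) together with the disulfide geometry — automated fold
classification is out of scope.

Exposure uses relative Shrake–Rupley SASA with a 0.25 buried/exposed
threshold; hydrogen-bond protection of backbone amides uses a heavy-atom
geometric criterion (models carry no hydrogens).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    MAX_ASA,
    MAX_ASA_DEFAULT,
    VDW_DEFAULT,
    VDW_RADIUS,
)
from .structure import StructureModel, read_structure, shrake_rupley

__all__ = [
    "ExposureProfile",
    "DisulfideSpec",
    "ConsistencyScore",
    "read_structure",
    "solvent_exposure",
    "backbone_hbond_protection",
    "check_disulfides",
    "hdx_consistency_score",
    "rank_models",
    "EXPOSED_RSASA",
    "FAST_CLASSES",
]

EXPOSED_RSASA = 0.25          # relative-SASA buried/exposed convention
FAST_CLASSES = ("fast", "very_fast")
HBOND_NO_DISTANCE = 3.5       # A, amide N to carbonyl O
HBOND_MIN_ANGLE_DEG = 90.0    # N-O-C angle at the acceptor
SS_BOND_MAX = 2.5             # A, SG-SG distance for a formed bridge
SS_FREE_MIN = 3.0             # A, minimum SG-SG distance for a free cysteine
CONTIGUITY_CA_MAX = 12.0      # A, max consecutive Calpha spacing in a region


@dataclass(frozen=True)
class ExposureProfile:
    """Per-residue absolute (A^2) and relative solvent accessibility."""

    absolute: dict[int, float]
    relative: dict[int, float]

    def __post_init__(self) -> None:
        high = [i for i, v in self.relative.items() if v > 1.2]
        if high:
            warnings.warn(
                f"relative SASA above 1.2 at residues {high[:5]}"
                f"{'...' if len(high) > 5 else ''}",
                stacklevel=3,
            )


@dataclass(frozen=True)
class DisulfideSpec:
    pairs: tuple[tuple[int, int], ...]
    free_cysteines: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a, b in self.pairs:
            for idx in (a, b):
                if idx in seen:
                    raise ValueError(f"cysteine {idx} listed twice")
                seen.add(idx)
        for idx in self.free_cysteines:
            if idx in seen:
                raise ValueError(f"cysteine {idx} both paired and free")


@dataclass(frozen=True)
class ConsistencyScore:
    model_id: str
    exposure_agreement: float
    binding_fragment_exposure: float
    disulfide_pass: dict[str, bool]
    composite: float


def solvent_exposure(model: StructureModel, chain_id: str) -> ExposureProfile:
    """Relative per-residue SASA of one chain, occluded by the whole model."""
    chain = model.chain(chain_id)
    coords, radii, owner = [], [], []
    for cid, ch in model.chains.items():
        for res in ch.residues:
            for name, xyz in res.atoms.items():
                el = res.element_of(name)
                if el == "H":
                    continue
                coords.append(xyz)
                radii.append(VDW_RADIUS.get(el, VDW_DEFAULT))
                owner.append((cid, res.index))
    if not coords:
        raise ValueError("model has no heavy atoms")
    subset = np.array(
        [k for k, (cid, _) in enumerate(owner) if cid == chain_id], dtype=int
    )
    areas = shrake_rupley(np.asarray(coords), np.asarray(radii), subset=subset)
    absolute: dict[int, float] = {r.index: 0.0 for r in chain.residues}
    for area, (cid, idx) in zip(areas, owner):
        if cid == chain_id:
            absolute[idx] += float(area)
    names = {r.index: r.name for r in chain.residues}
    relative = {
        idx: absolute[idx] / MAX_ASA.get(names[idx], MAX_ASA_DEFAULT)
        for idx in absolute
    }
    return ExposureProfile(absolute=absolute, relative=relative)


def backbone_hbond_protection(
    model: StructureModel, chain_id: str
) -> dict[int, bool | None]:
    """Which backbone amide donors are engaged in a hydrogen bond.

    A residue's amide N is protected iff it lies within 3.5 A of a carbonyl
    O (of a non-adjacent residue) with an N-O-C angle of at least 90 deg.
    Prolines have no amide hydrogen and are never protected donors;
    residues lacking a backbone N are reported as None (unknown).
    """
    chain = model.chain(chain_id)
    acceptors = []  # (O xyz, C xyz, owner chain, owner index)
    for cid, ch in model.chains.items():
        for res in ch.residues:
            if "O" in res.atoms and "C" in res.atoms:
                acceptors.append((res.atoms["O"], res.atoms["C"], cid, res.index))

    out: dict[int, bool | None] = {}
    for res in chain.residues:
        if res.name == "PRO":
            out[res.index] = False
            continue
        n_xyz = res.atoms.get("N")
        if n_xyz is None:
            out[res.index] = None
            continue
        protected = False
        for o_xyz, c_xyz, cid, idx in acceptors:
            if cid == chain_id and abs(idx - res.index) <= 1:
                continue  # own and peptide-bond-adjacent carbonyls
            d = float(np.linalg.norm(n_xyz - o_xyz))
            if d > HBOND_NO_DISTANCE or d == 0.0:
                continue
            v_n = n_xyz - o_xyz
            v_c = c_xyz - o_xyz
            denom = np.linalg.norm(v_n) * np.linalg.norm(v_c)
            if denom == 0.0:
                continue
            cosang = float(np.dot(v_n, v_c) / denom)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= HBOND_MIN_ANGLE_DEG:
                protected = True
                break
        out[res.index] = protected
    return out


def check_disulfides(
    model: StructureModel, spec: DisulfideSpec, chain_id: str | None = None
) -> dict[str, bool]:
    """Per-pair and per-free-cysteine verdicts on disulfide geometry."""
    if chain_id is None:
        chain_id = next(iter(model.chains))
    chain = model.chain(chain_id)
    res_map = chain.residue_map()

    def sg_of(idx: int) -> np.ndarray | None:
        res = res_map.get(idx)
        if res is None:
            return None
        return res.atoms.get("SG")

    all_sg = {
        idx: sg for idx in res_map if (sg := sg_of(idx)) is not None
    }
    verdicts: dict[str, bool] = {}
    for a, b in spec.pairs:
        key = f"{a}-{b}"
        sga, sgb = sg_of(a), sg_of(b)
        if sga is None or sgb is None:
            verdicts[key] = False
            continue
        verdicts[key] = float(np.linalg.norm(sga - sgb)) <= SS_BOND_MAX
    for idx in spec.free_cysteines:
        key = f"free:{idx}"
        sg = sg_of(idx)
        if sg is None:
            verdicts[key] = False
            continue
        others = [v for i, v in all_sg.items() if i != idx]
        verdicts[key] = all(
            float(np.linalg.norm(sg - o)) >= SS_FREE_MIN for o in others
        )
    return verdicts


def _region_contiguous(chain_residues: Mapping[int, np.ndarray], region: tuple[int, int]) -> bool:
    """True if the region's present Calphas form one chain segment within
    the consecutive-spacing limit."""
    present = sorted(i for i in chain_residues if region[0] <= i <= region[1])
    if len(present) < 2:
        return bool(present)
    for a, b in zip(present, present[1:]):
        d = float(np.linalg.norm(chain_residues[a] - chain_residues[b]))
        if d > CONTIGUITY_CA_MAX * max(1, b - a):
            return False
    return True


def hdx_consistency_score(
    model: StructureModel,
    exchange_classes: Mapping[int, str],
    binding_regions: Sequence[tuple[int, int]],
    disulfides: DisulfideSpec | None = None,
    weights: Sequence[float] | None = None,
    chain_id: str | None = None,
) -> ConsistencyScore:
    """Composite HDX-consistency score of one model.

    ``exchange_classes`` maps residue indices to exchange-speed classes
    from the differential analysis.  Residues named in the profile or the
    binding regions must exist in the model; unmatched indices raise.
    The composite is a weighted mean (equal weights by default) of
    exposure agreement, binding-fragment exposure, and the fraction of
    disulfide verdicts passing (the last only when a spec is given).
    """
    if chain_id is None:
        chain_id = next(iter(model.chains))
    chain = model.chain(chain_id)
    res_map = chain.residue_map()

    unmatched = [i for i in exchange_classes if i not in res_map]
    unmatched += [
        i
        for s, e in binding_regions
        for i in range(s, e + 1)
        if i not in res_map
    ]
    if unmatched:
        raise ValueError(
            f"residues absent from model chain {chain_id}: {sorted(set(unmatched))}"
        )

    exposure = solvent_exposure(model, chain_id)
    protection = backbone_hbond_protection(model, chain_id)

    fast = [i for i, cls in exchange_classes.items() if cls in FAST_CLASSES]
    if fast:
        ok = sum(
            1
            for i in fast
            if exposure.relative[i] >= EXPOSED_RSASA or protection[i] is not True
        )
        exposure_agreement = ok / len(fast)
    else:
        exposure_agreement = 1.0

    ca = {
        r.index: r.atoms["CA"] for r in chain.residues if "CA" in r.atoms
    }
    n_binding = 0
    n_ok = 0
    for region in binding_regions:
        contiguous = _region_contiguous(ca, region)
        for i in range(region[0], region[1] + 1):
            n_binding += 1
            if contiguous and exposure.relative[i] >= EXPOSED_RSASA:
                n_ok += 1
    binding_fragment_exposure = n_ok / n_binding if n_binding else 1.0

    components = [exposure_agreement, binding_fragment_exposure]
    ss_verdicts: dict[str, bool] = {}
    if disulfides is not None:
        ss_verdicts = check_disulfides(model, disulfides, chain_id)
        components.append(sum(ss_verdicts.values()) / len(ss_verdicts))

    if weights is None:
        weights = [1.0] * len(components)
    if len(weights) != len(components):
        raise ValueError("one weight per satisfied criterion required")
    w = np.asarray(weights, dtype=float)
    composite = float(np.dot(w, components) / w.sum())

    return ConsistencyScore(
        model_id=model.model_id,
        exposure_agreement=exposure_agreement,
        binding_fragment_exposure=binding_fragment_exposure,
        disulfide_pass=ss_verdicts,
        composite=composite,
    )


def rank_models(
    models: Sequence[StructureModel],
    exchange_classes: Mapping[int, str],
    binding_regions: Sequence[tuple[int, int]],
    disulfides: DisulfideSpec | None = None,
    weights: Sequence[float] | None = None,
    chain_id: str | None = None,
) -> list[ConsistencyScore]:
    """Score and order models, best first.

    Ties break by exposure agreement, then model id (ascending) so the
    ordering is deterministic and independent of input order.
    """
    if not models:
        raise ValueError("rank_models requires at least one model")
    scores = [
        hdx_consistency_score(
            m, exchange_classes, binding_regions, disulfides, weights, chain_id
        )
        for m in models
    ]
    return sorted(
        scores,
        key=lambda s: (-s.composite, -s.exposure_agreement, s.model_id),
    )
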