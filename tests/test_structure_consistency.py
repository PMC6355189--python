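"""PDB handling, SASA, hydrogen-bond protection and model scoring."""

import numpy as np
import pytest

from hdxmap.structure import (
    Chain,
    Residue,
    StructureModel,
    kabsch,
    read_structure,
    shrake_rupley,
    write_pdb,
)
from hdxmap.structure_consistency import (
    DisulfideSpec,
    backbone_hbond_protection,
    check_disulfides,
    hdx_consistency_score,
    rank_models,
    solvent_exposure,
)
from hdxmap.synthetic_data import (
    generate_model_decoys,
    generate_reference_model,
)

ALANINE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.987  -0.773  -1.199  1.00  0.00           C
END
"""


def _residue(index, name, atoms):
    return Residue(index=index, name=name,
                   atoms={k: np.asarray(v, dtype=float) for k, v in atoms.items()})


def _model(residues, chain_id="A", model_id="m"):
    return StructureModel(
        model_id=model_id,
        chains={chain_id: Chain(chain_id=chain_id, residues=residues)},
    )


class TestPDBIO:
    def test_single_alanine(self):
        (model,) = read_structure(ALANINE_PDB)
        assert list(model.chains) == ["A"]
        (res,) = model.chains["A"].residues
        assert res.name == "ALA" and len(res.atoms) == 5

    def test_multi_model_file(self):
        base = generate_reference_model(seed=0, n_residues=10,
                                        disulfide_pairs=(), free_cysteines=())
        text = write_pdb([base, base])
        models = read_structure(text)
        assert len(models) == 2

    def test_round_trip_preserves_coordinates(self):
        base = generate_reference_model(seed=1, n_residues=20,
                                        disulfide_pairs=((3, 12),),
                                        free_cysteines=(15,))
        (back,) = read_structure(write_pdb([base]))
        for res, bres in zip(base.chains["A"].residues,
                             back.chains["A"].residues):
            for name in res.atoms:
                assert np.allclose(res.atoms[name], bres.atoms[name], atol=1e-3)

    def test_insertion_code_rejected(self):
        text = ALANINE_PDB.replace("ALA A   1 ", "ALA A   1A")
        with pytest.raises(ValueError, match="insertion code"):
            read_structure(text)


class TestSASA:
    def test_isolated_sphere_matches_analytic_area(self):
        for r in (1.52, 1.70, 1.80):
            area = shrake_rupley(np.zeros((1, 3)), np.array([r]))[0]
            assert area == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.01)

    def test_rotation_invariance_within_quadrature_error(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 3, (30, 3))
        radii = np.full(30, 1.7)
        base = shrake_rupley(coords, radii).sum()
        theta = 0.8
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = shrake_rupley(coords @ rot.T, radii).sum()
        assert rotated == pytest.approx(base, rel=5e-3)

    def test_residue_areas_partition_chain_area(self):
        model = generate_reference_model(seed=2, n_residues=15,
                                         disulfide_pairs=(), free_cysteines=())
        profile = solvent_exposure(model, "A")
        coords, radii = model.all_atoms()
        total = shrake_rupley(coords, radii).sum()
        assert sum(profile.absolute.values()) == pytest.approx(total, abs=1e-6)

    def test_fully_caged_residue_is_buried(self):
        from hdxmap.synthetic_data import _cage_chain

        target = _residue(1, "ALA", {"CA": (0, 0, 0), "N": (-1.2, 0, 0.4),
                                     "C": (1.2, 0, 0.4), "O": (1.2, 0, 1.6)})
        cage = _cage_chain([np.zeros(3)], start_index=1)
        model = StructureModel(
            model_id="caged",
            chains={
                "A": Chain(chain_id="A", residues=[target]),
                "X": Chain(chain_id="X", residues=cage),
            },
        )
        profile = solvent_exposure(model, "A")
        assert profile.relative[1] < 0.05

    def test_biotite_oracle_on_toy_cluster(self):
        """Independent SASA oracle: biotite's Shrake-Rupley on carbons."""
        biotite_structure = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(11)
        coords = rng.normal(0, 3, (25, 3))
        ours = shrake_rupley(coords, np.full(25, 1.7), n_points=960)
        arr = biotite_structure.AtomArray(25)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 25)
        arr.atom_name = np.array(["CA"] * 25)
        arr.res_name = np.array(["ALA"] * 25)
        arr.res_id = np.arange(1, 26)
        arr.chain_id = np.array(["A"] * 25)
        theirs = biotite_structure.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii=np.full(25, 1.7),
        )
        assert np.allclose(ours, theirs, rtol=0.05, atol=1.0)


class TestHbondProtection:
    def test_constructed_donor_acceptor_pair(self):
        donor = _residue(1, "ALA", {"N": (0, 0, 0), "CA": (1.4, 0, 0),
                                    "C": (2.1, 1.2, 0), "O": (1.6, 2.3, 0)})
        acceptor = _residue(5, "ALA", {"N": (10, 10, 10), "CA": (11, 10, 10),
                                       "C": (0, -4.23, 0), "O": (0, -3.0, 0)})
        model = _model([donor, acceptor])
        assert backbone_hbond_protection(model, "A")[1] is True

    def test_far_acceptor_not_protecting(self):
        donor = _residue(1, "ALA", {"N": (0, 0, 0), "CA": (1.4, 0, 0),
                                    "C": (2.1, 1.2, 0), "O": (1.6, 2.3, 0)})
        acceptor = _residue(5, "ALA", {"N": (10, 10, 10), "CA": (11, 10, 10),
                                       "C": (0, -9.23, 0), "O": (0, -8.0, 0)})
        assert backbone_hbond_protection(_model([donor, acceptor]), "A")[1] is False

    def test_adjacent_carbonyl_excluded(self):
        donor = _residue(2, "ALA", {"N": (0, 0, 0), "CA": (1.4, 0, 0),
                                    "C": (2.1, 1.2, 0), "O": (1.6, 2.3, 0)})
        # ideal acceptor geometry (colinear, 2.5 A) that only adjacency excludes
        prev = _residue(1, "ALA", {"N": (-3, 0, 0), "CA": (-2, 0, 0),
                                   "C": (0, -3.73, 0), "O": (0, -2.5, 0)})
        assert backbone_hbond_protection(_model([prev, donor]), "A")[2] is False

    def test_proline_never_a_protected_donor(self):
        pro = _residue(1, "PRO", {"N": (0, 0, 0), "CA": (1.4, 0, 0),
                                  "C": (2.1, 1.2, 0), "O": (1.6, 2.3, 0)})
        acceptor = _residue(5, "ALA", {"C": (0, -4.23, 0), "O": (0, -3.0, 0)})
        assert backbone_hbond_protection(_model([pro, acceptor]), "A")[1] is False

    def test_sheet_like_ladder(self):
        """Alternating donors facing a carbonyl rail are protected exactly
        as constructed."""
        residues = []
        for i in range(1, 7):
            x = 3.4 * i
            residues.append(
                _residue(i, "ALA", {"N": (x, 0, 0), "CA": (x + 1.2, 0.6, 0),
                                    "C": (x + 2.0, 1.4, 0), "O": (x + 2.0, 2.6, 0)})
            )
        rail = []
        for k, i in enumerate((1, 3, 5)):
            x = 3.4 * i
            rail.append(
                _residue(100 + k, "ALA",
                         {"C": (x, -4.13, 0), "O": (x, -2.9, 0),
                          "CA": (x - 1.0, -5.0, 0), "N": (x - 2.0, -5.0, 0)})
            )
        model = StructureModel(
            model_id="sheet",
            chains={
                "A": Chain(chain_id="A", residues=residues),
                "B": Chain(chain_id="B", residues=rail),
            },
        )
        protection = backbone_hbond_protection(model, "A")
        assert [protection[i] for i in range(1, 7)] == [
            True, False, True, False, True, False,
        ]

    def test_missing_backbone_reported_unknown(self):
        res = _residue(1, "ALA", {"CA": (0, 0, 0)})
        assert backbone_hbond_protection(_model([res]), "A")[1] is None


class TestDisulfides:
    def _cys_pair(self, distance):
        a = _residue(3, "CYS", {"CA": (0, 0, 0), "SG": (0, 0, 0)})
        b = _residue(12, "CYS", {"CA": (5, 0, 0), "SG": (distance, 0, 0)})
        return _model([a, b])

    def test_bonded_pair_passes(self):
        verdicts = check_disulfides(
            self._cys_pair(2.05), DisulfideSpec(pairs=((3, 12),))
        )
        assert verdicts == {"3-12": True}

    def test_distant_pair_fails(self):
        verdicts = check_disulfides(
            self._cys_pair(6.0), DisulfideSpec(pairs=((3, 12),))
        )
        assert verdicts == {"3-12": False}

    def test_cd160_topology_three_verdicts(self):
        model = generate_reference_model(seed=3)
        spec = DisulfideSpec(pairs=((18, 86), (35, 42)), free_cysteines=(87,))
        verdicts = check_disulfides(model, spec)
        assert verdicts == {"18-86": True, "35-42": True, "free:87": True}

    def test_missing_cysteine_fails_with_reason(self):
        model = self._cys_pair(2.05)
        verdicts = check_disulfides(model, DisulfideSpec(pairs=((3, 99),)))
        assert verdicts == {"3-99": False}

    def test_duplicate_cysteine_rejected(self):
        with pytest.raises(ValueError):
            DisulfideSpec(pairs=((3, 12), (12, 20)))


@pytest.fixture(scope="module")
def scenario():
    base = generate_reference_model(seed=4)
    regions = [(18, 28), (60, 70)]
    fast = [
        i for i in range(1, 101)
        if not any(s <= i <= e for s, e in regions)
    ][:30]
    classes = {i: "very_fast" for i in fast}
    spec = DisulfideSpec(pairs=((18, 86), (35, 42)), free_cysteines=(87,))
    return base, regions, fast, classes, spec


class TestConsistencyScoring:
    def test_reference_model_scores_perfectly(self, scenario):
        base, regions, _, classes, spec = scenario
        score = hdx_consistency_score(base, classes, regions, spec)
        assert score.exposure_agreement == 1.0
        assert score.binding_fragment_exposure == 1.0
        assert score.composite == 1.0

    def test_buried_binding_region_drops_one_third(self, scenario):
        base, regions, fast, classes, spec = scenario
        decoys = generate_model_decoys(
            base, regions, fast, modes=("bury_binding_region",),
            n_decoys=1, seed=0,
        )
        decoy, manifest = decoys[0]
        score = hdx_consistency_score(decoy, classes, regions, spec)
        assert manifest["mode"] == "bury_binding_region"
        assert score.binding_fragment_exposure <= 0.5
        assert score.exposure_agreement == 1.0
        assert score.composite <= 1.0 - (1 - score.binding_fragment_exposure) / 3 + 1e-9

    def test_composite_monotone_in_disulfide_failure(self, scenario):
        base, regions, fast, classes, spec = scenario
        good = hdx_consistency_score(base, classes, regions, spec)
        decoy, _ = generate_model_decoys(
            base, regions, fast, modes=("break_disulfide",), n_decoys=1, seed=1
        )[0]
        bad = hdx_consistency_score(decoy, classes, regions, spec)
        assert sum(bad.disulfide_pass.values()) < sum(good.disulfide_pass.values())
        assert bad.composite < good.composite

    def test_numbering_mismatch_raises(self, scenario):
        base, regions, _, classes, spec = scenario
        classes = dict(classes)
        classes[999] = "fast"
        with pytest.raises(ValueError, match="999"):
            hdx_consistency_score(base, classes, regions, spec)

    def test_ranking_prefers_planted_model(self, scenario):
        base, regions, fast, classes, spec = scenario
        decoys = generate_model_decoys(base, regions, fast, n_decoys=3, seed=5)
        models = [d for d, _ in decoys] + [base]
        ranked = rank_models(models, classes, regions, spec)
        assert ranked[0].model_id == "reference"

    def test_ranking_order_independent(self, scenario):
        base, regions, fast, classes, spec = scenario
        decoys = [d for d, _ in generate_model_decoys(
            base, regions, fast, n_decoys=2, seed=6
        )]
        a = rank_models([base] + decoys, classes, regions, spec)
        b = rank_models(decoys[::-1] + [base], classes, regions, spec)
        assert [s.model_id for s in a] == [s.model_id for s in b]

    def test_single_model_ranks_itself(self, scenario):
        base, regions, _, classes, spec = scenario
        ranked = rank_models([base], classes, regions, spec)
        assert [s.model_id for s in ranked] == ["reference"]


def test_kabsch_reflection_guard():
    """Mirror-image coordinates must not superpose via an improper rotation."""
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    Q = P.copy()
    Q[:, 2] *= -1
    R, _, rmsd = kabsch(P, Q)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1
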