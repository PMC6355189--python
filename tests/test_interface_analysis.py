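"""Contact maps, salt bridges, hydrophobic contacts, RMSD and RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxmap.interface_analysis import (
    ContactConfig,
    contact_map,
    contact_score,
    hydrophobic_contacts,
    interface_residues,
    rmsf,
    salt_bridges,
    superpose_rmsd,
)
from hdxmap.structure import Chain, Residue, StructureModel
from hdxmap.synthetic_data import generate_toy_complex


def _residue(index, name, atoms):
    return Residue(index=index, name=name,
                   atoms={k: np.asarray(v, dtype=float) for k, v in atoms.items()})


def _two_chain(res_a, res_b, model_id="m"):
    return StructureModel(
        model_id=model_id,
        chains={
            "A": Chain(chain_id="A", residues=res_a),
            "B": Chain(chain_id="B", residues=res_b),
        },
    )


def _gly(index, xyz):
    return _residue(index, "GLY", {"N": np.add(xyz, (-1.2, 0, 0)),
                                   "CA": xyz, "C": np.add(xyz, (1.2, 0, 0)),
                                   "O": np.add(xyz, (1.2, 0, 1.2))})


class TestContactScore:
    @pytest.mark.parametrize("d, expected", [(5.0, 1.0), (8.0, 1.0),
                                             (9.0, 0.5), (10.0, 0.0),
                                             (12.0, 0.0)])
    def test_ramp_values(self, d, expected):
        assert contact_score(d) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None)
    @given(d=st.floats(0, 30), eps=st.floats(1e-6, 1.0))
    def test_monotone_nonincreasing(self, d, eps):
        assert contact_score(d + eps) <= contact_score(d) + 1e-12

    def test_step_mode(self):
        cfg = ContactConfig(ramp=False)
        assert contact_score(9.0, cfg) == 1.0
        assert contact_score(10.5, cfg) == 0.0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ContactConfig(cutoff1=10.0, cutoff2=8.0)


class TestContactMap:
    def test_single_pair_in_contact(self):
        m = _two_chain([_gly(1, (0, 0, 0))], [_gly(1, (5, 0, 0))])
        cmap = contact_map([m], "A", "B")
        assert cmap.scores[0, 0] == 1.0

    def test_ensemble_averages_scores(self):
        near = _two_chain([_gly(1, (0, 0, 0))], [_gly(1, (5, 0, 0))], "1")
        far = _two_chain([_gly(1, (0, 0, 0))], [_gly(1, (12, 0, 0))], "2")
        cmap = contact_map([near, far], "A", "B")
        assert cmap.scores[0, 0] == pytest.approx(0.5)

    def test_linearity_over_ensemble(self):
        models = generate_toy_complex(seed=4, n_models=4)
        full = contact_map(models, "A", "B")
        singles = [contact_map([m], "A", "B") for m in models]
        mean = np.mean([s.scores for s in singles], axis=0)
        assert np.allclose(full.scores, mean, atol=1e-12)

    def test_brute_force_oracle_small_toy(self):
        """All-pairs recomputation (independent code) matches the map."""
        rng = np.random.default_rng(9)
        res_a = [_gly(i, rng.uniform(0, 15, 3)) for i in range(1, 6)]
        res_b = [_gly(j, rng.uniform(0, 15, 3)) for j in range(1, 11)]
        m = _two_chain(res_a, res_b)
        cmap = contact_map([m], "A", "B")
        for i, ra in enumerate(res_a):
            for j, rb in enumerate(res_b):
                d = np.linalg.norm(ra.atoms["CA"] - rb.atoms["CA"])
                if d <= 8:
                    expected = 1.0
                elif d >= 10:
                    expected = 0.0
                else:
                    expected = (10 - d) / 2
                assert cmap.scores[i, j] == pytest.approx(expected, abs=1e-9)

    def test_inconsistent_numbering_rejected(self):
        a = _two_chain([_gly(1, (0, 0, 0))], [_gly(1, (5, 0, 0))], "1")
        b = _two_chain([_gly(2, (0, 0, 0))], [_gly(1, (5, 0, 0))], "2")
        with pytest.raises(ValueError, match="numbering"):
            contact_map([a, b], "A", "B")


class TestInterfaceResidues:
    def test_single_strong_pair(self):
        m = _two_chain(
            [_gly(1, (0, 0, 0)), _gly(2, (0, 50, 0))],
            [_gly(7, (5, 0, 0)), _gly(8, (5, 50, 50))],
        )
        iface = interface_residues(contact_map([m], "A", "B"))
        assert iface["A"]["residues"] == [1]
        assert iface["B"]["residues"] == [7]

    def test_planted_interface_recovered(self):
        models = generate_toy_complex(seed=2)
        iface = interface_residues(contact_map(models, "A", "B"))
        assert iface["A"]["intervals"] == [(20, 45)]
        assert iface["B"]["intervals"] == [(17, 39)]


class TestSaltBridges:
    def _glu(self, index, o_xyz):
        return _residue(index, "GLU",
                        {"CA": np.add(o_xyz, (0, -3, 0)),
                         "OE1": o_xyz, "OE2": np.add(o_xyz, (1, 0, 0))})

    def _arg(self, index, n_xyz):
        return _residue(index, "ARG",
                        {"CA": np.add(n_xyz, (0, 3, 0)),
                         "NH1": n_xyz, "NH2": np.add(n_xyz, (1, 0, 0)),
                         "NE": np.add(n_xyz, (0, 1, 0))})

    def test_close_pair_detected(self):
        m = _two_chain([self._glu(45, (0, 0, 0))], [self._arg(27, (2.8, 0, 0))])
        (bridge,) = salt_bridges(m)
        assert bridge.acidic == ("A", 45, "GLU")
        assert bridge.basic == ("B", 27, "ARG")
        assert bridge.min_distance == pytest.approx(1.8)  # OE2-NH1

    def test_distant_pair_ignored(self):
        m = _two_chain([self._glu(45, (0, 0, 0))], [self._arg(27, (7.0, 0, 0))])
        assert salt_bridges(m) == []

    def test_planted_bridges_full_occupancy(self):
        models = generate_toy_complex(seed=0, jitter_sd=0.0)
        bridges = salt_bridges(models)
        pairs = {(b.acidic, b.basic) for b in bridges}
        assert pairs == {
            (("A", 45, "GLU"), ("B", 27, "ARG")),
            (("B", 35, "GLU"), ("A", 30, "ARG")),
        }
        assert all(b.occupancy == 1.0 for b in bridges)

    def test_brute_force_oracle(self):
        """Exhaustive charged-atom scan reproduces the detected bridges."""
        models = generate_toy_complex(seed=5, n_models=3)
        found = {
            (b.acidic, b.basic): b.min_distance for b in salt_bridges(models)
        }
        acid_names = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
        base_names = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
        expected = {}
        for model in models:
            for ca_id, ca in model.chains.items():
                for cb_id, cb in model.chains.items():
                    if ca_id == cb_id:
                        continue
                    for ra in ca.residues:
                        if ra.name not in acid_names:
                            continue
                        for rb in cb.residues:
                            if rb.name not in base_names:
                                continue
                            d = min(
                                np.linalg.norm(ra.atoms[x] - rb.atoms[y])
                                for x in acid_names[ra.name]
                                for y in base_names[rb.name]
                            )
                            key = ((ca_id, ra.index, ra.name),
                                   (cb_id, rb.index, rb.name))
                            expected[key] = min(expected.get(key, np.inf), d)
        expected = {k: v for k, v in expected.items() if v <= 4.0}
        assert set(found) == set(expected)
        for key in found:
            assert found[key] == pytest.approx(expected[key], abs=1e-9)

    def test_histidine_optional(self):
        his = _residue(3, "HIS", {"CA": (0, 3, 0), "ND1": (2.8, 0, 0),
                                  "NE2": (3.5, 0, 0)})
        m = _two_chain([self._glu(45, (0, 0, 0))], [his])
        assert salt_bridges(m) == []
        (bridge,) = salt_bridges(m, include_histidine=True)
        assert bridge.basic == ("B", 3, "HIS")


class TestSuperposition:
    def test_identical_models_zero_rmsd(self):
        models = generate_toy_complex(seed=1, n_models=1)
        assert superpose_rmsd(models[0], models[0]) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        (model,) = generate_toy_complex(seed=1, n_models=1)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([5.0, -3.0, 2.0])
        moved = StructureModel(
            model_id="moved",
            chains={
                cid: Chain(
                    chain_id=cid,
                    residues=[
                        Residue(r.index, r.name,
                                {k: rot @ v + shift for k, v in r.atoms.items()})
                        for r in ch.residues
                    ],
                )
                for cid, ch in model.chains.items()
            },
        )
        assert superpose_rmsd(moved, model) == pytest.approx(0.0, abs=1e-6)

    def test_two_point_analytic_residual(self):
        """Segments of length 2 and 4: optimal fit leaves residual 1 per atom."""
        a = [_gly(1, (0, 0, 0)), _gly(2, (2, 0, 0))]
        b = [_gly(1, (0, 0, 0)), _gly(2, (4, 0, 0))]
        m1 = StructureModel("a", {"A": Chain("A", a)})
        m2 = StructureModel("b", {"A": Chain("A", b)})
        assert superpose_rmsd(m1, m2) == pytest.approx(1.0, abs=1e-9)

    def test_atom_mismatch_rejected(self):
        m1 = StructureModel("a", {"A": Chain("A", [_gly(1, (0, 0, 0))])})
        m2 = StructureModel(
            "b", {"A": Chain("A", [_residue(1, "GLY", {"N": (0, 0, 0)})])}
        )
        with pytest.raises(ValueError):
            superpose_rmsd(m2, m1)


class TestRMSF:
    def _rigid_frames(self, n_frames, perturb=None):
        frames = []
        for f in range(n_frames):
            residues = []
            for i in range(1, 41):
                # non-collinear rigid scaffold so superposition is well posed
                xyz = np.array([3.8 * i, 6.0 * np.sin(0.7 * i),
                                4.0 * np.cos(0.5 * i)])
                if perturb is not None:
                    xyz = xyz + perturb(f, i)
                residues.append(_gly(i, xyz))
            frames.append(StructureModel(str(f), {"A": Chain("A", residues)}))
        return frames

    def test_identical_frames_zero(self):
        prof = rmsf(self._rigid_frames(3))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in prof.rmsf.values())

    def test_translation_removed_by_superposition(self):
        prof = rmsf(
            self._rigid_frames(
                3, perturb=lambda f, i: np.array([0.0, 10.0 * f, 0.0])
            )
        )
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in prof.rmsf.values())

    def test_oscillating_residue(self):
        """One residue moving +/-1 A in an otherwise rigid body has RMSF
        close to 1 (slightly less: the moving Calpha drags the fit)."""
        prof = rmsf(
            self._rigid_frames(
                2,
                perturb=lambda f, i: np.array(
                    [0.0, (1.0 if f == 0 else -1.0) if i == 20 else 0.0, 0.0]
                ),
            )
        )
        assert prof.rmsf[20] == pytest.approx(1.0, abs=0.05)
        assert prof.rmsf[5] < 0.1

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(self._rigid_frames(1))


def test_hydrophobic_contacts_cross_chain():
    leu_a = _residue(4, "LEU", {"CA": (0, 0, 0), "CB": (0, 1, 0),
                                "CD1": (0, 2, 0)})
    leu_b = _residue(9, "LEU", {"CA": (4, 0, 0), "CB": (4, 1, 0),
                                "CD1": (4, 2, 0)})
    ser_b = _residue(10, "SER", {"CA": (4, 5, 0), "OG": (4, 6, 0)})
    m = _two_chain([leu_a], [leu_b, ser_b])
    contacts = hydrophobic_contacts(m, "A", "B")
    assert [(a, b) for a, b, _, _ in contacts] == [((4, "LEU"), (9, "LEU"))]
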