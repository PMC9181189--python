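"""Conformers, Gaussian overlap volumes, and alignment TanimotoCombo scores."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdMolTransforms
from scipy.spatial.transform import Rotation

from percepsim.chem_io import standardize_molecule
from percepsim.exceptions import ConformerGenerationError, PercepsimError
from percepsim.shape3d import (
    AlignmentResult,
    ConformerSet,
    GaussianShape,
    align_and_score,
    gaussian_overlap_volume,
    generate_conformers,
)


def grid_overlap(a: GaussianShape, b: GaussianShape, h: float = 0.1) -> float:
    """Independent quadrature oracle: integrate the density product on a grid."""
    allc = np.vstack([a.centers, b.centers])
    lo, hi = allc.min(axis=0) - 4.0, allc.max(axis=0) + 4.0
    axes = [np.arange(l, u, h) for l, u in zip(lo, hi)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def density(shape):
        d = np.zeros(len(pts))
        for c, alpha in zip(shape.centers, shape.alphas):
            d += shape.prefactor * np.exp(-alpha * np.sum((pts - c) ** 2, axis=1))
        return d

    return float(np.sum(density(a) * density(b)) * h**3)


def rigidly_moved(conf_set: ConformerSet, seed: int) -> ConformerSet:
    """Copy of a conformer set with a random rigid motion applied to all atoms."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    shift = rng.uniform(-5, 5, 3)
    mol = Chem.Mol(conf_set.mol)
    for conf in mol.GetConformers():
        pos = np.asarray(conf.GetPositions()) @ rot.T + shift
        for i, xyz in enumerate(pos):
            conf.SetAtomPosition(i, xyz.tolist())
    return ConformerSet(conf_set.mol_id, mol, conf_set.generator_seed)


def truncated(conf_set: ConformerSet, k: int) -> ConformerSet:
    mol = Chem.Mol(conf_set.mol)
    for conf in list(mol.GetConformers())[k:]:
        mol.RemoveConformer(conf.GetId())
    return ConformerSet(conf_set.mol_id, mol, conf_set.generator_seed)


class TestConformers:
    def test_methane_single_conformer(self):
        cs = generate_conformers(standardize_molecule("C"), max_confs=10, seed=1)
        assert cs.n_conformers == 1

    def test_butane_torsional_minima_survive_pruning(self):
        # torsion-enumeration oracle: ideal-geometry anti vs gauche heavy-atom
        # RMSD is ~0.71 A (>0.5), gauche+ vs gauche- ~0.46 (<0.5), so the
        # pruned ensemble must keep 2 rotamers (anti + one gauche)
        cs = generate_conformers(
            standardize_molecule("CCCC"), max_confs=200, seed=5
        )
        assert 2 <= cs.n_conformers <= 200
        torsions = {
            round(abs(rdMolTransforms.GetDihedralDeg(c, 0, 1, 2, 3)), -1)
            for c in cs.mol.GetConformers()
        }
        assert len(torsions) >= 2  # distinct rotamers, not near-duplicates

    def test_deterministic_under_fixed_seed(self):
        hexane = standardize_molecule("CCCCCC")
        c1 = generate_conformers(hexane, max_confs=200, seed=9)
        c2 = generate_conformers(hexane, max_confs=200, seed=9)
        assert c1.n_conformers == c2.n_conformers
        np.testing.assert_allclose(c1.coordinates(0), c2.coordinates(0))

    def test_embedding_failure_names_molecule(self):
        bad = standardize_molecule("C", "tiny")
        object.__setattr__(bad, "structure", Chem.MolFromSmiles(""))
        with pytest.raises(ConformerGenerationError, match="tiny"):
            generate_conformers(bad)


class TestGaussianOverlap:
    toy_a = GaussianShape(
        centers=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        radii=np.array([1.7, 1.55]),
    )
    toy_b = GaussianShape(
        centers=np.array([[0.5, 0.8, 0.0], [2.0, 0.5, 0.3], [1.0, -1.0, 0.5]]),
        radii=np.array([1.7, 1.52, 1.8]),
    )

    def test_self_overlap_of_single_atom(self):
        atom = GaussianShape(np.zeros((1, 3)), np.array([1.7]))
        analytic = gaussian_overlap_volume(atom, atom)
        assert analytic == pytest.approx(grid_overlap(atom, atom), rel=0.01)

    def test_distant_atoms_negligible_overlap(self):
        atom = GaussianShape(np.zeros((1, 3)), np.array([1.7]))
        far = GaussianShape(np.array([[100.0, 0.0, 0.0]]), np.array([1.7]))
        assert gaussian_overlap_volume(atom, far) < 1e-6 * atom.self_overlap()

    def test_toy_shapes_match_grid_quadrature(self):
        analytic = gaussian_overlap_volume(self.toy_a, self.toy_b)
        assert analytic == pytest.approx(
            grid_overlap(self.toy_a, self.toy_b), rel=0.01
        )

    def test_symmetric(self):
        assert gaussian_overlap_volume(self.toy_a, self.toy_b) == pytest.approx(
            gaussian_overlap_volume(self.toy_b, self.toy_a)
        )

    def test_invariant_under_common_rigid_motion(self):
        rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.0]).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        moved_a = GaussianShape(self.toy_a.centers @ rot.T + shift, self.toy_a.radii)
        moved_b = GaussianShape(self.toy_b.centers @ rot.T + shift, self.toy_b.radii)
        assert gaussian_overlap_volume(moved_a, moved_b) == pytest.approx(
            gaussian_overlap_volume(self.toy_a, self.toy_b), rel=1e-9
        )


class TestAlignAndScore:
    def test_identity_alignment_reaches_two(self, aspirin):
        confs = generate_conformers(aspirin, max_confs=1, seed=7)
        res = align_and_score(confs, confs)
        assert res.shape_tanimoto == pytest.approx(1.0, abs=1e-3)
        assert res.color_tanimoto == pytest.approx(1.0, abs=1e-3)
        assert res.tanimoto_combo == pytest.approx(2.0, abs=1e-3)

    def test_benzene_vs_methane_below_one(self):
        benzene = generate_conformers(standardize_molecule("c1ccccc1"), 1, seed=3)
        methane = generate_conformers(standardize_molecule("C"), 1, seed=3)
        res = align_and_score(benzene, methane)
        assert res.tanimoto_combo < 1.0

    def test_invariant_to_rigid_pretransform(self, aspirin, naphthalene):
        for rec, seed in ((aspirin, 11), (naphthalene, 12)):
            ca = generate_conformers(rec, max_confs=1, seed=5)
            cb = generate_conformers(rec, max_confs=1, seed=6)
            base = align_and_score(ca, cb).tanimoto_combo
            moved = align_and_score(ca, rigidly_moved(cb, seed)).tanimoto_combo
            assert moved == pytest.approx(base, abs=1e-3)

    def test_score_bounds_and_sum_invariant(self, aspirin, naphthalene):
        res = align_and_score(
            generate_conformers(aspirin, 1, seed=2),
            generate_conformers(naphthalene, 1, seed=2),
        )
        assert 0.0 <= res.shape_tanimoto <= 1.0
        assert 0.0 <= res.color_tanimoto <= 1.0
        assert res.tanimoto_combo == pytest.approx(
            res.shape_tanimoto + res.color_tanimoto
        )
        assert res.tanimoto_combo <= 2.0

    def test_adding_conformers_never_decreases_best_score(self):
        flexible = standardize_molecule("CCOC(=O)Cc1ccccc1")
        ca = generate_conformers(flexible, max_confs=4, seed=13)
        cb = generate_conformers(flexible, max_confs=1, seed=99)
        few = align_and_score(truncated(ca, 1), cb).tanimoto_combo
        more = align_and_score(ca, cb).tanimoto_combo
        assert more >= few - 1e-9

    def test_color_missing_flagged_as_zero(self):
        alkane = generate_conformers(standardize_molecule("CCCC"), 1, seed=4)
        res = align_and_score(alkane, alkane)
        # butane has a hydrophobe feature; use a molecule with none instead
        noble_like = generate_conformers(standardize_molecule("C"), 1, seed=4)
        res = align_and_score(noble_like, noble_like)
        if res.color_missing:
            assert res.color_tanimoto == 0.0

    def test_empty_conformer_set_rejected(self, aspirin):
        confs = generate_conformers(aspirin, max_confs=1, seed=1)
        with pytest.raises(PercepsimError):
            align_and_score(truncated(confs, 0), confs)

    def test_inconsistent_result_rejected(self):
        with pytest.raises(PercepsimError):
            AlignmentResult(
                rotation=np.eye(3),
                translation=np.zeros(3),
                shape_tanimoto=0.5,
                color_tanimoto=0.5,
                tanimoto_combo=1.5,  # != shape + color
                conformer_a=0,
                conformer_b=0,
            )
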