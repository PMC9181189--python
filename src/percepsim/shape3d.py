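"""Open 3D similarity protocol: conformers, Gaussian shape + pharmacophore
"color" overlap alignment, and the best-alignment TanimotoCombo score.

The score mirrors the ROCS-style TanimotoCombo: a shape Tanimoto in
[0, 1] plus a pharmacophore-color Tanimoto in [0, 1], so the combined
score tCS lies in [0, 2] and reaches 2 only when a molecule is aligned
onto an identical copy of itself.

Shape model
-----------
Each heavy atom is a spherical Gaussian ``p * exp(-alpha * r^2)`` with
fixed height ``p = 2.70`` and ``alpha`` chosen so the Gaussian's volume
integral equals the volume of a hard sphere with the element's
van-der-Waals radius (the classic soft-sphere description of molecular
volume).  The overlap volume between two molecules is the first-order
(pairwise) sum of two-center Gaussian product integrals, which has the
closed form

    V_ij = p^2 * (pi / (a_i + a_j))^(3/2) * exp(-a_i a_j / (a_i + a_j) d_ij^2)

Hydrogens are excluded throughout.  The shape Tanimoto is
``O_AB / (O_AA + O_BB - O_AB)``.

Color model
-----------
Pharmacophore features (donor, acceptor, cation, anion, hydrophobe,
aromatic ring) are detected with RDKit's chemical-feature definitions
and each placed as a Gaussian of radius ``sigma = 1.0`` angstrom at the
feature centroid.  Color overlap is accumulated only between features
of identical type, and turned into a color Tanimoto the same way.

Alignment
---------
Rigid-body alignment starts from centroid superposition plus the four
proper principal-axes sign combinations, then locally optimizes the six
rigid parameters (rotation vector + translation) to maximize the shape
overlap, derivative-free.  Over all conformer pairs and starting poses,
the pose with the largest TanimotoCombo is kept.

These scores are methodologically comparable to, but not bit-compatible
with, the commercial shape-similarity tools; published coefficient
tables should be reproduced from deposited feature values, not by
rescoring with this module.
"""

from __future__ import annotations

import itertools
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures, rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chem_io import MoleculeRecord
from .exceptions import ConformerGenerationError, PercepsimError

logger = logging.getLogger(__name__)

__all__ = [
    "GAUSSIAN_PREFACTOR",
    "COLOR_TYPES",
    "ConformerSet",
    "GaussianShape",
    "ColorFeatureSet",
    "AlignmentResult",
    "generate_conformers",
    "gaussian_overlap_volume",
    "align_and_score",
    "tanimoto3d",
]

#: Gaussian height mimicking a hard sphere (Grant-Pickup convention).
GAUSSIAN_PREFACTOR = 2.70

#: alpha = KAPPA / radius^2 makes the Gaussian integrate to the
#: hard-sphere volume 4/3 pi r^3 at height p:
#: p (pi/alpha)^(3/2) = 4/3 pi r^3  =>  KAPPA = pi (3 p / 4 pi)^(2/3).
KAPPA = np.pi * (3.0 * GAUSSIAN_PREFACTOR / (4.0 * np.pi)) ** (2.0 / 3.0)

COLOR_TYPES = ("donor", "acceptor", "cation", "anion", "hydrophobe", "ring")

_FAMILY_TO_COLOR = {
    "Donor": "donor",
    "Acceptor": "acceptor",
    "PosIonizable": "cation",
    "NegIonizable": "anion",
    "Hydrophobe": "hydrophobe",
    "Aromatic": "ring",
}

_FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(
    os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
)

_PT = Chem.GetPeriodicTable()


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianShape:
    """Heavy-atom Gaussian density of one conformer."""

    centers: np.ndarray  # (n, 3) angstrom
    radii: np.ndarray  # (n,) angstrom
    prefactor: float = GAUSSIAN_PREFACTOR

    def __post_init__(self):
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise PercepsimError("centers must be (n, 3)")
        if np.any(self.radii <= 0):
            raise PercepsimError("radii must be positive")

    @property
    def alphas(self) -> np.ndarray:
        return KAPPA / self.radii**2

    def self_overlap(self) -> float:
        return _overlap(self.centers, self.alphas, self.centers, self.alphas,
                        self.prefactor)


@dataclass(frozen=True)
class ColorFeatureSet:
    """Typed pharmacophore feature Gaussians of one conformer."""

    types: tuple[str, ...]
    centers: np.ndarray  # (m, 3)
    sigma: float = 1.0

    def __post_init__(self):
        unknown = set(self.types) - set(COLOR_TYPES)
        if unknown:
            raise PercepsimError(f"unknown color feature types: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.types)


@dataclass
class ConformerSet:
    """A molecule's heavy-atom conformer ensemble (coordinates in angstrom)."""

    mol_id: str
    mol: Chem.Mol = field(repr=False)  # heavy atoms only, carries conformers
    generator_seed: int = 42

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def coordinates(self, index: int) -> np.ndarray:
        return np.asarray(
            self.mol.GetConformer(self.mol.GetConformers()[index].GetId())
            .GetPositions(),
            dtype=float,
        )

    def shape(self, index: int) -> GaussianShape:
        radii = np.array(
            [_PT.GetRvdw(a.GetAtomicNum()) for a in self.mol.GetAtoms()]
        )
        return GaussianShape(centers=self.coordinates(index), radii=radii)

    def colors(self, index: int) -> ColorFeatureSet:
        conf_id = self.mol.GetConformers()[index].GetId()
        feats = _FEATURE_FACTORY.GetFeaturesForMol(self.mol, confId=conf_id)
        types, centers = [], []
        for f in feats:
            color = _FAMILY_TO_COLOR.get(f.GetFamily())
            if color is None:
                continue
            pos = f.GetPos()
            types.append(color)
            centers.append([pos.x, pos.y, pos.z])
        centers_arr = (
            np.array(centers, dtype=float) if centers else np.empty((0, 3))
        )
        return ColorFeatureSet(types=tuple(types), centers=centers_arr)


@dataclass(frozen=True)
class AlignmentResult:
    """Best rigid alignment of mol_b onto mol_a and its similarity scores.

    ``rotation``/``translation`` map mol_b's input coordinates into
    mol_a's frame: ``x_aligned = rotation @ x + translation``.
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    shape_tanimoto: float
    color_tanimoto: float
    tanimoto_combo: float
    conformer_a: int
    conformer_b: int
    color_missing: bool = False

    def __post_init__(self):
        if not (0.0 <= self.shape_tanimoto <= 1.0 + 1e-9):
            raise PercepsimError(f"shape Tanimoto out of [0,1]: {self.shape_tanimoto}")
        if not (0.0 <= self.color_tanimoto <= 1.0 + 1e-9):
            raise PercepsimError(f"color Tanimoto out of [0,1]: {self.color_tanimoto}")
        if abs(self.tanimoto_combo - self.shape_tanimoto - self.color_tanimoto) > 1e-9:
            raise PercepsimError("tanimoto_combo must equal shape + color Tanimoto")


# --------------------------------------------------------------------------
# conformer generation
# --------------------------------------------------------------------------

def generate_conformers(
    mol: MoleculeRecord,
    max_confs: int = 200,
    seed: int = 42,
    rms_thresh: float = 0.5,
    optimize: bool = True,
) -> ConformerSet:
    """Generate up to ``max_confs`` conformers with distance geometry.

    Uses the ETKDG torsion-knowledge sampler, optional MMFF94 refinement,
    and greedy heavy-atom RMSD pruning at ``rms_thresh`` angstrom.
    Deterministic for a fixed ``seed``.

    Raises :class:`ConformerGenerationError` when embedding fails, naming
    the molecule (mirroring pipelines where molecules failing conformer
    generation are discarded).
    """
    if mol.structure.GetNumHeavyAtoms() < 1:
        raise ConformerGenerationError(f"{mol.id}: no heavy atoms")
    molh = Chem.AddHs(mol.structure)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    # no embedding-time pruning: the symmetry-aware greedy prune below is
    # applied after refinement instead (the embedder's own prune is not
    # symmetry-aware and can collapse distinct torsional minima)
    params.pruneRmsThresh = -1.0
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(max_confs), params=params)
    if len(conf_ids) == 0:
        raise ConformerGenerationError(
            f"conformer embedding failed for molecule {mol.id!r} "
            f"({mol.smiles_standardized})"
        )
    if optimize:
        try:
            AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=200, numThreads=1)
        except Exception:  # pragma: no cover - MMFF typing gaps
            logger.debug("MMFF refinement skipped for %s", mol.id)
    heavy = Chem.RemoveHs(molh)
    _prune_conformers(heavy, rms_thresh)
    return ConformerSet(mol_id=mol.id, mol=heavy, generator_seed=int(seed))


def _prune_conformers(mol: Chem.Mol, rms_thresh: float) -> None:
    """Greedy duplicate removal by symmetry-aware heavy-atom RMSD."""
    if mol.GetNumConformers() <= 1:
        return
    keep: list[int] = []
    for cid in [c.GetId() for c in mol.GetConformers()]:
        duplicate = False
        for kid in keep:
            rms = rdMolAlign.GetBestRMS(mol, mol, prbId=cid, refId=kid,
                                        maxMatches=1000)
            if rms < rms_thresh:
                duplicate = True
                break
        if duplicate:
            mol.RemoveConformer(cid)
        else:
            keep.append(cid)


# --------------------------------------------------------------------------
# Gaussian overlap
# --------------------------------------------------------------------------

def _overlap(ca, aa, cb, ab, prefactor: float) -> float:
    """First-order pairwise Gaussian overlap volume (angstrom^3)."""
    if len(ca) == 0 or len(cb) == 0:
        return 0.0
    s = aa[:, None] + ab[None, :]
    k = aa[:, None] * ab[None, :] / s
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=2)
    return float(np.sum(prefactor**2 * (np.pi / s) ** 1.5 * np.exp(-k * d2)))


def gaussian_overlap_volume(
    a: GaussianShape,
    b: GaussianShape,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> float:
    """Overlap volume of two Gaussian shapes, optionally rigidly moving b.

    Symmetric, non-negative, and invariant under a common rigid motion of
    both shapes.
    """
    cb = b.centers
    if rotation is not None:
        cb = cb @ np.asarray(rotation).T
    if translation is not None:
        cb = cb + np.asarray(translation)
    return _overlap(a.centers, a.alphas, cb, b.alphas, a.prefactor)


def _color_overlap(a: ColorFeatureSet, b: ColorFeatureSet,
                   cb: np.ndarray | None = None) -> float:
    """Type-matched color overlap volume; ``cb`` overrides b's centers."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    centers_b = b.centers if cb is None else cb
    alpha_a = np.full(len(a), KAPPA / a.sigma**2)
    alpha_b = np.full(len(b), KAPPA / b.sigma**2)
    ta = np.array(a.types)
    tb = np.array(b.types)
    total = 0.0
    for t in set(a.types) & set(b.types):
        ia = ta == t
        ib = tb == t
        total += _overlap(a.centers[ia], alpha_a[ia], centers_b[ib],
                          alpha_b[ib], GAUSSIAN_PREFACTOR)
    return total


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal axes (columns) of a centered point cloud."""
    cov = np.cov(coords.T) if len(coords) > 1 else np.eye(3)
    cov = np.atleast_2d(cov)
    if cov.shape != (3, 3):
        cov = np.eye(3)
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # largest variance first
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs

# proper rotations flipping pairs of principal axes
_AXIS_FLIPS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def _optimize_pose(ca, aa, cb, ab, r0: np.ndarray, prefactor: float):
    """Locally maximize shape overlap over rotation-vector + translation."""

    def objective(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix() @ r0
        moved = cb @ rot.T + x[3:]
        return -_overlap(ca, aa, moved, ab, prefactor)

    res = minimize(
        objective,
        np.zeros(6),
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-6, "maxiter": 2000},
    )
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix() @ r0
    return rot, res.x[3:], -res.fun


def align_and_score(
    a: ConformerSet,
    b: ConformerSet,
    max_pairs: int | None = None,
) -> AlignmentResult:
    """Best-alignment TanimotoCombo over all conformer pairs.

    For every pair of conformers, alignment starts from centroid
    superposition with the four proper principal-axes orientations, the
    six rigid parameters are optimized to maximize the shape overlap,
    and both Tanimotos are scored at the optimized pose.  The pose with
    the largest combined score is returned.  ``max_pairs`` optionally
    caps the number of conformer pairs examined (taken in order).

    A molecule with no detected pharmacophore features gets
    ``color_tanimoto = 0`` and the result is flagged ``color_missing``.
    """
    if a.n_conformers == 0 or b.n_conformers == 0:
        raise PercepsimError("both conformer sets must be non-empty")

    best = None
    pairs = itertools.product(range(a.n_conformers), range(b.n_conformers))
    for n_done, (ia, ib) in enumerate(pairs):
        if max_pairs is not None and n_done >= max_pairs:
            break
        shape_a = a.shape(ia)
        shape_b = b.shape(ib)
        colors_a = a.colors(ia)
        colors_b = b.colors(ib)
        centroid_a = shape_a.centers.mean(axis=0)
        centroid_b = shape_b.centers.mean(axis=0)
        ca = shape_a.centers - centroid_a
        cb = shape_b.centers - centroid_b
        # work in A-centered frame for atoms and color features alike
        col_a = (
            ColorFeatureSet(colors_a.types, colors_a.centers - centroid_a,
                            colors_a.sigma)
            if len(colors_a) else colors_a
        )
        col_b_centered = colors_b.centers - centroid_b if len(colors_b) else None

        o_aa = shape_a.self_overlap()
        o_bb = shape_b.self_overlap()
        c_aa = _color_overlap(colors_a, colors_a)
        c_bb = _color_overlap(colors_b, colors_b)
        color_missing = len(colors_a) == 0 or len(colors_b) == 0

        axes_a = _principal_axes(ca)
        axes_b = _principal_axes(cb)
        for flip in _AXIS_FLIPS:
            r0 = axes_a @ flip @ axes_b.T
            rot, trans, o_ab = _optimize_pose(
                ca, shape_a.alphas, cb, shape_b.alphas, r0, shape_a.prefactor
            )
            o_ab = min(o_ab, min(o_aa, o_bb))  # guard numerical overshoot
            st = o_ab / (o_aa + o_bb - o_ab)
            if color_missing:
                ct = 0.0
            else:
                moved_cols = col_b_centered @ rot.T + trans
                c_ab = _color_overlap(col_a, colors_b, cb=moved_cols)
                c_ab = min(c_ab, min(c_aa, c_bb))
                ct = c_ab / (c_aa + c_bb - c_ab) if (c_aa + c_bb - c_ab) > 0 else 0.0
            combo = st + ct
            if best is None or combo > best.tanimoto_combo:
                # full transform on b's original coordinates
                full_t = centroid_a + trans - rot @ centroid_b
                best = AlignmentResult(
                    rotation=rot,
                    translation=full_t,
                    shape_tanimoto=min(st, 1.0),
                    color_tanimoto=min(ct, 1.0),
                    tanimoto_combo=min(st, 1.0) + min(ct, 1.0),
                    conformer_a=ia,
                    conformer_b=ib,
                    color_missing=color_missing,
                )
    if best is not None and best.color_missing:
        logger.info(
            "no pharmacophore features on one side of %s/%s: color Tanimoto "
            "set to 0", a.mol_id, b.mol_id,
        )
    return best


def tanimoto3d(
    a: MoleculeRecord,
    b: MoleculeRecord,
    max_confs: int = 200,
    seed: int = 42,
    max_pairs: int | None = None,
) -> AlignmentResult:
    """Convenience wrapper: conformers for both molecules, then best tCS."""
    confs_a = generate_conformers(a, max_confs=max_confs, seed=seed)
    confs_b = generate_conformers(b, max_confs=max_confs, seed=seed + 1)
    return align_and_score(confs_a, confs_b, max_pairs=max_pairs)
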