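"""Synthetic fixtures: vote tables from a known logistic law and
molecular-pair pools spanning the four calculated-similarity subsets.

The pool generator emulates the kind of survey design that samples
pairs from a large bioactive-compound extraction: instead of a
database, it composes real drug-like SMILES from a bundled
scaffold/substituent library, computes the actual 2D fingerprint
Tanimoto and 3D TanimotoCombo for each candidate with this package's
own featurizers, and rejection-samples against the buffer-zone
classifier until each subset's quota is filled.  Chemistry is chosen
per subset the way such pairs arise in practice:

* ``sim2D_sim3D`` — identical or homologous molecules on rigid fused
  aromatic scaffolds (2D and 3D agree they are similar);
* ``sim2D_dis3D`` — flexible close analogues and regioisomers whose
  graphs are nearly identical but whose sampled conformers differ;
* ``dis2D_sim3D`` — heteroatom-swapped ring isosteres (graph paths
  change, shape and pharmacophore pattern barely do);
* ``dis2D_dis3D`` — size- and functionality-mismatched pairs.

Pair features are screened with a single conformer per molecule — a
deliberately small budget that keeps pool construction cheap and, for
flexible molecules, produces genuine 3D mismatch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import MoleculePair, PairFeatureTable, standardize_molecule
from .exceptions import PoolGenerationError
from .perception_model import SimilarityFeatures, inverse_logit
from .sim2d import DEFAULT_SCHEME, fingerprint, tanimoto2d
from .shape3d import align_and_score, generate_conformers
from .subset_design import ASSIGNED_LABELS, SubsetLabel, SubsetThresholds, classify_pair

__all__ = [
    "VoteSimConfig",
    "simulate_votes",
    "PairPool",
    "generate_pair_pool",
]


# --------------------------------------------------------------------------
# expert-vote simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VoteSimConfig:
    """Configuration of a simulated expert survey.

    Votes per pair default to 21, a typical panel size for this kind of
    online survey.  Features are sampled uniformly over their domains:
    tXT ~ U(0, 1) and, when a two-feature law is simulated, tCS ~ U(0, 2).
    """

    true_omega0: float
    true_omega1: float
    true_omega2: float | None = None
    n_pairs: int = 100
    votes_per_pair: int = 21
    seed: int = 42
    feature_distribution: str = "uniform"

    def __post_init__(self):
        if self.n_pairs <= 0 or self.votes_per_pair <= 0:
            raise ValueError("n_pairs and votes_per_pair must be positive")
        if self.feature_distribution != "uniform":
            raise ValueError("only the 'uniform' feature distribution is built in")


def simulate_votes(cfg: VoteSimConfig) -> PairFeatureTable:
    """Draw a vote table from a known logistic perception law.

    For each pair, features are sampled, the true expert probability is
    ``inverse_logit(omega0 + omega1 t1 [+ omega2 t2])`` and the yes-vote
    count is Binomial(votes_per_pair, p).  Deterministic under the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    txt = rng.uniform(0.0, 1.0, cfg.n_pairs)
    data = {"pair_id": [f"sim-{i:05d}" for i in range(cfg.n_pairs)], "tXT": txt}
    y = cfg.true_omega0 + cfg.true_omega1 * txt
    if cfg.true_omega2 is not None:
        tcs = rng.uniform(0.0, 2.0, cfg.n_pairs)
        data["tCS"] = tcs
        y = y + cfg.true_omega2 * tcs
    p = np.array([inverse_logit(v) for v in y])
    data["n_similar"] = rng.binomial(cfg.votes_per_pair, p)
    data["n_total"] = np.full(cfg.n_pairs, cfg.votes_per_pair)
    return PairFeatureTable(df=pd.DataFrame(data), dialect="votes")


# --------------------------------------------------------------------------
# scaffold / substituent library (prefix-attachable substituent SMILES:
# the last atom of the substituent string bonds to the ring)
# --------------------------------------------------------------------------

_RIGID_SCAFFOLDS = [
    "{x}c1ccc2ccccc2c1",        # 2-substituted naphthalene
    "{x}c1cccc2ccccc12",        # 1-substituted naphthalene
    "{x}c1ccc2ncccc2c1",        # quinoline
    "{x}c1ccc2cnccc2c1",        # isoquinoline
    "{x}c1cc2ccccc2o1",         # benzofuran
    "{x}c1cc2ccccc2s1",         # benzothiophene
    "{x}c1cc2ccccc2[nH]1",      # indole
    "{x}c1cc(=O)oc2ccccc12",    # coumarin
    "{x}c1ccc2c(c1)OCO2",       # benzodioxole
    "{x}c1ccc2ccccc2n1",        # 2-substituted quinoline
]

_SUBSTITUENTS = ["C", "CC", "O", "CO", "CCO", "F", "Cl", "Br", "N", "N#C"]

# hetero-swapped scaffold pairs for dis2D_sim3D
_ISOSTERE_SCAFFOLD_PAIRS = [
    ("{x}c1ccc2ccccc2c1", "{x}c1ccc2ncccc2c1"),    # naphthalene / quinoline
    ("{x}c1ccc2ccccc2c1", "{x}c1ccc2cnccc2c1"),    # naphthalene / isoquinoline
    ("{x}c1cc2ccccc2o1", "{x}c1cc2ccccc2s1"),      # benzofuran / benzothiophene
    ("{x}c1cc2ccccc2[nH]1", "{x}c1cc2ccccc2o1"),   # indole / benzofuran
    ("{x}c1cc2ccccc2[nH]1", "{x}c1cc2ccccc2s1"),   # indole / benzothiophene
    ("{x}c1cccc2ccccc12", "{x}c1cccc2ncccc12"),    # 1-naphthyl / 8-aza
]

# flexible tails for the sim2D_dis3D family ("{r}" is the aryl ring)
_FLEX_TAILS = ["CC(=O)O", "CC(=O)OCC", "CCNC(C)=O", "CC(=O)N", "CCO", "CCN(C)C"]
_FLEX_HEADS = ["CCO", "CCCO", "CCC(=O)N", "CCOC"]

_LONG_PARTNERS = [
    "CCCCCCCCCCCC(=O)O",
    "CCCCCCCCCCCCCC",
    "CCOCCOCCOCCOCC",
    "CC(C)CCCC(C)CCCC(C)C",
    "C1CCC2(CC1)CCCCC2",
    "CCCCCCCCCCCCO",
]


def _candidates(label: SubsetLabel) -> list[tuple[str, str]]:
    """Deterministic candidate (smiles_a, smiles_b) list for one subset."""
    out: list[tuple[str, str]] = []
    if label is SubsetLabel.SIM2D_SIM3D:
        for scaf, sub in itertools.product(_RIGID_SCAFFOLDS, _SUBSTITUENTS):
            s = scaf.format(x=sub)
            out.append((s, s))  # identical rigid molecules
        for scaf in _RIGID_SCAFFOLDS:  # methyl/ethyl homologs
            out.append((scaf.format(x="C"), scaf.format(x="CC")))
            out.append((scaf.format(x="CO"), scaf.format(x="CCO")))
    elif label is SubsetLabel.SIM2D_DIS3D:
        for head, tail in itertools.product(_FLEX_HEADS, _FLEX_TAILS):
            para = f"{head}c1ccc({tail})cc1"
            meta = f"{head}c1cccc({tail})c1"
            homolog = f"C{head}c1ccc({tail})cc1"
            out.append((para, meta))      # regioisomers
            out.append((para, homolog))   # chain homologs
            out.append((para, para))      # identical flexible molecules
    elif label is SubsetLabel.DIS2D_SIM3D:
        for (sa, sb), sub in itertools.product(
            _ISOSTERE_SCAFFOLD_PAIRS, _SUBSTITUENTS
        ):
            out.append((sa.format(x=sub), sb.format(x=sub)))
        for scaf in _RIGID_SCAFFOLDS:  # halogen swaps scramble path bits
            out.append((scaf.format(x="F"), scaf.format(x="Cl")))
    elif label is SubsetLabel.DIS2D_DIS3D:
        smalls = [s.format(x=x) for s, x in
                  itertools.product(_RIGID_SCAFFOLDS[:5], ["O", "C", "N"])]
        for small, big in itertools.product(smalls, _LONG_PARTNERS):
            out.append((small, big))
    return out


@dataclass
class PairPool:
    """A generated pool: standardized pairs plus their computed features."""

    pairs: list[MoleculePair]
    table: PairFeatureTable = field(repr=False)


def generate_pair_pool(
    per_subset: int,
    seed: int = 42,
    thresholds: SubsetThresholds = SubsetThresholds(),
    max_attempts: int = 100_000,
) -> PairPool:
    """Build a pool of real molecular pairs covering all four subsets.

    Candidates from the scaffold library are taken in seed-shuffled
    order; each is standardized, featurized (fingerprint Tanimoto plus
    single-conformer TanimotoCombo), classified, and kept only when it
    falls in its intended subset.  Candidates missing because of
    conformer noise are retried with fresh conformer seeds in later
    rounds.  Raises :class:`PoolGenerationError` naming the first
    subset whose quota cannot be filled.
    """
    if per_subset < 1:
        raise PoolGenerationError("per_subset must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[MoleculePair] = []
    rows: list[dict] = []
    conf_cache: dict[tuple[str, int], object] = {}

    def confs(record, conf_seed):
        key = (record.smiles_standardized, conf_seed)
        if key not in conf_cache:
            conf_cache[key] = generate_conformers(
                record, max_confs=1, seed=conf_seed
            )
        return conf_cache[key]

    for label in ASSIGNED_LABELS:
        cands = _candidates(label)
        order = rng.permutation(len(cands))
        accepted = 0
        attempts = 0
        retired: set[int] = set()  # 2D-impossible or already accepted
        for round_no in range(20):
            if accepted >= per_subset:
                break
            for idx in order:
                if accepted >= per_subset or attempts >= max_attempts:
                    break
                if idx in retired:
                    continue
                attempts += 1
                sa, sb = cands[idx]
                rec_a = standardize_molecule(sa)
                rec_b = standardize_molecule(sb)
                txt = tanimoto2d(
                    fingerprint(rec_a, DEFAULT_SCHEME),
                    fingerprint(rec_b, DEFAULT_SCHEME),
                ).value
                # the 2D feature is deterministic: prune candidates whose
                # tXT can never match the target subset
                want_sim2d = label in (SubsetLabel.SIM2D_SIM3D,
                                       SubsetLabel.SIM2D_DIS3D)
                if want_sim2d and txt < thresholds.txt_sim:
                    retired.add(idx)
                    continue
                if not want_sim2d and txt > thresholds.txt_dis:
                    retired.add(idx)
                    continue
                conf_seed = int(rng.integers(1, 2**31 - 2))
                try:
                    res = align_and_score(
                        confs(rec_a, conf_seed), confs(rec_b, conf_seed + 1)
                    )
                except Exception:
                    retired.add(idx)
                    continue
                tcs = res.tanimoto_combo
                got = classify_pair(
                    SimilarityFeatures(tXT=txt, tCS=min(tcs, 2.0)), thresholds
                )
                if got is not label:
                    continue
                retired.add(idx)
                pair_id = f"{label.value}-{accepted:03d}"
                pairs.append(
                    MoleculePair(pair_id=pair_id, mol_a=rec_a, mol_b=rec_b,
                                 provenance=label.value)
                )
                rows.append(
                    {
                        "pair_id": pair_id,
                        "smiles_a": rec_a.smiles_standardized,
                        "smiles_b": rec_b.smiles_standardized,
                        "tXT": txt,
                        "tCS": min(tcs, 2.0),
                        "subset": label.value,
                    }
                )
                accepted += 1
        if accepted < per_subset:
            raise PoolGenerationError(
                f"could not fill subset {label.value}: {accepted}/{per_subset} "
                f"after {attempts} attempts"
            )
    table = PairFeatureTable(df=pd.DataFrame(rows), dialect="pairs")
    return PairPool(pairs=pairs, table=table)
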