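"""Buffer-zone classification of pairs into calculated-similarity subsets
and stratified selection of survey pairs.

A pair is *similar in 2D* when tXT >= 0.7 and *dissimilar in 2D* when
tXT <= 0.65; likewise *similar in 3D* when tCS >= 1.4 and *dissimilar*
when tCS <= 1.3.  The open intervals (0.65, 0.7) and (1.3, 1.4) are
buffer regions: pairs falling inside either buffer stay unassigned, so
that tiny numerical differences near a threshold cannot flip a pair
between subsets.  The four resulting classes stratify a survey set so
that it covers agreeing and conflicting 2D/3D similarity verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .chem_io import PairFeatureTable
from .exceptions import FeatureError, SelectionError
from .perception_model import SimilarityFeatures

__all__ = [
    "SubsetThresholds",
    "SubsetLabel",
    "classify_pair",
    "classify_table",
    "stratified_select",
]


class SubsetLabel(str, Enum):
    SIM2D_SIM3D = "sim2D_sim3D"
    SIM2D_DIS3D = "sim2D_dis3D"
    DIS2D_SIM3D = "dis2D_sim3D"
    DIS2D_DIS3D = "dis2D_dis3D"
    UNASSIGNED = "UNASSIGNED"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: the four assignable classes, in canonical order
ASSIGNED_LABELS = (
    SubsetLabel.SIM2D_SIM3D,
    SubsetLabel.SIM2D_DIS3D,
    SubsetLabel.DIS2D_SIM3D,
    SubsetLabel.DIS2D_DIS3D,
)


@dataclass(frozen=True)
class SubsetThresholds:
    """Similarity/dissimilarity cutoffs with their buffer bands.

    Defaults: 2D similar at tXT >= 0.7, dissimilar at tXT <= 0.65
    (0.05 buffer); 3D similar at tCS >= 1.4, dissimilar at tCS <= 1.3
    (0.1 buffer).
    """

    txt_sim: float = 0.70
    txt_dis: float = 0.65
    tcs_sim: float = 1.40
    tcs_dis: float = 1.30

    def __post_init__(self):
        if not (self.txt_dis < self.txt_sim and self.tcs_dis < self.tcs_sim):
            raise FeatureError(
                "dissimilarity thresholds must lie strictly below "
                "similarity thresholds"
            )


def classify_pair(
    features: SimilarityFeatures,
    thresholds: SubsetThresholds = SubsetThresholds(),
) -> SubsetLabel:
    """Assign a pair to one of the four subsets or leave it in a buffer.

    Boundary values belong to the labeled side: tXT exactly at the
    similarity threshold counts as similar (>=), exactly at the
    dissimilarity threshold as dissimilar (<=).
    """
    txt = features.get("tXT")
    tcs = features.get("tCS")
    if txt >= thresholds.txt_sim:
        d2 = "sim"
    elif txt <= thresholds.txt_dis:
        d2 = "dis"
    else:
        return SubsetLabel.UNASSIGNED
    if tcs >= thresholds.tcs_sim:
        d3 = "sim"
    elif tcs <= thresholds.tcs_dis:
        d3 = "dis"
    else:
        return SubsetLabel.UNASSIGNED
    return SubsetLabel(f"{d2}2D_{d3}3D")


def classify_table(
    table: PairFeatureTable,
    thresholds: SubsetThresholds = SubsetThresholds(),
) -> PairFeatureTable:
    """Return a copy of the table with a ``subset`` column appended."""
    df = table.df.copy()
    labels = [
        str(classify_pair(SimilarityFeatures(tXT=row.tXT, tCS=row.tCS), thresholds))
        for row in df.itertuples()
    ]
    df["subset"] = labels
    return PairFeatureTable(df=df, dialect=table.dialect)


def stratified_select(
    table: PairFeatureTable,
    per_subset: int = 25,
    seed: int = 42,
) -> PairFeatureTable:
    """Uniformly sample ``per_subset`` pairs from each of the four subsets.

    The table must carry a ``subset`` column (see :func:`classify_table`).
    Buffer (UNASSIGNED) pairs are never selected.  Raises
    :class:`SelectionError` naming any subset with fewer than
    ``per_subset`` members.  Deterministic for a fixed seed.
    """
    if per_subset < 0:
        raise SelectionError("per_subset must be non-negative")
    df = table.df
    if "subset" not in df.columns:
        raise FeatureError("table has no 'subset' column; classify it first")
    rng = np.random.default_rng(seed)
    chosen: list[pd.DataFrame] = []
    for label in ASSIGNED_LABELS:
        members = df[df["subset"] == label.value]
        if len(members) < per_subset:
            raise SelectionError(
                f"subset {label.value} has only {len(members)} pairs, "
                f"need {per_subset}"
            )
        idx = rng.choice(members.index.to_numpy(), size=per_subset, replace=False)
        chosen.append(df.loc[np.sort(idx)])
    out = (
        pd.concat(chosen, ignore_index=True)
        if chosen and per_subset > 0
        else df.iloc[0:0].copy()
    )
    return PairFeatureTable(df=out, dialect=table.dialect)
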