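"""Signature scoring, six-way AR/NE phenotype classification, and classical MDS.

A gene signature is scored per sample by the combined z-score: each gene's
expression is standardized across samples, and the score is the sum of the
gene z-scores divided by sqrt(k) over the k signature genes present. Phenotype
classes are assigned by thresholding the AR-axis and NE-axis scores into
negative / low / positive levels and combining them into the six classes used
for metastatic castration-resistant prostate cancer:

    AR+/NE-, ARlow/NE-, AR-/NE-, AR-/NElow, AR+/NE+, AR-/NE+
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io import SignatureSet

__all__ = [
    "PHENOTYPE_CLASSES", "MISSING", "combined_zscore", "score_signatures",
    "classify_phenotype", "aggregate_scores", "MdsEmbedding", "classical_mds",
]

PHENOTYPE_CLASSES = (
    "AR+/NE-", "ARlow/NE-", "AR-/NE-", "AR-/NElow", "AR+/NE+", "AR-/NE+",
)
MISSING = "missing"

# (AR level, NE level) -> printed class. Levels are "neg" / "low" / "pos".
# The two level grids cross in nine cells but only six classes are printed;
# the three unprinted cells collapse to the nearest printed class: a "low"
# level is demoted when the other axis is positive (full positivity on both
# axes is required for the amphicrine AR+/NE+ call), and ARlow paired with
# any NE signal is dominated by the NE axis.
_CLASS_TABLE: dict[tuple[str, str], str] = {
    ("pos", "neg"): "AR+/NE-",
    ("low", "neg"): "ARlow/NE-",
    ("neg", "neg"): "AR-/NE-",
    ("neg", "low"): "AR-/NElow",
    ("pos", "pos"): "AR+/NE+",
    ("neg", "pos"): "AR-/NE+",
    ("pos", "low"): "AR+/NE-",
    ("low", "low"): "ARlow/NE-",
    ("low", "pos"): "AR-/NE+",
}


def combined_zscore(expr: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Combined z-score of a gene set, per sample (column) of ``expr``.

    Each gene present in the matrix is z-scored across samples (sample SD,
    ddof=1); the score is sum(z)/sqrt(k) over the k retained genes.
    Zero-variance genes are dropped; if every present gene is zero-variance
    the score is 0 for all samples. A set with no gene present is an error.
    """
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("no signature gene present in expression matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        return pd.Series(0.0, index=expr.columns)
    sub = sub[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    score = z.sum(axis=0) / np.sqrt(keep.sum())
    return pd.Series(score, index=expr.columns)


def score_signatures(expr: pd.DataFrame, sets: Sequence[SignatureSet],
                     standardize: bool = True) -> pd.DataFrame:
    """Score several signatures; returns a samples x signatures table.

    With ``standardize=True`` (the default for phenotype calling) each
    signature's scores are divided by their cohort SD, putting every axis on a
    unit scale: the raw combined score's spread grows with gene-set size and
    inter-gene correlation, whereas the classification thresholds are
    expressed in cohort-SD units. Scores always have cohort mean 0.
    """
    out = {}
    for s in sets:
        score = combined_zscore(expr, s.genes)
        if standardize:
            sd = score.std(ddof=1)
            if sd > 0:
                score = score / sd
        out[s.name] = score
    return pd.DataFrame(out, index=expr.columns)


def _axis_level(score: float, low: float, high: float) -> str:
    if score >= high:  # boundary assigned upward
        return "pos"
    if score >= low:
        return "low"
    return "neg"


def classify_phenotype(scores: pd.DataFrame,
                       ar_thresholds: tuple[float, float] = (-0.5, 0.5),
                       ne_thresholds: tuple[float, float] = (-0.5, 0.5),
                       ar_col: str = "AR", ne_col: str = "NE") -> pd.DataFrame:
    """Six-way AR/NE phenotype call from per-sample axis scores.

    Per axis: positive if score >= high, low if low <= score < high, negative
    if score < low (thresholds default to -0.5/+0.5 cohort-SD units; boundary
    values are assigned upward). Samples with a missing axis score are called
    ``missing`` and excluded from concordance statistics downstream.
    """
    for col in (ar_col, ne_col):
        if col not in scores.columns:
            raise ValueError(f"score table lacks column {col!r}")
    calls = []
    for _, row in scores.iterrows():
        ar, ne = row[ar_col], row[ne_col]
        if pd.isna(ar) or pd.isna(ne):
            calls.append(MISSING)
            continue
        level = (_axis_level(ar, *ar_thresholds), _axis_level(ne, *ne_thresholds))
        calls.append(_CLASS_TABLE[level])
    out = scores[[ar_col, ne_col]].copy()
    out.columns = ["ar_score", "ne_score"]
    out["phenotype"] = calls
    return out


def aggregate_scores(scores: pd.DataFrame, annotations: pd.DataFrame,
                     level: str = "tumor") -> pd.DataFrame:
    """Average per-ROI scores to tumor (or patient) level before classifying."""
    key = {"tumor": "tumor_id", "patient": "patient_id"}.get(level)
    if key is None:
        raise ValueError(f"level must be 'tumor' or 'patient', got {level!r}")
    groups = annotations.set_index("roi_id")[key].reindex(scores.index)
    if groups.isna().any():
        raise ValueError(
            f"ROI {groups.index[groups.isna()][0]!r} has no annotation row")
    return scores.groupby(groups).mean()


@dataclasses.dataclass
class MdsEmbedding:
    """Classical MDS coordinates (centered) and the centered-matrix eigenvalues."""

    coords: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing


def classical_mds(expr: pd.DataFrame, n_components: int = 2,
                  samples_in_columns: bool = True) -> MdsEmbedding:
    """Classical (Torgerson) MDS of samples under Euclidean distance.

    The squared-distance matrix is double-centered (B = -1/2 J D^2 J) and
    eigendecomposed; coordinates are eigenvectors scaled by sqrt(eigenvalue)
    (negative eigenvalues clip to zero coordinates). Each coordinate's sign is
    fixed so its largest-magnitude entry is positive.
    """
    X = expr.T if samples_in_columns else expr
    labels = X.index
    n = len(labels)
    if n < max(3, n_components + 1):
        raise ValueError(f"classical MDS of {n_components} components needs "
                         f"more samples than {n}")
    d2 = squareform(pdist(X.to_numpy(dtype=float), metric="euclidean")) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, n_components))
    for k in range(n_components):
        if evals[k] > 0:
            v = evecs[:, k] * np.sqrt(evals[k])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, k] = v
    cols = [f"MDS{k + 1}" for k in range(n_components)]
    return MdsEmbedding(coords=pd.DataFrame(coords, index=labels, columns=cols),
                        eigenvalues=evals)
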