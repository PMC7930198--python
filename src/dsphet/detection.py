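"""Limits of quantitation, detection matrices, QC filters, and normalizations.

RNA LOQ per ROI is the geometric mean of the negative probes times the squared
geometric standard deviation of the negative probes — identically
exp2(mean(log2 x) + 2 sd(log2 x)), the log-space "geomean plus two SDs".
Protein LOQ is three times the geometric mean of the IgG control antibodies.
A target is *detected* in an ROI when its count is strictly above that ROI's
LOQ. All normalizations are per-ROI scalar multiplications, so within-ROI rank
order is always preserved.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._stats import log2_counts
from .io import ProbeCountMatrix, ProteinCountMatrix, parse_qc_flags

__all__ = [
    "LoqTable", "compute_rna_loq", "compute_protein_loq", "detection_matrix",
    "apply_qc_filters", "negative_normalize", "q3_normalize",
    "protein_snr", "housekeeping_normalize",
]

DEFAULT_MIN_GENES = 100
DEFAULT_SNR_CUTOFF = 3.0


@dataclasses.dataclass
class LoqTable:
    """Per-ROI limit of quantitation with the negative-control summaries."""

    table: pd.DataFrame  # index roi; columns loq, neg_geomean, neg_gsd

    @property
    def loq(self) -> pd.Series:
        return self.table["loq"]

    @property
    def neg_geomean(self) -> pd.Series:
        return self.table["neg_geomean"]

    @property
    def neg_gsd(self) -> pd.Series:
        return self.table["neg_gsd"]


def compute_rna_loq(negatives: pd.DataFrame | ProbeCountMatrix,
                    sd_multiplier: float = 2.0) -> LoqTable:
    """RNA LOQ per ROI from raw negative-probe counts.

    LOQ = exp2(mean(log2 x) + sd_multiplier * sd(log2 x)), i.e. the negative
    geometric mean times GSD**sd_multiplier. Requires >= 3 negative probes.
    """
    if isinstance(negatives, ProbeCountMatrix):
        negatives = negatives.negative_counts()
    if len(negatives) < 3:
        raise ValueError(f"need >= 3 negative probes, got {len(negatives)}")
    lx = log2_counts(negatives.to_numpy(dtype=float))
    mu = lx.mean(axis=0)
    sd = lx.std(axis=0, ddof=1)
    table = pd.DataFrame({
        "loq": 2.0 ** (mu + sd_multiplier * sd),
        "neg_geomean": 2.0 ** mu,
        "neg_gsd": 2.0 ** sd,
    }, index=negatives.columns)
    return LoqTable(table)


def compute_protein_loq(igg: pd.DataFrame | ProteinCountMatrix,
                        multiplier: float = 3.0) -> LoqTable:
    """Protein LOQ per ROI: ``multiplier`` x geometric mean of the IgG controls."""
    if isinstance(igg, ProteinCountMatrix):
        igg = igg.igg_counts()
    if len(igg) < 2:
        raise ValueError(f"need >= 2 IgG control antibodies, got {len(igg)}")
    lx = log2_counts(igg.to_numpy(dtype=float))
    mu = lx.mean(axis=0)
    sd = lx.std(axis=0, ddof=1)
    gm = 2.0 ** mu
    table = pd.DataFrame({
        "loq": multiplier * gm,
        "neg_geomean": gm,
        "neg_gsd": 2.0 ** sd,
    }, index=igg.columns)
    return LoqTable(table)


def detection_matrix(counts: pd.DataFrame, loq: LoqTable) -> pd.DataFrame:
    """Boolean detected matrix (targets x ROIs): detected <=> count > LOQ.

    The comparison is strict: a count exactly equal to the LOQ is not
    detected. Per-ROI detected counts are ``detection.sum(axis=0)``.
    """
    missing = counts.columns.difference(loq.table.index)
    if len(missing):
        raise ValueError(f"no LOQ for ROI {missing[0]!r}")
    thresholds = loq.loq.reindex(counts.columns).to_numpy()
    return pd.DataFrame(counts.to_numpy(dtype=float) > thresholds[None, :],
                        index=counts.index, columns=counts.columns)


def apply_qc_filters(detection: pd.DataFrame, annotations: pd.DataFrame,
                     min_genes: int = DEFAULT_MIN_GENES):
    """Drop flagged / low-complexity ROIs and never-detected genes.

    An ROI is excluded if its annotation carries a QC flag, or if its
    detected-gene count is <= ``min_genes``. Each excluded ROI is attributed
    to one reason with precedence missing/fat > stroma_only > seq_fail >
    low_genes. Genes detected in zero retained ROIs are then dropped.

    Returns (retained_rois, retained_genes, ledger) where the ledger's
    exclusion counts sum to input minus retained.
    """
    ann = annotations.set_index("roi_id")
    ledger = {"input": len(ann), "missing_or_fat": 0, "stroma_only": 0,
              "seq_fail": 0, "low_genes": 0}
    detected_per_roi = detection.sum(axis=0)
    retained_rois: list[str] = []
    for roi, row in ann.iterrows():
        flags = parse_qc_flags(row["qc_flags"])
        if flags & {"missing", "fat"}:
            ledger["missing_or_fat"] += 1
        elif "stroma_only" in flags:
            ledger["stroma_only"] += 1
        elif "seq_fail" in flags:
            ledger["seq_fail"] += 1
        elif roi in detected_per_roi.index and detected_per_roi[roi] <= min_genes:
            ledger["low_genes"] += 1
        else:
            retained_rois.append(roi)
    kept = detection.columns.intersection(retained_rois)
    gene_any = detection[kept].any(axis=1) if len(kept) else pd.Series(
        False, index=detection.index)
    retained_genes = list(detection.index[gene_any])
    ledger["retained"] = len(retained_rois)
    return retained_rois, retained_genes, ledger


def negative_normalize(counts: pd.DataFrame, loq: LoqTable) -> pd.DataFrame:
    """log2 negative-normalized expression: log2(count / negative geomean of ROI)."""
    gm = loq.neg_geomean.reindex(counts.columns)
    if gm.isna().any():
        raise ValueError(f"no negative geomean for ROI {gm.index[gm.isna()][0]!r}")
    return pd.DataFrame(
        log2_counts(counts.to_numpy(dtype=float)) - np.log2(gm.to_numpy())[None, :],
        index=counts.index, columns=counts.columns)


def q3_normalize(counts: pd.DataFrame, detection: pd.DataFrame,
                 min_detected: int = 4) -> pd.DataFrame:
    """Q3 normalization: scale each ROI by its 75th percentile of detected counts.

    Each ROI's counts are divided by that ROI's Q3 (linear-interpolation
    percentile over its detected targets) and multiplied by the geometric mean
    of all ROIs' Q3s, so an all-identical cohort is returned unchanged.
    """
    det = detection.reindex(index=counts.index, columns=counts.columns).fillna(False)
    q3 = np.empty(counts.shape[1])
    for j, roi in enumerate(counts.columns):
        vals = counts.loc[det[roi], roi].to_numpy(dtype=float)
        if len(vals) < min_detected:
            raise ValueError(
                f"ROI {roi!r} has {len(vals)} detected targets; "
                f"need >= {min_detected} for Q3 normalization")
        q3[j] = np.percentile(vals, 75)  # linear interpolation
    scale = 2.0 ** np.mean(np.log2(q3))
    return counts.astype(float) / q3[None, :] * scale


def protein_snr(proteins: ProteinCountMatrix,
                snr_cutoff: float = DEFAULT_SNR_CUTOFF):
    """Signal-to-noise ratios and SNR-based detection for the protein assay.

    SNR = antibody count / per-ROI geometric mean of the IgG controls; an
    antibody is detected when SNR >= cutoff (boundary inclusive). Returns
    (snr, detected) over the non-IgG antibodies.
    """
    igg = proteins.igg_counts()
    if len(igg) < 2:
        raise ValueError("protein SNR requires the IgG control antibodies")
    gm = 2.0 ** log2_counts(igg.to_numpy(dtype=float)).mean(axis=0)
    targets = proteins.target_counts()
    snr = pd.DataFrame(targets.to_numpy(dtype=float) / gm[None, :],
                       index=targets.index, columns=targets.columns)
    return snr, snr >= snr_cutoff


def housekeeping_normalize(proteins: ProteinCountMatrix) -> pd.DataFrame:
    """Scale each ROI by its housekeeping-antibody geometric mean.

    Counts are divided by the per-ROI housekeeper geometric mean and rescaled
    by the cohort geometric mean of those factors, preserving within-ROI
    antibody ratios exactly. Returns the normalized non-IgG antibody matrix.
    """
    hk = proteins.housekeeping_counts()
    if hk.empty:
        raise ValueError("no housekeeping antibodies in panel")
    if (hk.to_numpy() <= 0).all(axis=0).any():
        raise ValueError("a housekeeper is absent (all zero) in some ROI")
    factor = 2.0 ** log2_counts(hk.to_numpy(dtype=float)).mean(axis=0)
    scale = 2.0 ** np.mean(np.log2(factor))
    targets = proteins.target_counts()
    return targets.astype(float) / factor[None, :] * scale
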