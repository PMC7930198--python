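"""Phenotype-concordance statistics with BCa bootstrap uncertainty,
stratified expression-profile correlations, and per-gene group comparisons.

Concordance is the proportion of ROI pairs within a stratum that share the
same (nonmissing) six-way phenotype call. The three strata are disjoint:

* intratumor   — pairs of ROIs from the same tumor;
* intrapatient — pairs from the same patient but different tumors;
* interpatient — pairs from different patients.

The exact estimate enumerates all pairs; with class sizes n_g inside a group
it reduces to the hypergeometric identity sum_g C(n_g,2) / C(n,2). Sampled
estimates draw pairs uniformly with replacement. Uncertainty comes from a
bias-corrected and accelerated (BCa) bootstrap resampling patients (cluster
bootstrap, preserving the hierarchy), 1000 replicates by default.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signatures import MISSING

__all__ = [
    "STRATA", "ConcordanceResult", "pair_agreement_exact",
    "pair_agreement_sampled", "bca_bootstrap_ci", "bca_interval",
    "stratum_pairs", "stratified_profile_correlation", "differential_expression",
]

STRATA = ("intratumor", "intrapatient", "interpatient")


@dataclasses.dataclass
class ConcordanceResult:
    stratum: str
    estimate: float
    n_pairs: int
    method: str  # "exact" | "sampled"
    ci_low: float | None = None
    ci_high: float | None = None
    n_samples: int | None = None
    B: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# pair bookkeeping


def _calls_frame(calls: pd.DataFrame) -> pd.DataFrame:
    """Nonmissing calls with patient/tumor labels; index is roi_id."""
    for col in ("patient_id", "tumor_id", "phenotype"):
        if col not in calls.columns:
            raise ValueError(f"calls table lacks column {col!r}")
    keep = calls["phenotype"].notna() & (calls["phenotype"] != MISSING)
    return calls.loc[keep]


def stratum_pairs(calls: pd.DataFrame, stratum: str) -> np.ndarray:
    """All (i, j) index pairs of nonmissing ROIs in the stratum, i < j."""
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")
    df = _calls_frame(calls).reset_index(drop=True)
    pat = df["patient_id"].to_numpy()
    tum = df["tumor_id"].to_numpy()
    i, j = np.triu_indices(len(df), k=1)
    same_pat = pat[i] == pat[j]
    same_tum = tum[i] == tum[j]
    if stratum == "intratumor":
        sel = same_tum
    elif stratum == "intrapatient":
        sel = same_pat & ~same_tum
    else:
        sel = ~same_pat
    return np.column_stack([i[sel], j[sel]])


class _ClusterCounts:
    """Per-patient class-count matrices supporting fast stratum statistics."""

    def __init__(self, calls: pd.DataFrame):
        df = _calls_frame(calls)
        self.classes, class_idx = np.unique(df["phenotype"].to_numpy(),
                                            return_inverse=True)
        self.patients, pat_idx = np.unique(df["patient_id"].to_numpy(),
                                           return_inverse=True)
        tumors, tum_idx = np.unique(df["tumor_id"].to_numpy(), return_inverse=True)
        n_c = len(self.classes)
        # per-tumor class counts, and the tumor -> patient map
        tum_counts = np.zeros((len(tumors), n_c))
        np.add.at(tum_counts, (tum_idx, class_idx), 1.0)
        tum_patient = np.zeros(len(tumors), dtype=int)
        tum_patient[tum_idx] = pat_idx
        # per-patient aggregates
        p = len(self.patients)
        self.pat_counts = np.zeros((p, n_c))
        np.add.at(self.pat_counts, (pat_idx, class_idx), 1.0)
        self.pat_n = self.pat_counts.sum(axis=1)
        self.pat_sumsq = (self.pat_counts ** 2).sum(axis=1)
        # intratumor concordant/total pairs, summed per patient
        conc_t = (tum_counts * (tum_counts - 1) / 2).sum(axis=1)
        n_t = tum_counts.sum(axis=1)
        tot_t = n_t * (n_t - 1) / 2
        self.intratumor_conc = np.bincount(tum_patient, weights=conc_t, minlength=p)
        self.intratumor_tot = np.bincount(tum_patient, weights=tot_t, minlength=p)
        # intrapatient (same patient, different tumors)
        cross_sq = np.zeros(p)
        cross_n2 = np.zeros(p)
        np.add.at(cross_sq, tum_patient, (tum_counts ** 2).sum(axis=1))
        np.add.at(cross_n2, tum_patient, n_t ** 2)
        self.intrapatient_conc = (self.pat_sumsq - cross_sq) / 2.0
        self.intrapatient_tot = (self.pat_n ** 2 - cross_n2) / 2.0

    def statistic(self, stratum: str, idx: np.ndarray) -> float:
        """Pair agreement over the patient multiset ``idx`` (bootstrap copies
        of a patient are treated as distinct patients)."""
        if stratum == "intratumor":
            tot = self.intratumor_tot[idx].sum()
            return self.intratumor_conc[idx].sum() / tot if tot else np.nan
        if stratum == "intrapatient":
            tot = self.intrapatient_tot[idx].sum()
            return self.intrapatient_conc[idx].sum() / tot if tot else np.nan
        t_c = self.pat_counts[idx].sum(axis=0)
        n = self.pat_n[idx].sum()
        conc = ((t_c ** 2).sum() - self.pat_sumsq[idx].sum()) / 2.0
        tot = (n ** 2 - (self.pat_n[idx] ** 2).sum()) / 2.0
        return conc / tot if tot else np.nan

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _n_pairs(cc: _ClusterCounts, stratum: str) -> int:
    full = np.arange(cc.n_patients)
    if stratum == "intratumor":
        return int(cc.intratumor_tot.sum())
    if stratum == "intrapatient":
        return int(cc.intrapatient_tot.sum())
    n = cc.pat_n.sum()
    return int((n ** 2 - (cc.pat_n ** 2).sum()) / 2.0)


# ---------------------------------------------------------------------------
# agreement estimators


def pair_agreement_exact(calls: pd.DataFrame, stratum: str = "intratumor",
                         pairs: np.ndarray | None = None) -> ConcordanceResult:
    """Exact all-pairs agreement: concordant pairs / total pairs in the stratum.

    ``pairs=None`` with ``stratum="all"`` enumerates every nonmissing pair
    regardless of hierarchy (the all-pairs homogeneity of a small sample set).
    """
    df = _calls_frame(calls).reset_index(drop=True)
    phen = df["phenotype"].to_numpy()
    if pairs is None:
        if stratum == "all":
            i, j = np.triu_indices(len(df), k=1)
            pairs = np.column_stack([i, j])
        else:
            pairs = stratum_pairs(calls, stratum)
    if len(pairs) == 0:
        raise ValueError(f"no nonmissing pair in stratum {stratum!r}")
    agree = phen[pairs[:, 0]] == phen[pairs[:, 1]]
    return ConcordanceResult(stratum=stratum, estimate=float(agree.mean()),
                             n_pairs=len(pairs), method="exact")


def pair_agreement_sampled(calls: pd.DataFrame, stratum: str,
                           n_samples: int, seed: int) -> ConcordanceResult:
    """Monte-Carlo agreement: pairs drawn uniformly with replacement."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    df = _calls_frame(calls).reset_index(drop=True)
    phen = df["phenotype"].to_numpy()
    pairs = stratum_pairs(calls, stratum)
    if len(pairs) == 0:
        raise ValueError(f"no nonmissing pair in stratum {stratum!r}")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(pairs), size=n_samples)
    agree = phen[pairs[pick, 0]] == phen[pairs[pick, 1]]
    return ConcordanceResult(stratum=stratum, estimate=float(agree.mean()),
                             n_pairs=len(pairs), method="sampled",
                             n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# BCa bootstrap


def _percentile(sorted_vals: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of a sorted array, q in [0, 1]."""
    h = q * (len(sorted_vals) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(sorted_vals) - 1)
    return float(sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo]))


def bca_interval(theta_hat: float, theta_boot: np.ndarray,
                 theta_jack: np.ndarray, alpha: float = 0.05):
    """BCa endpoints from a bootstrap sample and jackknife replicates.

    Bias correction z0 is the normal quantile of the fraction of bootstrap
    replicates below the point estimate; acceleration a comes from the
    jackknife skewness; the percentile endpoints are read off the bootstrap
    distribution at the adjusted levels.
    """
    theta_boot = np.asarray(theta_boot, dtype=float)
    theta_boot = theta_boot[~np.isnan(theta_boot)]
    if len(theta_boot) == 0 or np.ptp(theta_boot) == 0:
        if len(theta_boot) and theta_boot[0] != theta_hat:
            return float(theta_boot[0]), float(theta_boot[0])
        return float(theta_hat), float(theta_hat)
    b = len(theta_boot)
    p0 = np.mean(theta_boot < theta_hat)
    p0 = min(max(p0, 0.5 / b), 1.0 - 0.5 / b)  # keep z0 finite
    z0 = stats.norm.ppf(p0)
    d = np.mean(theta_jack) - np.asarray(theta_jack, dtype=float)
    denom = (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0
    z = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    srt = np.sort(theta_boot)
    return _percentile(srt, adj[0]), _percentile(srt, adj[1])


def bca_bootstrap_ci(n_units: int, statistic: Callable[[np.ndarray], float],
                     B: int = 1000, seed: int = 0, alpha: float = 0.05):
    """Generic cluster BCa bootstrap.

    ``statistic`` maps an integer index array (a multiset of resampling units)
    to a scalar; the full sample is ``arange(n_units)``. Returns
    (theta_hat, (ci_low, ci_high)).
    """
    if n_units < 1:
        raise ValueError("need at least one resampling unit")
    full = np.arange(n_units)
    theta_hat = statistic(full)
    if n_units < 2:
        warnings.warn("single resampling unit: zero-width interval")
        return theta_hat, (theta_hat, theta_hat)
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        boot[b] = statistic(rng.integers(0, n_units, size=n_units))
    jack = np.array([statistic(np.delete(full, i)) for i in range(n_units)])
    return theta_hat, bca_interval(theta_hat, boot, jack, alpha=alpha)


def concordance_with_ci(calls: pd.DataFrame, stratum: str, B: int = 1000,
                        seed: int = 0, alpha: float = 0.05) -> ConcordanceResult:
    """Exact stratum agreement with a patient-cluster BCa confidence interval."""
    cc = _ClusterCounts(calls)
    theta, (lo, hi) = bca_bootstrap_ci(
        cc.n_patients, lambda idx: cc.statistic(stratum, idx), B=B, seed=seed,
        alpha=alpha)
    return ConcordanceResult(stratum=stratum, estimate=float(theta),
                             n_pairs=_n_pairs(cc, stratum), method="exact",
                             ci_low=float(lo), ci_high=float(hi), B=B, seed=seed)


# ---------------------------------------------------------------------------
# profile correlations and per-gene comparisons


def stratified_profile_correlation(expr: pd.DataFrame,
                                   annotations: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of expression profiles for every ROI pair, by stratum.

    ``expr`` is genes x ROIs (log2 scale). Zero-variance profiles are skipped;
    the number skipped is recorded in ``DataFrame.attrs["n_skipped"]``.
    """
    ann = annotations.set_index("roi_id")
    rois = [r for r in expr.columns if r in ann.index]
    x = expr[rois].to_numpy(dtype=float)
    var = x.var(axis=0)
    ok = var > 0
    n_skipped = int((~ok).sum())
    rois = [r for r, keep in zip(rois, ok) if keep]
    x = x[:, ok]
    if x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 ROIs with >= 2 genes for profile correlation")
    corr = np.corrcoef(x, rowvar=False)
    pat = ann.loc[rois, "patient_id"].to_numpy()
    tum = ann.loc[rois, "tumor_id"].to_numpy()
    i, j = np.triu_indices(len(rois), k=1)
    same_pat = pat[i] == pat[j]
    same_tum = tum[i] == tum[j]
    stratum = np.where(same_tum, "intratumor",
                       np.where(same_pat, "intrapatient", "interpatient"))
    out = pd.DataFrame({
        "roi_a": np.asarray(rois)[i],
        "roi_b": np.asarray(rois)[j],
        "stratum": stratum,
        "r": corr[i, j],
    })
    out.attrs["n_skipped"] = n_skipped
    return out


def differential_expression(expr_a: pd.DataFrame,
                            expr_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-sided rank-sum comparison of two ROI groups.

    Inputs are genes x samples on log2 scale with matching gene indices.
    Returns a volcano-ready table with the log2 fold change (mean A - mean B),
    the exact two-sided Wilcoxon rank-sum p where sizes permit (scipy switches
    to the tie-corrected normal approximation when ties are present), and
    Benjamini-Hochberg adjusted q-values.
    """
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    genes = expr_a.index.intersection(expr_b.index)
    if genes.empty:
        raise ValueError("no shared genes between groups")
    lfc = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for k, g in enumerate(genes):
        a = expr_a.loc[g].to_numpy(dtype=float)
        b = expr_b.loc[g].to_numpy(dtype=float)
        lfc[k] = a.mean() - b.mean()
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[k] = 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        pvals[k] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"log2_fc": lfc, "p_value": pvals, "q_value": qvals},
                        index=genes)
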