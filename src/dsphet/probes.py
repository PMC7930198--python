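"""Probe-to-gene collapsing with iterative Grubbs outlier removal.

Within each gene's probe group in each ROI, probes whose log2 count is a
statistical outlier (two-sided Grubbs test, alpha = 0.01) are flagged and the
gene's reported count is the geometric mean of the retained probes. Groups
with fewer than three probes are never flagged, and negative-control probes
are exempt (the detection stage consumes them raw).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import log2_counts
from .io import NEGATIVE, ProbeCountMatrix

__all__ = ["grubbs_critical", "flag_outlier_probes", "collapse_to_genes"]

MIN_PROBES_FOR_GRUBBS = 3


def grubbs_critical(n, alpha: float = 0.01) -> np.ndarray:
    """Two-sided Grubbs critical value G for group size(s) n.

    G = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the lower
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.t.ppf(alpha / (2.0 * n), n - 2.0)
        t2 = t * t
        g = (n - 1.0) / np.sqrt(n) * np.sqrt(t2 / (n - 2.0 + t2))
    return np.where(n >= MIN_PROBES_FOR_GRUBBS, g, np.inf)


def _padded_layout(targets: pd.Series):
    """Map probe rows into a dense (gene, slot) layout for vectorized stats."""
    genes, gene_idx = np.unique(targets.to_numpy(), return_inverse=True)
    slot = np.zeros(len(gene_idx), dtype=np.int64)
    seen: dict[int, int] = {}
    for row, g in enumerate(gene_idx):
        slot[row] = seen.get(g, 0)
        seen[g] = slot[row] + 1
    return genes, gene_idx, slot


def flag_outlier_probes(probes: ProbeCountMatrix, alpha: float = 0.01,
                        max_rounds: int | None = None) -> pd.DataFrame:
    """Boolean mask (probes x ROIs), True where a probe is flagged as outlier.

    The Grubbs test is applied per gene per ROI on log2(count floored at 1),
    iteratively: each round flags the single most extreme probe of any group
    whose Grubbs statistic exceeds the alpha critical value, until no group
    flags. Groups shrink as probes are removed; testing stops once a group is
    below three probes, so at least two probes always survive.
    """
    # negative-control probes are exempt (and would blow up the padded
    # layout: they all share one target)
    eligible = ~probes.is_negative
    counts = probes.counts.loc[eligible].to_numpy(dtype=float)
    genes, gene_idx, slot = _padded_layout(probes.targets.loc[eligible])
    n_genes = len(genes)
    max_slot = int(slot.max()) + 1 if len(slot) else 1
    n_rois = counts.shape[1]

    # flat (group, slot) layout: one row per (gene, ROI) group; retained
    # values in ``vals`` (zeros where invalid), validity in ``valid``
    vals = np.zeros((n_genes * n_rois, max_slot))
    valid = np.zeros_like(vals, dtype=bool)
    v3 = vals.reshape(n_genes, n_rois, max_slot)
    m3 = valid.reshape(n_genes, n_rois, max_slot)
    v3[gene_idx, :, slot] = log2_counts(counts)
    m3[gene_idx, :, slot] = True

    flagged = np.zeros_like(valid)
    active = np.arange(vals.shape[0])  # only re-test groups that just changed
    rounds = max_rounds if max_rounds is not None else max_slot
    for _ in range(rounds):
        v, m = vals[active], valid[active]
        n = m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = v.sum(axis=1) / np.maximum(n, 1)
            var = ((v * v).sum(axis=1) - n * mean ** 2) / np.maximum(n - 1, 1)
            sd = np.sqrt(np.maximum(var, 0.0))
            dev = np.where(m, np.abs(v - mean[:, None]), -1.0)
            arg = dev.argmax(axis=1)
            gmax = dev[np.arange(len(dev)), arg]
            gstat = np.where(sd > 0, gmax / sd, 0.0)
        hit = (n >= MIN_PROBES_FOR_GRUBBS) & (gstat > grubbs_critical(n, alpha=alpha))
        if not hit.any():
            break
        # flag the first probe attaining the group maximum (one per group/round)
        rows, cols = active[hit], arg[hit]
        flagged[rows, cols] = True
        valid[rows, cols] = False
        vals[rows, cols] = 0.0
        active = rows

    mask = flagged.reshape(n_genes, n_rois, max_slot)[gene_idx, :, slot]
    out = pd.DataFrame(False, index=probes.counts.index,
                       columns=probes.counts.columns)
    out.loc[eligible] = mask
    return out


def collapse_to_genes(probes: ProbeCountMatrix,
                      mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Collapse probe counts to gene counts (genes x ROIs).

    The gene count is the geometric mean of the retained (unflagged) probes of
    that gene in that ROI. Negative-control probes are excluded from the
    output; they stay probe-level for the LOQ computation.
    """
    keep = ~probes.is_negative
    counts = probes.counts.loc[keep]
    targets = probes.targets.loc[keep]
    if counts.empty:
        raise ValueError("no non-negative probes to collapse")

    logx = log2_counts(counts.to_numpy(dtype=float))
    if mask is not None:
        m = mask.reindex(index=counts.index, columns=counts.columns).fillna(False)
        logx = np.where(m.to_numpy(dtype=bool), np.nan, logx)
        if np.isnan(logx).all(axis=0).any():
            raise ValueError("mask removes every probe of a gene in some ROI")

    genes, gene_idx = np.unique(targets.to_numpy(), return_inverse=True)
    n = np.zeros((len(genes), counts.shape[1]))
    s = np.zeros_like(n)
    valid = ~np.isnan(logx)
    np.add.at(n, gene_idx, valid.astype(float))
    np.add.at(s, gene_idx, np.where(valid, logx, 0.0))
    if (n == 0).any():
        bad = genes[np.nonzero((n == 0).any(axis=1))[0][0]]
        raise ValueError(f"gene {bad!r} has no retained probes in some ROI")
    collapsed = 2.0 ** (s / n)
    out = pd.DataFrame(collapsed, index=pd.Index(genes, name="gene"),
                       columns=counts.columns)
    return out


def process_probes(probes: ProbeCountMatrix, alpha: float = 0.01):
    """Convenience: flag outliers then collapse; returns (gene_counts, mask)."""
    mask = flag_outlier_probes(probes, alpha=alpha)
    return collapse_to_genes(probes, mask), mask
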