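"""Ground-truthed synthetic digital-spatial-profiling cohorts.

The generator emulates a rapid-autopsy style study: patients contribute two
metastatic tumors, each sampled at three regions of interest (ROIs), and every
ROI is assayed with a ~2000-gene in-situ-hybridization panel (median 10
barcoded probes per gene plus 220 negative-control probes) and a ~60-antibody
protein panel (3 IgG controls, 3 housekeeping antibodies). Counts follow a
multiplicative (lognormal) noise model:

    count = round( depth_ROI * 2**(base_gene + effect * activity) *
                   probe_factor * lognormal_error )

so geometric means, geometric SDs and the negative-probe LOQ rule all behave
as they do on real data. Each tumor carries one of the six AR/NE phenotype
classes; AR- and NE-signature genes are shifted (log2 scale) according to the
class's planted activity. Negative probes are drawn from a phenotype-
independent background, which is what makes them usable as detection
controls. A truth table records the hierarchy, planted phenotypes and per-ROI
depth factors for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (NEGATIVE, AlignmentRecord, ProbeCountMatrix,
                 ProteinCountMatrix, SignatureSet)
from .signatures import PHENOTYPE_CLASSES
from .splice import AR_V7_JUNCTION, JunctionInterval

__all__ = [
    "CohortConfig", "PanelConfig", "ProteinPanelConfig", "TruthTable",
    "DEFAULT_CLASS_WEIGHTS", "PHENOTYPE_ACTIVITY", "default_signature_map",
    "generate_cohort", "generate_annotations", "generate_rna_probe_counts",
    "generate_protein_counts", "generate_junction_alignments",
    "simulate_dataset",
]

# planted (AR, NE) activity per class: 1 = fully active, 0.5 = intermediate
PHENOTYPE_ACTIVITY: dict[str, tuple[float, float]] = {
    "AR+/NE-": (1.0, 0.0),
    "ARlow/NE-": (0.5, 0.0),
    "AR-/NE-": (0.0, 0.0),
    "AR-/NElow": (0.0, 0.5),
    "AR+/NE+": (1.0, 1.0),
    "AR-/NE+": (0.0, 1.0),
}

# default class mix of a castration-resistant metastatic cohort: AR-driven
# adenocarcinoma dominates, with small amphicrine and neuroendocrine fractions
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "AR+/NE-": 0.72,
    "ARlow/NE-": 0.06,
    "AR-/NE-": 0.05,
    "AR-/NElow": 0.04,
    "AR+/NE+": 0.06,
    "AR-/NE+": 0.07,
}


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class CohortConfig:
    """Patient / tumor / ROI hierarchy and planted-phenotype layout."""

    n_patients: int = 26
    tumors_per_patient: int = 2
    rois_per_tumor: int = 3
    phenotype_assignment: Mapping[str, str] | None = None  # tumor_id -> class
    class_weights: Mapping[str, float] | None = None  # None -> DEFAULT
    discordant_tumor_fraction: float = 0.08
    discordant_roi_fraction: float = 0.02
    roi_depth_spread: float = 2.0  # geometric SD of per-ROI depth factors
    mean_cd3_per_roi: float = 13.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "tumors_per_patient", "rois_per_tumor"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("discordant_tumor_fraction", "discordant_roi_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.roi_depth_spread < 1.0:
            raise ConfigurationError("roi_depth_spread is a geometric SD >= 1")
        weights = dict(self.class_weights or DEFAULT_CLASS_WEIGHTS)
        unknown = set(weights) - set(PHENOTYPE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown phenotype classes: {sorted(unknown)}")
        total = sum(weights.values())
        if total <= 0:
            raise ConfigurationError("class weights must sum to a positive value")
        self._weights = np.array(
            [weights.get(c, 0.0) / total for c in PHENOTYPE_CLASSES])


def balanced_assignment(config: CohortConfig,
                        discordant_tumor_fraction: float | None = None,
                        seed: int | None = None) -> dict[str, str]:
    """Deterministic tumor -> class map cycling the six classes over patients.

    A validation cohort should represent every class near-equally; random
    patient-level assignment over ~26 patients can leave a class empty, which
    makes recovery statistics meaningless for it. All tumors of a patient
    share the patient's class; optionally a seeded fraction of tumors is
    flipped to a different class to plant intrapatient discordance.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes = list(PHENOTYPE_CLASSES)
    assignment: dict[str, str] = {}
    for p in range(1, config.n_patients + 1):
        patient_class = classes[(p - 1) % len(classes)]
        for t in range(1, config.tumors_per_patient + 1):
            tumor_class = patient_class
            if (discordant_tumor_fraction
                    and rng.random() < discordant_tumor_fraction):
                others = [c for c in classes if c != patient_class]
                tumor_class = others[rng.integers(len(others))]
            assignment[f"P{p:02d}_T{t}"] = tumor_class
    return assignment


def default_signature_map(genes: Sequence[str]) -> dict[str, tuple[str, ...]]:
    """Assign the first panel genes to the five scored signatures.

    Synthetic placeholder memberships: real AR/NE/CCP/FGFR-MEK/RB1-loss gene
    lists live in external references; these sets exist to plant and recover
    signal, not to reproduce published memberships.
    """
    need = 10 + 10 + 8 + 8 + 8
    if len(genes) < need:
        raise ConfigurationError(f"panel needs >= {need} genes for default signatures")
    it = iter(genes)
    take = lambda k: tuple(next(it) for _ in range(k))
    return {"AR": take(10), "NE": take(10), "CCP": take(8),
            "FGFR_MEK": take(8), "RB1loss": take(8)}


@dataclasses.dataclass
class PanelConfig:
    """RNA probe-panel geometry and noise model."""

    n_genes: int = 2093
    probes_per_gene: int = 10  # Poisson median target (min 1 probe)
    n_negative_probes: int = 220
    signature_map: Mapping[str, Sequence[str]] | None = None  # None -> default
    effect_size: float = 2.0  # log2 shift per unit planted activity
    probe_dispersion: float = 1.6  # geometric SD: probe efficiency + noise
    outlier_probe_rate: float = 0.01
    outlier_magnitude: float = 20.0
    neg_background_geomean: float = 20.0
    base_log2_mean: float = 4.5  # non-signature genes: N(mean, sd) log2 baseline
    base_log2_sd: float = 2.5
    signature_base_log2_mean: float = 6.5  # signature genes are well expressed
    signature_base_log2_sd: float = 0.75
    # hierarchical biological variance of non-signature genes (log2 SD): ROIs
    # of one tumor share a tumor effect, tumors of one patient a patient
    # effect — this is what orders intratumor > intrapatient > interpatient
    # profile correlations. Signature genes carry their planted activity
    # instead.
    patient_bio_sd: float = 0.5
    tumor_bio_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_negative_probes < 3:
            raise ConfigurationError("need >= 3 negative probes for the LOQ")
        if self.probe_dispersion < 1.0:
            raise ConfigurationError("probe_dispersion is a geometric SD >= 1")
        if not 0.0 <= self.outlier_probe_rate <= 1.0:
            raise ConfigurationError("outlier_probe_rate must be in [0, 1]")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def signatures(self) -> dict[str, tuple[str, ...]]:
        if self.signature_map is not None:
            sig = {k: tuple(v) for k, v in self.signature_map.items()}
        else:
            sig = default_signature_map(self.gene_ids())
        genes = set(self.gene_ids())
        for name, members in sig.items():
            stray = set(members) - genes
            if stray:
                raise ConfigurationError(
                    f"signature {name!r} has genes outside the panel: {sorted(stray)[:3]}")
        return sig

    def signature_sets(self) -> list[SignatureSet]:
        return [SignatureSet(name=k, genes=v, description="synthetic placeholder set")
                for k, v in self.signatures().items()]


@dataclasses.dataclass
class ProteinPanelConfig:
    """Antibody panel: 57 assay antibodies (3 of them housekeepers) + 3 IgGs."""

    n_antibodies: int = 57
    n_igg: int = 3
    housekeepers: tuple[str, ...] = ("RPS6", "HistoneH3", "GAPDH")
    ar_antibodies: tuple[str, ...] = ("AR",)
    ne_antibodies: tuple[str, ...] = ("SYP",)
    effect_size: float = 2.0
    dispersion: float = 1.4  # geometric SD of antibody noise
    igg_geomean: float = 25.0
    housekeeper_log2_mean: float = 8.2  # depth-tracking targets, well expressed
    base_log2_mean: float = 5.7
    base_log2_sd: float = 1.6

    def __post_init__(self) -> None:
        if self.n_igg < 2:
            raise ConfigurationError("need >= 2 IgG controls")
        if self.dispersion < 1.0:
            raise ConfigurationError("dispersion is a geometric SD >= 1")
        named = len(self.housekeepers) + len(self.ar_antibodies) + len(self.ne_antibodies)
        if self.n_antibodies < named:
            raise ConfigurationError("n_antibodies smaller than the named antibodies")

    def antibody_ids(self) -> list[str]:
        named = [*self.ar_antibodies, *self.ne_antibodies, *self.housekeepers]
        fill = self.n_antibodies - len(named)
        return named + [f"Ab{i:02d}" for i in range(1, fill + 1)]

    def igg_ids(self) -> list[str]:
        return [f"IgG{i}" for i in range(1, self.n_igg + 1)]


@dataclasses.dataclass
class TruthTable:
    """Per-ROI ground truth: hierarchy, phenotype, activities, depth factor."""

    rois: pd.DataFrame
    seed: int

    def __len__(self) -> int:
        return len(self.rois)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_cohort(config: CohortConfig) -> TruthTable:
    """Build the patient/tumor/ROI hierarchy with planted phenotypes.

    Tumors inherit their patient's phenotype and flip to a different class
    with probability ``discordant_tumor_fraction``; ROIs likewise flip from
    their tumor's class with probability ``discordant_roi_fraction``. The
    truth table is byte-identical for identical config + seed.
    """
    rng = _rng(config.seed, 0)
    classes = np.asarray(PHENOTYPE_CLASSES, dtype=object)
    records = []
    assignment = dict(config.phenotype_assignment or {})
    for p in range(1, config.n_patients + 1):
        patient_id = f"P{p:02d}"
        patient_class = rng.choice(classes, p=config._weights)
        for t in range(1, config.tumors_per_patient + 1):
            tumor_id = f"{patient_id}_T{t}"
            if tumor_id in assignment:
                tumor_class = assignment[tumor_id]
                if tumor_class not in PHENOTYPE_ACTIVITY:
                    raise ConfigurationError(
                        f"unknown phenotype {tumor_class!r} for {tumor_id}")
            else:
                tumor_class = patient_class
                if rng.random() < config.discordant_tumor_fraction:
                    tumor_class = _flip_class(rng, tumor_class, config._weights)
            for r in range(1, config.rois_per_tumor + 1):
                roi_class = tumor_class
                if rng.random() < config.discordant_roi_fraction:
                    roi_class = _flip_class(rng, roi_class, config._weights)
                ar, ne = PHENOTYPE_ACTIVITY[roi_class]
                depth = 2.0 ** rng.normal(0.0, np.log2(config.roi_depth_spread))
                records.append({
                    "roi_id": f"{tumor_id}_R{r}",
                    "patient_id": patient_id,
                    "tumor_id": tumor_id,
                    "phenotype": roi_class,
                    "act_AR": ar,
                    "act_NE": ne,
                    "depth_factor": depth,
                })
    rois = pd.DataFrame.from_records(records)
    return TruthTable(rois=rois, seed=config.seed)


def _flip_class(rng: np.random.Generator, current: str, weights: np.ndarray) -> str:
    classes = [c for c in PHENOTYPE_CLASSES if c != current]
    w = np.array([weights[PHENOTYPE_CLASSES.index(c)] for c in classes])
    if w.sum() <= 0:
        w = np.ones(len(classes))
    return rng.choice(np.asarray(classes, dtype=object), p=w / w.sum())


def generate_annotations(truth: TruthTable,
                         config: CohortConfig | None = None) -> pd.DataFrame:
    """ROI annotation table (tissue class, CD3 counts, composition, clean QC).

    CD3+ leukocyte counts are negative-binomial with the configured mean
    (default 13.9 per ROI) and strong overdispersion, matching tumor-rich
    regions that are largely devoid of immune infiltrate but occasionally
    include a hot ROI.
    """
    cfg = config or CohortConfig(seed=truth.seed)
    rng = _rng(truth.seed, 3)
    n = len(truth.rois)
    tissue = rng.choice(np.asarray(["T", "TS", "ST"], dtype=object),
                        p=[0.55, 0.36, 0.09], size=n)
    tumor_pct = np.where(tissue == "T", 100.0,
                         np.where(tissue == "TS",
                                  rng.integers(55, 96, size=n),
                                  rng.integers(10, 50, size=n)))
    stroma_pct = 100.0 - tumor_pct
    size_nb = 0.35  # dispersion of the CD3 counts (variance >> mean)
    p_nb = size_nb / (size_nb + cfg.mean_cd3_per_roi)
    cd3 = rng.negative_binomial(size_nb, p_nb, size=n)
    sites = rng.choice(np.asarray(["liver", "lymph_node", "lung", "bone", "other"],
                                  dtype=object),
                       p=[0.30, 0.29, 0.11, 0.07, 0.23],
                       size=cfg.n_patients * cfg.tumors_per_patient)
    site_by_tumor = dict(zip(pd.unique(truth.rois["tumor_id"]), sites))
    return pd.DataFrame({
        "roi_id": truth.rois["roi_id"],
        "patient_id": truth.rois["patient_id"],
        "tumor_id": truth.rois["tumor_id"],
        "site": truth.rois["tumor_id"].map(site_by_tumor),
        "tissue_class": tissue,
        "cd3_count": cd3,
        "tumor_pct": tumor_pct,
        "stroma_pct": stroma_pct,
        "qc_flags": [""] * n,
    })


def generate_rna_probe_counts(truth: TruthTable,
                              panel: PanelConfig) -> ProbeCountMatrix:
    """Probe-level RNA counts for every ROI of the truth table."""
    if len(truth) == 0:
        raise ConfigurationError("truth table is empty")
    rng = _rng(truth.seed, 1)
    genes = panel.gene_ids()
    signatures = panel.signatures()

    n_probes = np.maximum(1, rng.poisson(panel.probes_per_gene, size=len(genes)))
    gene_of_probe = np.repeat(np.arange(len(genes)), n_probes)
    probe_ids = [f"{genes[g]}_p{k + 1:02d}"
                 for g, cnt in zip(range(len(genes)), n_probes)
                 for k in range(cnt)]

    base = rng.normal(panel.base_log2_mean, panel.base_log2_sd, size=len(genes))
    sig_members = {g for members in signatures.values() for g in members}
    is_sig = np.array([g in sig_members for g in genes])
    base[is_sig] = rng.normal(panel.signature_base_log2_mean,
                              panel.signature_base_log2_sd, size=is_sig.sum())

    # planted activity per gene x ROI: AR/NE follow the phenotype truth,
    # other signatures carry no planted signal (they exercise scoring only)
    n_rois = len(truth.rois)
    shift = np.zeros((len(genes), n_rois))
    gene_index = {g: i for i, g in enumerate(genes)}
    for sig_name, act_col in (("AR", "act_AR"), ("NE", "act_NE")):
        if sig_name in signatures:
            act = truth.rois[act_col].to_numpy(dtype=float)
            for g in signatures[sig_name]:
                shift[gene_index[g]] = panel.effect_size * act

    # patient- and tumor-level biological effects for non-signature genes
    patients, pat_idx = np.unique(truth.rois["patient_id"].to_numpy(),
                                  return_inverse=True)
    tumors, tum_idx = np.unique(truth.rois["tumor_id"].to_numpy(),
                                return_inverse=True)
    bio = np.zeros((len(genes), n_rois))
    if panel.patient_bio_sd > 0:
        pat_eff = rng.normal(0.0, panel.patient_bio_sd,
                             size=(len(genes), len(patients)))
        bio += pat_eff[:, pat_idx]
    if panel.tumor_bio_sd > 0:
        tum_eff = rng.normal(0.0, panel.tumor_bio_sd,
                             size=(len(genes), len(tumors)))
        bio += tum_eff[:, tum_idx]
    bio[is_sig] = 0.0

    log_disp = np.log2(panel.probe_dispersion)
    probe_factor = rng.normal(0.0, log_disp, size=len(gene_of_probe))
    depth_log2 = np.log2(truth.rois["depth_factor"].to_numpy(dtype=float))

    log2_mean = (base[gene_of_probe][:, None] + shift[gene_of_probe]
                 + bio[gene_of_probe]
                 + probe_factor[:, None] + depth_log2[None, :])
    noise = rng.normal(0.0, log_disp, size=log2_mean.shape)
    counts = np.rint(2.0 ** (log2_mean + noise))

    # negatives: phenotype-independent background with the same noise model
    neg_ids = [f"neg{i:03d}" for i in range(1, panel.n_negative_probes + 1)]
    neg_factor = rng.normal(0.0, log_disp, size=panel.n_negative_probes)
    neg_log2 = (np.log2(panel.neg_background_geomean) + neg_factor[:, None]
                + depth_log2[None, :])
    neg_noise = rng.normal(0.0, log_disp, size=neg_log2.shape)
    neg_counts = np.rint(2.0 ** (neg_log2 + neg_noise))

    all_counts = np.vstack([counts, neg_counts])
    if panel.outlier_probe_rate > 0:
        hit = rng.random(all_counts.shape) < panel.outlier_probe_rate
        all_counts = np.where(hit, np.rint(all_counts * panel.outlier_magnitude),
                              all_counts)

    index = pd.Index(probe_ids + neg_ids, name="probe_id")
    targets = pd.Series([genes[g] for g in gene_of_probe] + [NEGATIVE] * len(neg_ids),
                        index=index)
    counts_df = pd.DataFrame(all_counts.astype(np.int64), index=index,
                             columns=truth.rois["roi_id"].to_numpy())
    return ProbeCountMatrix(counts=counts_df, targets=targets)


def generate_protein_counts(truth: TruthTable,
                            panel: ProteinPanelConfig) -> ProteinCountMatrix:
    """Antibody counts: IgGs are phenotype-independent background, housekeepers
    track ROI depth only, AR/NE antibodies follow the planted phenotype."""
    if len(truth) == 0:
        raise ConfigurationError("truth table is empty")
    rng = _rng(truth.seed, 2)
    antibodies = panel.antibody_ids()
    iggs = panel.igg_ids()
    n_rois = len(truth.rois)
    depth_log2 = np.log2(truth.rois["depth_factor"].to_numpy(dtype=float))
    log_disp = np.log2(panel.dispersion)

    base = rng.normal(panel.base_log2_mean, panel.base_log2_sd, size=len(antibodies))
    shift = np.zeros((len(antibodies), n_rois))
    ar_act = truth.rois["act_AR"].to_numpy(dtype=float)
    ne_act = truth.rois["act_NE"].to_numpy(dtype=float)
    for i, ab in enumerate(antibodies):
        if ab in panel.housekeepers:
            base[i] = panel.housekeeper_log2_mean
        elif ab in panel.ar_antibodies:
            shift[i] = panel.effect_size * ar_act
        elif ab in panel.ne_antibodies:
            shift[i] = panel.effect_size * ne_act

    log2_mean = base[:, None] + shift + depth_log2[None, :]
    counts = np.rint(2.0 ** (log2_mean + rng.normal(0.0, log_disp,
                                                    size=log2_mean.shape)))
    igg_log2 = np.log2(panel.igg_geomean) + depth_log2[None, :]
    igg_counts = np.rint(2.0 ** (igg_log2 + rng.normal(
        0.0, log_disp, size=(len(iggs), n_rois))))

    index = pd.Index(antibodies + iggs, name="antibody_id")
    ctype = pd.Series(["housekeeping" if ab in panel.housekeepers else "none"
                       for ab in antibodies] + ["igg"] * len(iggs), index=index)
    counts_df = pd.DataFrame(np.vstack([counts, igg_counts]).astype(np.int64),
                             index=index,
                             columns=truth.rois["roi_id"].to_numpy())
    return ProteinCountMatrix(counts=counts_df, control_type=ctype)


def generate_junction_alignments(srpm_target: float, total_reads: int,
                                 seed: int,
                                 junction: JunctionInterval = AR_V7_JUNCTION,
                                 sample_id: str = "S",
                                 ) -> list[AlignmentRecord]:
    """Alignment records with a Poisson number of junction-spanning gapped reads.

    Of ``total_reads`` records, Poisson(srpm_target * total_reads / 1e6) carry
    an N gap whose skipped interval lies inside the junction; the remainder
    are ungapped, or gapped well away from the junction. Identical arguments
    and seed reproduce the identical record set.
    """
    if srpm_target < 0:
        raise ConfigurationError("srpm_target must be >= 0")
    if total_reads < 0:
        raise ConfigurationError("total_reads must be >= 0")
    rng = np.random.default_rng(seed)
    n_junction = min(int(rng.poisson(srpm_target * total_reads / 1e6)), total_reads)
    n_bg = total_reads - n_junction

    records: list[AlignmentRecord] = []
    span = junction.end - junction.start
    g_start = junction.start + rng.integers(0, max(1, span - 200), size=n_junction)
    g_len = rng.integers(100, 2000, size=n_junction)
    g_len = np.minimum(g_len, junction.end - g_start + 1)
    for k in range(n_junction):
        pos = int(g_start[k]) - 30  # 30M left block ends right before the gap
        cigar = f"30M{int(g_len[k])}N30M"
        records.append(AlignmentRecord(qname=f"{sample_id}_junc{k + 1}",
                                       chrom=junction.chrom, pos=pos, cigar=cigar))

    # background: mostly ungapped, some gapped far upstream of the junction
    gapped_bg = rng.random(n_bg) < 0.15
    bg_pos = rng.integers(1_000_000, 60_000_000, size=n_bg)
    for k in range(n_bg):
        cigar = "30M500N30M" if gapped_bg[k] else "76M"
        records.append(AlignmentRecord(qname=f"{sample_id}_bg{k + 1}",
                                       chrom=junction.chrom, pos=int(bg_pos[k]),
                                       cigar=cigar))
    return records


def simulate_dataset(cohort: CohortConfig | None = None,
                     panel: PanelConfig | None = None,
                     protein_panel: ProteinPanelConfig | None = None) -> dict:
    """One-call cohort simulation; returns truth, annotations, both count
    matrices and the signature sets used to plant the RNA signal."""
    cohort = cohort or CohortConfig()
    panel = panel or PanelConfig()
    protein_panel = protein_panel or ProteinPanelConfig()
    truth = generate_cohort(cohort)
    return {
        "truth": truth,
        "annotations": generate_annotations(truth, cohort),
        "probes": generate_rna_probe_counts(truth, panel),
        "proteins": generate_protein_counts(truth, protein_panel),
        "signature_sets": panel.signature_sets(),
    }
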