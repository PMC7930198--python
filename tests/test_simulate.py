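"""Synthetic cohort generator: hierarchy, noise model, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsphet.detection import compute_protein_loq
from dsphet.io import NEGATIVE, write_sam, read_sam
from dsphet.simulate import (CohortConfig, ConfigurationError, PanelConfig,
                             ProteinPanelConfig, balanced_assignment,
                             generate_annotations, generate_cohort,
                             generate_junction_alignments,
                             generate_protein_counts, generate_rna_probe_counts)
from dsphet.splice import AR_V7_JUNCTION, count_junction_spanning_reads

SMALL_PANEL = dict(n_genes=60, n_negative_probes=20)


def small_cohort(seed=0, **kw):
    defaults = dict(n_patients=4, tumors_per_patient=2, rois_per_tumor=3,
                    seed=seed)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestGenerateCohort:
    def test_minimal_hierarchy(self):
        truth = generate_cohort(CohortConfig(n_patients=1, tumors_per_patient=1,
                                             rois_per_tumor=1, seed=5))
        assert len(truth) == 1

    def test_study_design_26x2x3(self):
        truth = generate_cohort(CohortConfig(seed=0))
        assert len(truth) == 156
        assert truth.rois["tumor_id"].nunique() == 52
        assert truth.rois["patient_id"].nunique() == 26

    def test_determinism_under_seed(self):
        a = generate_cohort(CohortConfig(seed=42)).rois
        b = generate_cohort(CohortConfig(seed=42)).rois
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(CohortConfig(seed=43)).rois
        assert not a["depth_factor"].equals(c["depth_factor"])

    @pytest.mark.parametrize("kw", [
        dict(n_patients=0), dict(rois_per_tumor=0),
        dict(discordant_roi_fraction=1.5), dict(roi_depth_spread=0.5),
    ])
    def test_invalid_config(self, kw):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kw)

    def test_phenotype_assignment_map(self):
        cfg = small_cohort(discordant_tumor_fraction=0.0,
                           discordant_roi_fraction=0.0)
        cfg.phenotype_assignment = balanced_assignment(cfg)
        truth = generate_cohort(cfg)
        by_tumor = truth.rois.groupby("tumor_id")["phenotype"].unique()
        for tumor, phen in by_tumor.items():
            assert list(phen) == [cfg.phenotype_assignment[tumor]]

    def test_discordant_roi_fraction_planted(self):
        cfg = CohortConfig(n_patients=120, discordant_tumor_fraction=0.0,
                           discordant_roi_fraction=0.25, seed=9)
        truth = generate_cohort(cfg)
        dominant = truth.rois.groupby("tumor_id")["phenotype"].agg(
            lambda s: s.mode().iloc[0])
        flipped = (truth.rois["phenotype"].to_numpy()
                   != dominant[truth.rois["tumor_id"]].to_numpy())
        # binomial(720, 0.25): observed fraction within 5 sigma
        assert abs(flipped.mean() - 0.25) < 5 * np.sqrt(0.25 * 0.75 / 720) + 0.02


class TestRnaProbeCounts:
    def test_counts_nonnegative_integers(self):
        probes = generate_rna_probe_counts(generate_cohort(small_cohort()),
                                           PanelConfig(**SMALL_PANEL))
        arr = probes.counts.to_numpy()
        assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)

    def test_degenerate_noise_probes_equal(self):
        cfg = small_cohort(roi_depth_spread=1.0)
        panel = PanelConfig(probe_dispersion=1.0, outlier_probe_rate=0.0,
                            **SMALL_PANEL)
        probes = generate_rna_probe_counts(generate_cohort(cfg), panel)
        for roi in probes.rois:
            sub = probes.gene_counts()[roi].groupby(probes.targets).agg(["min", "max"])
            assert (sub["min"] == sub["max"]).all()

    def test_default_panel_geometry(self):
        panel = PanelConfig()
        truth = generate_cohort(CohortConfig(n_patients=1, tumors_per_patient=1,
                                             rois_per_tumor=1, seed=1))
        probes = generate_rna_probe_counts(truth, panel)
        per_gene = probes.targets[~probes.is_negative].value_counts()
        assert per_gene.median() == 10
        assert int(probes.is_negative.sum()) == 220
        assert per_gene.index.nunique() == 2093

    def test_negative_geomean_recovers_background(self):
        # depth spread off so the per-ROI negative geomean estimates the
        # configured background directly
        cfg = small_cohort(roi_depth_spread=1.0, seed=3)
        panel = PanelConfig(n_genes=50, n_negative_probes=220,
                            neg_background_geomean=20.0, probe_dispersion=1.15,
                            outlier_probe_rate=0.0)
        probes = generate_rna_probe_counts(generate_cohort(cfg), panel)
        neg = probes.negative_counts().to_numpy(dtype=float)
        # Monte-Carlo oracle: the configured lognormal with integer rounding
        rng = np.random.default_rng(99)
        sd = np.log2(panel.probe_dispersion) * np.sqrt(2)  # probe + obs noise
        draws = np.rint(2 ** (np.log2(20.0) + rng.normal(0, sd, size=200_000)))
        oracle = 2 ** np.mean(np.log2(np.maximum(draws, 1)))
        geomeans = 2 ** np.log2(np.maximum(neg, 1)).mean(axis=0)
        assert np.all(np.abs(geomeans / oracle - 1) < 0.05)

    def test_signature_genes_shifted_by_effect(self):
        cfg = small_cohort(roi_depth_spread=1.0, discordant_tumor_fraction=0.0,
                           discordant_roi_fraction=0.0)
        cfg.phenotype_assignment = {t: ("AR+/NE-" if t.endswith("T1") else "AR-/NE-")
                                    for t in balanced_assignment(cfg)}
        panel = PanelConfig(probe_dispersion=1.0, outlier_probe_rate=0.0,
                            effect_size=2.0, **SMALL_PANEL)
        truth = generate_cohort(cfg)
        probes = generate_rna_probe_counts(truth, panel)
        ar_genes = panel.signatures()["AR"]
        probe_ids = probes.targets[probes.targets.isin(ar_genes)].index
        pos = truth.rois.roi_id[truth.rois.phenotype == "AR+/NE-"]
        neg = truth.rois.roi_id[truth.rois.phenotype == "AR-/NE-"]
        ratio = (probes.counts.loc[probe_ids, pos].mean(axis=1)
                 / probes.counts.loc[probe_ids, neg].mean(axis=1))
        assert np.allclose(ratio, 4.0, rtol=0.1)  # 2**effect_size

    def test_negatives_phenotype_independent(self):
        cfg = CohortConfig(n_patients=20, tumors_per_patient=1, rois_per_tumor=3,
                           roi_depth_spread=1.0, seed=8)
        cfg.phenotype_assignment = {f"P{p:02d}_T1": ("AR+/NE+" if p <= 10
                                                    else "AR-/NE-")
                                    for p in range(1, 21)}
        probes = generate_rna_probe_counts(generate_cohort(cfg),
                                           PanelConfig(**SMALL_PANEL))
        truth = generate_cohort(cfg)
        neg = probes.negative_counts()
        a = neg[truth.rois.roi_id[truth.rois.act_AR == 1.0]].to_numpy().ravel()
        b = neg[truth.rois.roi_id[truth.rois.act_AR == 0.0]].to_numpy().ravel()
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_determinism(self):
        cfg = small_cohort(seed=12)
        t = generate_cohort(cfg)
        p1 = generate_rna_probe_counts(t, PanelConfig(**SMALL_PANEL))
        p2 = generate_rna_probe_counts(t, PanelConfig(**SMALL_PANEL))
        pd.testing.assert_frame_equal(p1.counts, p2.counts)

    def test_empty_truth_rejected(self):
        truth = generate_cohort(small_cohort())
        truth.rois = truth.rois.iloc[:0]
        with pytest.raises(ConfigurationError):
            generate_rna_probe_counts(truth, PanelConfig(**SMALL_PANEL))


class TestProteinCounts:
    def test_default_panel_emits_57_plus_3(self):
        prot = generate_protein_counts(generate_cohort(small_cohort()),
                                       ProteinPanelConfig())
        assert (prot.control_type == "igg").sum() == 3
        assert (prot.control_type != "igg").sum() == 57
        assert (prot.control_type == "housekeeping").sum() == 3

    def test_zero_dispersion_constant_within_phenotype(self):
        cfg = small_cohort(roi_depth_spread=1.0, discordant_tumor_fraction=0.0,
                           discordant_roi_fraction=0.0)
        cfg.phenotype_assignment = balanced_assignment(cfg)
        truth = generate_cohort(cfg)
        prot = generate_protein_counts(truth, ProteinPanelConfig(dispersion=1.0))
        for phen, grp in truth.rois.groupby("phenotype"):
            sub = prot.counts[grp.roi_id.to_numpy()]
            assert (sub.nunique(axis=1) == 1).all()

    def test_snr_detection_fraction_matches_generating_oracle(self):
        # plant one antibody near the SNR threshold, compare the detected
        # fraction with a Monte-Carlo application of the SNR rule to the
        # generating parameters
        cfg = CohortConfig(n_patients=60, tumors_per_patient=1,
                           rois_per_tumor=2, roi_depth_spread=1.0, seed=21)
        panel = ProteinPanelConfig(base_log2_mean=np.log2(75.0), base_log2_sd=0.0,
                                   dispersion=1.4, igg_geomean=25.0)
        truth = generate_cohort(cfg)
        prot = generate_protein_counts(truth, panel)
        from dsphet.detection import protein_snr
        snr, det = protein_snr(prot)
        plain = prot.control_type[prot.control_type == "none"].index[3:]
        observed = det.loc[plain].to_numpy().mean()
        rng = np.random.default_rng(7)
        sd = np.log2(panel.dispersion)
        n = 200_000
        ab = np.rint(2 ** (np.log2(75.0) + rng.normal(0, sd, n)))
        igg = np.rint(2 ** (np.log2(25.0) + rng.normal(0, sd, (3, n))))
        igg_gm = 2 ** np.log2(np.maximum(igg, 1)).mean(axis=0)
        expected = (ab / igg_gm >= 3.0).mean()
        n_obs = det.loc[plain].size
        tol = 4 * np.sqrt(expected * (1 - expected) / n_obs) + 0.01
        assert abs(observed - expected) < tol


class TestAnnotations:
    def test_valid_and_cd3_mean(self):
        cfg = CohortConfig(seed=4)
        truth = generate_cohort(cfg)
        ann = generate_annotations(truth, cfg)
        from dsphet.io import validate_annotations
        validate_annotations(ann)
        assert abs(ann["cd3_count"].mean() - 13.9) < 8.0  # overdispersed mean


class TestJunctionAlignments:
    def test_zero_rate_no_junction_reads(self):
        records = generate_junction_alignments(0.0, 5000, seed=1)
        assert len(records) == 5000
        assert count_junction_spanning_reads(records).count == 0

    def test_poisson_rate_recovered(self):
        total, target = 100_000, 2000.0
        records = generate_junction_alignments(target, total, seed=2)
        count = count_junction_spanning_reads(records).count
        lam = target * total / 1e6
        assert abs(count - lam) < 5 * np.sqrt(lam)

    def test_determinism(self):
        a = generate_junction_alignments(5.0, 2000, seed=3)
        b = generate_junction_alignments(5.0, 2000, seed=3)
        assert a == b

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_junction_alignments(-1.0, 100, seed=0)

    def test_sam_roundtrip_preserves_count(self, tmp_path):
        records = generate_junction_alignments(2000.0, 20_000, seed=5)
        path = tmp_path / "reads.sam"
        write_sam(records, path)
        back = read_sam(path)
        assert len(back) == len(records)
        assert (count_junction_spanning_reads(back).count
                == count_junction_spanning_reads(records).count)
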