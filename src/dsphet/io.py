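"""File formats, container types, validation, and small annotation-derived scores.

Formats
-------
* Count matrices are tab-separated: one metadata column block (``probe_id`` +
  ``target`` for RNA probes; ``antibody_id`` + ``control_type`` for protein),
  then one column per ROI. Negative RNA probes carry the target sentinel
  ``NEGATIVE``; protein control types are ``none`` / ``igg`` / ``housekeeping``.
* ROI annotations are CSV with one row per ROI; ``qc_flags`` is a
  semicolon-joined set drawn from {missing, fat, stroma_only, seq_fail}.
* Gene sets use the GMT convention (name, description, genes...).
* Alignments are a plain-text SAM subset read and written through pysam.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

NEGATIVE = "NEGATIVE"
TISSUE_CLASSES = ("T", "TS", "ST", "S")
QC_FLAGS = ("missing", "fat", "stroma_only", "seq_fail")

ANNOTATION_COLUMNS = [
    "roi_id", "patient_id", "tumor_id", "site", "tissue_class",
    "cd3_count", "tumor_pct", "stroma_pct", "qc_flags",
]


class ValidationError(ValueError):
    """Raised when cross-file consistency checks fail."""


class ParseError(ValueError):
    """Raised on malformed input files; message carries the line number."""


# ---------------------------------------------------------------------------
# container types


@dataclasses.dataclass
class ProbeCountMatrix:
    """Raw probe-level counts (probes x ROIs) with a probe -> target mapping.

    ``targets`` maps every probe_id to a gene identifier, or to the
    ``NEGATIVE`` sentinel for negative-control probes.
    """

    counts: pd.DataFrame
    targets: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate probe_id in count matrix")
        self.targets = self.targets.reindex(self.counts.index)
        if self.targets.isna().any():
            missing = self.targets.index[self.targets.isna()][0]
            raise ValidationError(f"probe {missing!r} has no target mapping")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts in probe matrix")

    @property
    def rois(self) -> pd.Index:
        return self.counts.columns

    @property
    def is_negative(self) -> pd.Series:
        return self.targets == NEGATIVE

    def negative_counts(self) -> pd.DataFrame:
        """Counts of the negative-control probes (probes x ROIs)."""
        return self.counts.loc[self.is_negative]

    def gene_counts(self) -> pd.DataFrame:
        """Counts of the non-negative (target) probes."""
        return self.counts.loc[~self.is_negative]


@dataclasses.dataclass
class ProteinCountMatrix:
    """Antibody counts (antibodies x ROIs) with IgG / housekeeping flags."""

    counts: pd.DataFrame
    control_type: pd.Series  # "none" | "igg" | "housekeeping"

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate antibody_id in count matrix")
        self.control_type = self.control_type.reindex(self.counts.index).fillna("none")
        bad = set(self.control_type.unique()) - {"none", "igg", "housekeeping"}
        if bad:
            raise ValidationError(f"unknown control_type values: {sorted(bad)}")

    @property
    def rois(self) -> pd.Index:
        return self.counts.columns

    def igg_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.control_type == "igg"]

    def housekeeping_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.control_type == "housekeeping"]

    def target_counts(self) -> pd.DataFrame:
        """Counts of the assay antibodies (everything that is not an IgG)."""
        return self.counts.loc[self.control_type != "igg"]


@dataclasses.dataclass(frozen=True)
class SignatureSet:
    """A named gene set (unique, nonempty gene list)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")


@dataclasses.dataclass(frozen=True)
class AlignmentRecord:
    """Minimal spliced-alignment carrier: 1-based leftmost position + CIGAR."""

    qname: str
    chrom: str
    pos: int  # 1-based leftmost aligned position
    cigar: str


# ---------------------------------------------------------------------------
# count matrices


def write_probe_counts(matrix: ProbeCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "target", matrix.targets)
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_probe_counts(path: str | Path,
                      column_map: Mapping[str, str] | None = None) -> ProbeCountMatrix:
    """Read a probe-level TSV. ``column_map`` renames nonstandard metadata
    columns to the expected ``probe_id`` / ``target``."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("probe_id", "target"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df = df.set_index("probe_id")
    targets = df.pop("target")
    return ProbeCountMatrix(counts=df, targets=targets)


def write_protein_counts(matrix: ProteinCountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "control_type", matrix.control_type)
    out.to_csv(path, sep="\t", index_label="antibody_id")


def read_protein_counts(path: str | Path,
                        column_map: Mapping[str, str] | None = None) -> ProteinCountMatrix:
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("antibody_id", "control_type"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df = df.set_index("antibody_id")
    ctype = df.pop("control_type")
    return ProteinCountMatrix(counts=df, control_type=ctype)


# ---------------------------------------------------------------------------
# ROI annotations


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    bad = set(ann["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValidationError(f"unknown tissue_class values: {sorted(bad)}")
    if (ann["cd3_count"] < 0).any():
        raise ValidationError("negative cd3_count")
    over = ann["tumor_pct"] + ann["stroma_pct"] > 100 + 1e-9
    if over.any():
        roi = ann.loc[over, "roi_id"].iloc[0]
        raise ValidationError(f"ROI {roi!r}: tumor_pct + stroma_pct > 100")
    for flags in ann["qc_flags"]:
        unknown = set(parse_qc_flags(flags)) - set(QC_FLAGS)
        if unknown:
            raise ValidationError(f"unknown qc flags: {sorted(unknown)}")
    return ann


def parse_qc_flags(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    if isinstance(value, frozenset | set):
        return frozenset(value)
    return frozenset(p for p in str(value).split(";") if p)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["qc_flags"] = [";".join(sorted(parse_qc_flags(v))) for v in out["qc_flags"]]
    out.to_csv(path, index=False)


def read_annotations(path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype={"qc_flags": str}, keep_default_na=True)
    if column_map:
        ann = ann.rename(columns=dict(column_map))
    ann["qc_flags"] = ann["qc_flags"].fillna("")
    return validate_annotations(ann)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> list[SignatureSet]:
    sets: list[SignatureSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            try:
                sets.append(SignatureSet(name=name, genes=tuple(genes), description=desc))
            except ValidationError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from err
    return sets


def write_gmt(sets: Sequence[SignatureSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# SAM text subset


_SAM_HEADER = {"HD": {"VN": "1.6"},
               "SQ": [{"SN": "chrX", "LN": 156_040_895}]}


def write_sam(records: Sequence[AlignmentRecord], path: str | Path,
              chrom_lengths: Mapping[str, int] | None = None) -> None:
    header = dict(_SAM_HEADER)
    if chrom_lengths:
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.qname
            seg.flag = 0
            seg.reference_name = rec.chrom
            seg.reference_start = rec.pos - 1  # pysam is 0-based
            seg.mapping_quality = 255
            seg.cigarstring = rec.cigar
            out.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigarstring is None:
                continue
            records.append(AlignmentRecord(
                qname=seg.query_name,
                chrom=seg.reference_name,
                pos=seg.reference_start + 1,
                cigar=seg.cigarstring,
            ))
    return records


# ---------------------------------------------------------------------------
# dataset loading


def load_dataset(counts_path: str | Path,
                 annotations_path: str | Path,
                 gene_sets_path: str | Path | None = None,
                 kind: str = "rna",
                 column_map: Mapping[str, str] | None = None):
    """Load a count matrix + annotations (+ optional gene sets), cross-validated.

    Every ROI column of the count matrix must have an annotation row; unknown
    ROIs are rejected with a :class:`ValidationError` naming the first one.
    """
    if kind == "rna":
        matrix = read_probe_counts(counts_path, column_map=column_map)
    elif kind == "protein":
        matrix = read_protein_counts(counts_path, column_map=column_map)
    else:
        raise ValueError(f"kind must be 'rna' or 'protein', got {kind!r}")
    ann = read_annotations(annotations_path)
    known = set(ann["roi_id"])
    unknown = [r for r in matrix.rois if r not in known]
    if unknown:
        raise ValidationError(
            f"ROI {unknown[0]!r} in count matrix has no annotation row "
            f"({len(unknown)} unannotated ROIs total)")
    sets: list[SignatureSet] = []
    if gene_sets_path is not None:
        sets = read_gmt(gene_sets_path)
    return matrix, ann, sets


# ---------------------------------------------------------------------------
# immunohistochemistry H-score


def ihc_hscore(pct_at_intensity: Mapping[int, float]) -> float:
    """H-score: sum of (staining intensity x percentage of cells), range 0-200.

    Intensities are 0 (none), 1 (weak), 2 (strong); the percentages must sum
    to 100.
    """
    unknown = set(pct_at_intensity) - {0, 1, 2}
    if unknown:
        raise ValueError(f"unknown staining intensities: {sorted(unknown)}")
    total = sum(pct_at_intensity.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"percentages must sum to 100, got {total}")
    if any(p < 0 for p in pct_at_intensity.values()):
        raise ValueError("negative percentage")
    return float(sum(i * p for i, p in pct_at_intensity.items()))


def ihc_average(scores: Sequence[float | None]) -> float:
    """Average replicate H-scores, ignoring missing replicates.

    Triplicate scores are averaged; with one replicate missing the remaining
    two are averaged, and so on. All-missing input is an error.
    """
    present = [s for s in scores if s is not None]
    if not present:
        raise ValueError("no replicate scores present")
    return float(np.mean(present))
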