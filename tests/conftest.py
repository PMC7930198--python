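import numpy as np
import pandas as pd
import pytest

from dsphet.io import NEGATIVE, ProbeCountMatrix


def probe_matrix(genes: dict[str, list[list[int]]],
                 negatives: list[list[int]] | None = None,
                 roi_prefix: str = "roi") -> ProbeCountMatrix:
    """Build a ProbeCountMatrix from {gene: probes x ROIs count lists}."""
    rows, targets, index = [], [], []
    n_rois = None
    for gene, probe_rows in genes.items():
        for k, counts in enumerate(probe_rows, start=1):
            rows.append(counts)
            targets.append(gene)
            index.append(f"{gene}_p{k}")
            n_rois = len(counts)
    for k, counts in enumerate(negatives or [], start=1):
        rows.append(counts)
        targets.append(NEGATIVE)
        index.append(f"neg_{k}")
        n_rois = len(counts)
    cols = [f"{roi_prefix}{j + 1}" for j in range(n_rois)]
    counts = pd.DataFrame(np.asarray(rows), index=pd.Index(index, name="probe_id"),
                          columns=cols)
    return ProbeCountMatrix(counts=counts, targets=pd.Series(targets, index=counts.index))


def calls_table(phenotypes: list[str], patients: list[str],
                tumors: list[str]) -> pd.DataFrame:
    """Phenotype-call table in the layout the concordance module expects."""
    return pd.DataFrame({
        "patient_id": patients,
        "tumor_id": tumors,
        "phenotype": phenotypes,
    }, index=pd.Index([f"r{i}" for i in range(len(phenotypes))], name="roi_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
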