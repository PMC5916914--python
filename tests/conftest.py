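import numpy as np
import pandas as pd
import pytest

from methvar import BetaMatrix, ProbeAnnotation, QCMetrics, SampleSheet
from methvar.core import build_probe_annotation


def make_paired_sheet(n_conv=3, n_nonc=4):
    """Sample sheet for a fully paired two-group cohort."""
    subjects = [f"C{i}" for i in range(n_conv)] + [f"N{i}" for i in range(n_nonc)]
    groups = ["converter"] * n_conv + ["nonconverter"] * n_nonc
    rows = []
    for subj, grp in zip(subjects, groups):
        for tp in ("M0", "MF"):
            rows.append({"sample_id": f"{subj}_{tp}", "subject_id": subj,
                         "group": grp, "timepoint": tp})
    return SampleSheet(pd.DataFrame(rows))


def make_betas(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))


def random_betas(rng, n_probes, sheet):
    samples = list(sheet.data["sample_id"])
    vals = rng.uniform(0.02, 0.98, (n_probes, len(samples)))
    return make_betas(vals, samples=samples)


@pytest.fixture
def paired_sheet():
    return make_paired_sheet()


@pytest.fixture
def annotation():
    table = pd.DataFrame({
        "probe_id": ["cg00000000", "cg00000001", "cg00000002", "cg00000003"],
        "chrom": ["chr1", "chr8", "chrX", "chr2"],
        "pos": [100, 129702875, 500, 900],
        "gene": ["GENE1", "", "XG", "GENE2;GENE3"],
        "flags": [None, None, None, "snp_probe;cross_reactive"],
    })
    return build_probe_annotation(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1)
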