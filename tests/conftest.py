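import numpy as np
import pytest

from neoprior.dataset_assembly import (
    LABEL_IMMUNOGENIC,
    LABEL_NON_IMMUNOGENIC,
    PHLATCRComplex,
)
from neoprior.feature_engine import FeatureRow
from neoprior.repertoire import Clonotype, ClonotypeTable


@pytest.fixture
def small_table():
    return ClonotypeTable(
        sample_id="s1",
        clonotypes=[
            Clonotype("CASSL", "TRBV1", "TRBJ1", 1),
            Clonotype("CASSQ", "TRBV1", "TRBJ2", 1),
            Clonotype("CASSR", "TRBV2", "TRBJ1", 4),
        ],
    )


@pytest.fixture
def airr_tsv(tmp_path):
    def _write(rows, name="sample.tsv", header=None):
        header = header or ["junction_aa", "v_call", "j_call", "duplicate_count"]
        lines = ["\t".join(header)]
        lines += ["\t".join(str(x) for x in row) for row in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def positives():
    return [
        PHLATCRComplex("SIINFEKLAA", "HLA-A*02:01", "CASSLGAA", LABEL_IMMUNOGENIC, "x"),
        PHLATCRComplex("GILGFVFTL", "HLA-A*02:01", "CASSIRSS", LABEL_IMMUNOGENIC, "x"),
        PHLATCRComplex("NLVPMVATV", "HLA-B*07:02", "CASSQETQ", LABEL_IMMUNOGENIC, "x"),
    ]


@pytest.fixture
def tcr_pool():
    rng = np.random.default_rng(7)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    return [
        "C" + "".join(rng.choice(aa, size=12)) + "F" for _ in range(50)
    ]


def make_rows(phla, ptcr, labels):
    """Build FeatureRows from parallel feature/label sequences."""
    out = []
    for i, (a, b, lab) in enumerate(zip(phla, ptcr, labels)):
        label = LABEL_IMMUNOGENIC if lab else LABEL_NON_IMMUNOGENIC
        out.append(FeatureRow(key=(f"PEP{i}", "HLA-A*02:01"), phla_rank=a,
                              ptcr_rank=b, label=label))
    return out
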