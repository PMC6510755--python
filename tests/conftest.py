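import numpy as np
import pytest

from petguard import generate_cohort
from petguard.model import TrainingConfig, split_patients
from petguard.orchestration import project_cohort, run_sex_fold


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 desk-scale phantom patients with rendered MIP sets."""
    records = generate_cohort(30, seed=5)
    mips, truths = project_cohort(records)
    return records, mips, truths


@pytest.fixture(scope="session")
def tiny_trained(tiny_cohort):
    """A quickly trained sex classifier plus its held-out evaluation."""
    _, mips, truths = tiny_cohort
    train_ids, test_ids = split_patients(sorted(mips), 0.7, seed=5)
    report, preds = run_sex_fold(
        mips,
        truths,
        train_ids,
        test_ids,
        train_cfg=TrainingConfig(seed=5, max_epochs=2, patience=2),
        seed=5,
    )
    return {
        "model": report.model,
        "report": report,
        "preds": preds,
        "mips": mips,
        "truths": truths,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
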