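import numpy as np
import pytest

from vividstats.synthetic_cohort import GroupSpec, generate_subjects, generate_trials

#: Fixed seed for every seeded test in the suite.
SEED = 12345


@pytest.fixture(scope="session")
def subjects_small():
    """20 subjects in two well-separated VVIQ groups."""
    spec = {
        "high": GroupSpec(10, 75.5, 2.72, female_ratio=0.6),
        "low": GroupSpec(10, 41.9, 11.99, female_ratio=0.5),
    }
    return generate_subjects(20, spec, plant_extremes=True, seed=SEED)


@pytest.fixture(scope="session")
def trials_one_subject():
    """Default 120-trial table (30 per condition) for a single subject."""
    return generate_trials("S001", seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def make_trial_row(
    target=(100.0, 100.0),
    response=(100.0, 100.0),
    nts=None,
    identified=True,
    rt=1.0,
    subject_id="S001",
    block=1,
    delay_s=1,
):
    """One trials-table row with explicit geometry (3-item iff nts given)."""
    n_items = 3 if nts else 1
    nts = nts or ((np.nan, np.nan), (np.nan, np.nan))
    return {
        "subject_id": subject_id,
        "block": block,
        "n_items": n_items,
        "delay_s": delay_s,
        "target_x": target[0],
        "target_y": target[1],
        "nt1_x": nts[0][0],
        "nt1_y": nts[0][1],
        "nt2_x": nts[1][0],
        "nt2_y": nts[1][1],
        "identified_correctly": identified,
        "response_x": response[0],
        "response_y": response[1],
        "response_time_s": rt,
    }
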