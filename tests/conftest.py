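import warnings

import pytest

from ccdm import behavior, design, synthetic_data

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """paper_like cohort, 6 subjects, fixed seed; shared across tests."""
    truth = synthetic_data.default_ground_truth("paper_like", n_subjects=6)
    table = synthetic_data.simulate_cohort(truth, seed=101)
    return truth, table


@pytest.fixture(scope="session")
def small_cohort_filtered(small_cohort):
    _, table = small_cohort
    rt_tbl, rt_rep = behavior.filter_trials(table, purpose="rt_analysis")
    ddm_tbl, ddm_rep = behavior.filter_trials(table, purpose="ddm")
    return {"rt": rt_tbl, "rt_report": rt_rep, "ddm": ddm_tbl, "ddm_report": ddm_rep}


@pytest.fixture(scope="session")
def unisensory_schedule():
    old, new = design.sample_display_sets(7)
    return design.build_session_schedule(design.UNISENSORY, old, new, seed=11)


@pytest.fixture(scope="session")
def multisensory_schedule():
    old, new = design.sample_display_sets(8)
    return design.build_session_schedule(design.MULTISENSORY, old, new, seed=12)
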