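import pytest

from oligoscreen.panels import TransitionKey, load_panel_registry
from oligoscreen.quantify import (PeakAreaTable, SampleMeta, adjust_creatinine,
                                  compute_ratio_profile)
from oligoscreen.reference import build_reference, compute_mom


@pytest.fixture(scope="session")
def registry():
    return load_panel_registry()


@pytest.fixture(scope="session")
def is_key_neg(registry):
    return registry.is_keys("negative")[0]


@pytest.fixture(scope="session")
def is_key_pos(registry):
    return registry.is_keys("positive")[0]


def single_transition_mom(registry, key, matrix, control_area, patient_area,
                          is_area=1000.0, n_controls=11, creatinine_mM=1.0,
                          dilution_applied=True):
    """End-to-end MoM on one transition: build a reference from identical
    controls carrying only that transition plus the matching-polarity IS,
    then score one patient through ratio -> creatinine adjust -> MoM."""
    is_key = registry.is_keys(key.polarity)[0]

    def profile(sid, area, creat, diluted):
        table = PeakAreaTable(sample_id=sid, entries={key: area, is_key: is_area})
        meta = SampleMeta(sample_id=sid, matrix=matrix, creatinine_mM=creat,
                          dilution_applied=diluted)
        return adjust_creatinine(compute_ratio_profile(table, registry), meta)

    controls = [profile(f"ctrl{i}", control_area, 1.0, True) for i in range(n_controls)]
    ref = build_reference(controls, matrix)
    patient = profile("patient", patient_area, creatinine_mM, dilution_applied)
    return compute_mom(patient, ref).moms[key]


@pytest.fixture(scope="session")
def worked_example():
    return single_transition_mom
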