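import numpy as np
import pandas as pd
import pytest

from nhqi import QIDefinition, SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def prevalence_qi() -> QIDefinition:
    """Cross-sectional adverse-outcome QI over the synthetic item vocabulary."""
    return QIDefinition(
        qi_id="PRU01",
        description="pressure ulcer prevalence",
        scope="cross_sectional",
        numerator_rule={"item": "pressure_ulcer", "op": "==", "value": 1},
        denominator_rule=True,
        covariate_names=("cognition_scale", "comorbidity_index"),
        stratifier_name="adl_long_form",
    )


@pytest.fixture(scope="session")
def change_qi() -> QIDefinition:
    """Worsening-pain QI evaluated on consecutive-quarter record pairs."""
    return QIDefinition(
        qi_id="PAN01",
        description="worsening pain",
        scope="change",
        numerator_rule={"item": "pain_level", "op": ">", "value": {"item": "pain_level@baseline"}},
        denominator_rule={"item": "pain_level@baseline", "op": "<=", "value": 1},
        covariate_names=("cognition_scale", "comorbidity_index"),
        stratifier_name="adl_long_form",
    )


def make_panel(rows: list[dict]) -> pd.DataFrame:
    """Build a small panel from row dicts, filling structural defaults."""
    frame = pd.DataFrame(rows)
    for col, default in (("new_admission", False), ("quarter", 1)):
        if col not in frame.columns:
            frame[col] = default
    return frame


@pytest.fixture(scope="session")
def toy_panel() -> pd.DataFrame:
    """3 facilities x 8 residents, one quarter, hand-checkable outcome flags.

    Facility A: 2 of 8 trigger; B: 0 of 8; C: 8 of 8.  One extra excluded
    (new admission, triggering) resident per facility must not count.
    """
    rows = []
    rng = np.random.default_rng(7)
    for fac, n_trigger in (("A", 2), ("B", 0), ("C", 8)):
        for r in range(8):
            rows.append({
                "resident_id": f"{fac}{r}",
                "facility_id": fac,
                "quarter": 1,
                "new_admission": False,
                "pressure_ulcer": 1 if r < n_trigger else 0,
                "cognition_scale": float(rng.normal()),
                "comorbidity_index": float(rng.normal()),
                "adl_long_form": float(rng.normal()),
            })
        rows.append({
            "resident_id": f"{fac}_new",
            "facility_id": fac,
            "quarter": 1,
            "new_admission": True,
            "pressure_ulcer": 1,
            "cognition_scale": 0.0,
            "comorbidity_index": 0.0,
            "adl_long_form": 0.0,
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_world():
    """A small default-structure synthetic world shared across tests."""
    config = SimulationConfig(n_facilities=40, residents_per_facility=40, seed=11)
    panel, truth = simulate_panel(config)
    return config, panel, truth
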