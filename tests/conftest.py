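import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def term_set():
    from thrombosignal.terms import default_term_set

    return default_term_set()


@pytest.fixture()
def tiny_rows():
    """Hand-enumerable integrated table: 4 cases, 3 drugs, 4 PTs."""
    data = [
        ("C1", "DRUGA", "DEEP VEIN THROMBOSIS"),
        ("C1", "DRUGA", "HEADACHE"),
        ("C2", "DRUGA", "PULMONARY EMBOLISM"),
        ("C2", "DRUGA", "NAUSEA"),
        ("C3", "DRUGB", "HEADACHE"),
        ("C3", "DRUGB", "NAUSEA"),
        ("C4", "DRUGC", "DEEP VEIN THROMBOSIS"),
        ("C4", "DRUGC", "HEADACHE"),
        ("C4", "DRUGC", "NAUSEA"),
        ("C4", "DRUGC", "PULMONARY EMBOLISM"),
    ]
    return pd.DataFrame(data, columns=["case_id", "drug_name", "pt"])
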