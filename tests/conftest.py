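import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230417)


@pytest.fixture
def small_table():
    """Hand-built valid token table: 3 speakers, 2 styles, all unit types."""
    from phonlr.data_model import TokenTable

    rows = []
    rng = np.random.default_rng(5)
    for spk in ("alice", "bob", "carol"):
        for style in ("dialogue", "interview"):
            for k in range(6):
                f1 = rng.uniform(300, 600)
                rows.append(
                    {
                        "speaker": spk, "style": style, "unit_type": "vowel",
                        "vowel_quality": "a", "chunk_id": "",
                        "F1": f1, "F2": f1 + 900, "F3": f1 + 2000, "F4": f1 + 3100,
                        "duration_ms": rng.uniform(40, 150),
                    }
                )
                rows.append(
                    {
                        "speaker": spk, "style": style, "unit_type": "vv_unit",
                        "vowel_quality": "", "chunk_id": "",
                        "duration_ms": rng.uniform(100, 300),
                    }
                )
                rows.append(
                    {
                        "speaker": spk, "style": style, "unit_type": "silent_pause",
                        "vowel_quality": "", "chunk_id": "",
                        "duration_ms": rng.uniform(100, 900),
                    }
                )
                rows.append(
                    {
                        "speaker": spk, "style": style, "unit_type": "chunk",
                        "vowel_quality": "", "chunk_id": f"{spk}-{style}-c{k}",
                        "f0_median_st": rng.uniform(80, 86),
                        "f0_base_st": rng.uniform(75, 80),
                    }
                )
    return TokenTable(pd.DataFrame(rows))
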