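import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def units_frame(sp, p, **outcomes) -> pd.DataFrame:
    """Weighted-unit frame for causal tests: scores, IPW weights, outcomes."""
    sp = np.asarray(sp, dtype=int)
    p = np.asarray(p, dtype=float)
    frame = pd.DataFrame({"SP": sp, "p": p})
    frame["weight"] = np.where(sp == 1, 1.0 / p, 1.0 / (1.0 - p))
    frame["trimmed"] = False
    for name, vals in outcomes.items():
        frame[name] = np.asarray(vals, dtype=float)
    return frame


@pytest.fixture(scope="session")
def weekly_table():
    """One synthetic account-week table (study-default shape, fixed seed)."""
    from tweetfx.simulate import SyntheticConfig, generate_weekly

    frame, truth = generate_weekly(SyntheticConfig(seed=0))
    return frame, truth
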