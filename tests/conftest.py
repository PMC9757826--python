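import numpy as np
import pandas as pd
import pytest

from decoychoice.synth import GeneratorConfig, generate_choice_sets


def make_trials(rows, deadline=1.5):
    """Build a trials DataFrame from (condition, hx, hp, lx, lp, dx, dp, choice, rt)."""
    df = pd.DataFrame(
        rows, columns=["condition", "hx", "hp", "lx", "lp", "dx", "dp", "choice", "rt"]
    )
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(0, "subject", "s1")
    return df


@pytest.fixture()
def toy_trials():
    return make_trials(
        [
            ("binary", 0.8, 0.6, 0.5, 0.7, np.nan, np.nan, "H", 0.8),
            ("binary", 0.8, 0.6, 0.5, 0.7, np.nan, np.nan, "L", 1.1),
            ("ternary", 0.8, 0.6, 0.5, 0.7, 0.4, 0.5, "H", 0.9),
            ("ternary", 0.8, 0.6, 0.5, 0.7, 0.7, 0.8, "L", 1.0),
        ]
    )


@pytest.fixture(scope="session")
def design():
    """A generated study-structure design (150 ternary + 150 binary trials)."""
    return generate_choice_sets(GeneratorConfig(seed=21))
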