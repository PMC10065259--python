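import numpy as np
import pandas as pd
import pytest

import momfa


@pytest.fixture
def tiny_counts():
    return momfa.OmicView(
        "toy",
        ["G1", "G2", "G3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [1.0, 2.0], [2.0, 4.0]]),
        "counts",
    )


@pytest.fixture
def meta6():
    """Six samples, two mice, three weeks, one view's worth of metadata."""
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(1, 7)],
            "mouse_id": ["m1", "m1", "m1", "m2", "m2", "m2"],
            "group": ["WT"] * 3 + ["mdx"] * 3,
            "week": [6, 12, 18, 6, 12, 18],
            "tissue": ["blood"] * 6,
        }
    )


# Heterogeneous per-view variance shares: every factor clears 10% in every
# view but is dominant in a different one, which pins down the factor axes.
RECOVERY_SHARES = {
    "muscle_rna": np.array([0.40, 0.10, 0.10, 0.12]),
    "blood_rna": np.array([0.10, 0.40, 0.12, 0.10]),
    "lipids": np.array([0.12, 0.10, 0.40, 0.10]),
    "metabolites": np.array([0.10, 0.12, 0.10, 0.40]),
}

RECOVERY_FEATURES = {
    "muscle_rna": 60,
    "blood_rna": 60,
    "lipids": 40,
    "metabolites": 30,
}


@pytest.fixture
def recovery_study():
    ps, z = momfa.make_gaussian_study(100, RECOVERY_FEATURES, RECOVERY_SHARES, seed=11)
    return ps, z


@pytest.fixture(scope="session")
def small_study():
    """A reduced but complete four-view longitudinal study."""
    design = momfa.StudyDesign(n_mice_per_group=4)
    truth = momfa.TruthModel(
        n_features={"muscle_rna": 300, "blood_rna": 300, "lipids": 120,
                    "metabolites": 60}
    )
    return momfa.simulate_study(design, truth, seed=5)
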