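import numpy as np
import pytest

from partgmm import PanelDataset, SyntheticSpec, generate_panel


@pytest.fixture
def tiny_panel():
    """2 subjects x 4 waves, 1 time-dependent + 1 fixed covariate, by hand."""
    return PanelDataset(
        subject_ids=np.array([101, 202]),
        y=np.array([[1, 0, 1, 1], [0, 0, 1, 0]]),
        x_td=np.array([[1, 0, 1, 1], [0, 1, 1, 0]])[:, :, None],
        td_names=["x1"],
        x_fixed=np.array([[1.0], [0.0]]),
        fixed_names=["male"],
        wave_labels=[2005, 2008, 2011, 2014],
    )


@pytest.fixture
def default_panel():
    """Moderate panel from the default generator settings (exact marginal model)."""
    return generate_panel(SyntheticSpec(n_subjects=800, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
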