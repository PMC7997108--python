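import numpy as np
import pytest

from sersils.spectra import DEFAULT_METHODS
from sersils.synthetic import SyntheticConfig, generate_collection, noise_free_config


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """One colloidal method, two labs, short axis: fast but full-featured."""
    base = dict(
        methods=(DEFAULT_METHODS[1],),  # cAg@785, colloidal: 3 replicates
        labs_per_method=2,
        cal_concentrations=tuple(np.geomspace(1.0, 100.0, 5)),
        test_concentrations=tuple(np.geomspace(2.0, 80.0, 5)),
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def clean_collection():
    """Noise-free linear two-lab collection with its truth record."""
    cfg = noise_free_config(11)
    d = {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
    d.update(methods=(DEFAULT_METHODS[1],), labs_per_method=2)
    return generate_collection(SyntheticConfig(**d))


@pytest.fixture
def noisy_dataset():
    """One realistic noisy dataset."""
    cfg = small_config(
        seed=5,
        lab_gain_sd=0.15,
        replicate_sd=0.1,
        noise_sd_additive=2.0,
        noise_sd_proportional=0.01,
        baseline_poly_coeffs=(250.0, -120.0, 60.0),
    )
    collection, truth = generate_collection(cfg)
    return collection[0]
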