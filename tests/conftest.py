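import numpy as np
import pytest

from penstroke.preprocess import RowInstance
from penstroke.synth import GeneratorConfig, SubjectProfile, render_sheet


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def hs_sheet(default_config):
    """One clean healthy-subject sheet at the cohort-mean parameters."""
    profile = SubjectProfile(
        "HS-fix", "HS", base_area_mm2=126.72, seq_effect=1.05
    )
    page, gt = render_sheet(profile, "sentence", default_config, seed=7)
    return page, gt


@pytest.fixture(scope="session")
def pd_sheet(default_config):
    """One clean PD sheet with a shrinking sequence effect."""
    profile = SubjectProfile(
        "PD-fix", "PD", stage="early", state="OFF",
        base_area_mm2=89.78, seq_effect=0.92,
    )
    page, gt = render_sheet(profile, "sentence", default_config, seed=11)
    return page, gt


def make_toy_instances(n_per_class: int = 30, noise: float = 0.05, seed: int = 0,
                       shape=(32, 96)):
    """Linearly separable toy instances: an ink blob on the left or right."""
    rng = np.random.default_rng(seed)
    instances, labels = [], []
    for cls in (0, 1):
        for i in range(n_per_class):
            img = np.ones(shape, dtype=np.float32)
            if cls == 0:
                img[8:24, 10:34] = 0.0
            else:
                img[8:24, 60:84] = 0.0
            img = np.clip(img + rng.normal(0, noise, shape), 0, 1).astype(np.float32)
            instances.append(
                RowInstance(f"subj-{cls}-{i}", "toy", 1, img, 0.1, (0, 0, 1, 1))
            )
            labels.append(cls)
    return instances, np.asarray(labels)


@pytest.fixture()
def toy_instances():
    return make_toy_instances()
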