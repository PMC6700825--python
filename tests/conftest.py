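import numpy as np
import pandas as pd
import pytest

from pescreen.cohort import pe_status_frame
from pescreen.mom import MoMTransformer
from pescreen.pipeline import mom_input_frame
from pescreen.simulate import default_config, generate


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study-flow config (~800 pregnancies) for fast tests."""
    return default_config(n_total=800, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Generated small cohort with its latent draws."""
    frame, latent = generate(small_config, return_latent=True)
    return frame, latent


@pytest.fixture(scope="session")
def small_scored(small_config, small_cohort):
    """MoM frame + PE status for the small cohort (shipped median model)."""
    frame, _ = small_cohort
    transformer = MoMTransformer(median_model=small_config.median_model).fit(None)
    moms = transformer.transform(mom_input_frame(frame))
    return moms, pe_status_frame(frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def cohort_csv(tmp_path, small_cohort):
    from pescreen.cohort import write_cohort

    frame, _ = small_cohort
    path = tmp_path / "cohort.csv"
    write_cohort(frame, path)
    return path
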