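import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Four study-scale head phantoms, one asymmetric."""
    from negvol.studies import make_study_cohort

    return make_study_cohort(4, seed=11, n_asymmetric=1)


@pytest.fixture(scope="session")
def toy_models(small_cohort):
    """Toy localization + segmentation models trained on the last three
    heads of the small cohort (one of them asymmetric); the first head
    stays held out."""
    from negvol.studies import (
        LOC_TRAIN,
        SEG_TRAIN,
        train_localization_model,
        train_segmentation_model,
    )

    # three heads give only six patches, so the toy net needs a longer
    # schedule than the ten-head study to converge
    seg_cfg = dataclasses.replace(SEG_TRAIN, epochs=60)
    seg, _ = train_segmentation_model(small_cohort[1:], train_cfg=seg_cfg, seed=0)
    loc, _ = train_localization_model(small_cohort[1:], train_cfg=LOC_TRAIN, seed=0)
    return {"seg": seg, "loc": loc}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
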