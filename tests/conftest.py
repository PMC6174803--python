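import warnings

import numpy as np
import pytest

from ropseg.phantom import PhantomParams, generate_cohort
from ropseg.pipeline import JointSegmentationModel


@pytest.fixture(scope="session")
def cohort2d():
    """Eight fast-2D phantom subjects sharing one base anatomy (seed 5)."""
    return generate_cohort(8, PhantomParams.fast_2d(seed=5))


@pytest.fixture(scope="session")
def fitted(cohort2d):
    """Pipeline fitted on the first six subjects of the 2D cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return JointSegmentationModel(cohort2d[:6]).fit()


@pytest.fixture(scope="session")
def held_out_segmentations(fitted, cohort2d):
    """Fine/coarse masks and tumor predictions for the two held-out subjects."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for vol, liver, tumor in cohort2d[6:]:
            seg = fitted.segment(vol, keep_intermediates=True)
            pred_tumor = fitted.segment_tumor(vol, seg.fine)
            out.append({"volume": vol, "liver": liver, "tumor": tumor,
                        "seg": seg, "pred_tumor": pred_tumor})
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
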