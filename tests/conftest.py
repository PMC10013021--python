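import numpy as np
import pandas as pd
import pytest

from cardiosleep.core import Hypnogram
from cardiosleep.synth import ModelError, StageResp, StageRR, scenario

T0 = pd.Timestamp("2000-01-01 20:00:00")


def make_hypnogram(stages, start=T0, source="test"):
    return Hypnogram(start=start, stages=np.array(stages, dtype=object),
                     source=source)


@pytest.fixture
def flat_stage_resp():
    """Identical breathing in every stage: 15 breaths/min, no variability."""
    return {s: StageResp(rate_mean=15.0, rate_cv=0.0, amp_cv=0.0)
            for s in ("W", "N1", "N2", "N3", "R")}


@pytest.fixture
def flat_stage_rr():
    """Constant 1000-ms heart rhythm, no variability, no oscillation."""
    return {s: StageRR(rr_mean_ms=1000.0, rmssd_ms=0.0, lf_hf_ratio=0.0)
            for s in ("W", "N1", "N2", "N3", "R")}


@pytest.fixture
def adjacent_error():
    """Substitution error whose confusion mass sits on adjacent stages."""
    cfg = scenario("icu-like", duration_h=1.0)
    return ModelError(substitution_rate=0.25,
                      confusion_bias=cfg.model_error.confusion_bias)
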