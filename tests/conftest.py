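import pandas as pd
import pytest

from peristartle import synth
from peristartle.scoring import score_cohort

#: cohorts in the shared Monte-Carlo batch (calibration-level checks)
N_BATCH = 500


@pytest.fixture(scope="session")
def default_cfg():
    return synth.default_config()


@pytest.fixture(scope="session")
def cohort_batch(default_cfg):
    """500 default-config cohorts, generated and scored once per run.

    One row per animal with endpoints, latent truth, ranks, composite
    score, decline ratios/labels, subgroup, and the cohort seed.
    """
    frames = []
    for s in range(1, N_BATCH + 1):
        df = synth.generate_cohort(default_cfg, seed=s).to_frame()
        scored = score_cohort(df)
        merged = df.merge(scored.drop(columns=["group"]), on="animal_id")
        merged["cohort_seed"] = s
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def one_cohort(default_cfg):
    """A single default cohort as an animals table."""
    return synth.generate_cohort(default_cfg, seed=11).to_frame()
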