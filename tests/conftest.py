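import pytest

from nirsav import default_montage, simulate_cohort, preprocess_cohort
from nirsav.simulate import (
    SimulationConfig, ArtifactConfig, AttritionConfig, EffectSpec, NoiseConfig,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def clean_config(seed, n=6, session=240.0, effects=(), **kw):
    """A cohort config with no artifacts and no attrition (single age group)."""
    return SimulationConfig(
        seed=seed, n_younger=n, n_older=0, n_pandemic_younger=0,
        n_pandemic_older=0, session_length_s=session,
        artifact=ArtifactConfig(spike_rate_per_min=0.0, shift_rate_per_min=0.0),
        attrition=AttritionConfig(p_channel_missing=0.0),
        effects=list(effects), **kw,
    )


@pytest.fixture(scope="session")
def small_null_cohort():
    recs, gt = simulate_cohort(clean_config(seed=11, n=6))
    return recs, gt


@pytest.fixture(scope="session")
def effect_cohort_table():
    """n=12 cohort with a strong super-additive HbO effect on right-hemisphere
    channels 24/26/27/29, preprocessed to window means."""
    cfg = clean_config(
        seed=21, n=12,
        effects=[EffectSpec(channels=(24, 26, 27, 29), amplitude_um=0.9,
                            additivity="super")],
    )
    recs, gt = simulate_cohort(cfg)
    table, verdicts = preprocess_cohort(recs)
    assert all(v.included for v in verdicts)
    return table
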