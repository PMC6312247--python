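import numpy as np
import pytest

from nciwear import (
    SyntheticConfig,
    build_pattern,
    build_scenario,
    classify_wear,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def scenario_a():
    return build_scenario(build_pattern("A"))


@pytest.fixture(scope="session")
def scenario_b():
    return build_scenario(build_pattern("B"))


@pytest.fixture(scope="session")
def labels_a(scenario_a):
    return classify_wear(scenario_a)


@pytest.fixture(scope="session")
def labels_b(scenario_b):
    return classify_wear(scenario_b)


@pytest.fixture(scope="session")
def clean_cohort():
    """No noise, no low/zero wear counts, no planted corner cases: the
    classifier should recover the generator's wear mask exactly."""
    cfg = SyntheticConfig(
        n_participants=6,
        n_days=3,
        seed=11,
        p_wear_zero=0.0,
        p_wear_low=0.0,
        nonwear_noise_per_hour=0.0,
        a_type_rate=0.0,
        b_type_rate=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Noise-free cohort with planted A-type and B-type corner-case hours."""
    cfg = SyntheticConfig(
        n_participants=20,
        n_days=3,
        seed=7,
        p_wear_zero=0.0,
        p_wear_low=0.0,
        nonwear_noise_per_hour=0.0,
        a_type_rate=2.0,
        b_type_rate=1.0,
    )
    return simulate_cohort(cfg)


def random_count_series(rng: np.random.Generator, max_len: int = 300) -> np.ndarray:
    """Random series biased toward the rule-relevant count strata, with
    fragments of the corner-case hourly patterns spliced in."""
    from nciwear import PATTERN_A, PATTERN_B

    pieces = []
    total = 0
    target = int(rng.integers(1, max_len + 1))
    while total < target:
        kind = rng.integers(0, 5)
        if kind == 0:
            frag = np.asarray(PATTERN_A)[: rng.integers(1, 61)]
        elif kind == 1:
            frag = np.asarray(PATTERN_B)[: rng.integers(1, 61)]
        elif kind == 2:
            frag = np.zeros(rng.integers(1, 80), dtype=np.int64)
        elif kind == 3:
            frag = rng.choice([1, 50, 99, 100, 101, 500, 2020], size=rng.integers(1, 10))
        else:
            frag = rng.integers(0, 200, size=rng.integers(1, 30))
        pieces.append(frag)
        total += len(frag)
    return np.concatenate(pieces)[:target].astype(np.int64)
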