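import numpy as np
import pytest

from ctt import PatternSet, SimSpec, generate_truth, simulate_localizer, \
    simulate_main_task


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Two-condition pattern-mode simulation, moderate noise."""
    return SimSpec(n_units=50, n_conditions=2,
                   n_localizer_trials_per_condition=8,
                   n_main_trials_per_condition=8,
                   n_runs_localizer=2, n_chunks_main=4,
                   noise_sd=0.3, seed=42)


@pytest.fixture
def small_datasets(small_spec):
    truth = generate_truth(small_spec)
    loc = simulate_localizer(truth, small_spec)
    main = simulate_main_task(truth, small_spec)
    return truth, loc, main


def make_patternset(patterns, conditions=None, runs=None, **kw):
    """Quick PatternSet around a raw matrix."""
    patterns = np.asarray(patterns, dtype=float)
    n, v = patterns.shape
    return PatternSet(
        patterns=patterns,
        condition_labels=conditions if conditions is not None
        else [f"c{i % 2}" for i in range(n)],
        run_ids=runs if runs is not None else np.zeros(n, dtype=int),
        unit_ids=np.arange(v),
        **kw,
    )
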