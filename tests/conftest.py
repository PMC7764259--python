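"""Shared fixtures: small synthetic blocks generated at test time."""

import numpy as np
import pytest

from nirgrid import Segment, SpectraBlock, SyntheticSpec, WavenumberAxis, generate


@pytest.fixture(scope="session")
def short_axis():
    """Descending 2 cm^-1 axis with 201 points (8000 -> 7600)."""
    return np.arange(8000.0, 7599.0, -2.0)


@pytest.fixture()
def tiny_block(short_axis):
    """2 classes x 3 samples x 4 scans on a short axis, deterministic."""
    rng = np.random.default_rng(1234)
    n_samples, spsc = 6, 4
    X = rng.normal(0.5, 0.05, (n_samples * spsc, short_axis.size))
    sample_id = np.repeat([f"s{i}" for i in range(n_samples)], spsc).astype(object)
    replicate_id = np.tile(["r1", "r1", "r2", "r2"], n_samples).astype(object)
    class_label = np.repeat(["north"] * 3 + ["south"] * 3, spsc).astype(object)
    return SpectraBlock(
        axis=WavenumberAxis(short_axis),
        intensities=X,
        sample_id=sample_id,
        replicate_id=replicate_id,
        class_label=class_label,
    )


@pytest.fixture(scope="session")
def small_study_block():
    """7 classes x 10 samples, 6 scans each, with strong scatter injected."""
    spec = SyntheticSpec(
        class_sizes=tuple((c, 10) for c in "ABCDEFG"),
        replicates_per_sample=3,
        scans_per_replicate=2,
        scatter_a_sd=0.08,
        scatter_b_range=(0.6, 1.4),
        seed=9,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def full_range_segment():
    return (Segment(11550, 3950),)
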