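"""Shared fixtures and random-curve helpers for the test suite."""

import numpy as np
import pytest

from ntcpselect.dvh import DVHCurve


def make_curve(edges, volumes, pid="p1", sid="oar", tech="photon"):
    return DVHCurve(
        patient_id=pid,
        structure_id=sid,
        technique=tech,
        dose_edges=np.asarray(edges, dtype=float),
        cum_volume=np.asarray(volumes, dtype=float),
    )


def random_curve(rng, n_points=None, dmax=None, reach_zero=True):
    """Random valid cumulative DVH with strictly decreasing interior volumes
    (no plateaus, so dose/volume inversion is unique)."""
    n = n_points or rng.integers(3, 30)
    dmax = dmax or rng.uniform(5.0, 80.0)
    edges = np.concatenate(
        [[0.0], np.sort(rng.uniform(0.0, dmax, size=n - 2)), [dmax]]
    )
    edges = np.unique(edges)
    # strictly decreasing volumes from 1 to (0 or a positive tail)
    interior = np.sort(rng.uniform(0.0, 1.0, size=len(edges) - 2))[::-1]
    tail = 0.0 if reach_zero else float(rng.uniform(0.0, 0.3))
    volumes = np.concatenate([[1.0], interior * (1.0 - tail) + tail, [tail]])
    # enforce strict decrease (ties possible at float resolution are fine)
    return make_curve(edges, volumes)


@pytest.fixture
def four_point_curve():
    """The worked example used throughout: V = (1, 0.8, 0.2, 0) at
    (0, 20, 40, 60) Gy — Dmean 30 Gy, D50 30 Gy."""
    return make_curve([0, 20, 40, 60], [1.0, 0.8, 0.2, 0.0])


@pytest.fixture
def step_curve():
    """Two-point ramp from (0 Gy, 1.0) to (60 Gy, 0.0)."""
    return make_curve([0, 60], [1.0, 0.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)
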