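"""Shared constants and helpers for the test suite."""

import numpy as np
import pytest
from scipy import stats

#: Frame interval (s) and apparent diffusion coefficient (μm²/s) used
#: throughout: the imaging conditions the analysis assumes.
DT = 0.46
D_APP = 0.25

#: SD of the diffusive instant-velocity law N(0, sqrt(2·D·Δt)/Δt), μm/s.
DIFF_SD = np.sqrt(2.0 * D_APP * DT) / DT


def diffusive_cdf(edges):
    """CDF of the signed diffusive velocity law."""
    return stats.norm.cdf(np.asarray(edges, dtype=float), 0.0, DIFF_SD)


def diffusive_speed_cdf(edges):
    """CDF of the diffusive speed law (half-normal)."""
    e = np.asarray(edges, dtype=float)
    return 2.0 * stats.norm.cdf(np.maximum(e, 0.0) / DIFF_SD) - 1.0


def draw_direction_sample(rng, n, active_fraction, gauss_mu, gauss_sigma):
    """Signed velocities: active Gaussian runs mixed into the diffusive law."""
    active = rng.random(n) < active_fraction
    return np.where(
        active,
        rng.normal(gauss_mu, gauss_sigma, n),
        rng.normal(0.0, DIFF_SD, n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
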