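import numpy as np
import pytest

from circaquant.core import Trace


@pytest.fixture
def lum_time_axis():
    """A week of 10-min luminometer sampling."""
    return np.arange(0, 168 + 1e-9, 1 / 6)


@pytest.fixture
def clean_cosine(lum_time_axis):
    """Noise-free 24-h cosine peaking at t=0, detrended kind."""
    t = lum_time_axis
    return Trace(t, np.cos(2 * np.pi * t / 24.0), kind="detrended")


def brute_force_period(t, y, scan=(16.0, 32.0), step=0.01):
    """Independent period estimator: least-squares sinusoid scan.

    For each candidate period fit y ~ a*cos + b*sin on mean-centered data
    and return the period minimizing the residual sum of squares.
    """
    yc = y - y.mean()
    best_period, best_rss = None, np.inf
    for period in np.arange(scan[0], scan[1] + step / 2, step):
        w = 2 * np.pi / period
        design = np.column_stack([np.cos(w * t), np.sin(w * t)])
        beta, *_ = np.linalg.lstsq(design, yc, rcond=None)
        r = yc - design @ beta
        rss = float(r @ r)
        if rss < best_rss:
            best_period, best_rss = float(period), rss
    return best_period


def raw_mad(x):
    """Median absolute deviation without a consistency constant."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))
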