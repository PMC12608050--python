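"""Synthetic recordings with the statistical structure the pipeline assumes.

Luminometer traces are damped cosines on a slow monoexponential baseline
with Gaussian read noise and rare single-sample spike artifacts; image
stacks share one oscillator across pixels but give each cell-scale block
of pixels its own phase offset drawn from a zero-median Laplace law whose
population MAD is a parameter (optionally inflated cycle by cycle, a
coherence-loss model); decay traces are clean exponentials plus noise.

All randomness flows from one explicit integer seed per call, through
independent child streams (noise / spikes / offsets / hot pixels), so a
test can regenerate any one ingredient on its own.  There is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageStack, Trace

__all__ = [
    "OscillatorParams",
    "StackParams",
    "StackTruth",
    "gen_lum_trace",
    "gen_decay_trace",
    "gen_image_stack",
    "gen_expression_table",
    "gen_ct_table",
    "oscillator_signal",
    "draw_spike_indices",
]

#: Laplace(0, b) has population MAD = b * ln 2
_LAPLACE_MAD = math.log(2.0)


@dataclass
class OscillatorParams:
    """Parameters of one damped circadian oscillator on a drifting baseline.

    The deterministic part of the trace is::

        baseline_start * exp(-t / baseline_tau_h)
          + amplitude * exp(-t / damping_tau_h) * cos(2*pi*(t - phase_h) / period_h)

    ``phase_h`` is the time of the first peak.  Infinite taus give an
    undamped rhythm / constant baseline.  ``spike_rate`` is the expected
    number of single-sample positive spike artifacts per 24 h, each of
    size ``spike_magnitude`` times the local deterministic level.
    """

    period_h: float = 24.0
    amplitude: float = 100.0
    phase_h: float = 12.0
    damping_tau_h: float = math.inf
    baseline_start: float = 300.0
    baseline_tau_h: float = math.inf
    noise_sd: float = 10.0
    spike_rate: float = 0.25
    spike_magnitude: float = 5.0
    duration_h: float = 168.0
    dt_h: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.period_h) and self.period_h > 0):
            raise ValueError(f"period_h must be positive and finite, got {self.period_h}")
        if not (np.isfinite(self.dt_h) and self.dt_h > 0):
            raise ValueError(f"dt_h must be positive and finite, got {self.dt_h}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.damping_tau_h <= 0 or self.baseline_tau_h <= 0:
            raise ValueError("taus must be positive (inf allowed)")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be nonnegative")
        if self.duration_h < 2 * self.period_h:
            raise ValueError(
                f"duration_h={self.duration_h} must cover at least two periods "
                f"({2 * self.period_h} h)"
            )

    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration_h / self.dt_h + 1e-9)) + 1
        return np.arange(n) * self.dt_h


def oscillator_signal(params: OscillatorParams, t: np.ndarray) -> np.ndarray:
    """Deterministic (noise- and spike-free) oscillator value at times ``t``."""
    t = np.asarray(t, dtype=float)
    baseline = params.baseline_start * np.exp(-t / params.baseline_tau_h)
    envelope = params.amplitude * np.exp(-t / params.damping_tau_h)
    return baseline + envelope * np.cos(
        2.0 * np.pi * (t - params.phase_h) / params.period_h
    )


def _local_level(params: OscillatorParams, t: np.ndarray) -> np.ndarray:
    """Positive local signal scale used to size spike artifacts."""
    baseline = np.abs(params.baseline_start) * np.exp(-t / params.baseline_tau_h)
    envelope = params.amplitude * np.exp(-t / params.damping_tau_h)
    return baseline + envelope


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def draw_spike_indices(params: OscillatorParams) -> np.ndarray:
    """Sample indices where :func:`gen_lum_trace` places spike artifacts.

    Regenerates exactly the spike draw of ``gen_lum_trace`` for the same
    parameters, independently of the noise stream.
    """
    _, spike_rng = _streams(params.seed, 2)
    n = len(params.times())
    lam = params.spike_rate * params.duration_h / 24.0
    count = min(int(spike_rng.poisson(lam)), n)
    if count == 0:
        return np.empty(0, dtype=int)
    return np.sort(spike_rng.choice(n, size=count, replace=False))


def gen_lum_trace(params: OscillatorParams) -> Trace:
    """Synthetic luminometer trace on a uniform grid 0..duration_h step dt_h.

    value(t) = baseline(t) + amplitude * e^(-t/tau) * cos(2*pi*(t-phase)/period)
               + N(0, noise_sd^2), plus Poisson-placed single-sample spikes
    of ``spike_magnitude`` times the local deterministic level.
    """
    t = params.times()
    noise_rng, spike_rng = _streams(params.seed, 2)
    value = oscillator_signal(params, t)
    if params.noise_sd > 0:
        value = value + noise_rng.normal(0.0, params.noise_sd, size=len(t))
    else:
        noise_rng.normal(0.0, 1.0, size=len(t))  # keep stream alignment
    lam = params.spike_rate * params.duration_h / 24.0
    count = min(int(spike_rng.poisson(lam)), len(t))
    if count > 0:
        idx = np.sort(spike_rng.choice(len(t), size=count, replace=False))
        value[idx] += params.spike_magnitude * _local_level(params, t[idx])
    return Trace(t, value, kind="raw", meta={"simulated": True, "seed": params.seed})


def gen_decay_trace(
    k_h: float,
    noise_sd: float = 0.0,
    duration_h: float = 24.0,
    dt_h: float = 1.0 / 6.0,
    seed: int = 0,
) -> Trace:
    """Exponential decay e^(-t/k_h) with additive noise, clipped at zero."""
    if not (np.isfinite(k_h) and k_h > 0):
        raise ValueError(f"k_h must be positive and finite, got {k_h}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    n = int(np.floor(duration_h / dt_h + 1e-9)) + 1
    t = np.arange(n) * dt_h
    value = np.exp(-t / k_h)
    if noise_sd > 0:
        value = value + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return Trace(t, np.clip(value, 0.0, None), kind="raw", meta={"simulated": True})


@dataclass
class StackParams:
    """Parameters of a synthetic CCD image stack.

    Every in-mask pixel follows ``oscillator`` with a phase offset drawn
    once per ``phase_block`` x ``phase_block`` block from Laplace(0, b)
    with b = pixel_phase_mad_h / ln 2, so the population MAD of the
    offsets equals ``pixel_phase_mad_h`` exactly.  Offsets are inflated by
    ``dispersion_growth_h_per_cycle`` per elapsed cycle (preserving pixel
    rank order: coherence loss, not re-randomization).  Blocks model
    cell-scale phase-coherence domains and match the downstream software
    binning scale, so binned-pixel offsets have the stated MAD.
    """

    n_frames: int = 110
    height: int = 64
    width: int = 64
    frame_interval_h: float = 1.0
    mask_spec: str = "full"          # "full" or "ellipse"
    pixel_phase_mad_h: float = 0.8
    dispersion_growth_h_per_cycle: float = 0.0
    hot_pixel_rate: float = 0.0      # per pixel-frame probability
    phase_block: int = 4
    oscillator: OscillatorParams = field(
        default_factory=lambda: OscillatorParams(
            period_h=24.0, amplitude=100.0, phase_h=12.0,
            baseline_start=300.0, noise_sd=20.0,
            spike_rate=0.0, duration_h=110.0, dt_h=1.0,
        )
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.height < 1 or self.width < 1:
            raise ValueError("frame must be at least 1x1")
        if self.pixel_phase_mad_h < 0 or self.dispersion_growth_h_per_cycle < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if not 0 <= self.hot_pixel_rate <= 1:
            raise ValueError("hot_pixel_rate must be a probability")
        if self.phase_block < 1:
            raise ValueError("phase_block must be >= 1")
        if self.mask_spec not in ("full", "ellipse"):
            raise ValueError("mask_spec must be 'full' or 'ellipse'")


@dataclass
class StackTruth:
    """Ground truth behind a generated stack, for estimator validation."""

    mask: np.ndarray            # per-pixel in-mask flags
    block_offsets_h: np.ndarray  # per-block drawn phase offsets (blocks grid)
    block_in_mask: np.ndarray    # per-block fraction of in-mask source pixels
    pixel_offsets_h: np.ndarray  # per-pixel offsets (block offsets broadcast)
    hot_events: np.ndarray       # (n_events, 3) array of frame, row, col

    def offsets_of_covered_blocks(self, min_coverage: float = 0.5) -> np.ndarray:
        """Offsets of blocks with at least ``min_coverage`` in-mask pixels."""
        return self.block_offsets_h[self.block_in_mask >= min_coverage]


def _build_mask(params: StackParams) -> np.ndarray:
    if params.mask_spec == "full":
        return np.ones((params.height, params.width), dtype=bool)
    r = np.arange(params.height)[:, None]
    c = np.arange(params.width)[None, :]
    cy, cx = (params.height - 1) / 2.0, (params.width - 1) / 2.0
    ry, rx = params.height * 0.4, params.width * 0.4
    return ((r - cy) / ry) ** 2 + ((c - cx) / rx) ** 2 <= 1.0


def gen_image_stack(
    params: StackParams, return_truth: bool = False
) -> ImageStack | tuple[ImageStack, StackTruth]:
    """Render a synthetic image stack (optionally with its ground truth).

    Out-of-mask pixels carry read noise only.  Hot pixels are injected in
    exactly one frame each (an event whose temporal neighbour at the same
    pixel is also hot is dropped), emulating single-frame CCD artifacts.
    """
    osc = params.oscillator
    H, W, B = params.height, params.width, params.phase_block
    mask = _build_mask(params)
    if mask.shape != (H, W):
        raise ValueError("mask larger than frame")
    t = np.arange(params.n_frames) * params.frame_interval_h

    offset_rng, noise_rng, hot_rng = _streams(params.seed, 3)

    nb_r, nb_c = math.ceil(H / B), math.ceil(W / B)
    if params.pixel_phase_mad_h > 0:
        b = params.pixel_phase_mad_h / _LAPLACE_MAD
        block_offsets = offset_rng.laplace(0.0, b, size=(nb_r, nb_c))
    else:
        block_offsets = np.zeros((nb_r, nb_c))
    pixel_offsets = np.repeat(np.repeat(block_offsets, B, axis=0), B, axis=1)[:H, :W]

    ones = np.ones((H, W))
    block_cov = np.zeros((nb_r, nb_c))
    for i in range(nb_r):
        for j in range(nb_c):
            blk = mask[i * B:(i + 1) * B, j * B:(j + 1) * B]
            block_cov[i, j] = blk.mean() if blk.size else 0.0

    # cycle index per frame, boundaries at mid-cycle (troughs) so each
    # pixel's peak sits safely inside its cycle segment
    cycle = np.floor((t - osc.phase_h + osc.period_h / 2.0) / osc.period_h) + 1
    cycle = np.clip(cycle, 1, None)
    if params.pixel_phase_mad_h > 0:
        scale = (
            params.pixel_phase_mad_h
            + params.dispersion_growth_h_per_cycle * (cycle - 1)
        ) / params.pixel_phase_mad_h
    else:
        scale = np.ones_like(cycle)

    tt = t[:, None, None]
    delta = scale[:, None, None] * pixel_offsets[None, :, :]
    baseline = osc.baseline_start * np.exp(-tt / osc.baseline_tau_h) * ones
    envelope = osc.amplitude * np.exp(-tt / osc.damping_tau_h)
    signal = baseline + envelope * np.cos(
        2.0 * np.pi * (tt - osc.phase_h - delta) / osc.period_h
    )
    stack = np.where(mask[None, :, :], signal, 0.0)
    if osc.noise_sd > 0:
        stack = stack + noise_rng.normal(0.0, osc.noise_sd, size=stack.shape)

    hot_events = np.empty((0, 3), dtype=int)
    if params.hot_pixel_rate > 0:
        hot = hot_rng.random(stack.shape) < params.hot_pixel_rate
        # single-frame artifacts only: drop an event whose predecessor
        # frame is hot at the same pixel
        hot[1:] &= ~hot[:-1]
        hot_events = np.argwhere(hot)
        if len(hot_events):
            stack[hot] = stack.max() * 10.0
    stack = np.clip(stack, 0.0, None)

    image = ImageStack(
        intensity=stack,
        frame_interval_h=params.frame_interval_h,
        mask=mask if params.mask_spec != "full" else None,
        meta={"simulated": True, "seed": params.seed},
    )
    if not return_truth:
        return image
    truth = StackTruth(
        mask=mask,
        block_offsets_h=block_offsets,
        block_in_mask=block_cov,
        pixel_offsets_h=pixel_offsets,
        hot_events=hot_events,
    )
    return image, truth


def gen_expression_table(
    mesor: float,
    amp: float,
    acrophase_h: float,
    period_h: float = 24.0,
    timepoints=tuple(range(0, 24, 3)),
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    gene: str = "gene",
) -> pd.DataFrame:
    """Tidy timed-expression table y = mesor + amp*cos(2*pi*(t - acrophase)/period) + noise.

    Columns: gene, time_h, rep, value.
    """
    if amp < 0:
        raise ValueError("amp must be nonnegative")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for tp in timepoints:
        mu = mesor + amp * np.cos(2.0 * np.pi * (tp - acrophase_h) / period_h)
        for r in range(reps):
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"gene": gene, "time_h": float(tp), "rep": r + 1, "value": y})
    return pd.DataFrame(rows)


def gen_ct_table(
    dct_means: dict,
    n_per_group: int = 4,
    sd: float = 0.0,
    housekeeping_gene: str = "Rpl19",
    housekeeping_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy qPCR Ct table from target (gene, group) -> mean dCt values.

    Each sample gets a housekeeping Ct of ``housekeeping_ct`` and, per
    gene, Ct = housekeeping_ct + dCt (+ noise).  Columns: sample, group,
    gene, ct.
    """
    rng = np.random.default_rng(seed)
    groups = sorted({g for (_, g) in dct_means})
    genes = sorted({gn for (gn, _) in dct_means})
    rows = []
    for group in groups:
        for i in range(n_per_group):
            sample = f"{group}_{i + 1}"
            rows.append(
                {"sample": sample, "group": group,
                 "gene": housekeeping_gene, "ct": housekeeping_ct}
            )
            for gene_ in genes:
                if (gene_, group) not in dct_means:
                    continue
                dct = dct_means[(gene_, group)]
                if sd > 0:
                    dct = dct + rng.normal(0.0, sd)
                rows.append(
                    {"sample": sample, "group": group,
                     "gene": gene_, "ct": housekeeping_ct + dct}
                )
    return pd.DataFrame(rows)
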