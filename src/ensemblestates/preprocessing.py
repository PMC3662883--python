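"""Spike timestamps -> instantaneous firing-rate population vectors.

Each spike train is treated as a sum of unit-area Gaussian kernels
(SD = 125 ms by default) centred on the spike times; the instantaneous
firing rate in a 500 ms bin is the average of that rate function over the
bin.  The bin value is evaluated exactly through normal-CDF differences
rather than by sampling the convolution on a grid, so results carry no
grid-resolution ambiguity:

    r(bin) = sum_spikes [ Phi((b_hi - s)/sigma) - Phi((b_lo - s)/sigma) ] / bin_width

Kernels are truncated at the session boundaries without renormalisation
(mass falling outside the session is simply not counted); the bin grid is
anchored at session_start.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .core import (
    DEFAULT_BIN_WIDTH,
    EmptyEnsembleError,
    RateMatrix,
    SpikeTrainSet,
)

DEFAULT_KERNEL_SD = 0.125  # s = 500/4 ms


def compute_ifr(spikes: SpikeTrainSet, bin_width: float = DEFAULT_BIN_WIDTH,
                kernel_sd: float = DEFAULT_KERNEL_SD) -> RateMatrix:
    """Convert a spike-train set to an N x T rate matrix (spikes/s).

    A unit with no spikes yields an all-zero row.  The last partial bin, if
    the session length is not a bin multiple, is dropped.
    """
    if bin_width <= 0 or kernel_sd <= 0:
        raise ValueError("bin_width and kernel_sd must be positive")
    T = int(np.floor((spikes.duration + 1e-9) / bin_width))
    if T < 1:
        raise ValueError("session shorter than one bin")
    edges = spikes.session_start + np.arange(T + 1) * bin_width

    # each spike only touches edges within ~6 sigma; window in edge indices
    half = 6.0 * kernel_sd
    w_edges = int(np.ceil(2 * half / bin_width)) + 2

    values = np.zeros((spikes.n_units, T))
    for u, train in enumerate(spikes.spikes):
        if train.size == 0:
            continue
        j0 = np.searchsorted(edges, train - half, side="right") - 1
        j0 = np.clip(j0, 0, T)
        idx = np.clip(j0[:, None] + np.arange(w_edges + 1)[None, :], 0, T)
        cdf = norm.cdf((edges[idx] - train[:, None]) / kernel_sd)
        mass = np.diff(cdf, axis=1)          # duplicate clipped edges give 0
        bin_idx = np.clip(j0[:, None] + np.arange(w_edges)[None, :], 0, T - 1)
        row = np.zeros(T)
        np.add.at(row, bin_idx.ravel(), mass.ravel())
        values[u] = row / bin_width
    return RateMatrix(values, bin_width, spikes.session_start,
                      list(spikes.unit_ids), spikes.epochs)


def filter_low_rate(spikes: SpikeTrainSet, threshold: float = 0.1) -> SpikeTrainSet:
    """Drop units whose whole-session mean rate is strictly below threshold.

    A unit at exactly the threshold is retained.  Removing every unit raises
    :class:`EmptyEnsembleError`.
    """
    if spikes.duration <= 0:
        raise ValueError("session duration must be positive")
    keep = spikes.mean_rates() >= threshold
    if not keep.any():
        raise EmptyEnsembleError(
            f"all {spikes.n_units} units below {threshold} spikes/s")
    return SpikeTrainSet(
        unit_ids=[uid for uid, k in zip(spikes.unit_ids, keep) if k],
        spikes=[s for s, k in zip(spikes.spikes, keep) if k],
        session_start=spikes.session_start,
        session_end=spikes.session_end,
        epochs=spikes.epochs,
        events=spikes.events,
    )


def merge_sessions(rate_matrices: list[RateMatrix],
                   align_event: list[float]) -> RateMatrix:
    """Stack sessions' units after aligning each time axis to a per-session
    reference event (the first pellet drop in the study's usage).

    The merged matrix is truncated to the common support
    ``[-min pre-event length, +min post-event length)`` and re-timed so the
    aligning event falls at 0 s.  Epoch metadata is taken from the first
    session, shifted into event-relative time.
    """
    if not rate_matrices:
        raise ValueError("no sessions to merge")
    if len(align_event) != len(rate_matrices):
        raise ValueError("need one align_event per session")
    bw = rate_matrices[0].bin_width
    if any(abs(rm.bin_width - bw) > 1e-12 for rm in rate_matrices):
        raise ValueError("sessions have mismatched bin widths")

    event_bin = [int(np.floor((ae - rm.t0) / bw))
                 for rm, ae in zip(rate_matrices, align_event)]
    n_pre = min(event_bin)
    n_post = min(rm.n_bins - eb for rm, eb in zip(rate_matrices, event_bin))
    if n_pre < 0 or n_post < 1:
        raise ValueError("align event outside a session's support")

    blocks, unit_ids = [], []
    for s, (rm, eb) in enumerate(zip(rate_matrices, event_bin)):
        blocks.append(rm.values[:, eb - n_pre: eb + n_post])
        unit_ids.extend(f"s{s}:{uid}" for uid in rm.unit_ids)

    epochs = None
    first = rate_matrices[0]
    if first.epochs is not None:
        shift = align_event[0]
        e = first.epochs
        lo, hi = -n_pre * bw, n_post * bw
        clip = lambda iv: (max(iv[0] - shift, lo), min(iv[1] - shift, hi))
        try:
            epochs = type(e)(clip(e.baseline), clip(e.drop_period), clip(e.post))
        except ValueError:
            epochs = None  # common support does not cover all three epochs
    return RateMatrix(np.vstack(blocks), bw, -n_pre * bw, unit_ids, epochs)
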