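"""Complexity measures on ensemble activity and the entropy change point.

Three complementary views of how "rich" population activity is at a moment:

* Shannon entropy of the smoothed HMM state posteriors, H(t) = -sum_i P_i ln P_i
  (nats; 0 when one state is certain, ln Q when all are equiprobable), and its
  perplexity exp(H) — an equivalent number of equiprobable states.
* An upper-bound estimate of Kolmogorov complexity: the bzip2-compressed byte
  size of a deterministically serialised sliding window of the rate matrix.
* A per-bin count of principal components needed to cover 90% of the absolute
  component scores, with the axes fit once on the whole session.

A cumulative-sum statistic localises the level shift in the entropy trace at
the transition from exploration to the reward period.
"""

from __future__ import annotations

import bz2
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import PosteriorMatrix, RateMatrix

TRACE_KINDS = ("entropy_nats", "effective_states", "kc_bytes", "pca_components")


@dataclass
class ComplexityTrace:
    """A time-indexed scalar complexity series."""

    kind: str
    times: np.ndarray   # bin or window centers, s
    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    def epoch_values(self, epochs, epoch: str) -> np.ndarray:
        lo, hi = getattr(epochs, "drop_period" if epoch == "drop" else epoch)
        return self.values[(self.times >= lo) & (self.times < hi)]


@dataclass
class ChangePoint:
    """CUSUM change localisation: the shift lies between bins k and k+1
    (k counts bins in the first segment, so k is 1-based)."""

    k: int
    time: float | None = None
    degenerate: bool = False


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis; edges use shrunken
    windows (the average runs over whatever part of the window exists)."""
    if window == 1:
        return x.copy()
    kern = np.ones(window)
    counts = np.convolve(np.ones(x.shape[-1]), kern, mode="same")
    if x.ndim == 1:
        return np.convolve(x, kern, mode="same") / counts
    return np.vstack([np.convolve(row, kern, mode="same") for row in x]) / counts


def smooth_posteriors(post: PosteriorMatrix, window_bins: int = 3) -> PosteriorMatrix:
    """Centered moving average of each state's posterior series, columns
    renormalised to sum to 1.  The 3-bin window is the analysis default;
    61 bins is the whole-session visualisation variant."""
    if window_bins % 2 != 1 or window_bins < 1:
        raise ValueError("window_bins must be odd and positive")
    if window_bins > post.n_bins:
        raise ValueError("smoothing window exceeds the series length")
    sm = _moving_average(post.values, window_bins)
    sm /= sm.sum(axis=0, keepdims=True)
    return PosteriorMatrix(sm, post.bin_width, post.t0)


def entropy_trace(post: PosteriorMatrix) -> ComplexityTrace:
    """Per-bin Shannon entropy of the state posteriors, in nats (0 ln 0 = 0)."""
    p = post.values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -terms.sum(axis=0)
    H = np.clip(H, 0.0, None)  # kill -0.0 / tiny negative fp residue
    return ComplexityTrace("entropy_nats", post.bin_centers, H)


def effective_state_count(entropy: ComplexityTrace) -> ComplexityTrace:
    """Perplexity exp(H): the number of equiprobable states with the same
    entropy — an indicator of how many states carry posterior mass."""
    if entropy.kind != "entropy_nats":
        raise ValueError("expected an entropy_nats trace")
    return ComplexityTrace("effective_states", entropy.times,
                           np.exp(entropy.values))


def thresholded_state_count(post: PosteriorMatrix, eps: float = 0.01) -> ComplexityTrace:
    """Alternative state-count reading: number of states with posterior
    above ``eps`` at each bin."""
    counts = (post.values > eps).sum(axis=0).astype(float)
    return ComplexityTrace("effective_states", post.bin_centers, counts)


def cusum_change_point(values: np.ndarray, times: np.ndarray | None = None) -> ChangePoint:
    """Cumulative sum of mean-centred values; the |S| extremum localises a
    level shift between bins k and k+1 (earliest k on ties)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        return ChangePoint(1, None if times is None else float(times[0]), True)
    S = np.cumsum(x - x.mean())
    k = int(np.argmax(np.abs(S))) + 1
    t = None
    if times is not None:
        # boundary between bin k-1 and bin k (0-based centers)
        t = float((times[k - 1] + times[k]) / 2) if k < x.size else float(times[-1])
    return ChangePoint(k, t, False)


def serialize_window(values: np.ndarray) -> bytes:
    """Deterministic fixed-precision serialisation of a rate submatrix:
    4-decimal text, row-major units x bins, single-space separated, one line
    per unit.  Compressed sizes are only comparable within this dialect."""
    lines = (" ".join(format(v, ".4f") for v in row) for row in values)
    return ("\n".join(lines) + "\n").encode("ascii")


def kolmogorov_trace(rates: RateMatrix, window: float = 150.0,
                     step: float = 5.0) -> ComplexityTrace:
    """Sliding-window compression complexity: bzip2-compressed byte count of
    each serialised window, at maximum compression level."""
    bw = rates.bin_width
    w_bins = int(round(window / bw))
    s_bins = max(int(round(step / bw)), 1)
    if w_bins < 2:
        raise ValueError("window shorter than 2 bins")
    if w_bins > rates.n_bins:
        raise ValueError("window exceeds the session length")
    starts = np.arange(0, rates.n_bins - w_bins + 1, s_bins)
    sizes = np.empty(starts.size)
    for i, s in enumerate(starts):
        blob = serialize_window(rates.values[:, s:s + w_bins])
        sizes[i] = len(bz2.compress(blob, 9))
    centers = rates.t0 + (starts + w_bins / 2.0) * bw
    return ComplexityTrace("kc_bytes", centers, sizes)


def pca_component_counts(rates: RateMatrix, coverage: float = 0.90
                         ) -> tuple[np.ndarray, bool]:
    """Per-bin count of principal components covering the signal.

    Axes are fit once on the whole mean-centred session.  For each bin the
    absolute scores on all N axes are sorted descending; the count is the
    smallest m whose partial sum strictly exceeds ``coverage`` of the total.
    Returns (counts, degenerate); a zero-variance matrix yields all-1 counts
    with the degenerate flag set.
    """
    N, T = rates.values.shape
    if N < 2:
        raise ValueError("need at least 2 units")
    if T <= N:
        raise ValueError("need more bins than units")
    X = rates.values.T  # (T, N)
    if np.allclose(X.var(axis=0), 0.0):
        return np.ones(T), True
    scores = np.abs(PCA(n_components=N).fit_transform(X))  # (T, N)
    srt = np.sort(scores, axis=1)[:, ::-1]
    csum = np.cumsum(srt, axis=1)
    total = csum[:, -1]
    counts = np.empty(T)
    for t in range(T):
        if total[t] == 0:
            counts[t] = 1.0
            continue
        counts[t] = int(np.argmax(csum[t] > coverage * total[t])) + 1
    return counts, False


def pca_complexity_trace(rates: RateMatrix, coverage: float = 0.90,
                         smooth_window_bins: int = 61) -> ComplexityTrace:
    """PCA component-count series with a centred moving-average smoother
    (pass ``smooth_window_bins=1`` for the raw integer counts)."""
    counts, degenerate = pca_component_counts(rates, coverage)
    window = min(smooth_window_bins, counts.size if counts.size % 2 else counts.size - 1)
    smoothed = _moving_average(counts, max(window, 1))
    return ComplexityTrace("pca_components", rates.bin_centers, smoothed,
                           degenerate)


def write_trace(path, trace: ComplexityTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={trace.kind} degenerate={int(trace.degenerate)}\n")
        fh.write("time_s,value\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.6f},{v:.9f}\n")


def read_trace(path) -> ComplexityTrace:
    with open(path) as fh:
        meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
        fh.readline()
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return ComplexityTrace(meta["kind"], data[:, 0], data[:, 1],
                           bool(int(meta.get("degenerate", "0"))))
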