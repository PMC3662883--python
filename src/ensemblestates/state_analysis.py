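"""Epoch-level state categorisation, peri-event analyses, and the
three-factor single-unit regression.

States are categorised as baseline-dominant or drop-dominant by comparing
each state's time-mean posterior over the baseline epoch against an
equal-duration interval at the start of the pellet-drop epoch.  Peri-event
analyses average posteriors across repeated 10 s windows centred on each
pellet drop and compare entropy area-under-curve against matched baseline
windows.  The regression explains each unit's drop-period firing rate with
three mutually exclusive indicator factors: pellet drop, consumption, and
the intertrial remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core import EpochDefinition, EventSchedule, PosteriorMatrix, RateMatrix
from .complexity import ComplexityTrace, entropy_trace

PELLET_DROP_WINDOW = (-0.5, 1.5)   # s relative to each drop
CONSUMPTION_WINDOW = (3.0, 6.0)    # s; brackets the ~4.4 s mean consume latency
FACTORS = ("intertrial", "pellet_drop", "consumption")


@dataclass
class StateCategorization:
    """Per-state epoch posterior means and the dominance label."""

    baseline_mean: np.ndarray
    drop_mean: np.ndarray       # over an equal-duration interval at drop start
    post_mean: np.ndarray
    labels: list[str]           # 'baseline_dominant' | 'drop_dominant'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": np.arange(len(self.labels)),
            "baseline_mean": self.baseline_mean,
            "drop_mean": self.drop_mean,
            "post_mean": self.post_mean,
            "label": self.labels,
        })


@dataclass
class PeriEventSummary:
    """Event-triggered posterior averages and entropy AUCs."""

    half_window: float
    avg_posteriors: np.ndarray       # Q x W, averaged over events
    rel_times: np.ndarray            # W bin centers relative to the event, s
    entropy_profile: np.ndarray      # W nats, from the averaged posteriors
    auc_event: float                 # mean per-event-window entropy AUC
    auc_event_windows: np.ndarray    # one AUC per event window
    auc_baseline_windows: np.ndarray # one AUC per matched baseline window
    n_events_used: int


def categorize_states(post: PosteriorMatrix,
                      epochs: EpochDefinition) -> StateCategorization:
    """Label each state by where its posterior mass lives.

    baseline_dominant iff the baseline mean is strictly greater than the
    mean over the first baseline-duration-length segment of the drop period;
    an exact tie is drop_dominant.
    """
    c = post.bin_centers
    b_lo, b_hi = epochs.baseline
    base = (c >= b_lo) & (c < b_hi)
    b_dur = b_hi - b_lo
    d_lo = epochs.drop_period[0]
    d_hi = min(d_lo + b_dur, epochs.drop_period[1])
    drop = (c >= d_lo) & (c < d_hi)
    p_lo, p_hi = epochs.post
    postm = (c >= p_lo) & (c < p_hi)
    if base.sum() < 2 or drop.sum() < 2:
        raise ValueError("epoch shorter than 2 bins within the posterior support")
    bm = post.values[:, base].mean(axis=1)
    dm = post.values[:, drop].mean(axis=1)
    pm = (post.values[:, postm].mean(axis=1)
          if postm.any() else np.full(post.n_states, np.nan))
    labels = ["baseline_dominant" if b > d else "drop_dominant"
              for b, d in zip(bm, dm)]
    return StateCategorization(bm, dm, pm, labels)


def _paired_t(a, b) -> tuple[float, float]:
    """Paired two-sided t; identical samples give (0, 1) instead of nan."""
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def epoch_posterior_comparison(categorizations: list[StateCategorization]) -> dict:
    """Pool states across sessions per category and compare epochs.

    Per category: mean +/- s.e.m. of per-state epoch means, a paired t-test
    across states between baseline and drop-period means, a baseline-vs-post
    paired test likewise, and the baseline/drop mean ratio.
    """
    rows = []
    for cat in categorizations:
        for b, d, p, lab in zip(cat.baseline_mean, cat.drop_mean,
                                cat.post_mean, cat.labels):
            rows.append((lab, b, d, p))
    df = pd.DataFrame(rows, columns=["label", "baseline", "drop", "post"])
    out: dict = {}
    for lab, grp in df.groupby("label"):
        n = len(grp)
        if n < 2:
            raise ValueError(f"category {lab!r} has fewer than 2 states")
        sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n))
        t_bd, p_bd = _paired_t(grp["baseline"], grp["drop"])
        t_bp, p_bp = _paired_t(grp["baseline"], grp["post"])
        out[lab] = {
            "n_states": n,
            "baseline_mean": float(grp["baseline"].mean()),
            "baseline_sem": sem(grp["baseline"]),
            "drop_mean": float(grp["drop"].mean()),
            "drop_sem": sem(grp["drop"]),
            "post_mean": float(grp["post"].mean()),
            "post_sem": sem(grp["post"]),
            "t_baseline_vs_drop": float(t_bd), "p_baseline_vs_drop": float(p_bd),
            "df": n - 1,
            "t_baseline_vs_post": float(t_bp), "p_baseline_vs_post": float(p_bp),
        }
        denom = (out[lab]["drop_mean"] if lab == "baseline_dominant"
                 else out[lab]["baseline_mean"])
        numer = (out[lab]["baseline_mean"] if lab == "baseline_dominant"
                 else out[lab]["drop_mean"])
        out[lab]["dominance_ratio"] = float(numer / denom) if denom > 0 else np.inf
    return out


def _window_entropy_auc(values: np.ndarray) -> float:
    """Sum of per-bin entropies over one posterior window (rectangle rule)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(values > 0, values * np.log(values), 0.0)
    return float(np.clip(-terms.sum(axis=0), 0.0, None).sum())


def perievent_average(post: PosteriorMatrix, events: EventSchedule,
                      epochs: EpochDefinition,
                      half_window: float = 5.0) -> PeriEventSummary:
    """Average posteriors across windows centred on each pellet drop, and
    compute entropy AUCs for the event windows and for an equal number of
    same-length baseline windows tiled from the baseline start.
    """
    bw = post.bin_width
    w_half = int(round(half_window / bw))
    W = 2 * w_half
    drops = events.drop_times
    event_wins = []
    for d in drops:
        b = int(np.floor((d - post.t0) / bw))
        lo, hi = b - w_half, b + w_half
        if lo < 0 or hi > post.n_bins:
            continue
        t_lo = post.t0 + lo * bw
        t_hi = post.t0 + hi * bw
        if t_lo < epochs.drop_period[0] - half_window - bw or t_hi > epochs.post[1]:
            continue
        event_wins.append(post.values[:, lo:hi])
    if len(event_wins) < 2:
        raise ValueError("fewer than 2 usable event windows")
    stack = np.stack(event_wins)                 # (E, Q, W)
    avg = stack.mean(axis=0)
    rel = (np.arange(W) - w_half + 0.5) * bw
    profile = entropy_trace(PosteriorMatrix(
        avg / avg.sum(axis=0, keepdims=True), bw, 0.0)).values
    auc_events = np.array([_window_entropy_auc(w) for w in event_wins])

    # matched baseline windows: same count, tiled from the baseline start
    b0 = int(np.ceil((epochs.baseline[0] - post.t0) / bw - 1e-9))
    b_end = int(np.floor((epochs.baseline[1] - post.t0) / bw + 1e-9))
    n_fit = (b_end - b0) // W
    starts = [b0 + i * W for i in range(n_fit)]
    if len(starts) > len(event_wins):
        starts = starts[:len(event_wins)]
    auc_base = np.array([_window_entropy_auc(post.values[:, s:s + W])
                         for s in starts])
    return PeriEventSummary(half_window, avg, rel, profile,
                            float(auc_events.mean()), auc_events, auc_base,
                            len(event_wins))


def perievent_entropy_auc(summary: PeriEventSummary) -> dict:
    """Baseline vs peri-event entropy AUC comparison for one session."""
    return {
        "auc_baseline_mean": float(summary.auc_baseline_windows.mean()),
        "auc_event_mean": summary.auc_event,
        "n_baseline_windows": int(summary.auc_baseline_windows.size),
        "n_event_windows": int(summary.auc_event_windows.size),
    }


def auc_comparison_across_sessions(summaries: list[PeriEventSummary]) -> dict:
    """Paired t-test of per-session (baseline mean, peri-event mean) AUCs."""
    base = np.array([s.auc_baseline_windows.mean() for s in summaries])
    peri = np.array([s.auc_event for s in summaries])
    t, p = stats.ttest_rel(base, peri)
    return {"auc_baseline": base, "auc_event": peri,
            "t": float(t), "p": float(p), "df": len(summaries) - 1}


def top_perievent_states(summary: PeriEventSummary, k: int = 3
                         ) -> tuple[np.ndarray, np.ndarray]:
    """The k states with the largest mean averaged posterior over the
    peri-event window; returns (state indices, k x W profiles), sorted by
    descending mean."""
    Q = summary.avg_posteriors.shape[0]
    if k > Q:
        raise ValueError("k exceeds the number of states")
    means = summary.avg_posteriors.mean(axis=1)
    order = np.argsort(-means, kind="stable")[:k]
    return order, summary.avg_posteriors[order]


@dataclass
class FactorDesign:
    """Per-drop-period-bin factor indicators (mutually exclusive, exhaustive)."""

    bin_indices: np.ndarray        # indices into the session's bins
    indicators: np.ndarray         # (n_bins, 3) 0/1 columns in FACTORS order
    factor_names: tuple[str, ...] = FACTORS


def make_factor_design(rates: RateMatrix, events: EventSchedule,
                       epochs: EpochDefinition,
                       pellet_drop_window: tuple[float, float] = PELLET_DROP_WINDOW,
                       consumption_window: tuple[float, float] = CONSUMPTION_WINDOW,
                       ) -> FactorDesign:
    """Assign every drop-period bin to pellet_drop, consumption, or
    intertrial by its centre's time relative to the nearest pellet drop."""
    c = rates.bin_centers
    in_drop = np.flatnonzero((c >= epochs.drop_period[0])
                             & (c < epochs.drop_period[1]))
    drops = events.drop_times
    rel = c[in_drop][:, None] - drops[None, :]        # (bins, drops)
    pd_hit = ((rel >= pellet_drop_window[0])
              & (rel < pellet_drop_window[1])).any(axis=1)
    co_hit = ((rel >= consumption_window[0])
              & (rel < consumption_window[1])).any(axis=1)
    if np.any(pd_hit & co_hit):
        raise ValueError("factor windows overlap; choose disjoint windows")
    ind = np.zeros((in_drop.size, 3))
    ind[:, 1] = pd_hit
    ind[:, 2] = co_hit
    ind[:, 0] = ~(pd_hit | co_hit)
    return FactorDesign(in_drop, ind)


def unit_factor_regression(rates: RateMatrix, design: FactorDesign) -> pd.DataFrame:
    """OLS of each unit's drop-period rate on the three factor indicators.

    No intercept — the indicators partition the drop-period bins, so each
    coefficient is that factor's mean rate.  Returns a long table
    (unit, factor, beta, t, p) with units ranked by p within factor.
    """
    X = design.indicators
    if np.any(X.sum(axis=0) == 0):
        raise ValueError("a design column is all zero")
    rows = []
    for uid, y in zip(rates.unit_ids, rates.values[:, design.bin_indices]):
        res = sm.OLS(y, X).fit()
        for j, name in enumerate(design.factor_names):
            rows.append((uid, name, res.params[j], res.tvalues[j], res.pvalues[j]))
    df = pd.DataFrame(rows, columns=["unit", "factor", "beta", "t", "p"])
    df["rank_in_factor"] = df.groupby("factor")["p"].rank(method="first")
    return df


def factor_contrasts(rates: RateMatrix, design: FactorDesign,
                     reference: str = "intertrial") -> pd.DataFrame:
    """Per-unit contrasts of each non-reference factor's mean rate against
    the reference factor's, from the same no-intercept OLS fit.

    Because a contrast removes the unit's overall firing level, its
    t-statistic is centred at 0 for a unit with no factor selectivity —
    the right null quantity when firing rates are necessarily positive.
    """
    X = design.indicators
    ref = design.factor_names.index(reference)
    xtx_inv = np.linalg.inv(X.T @ X)
    rows = []
    for uid, y in zip(rates.unit_ids, rates.values[:, design.bin_indices]):
        res = sm.OLS(y, X).fit()
        for j, name in enumerate(design.factor_names):
            if j == ref:
                continue
            c = np.zeros(3)
            c[j], c[ref] = 1.0, -1.0
            est = float(c @ res.params)
            se = float(np.sqrt(res.mse_resid * (c @ xtx_inv @ c)))
            t = est / se
            p = 2 * stats.t.sf(abs(t), df=res.df_resid)
            rows.append((uid, f"{name}-{reference}", est, t, float(p)))
    return pd.DataFrame(rows, columns=["unit", "contrast", "estimate", "t", "p"])


def epoch_distribution_test(trace: ComplexityTrace,
                            epochs: EpochDefinition) -> dict:
    """Two-sample KS tests between the trace's values per epoch pair."""
    base = trace.epoch_values(epochs, "baseline")
    drop = trace.epoch_values(epochs, "drop")
    post = trace.epoch_values(epochs, "post")
    out = {}
    for name, a, b in (("baseline_vs_drop", base, drop),
                       ("baseline_vs_post", base, post)):
        if a.size < 5 or b.size < 5:
            raise ValueError(f"{name}: fewer than 5 values in an epoch")
        ks = stats.ks_2samp(a, b)
        out[name] = {"statistic": float(ks.statistic), "p": float(ks.pvalue)}
    return out
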