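"""Ground-truth session simulator for the pellet-drop foraging task.

Emulates a recording session in which an animal freely explores for a
baseline period, then receives food pellets dropped at fixed intervals for a
reward period, then explores again in a short post period.  The population
is modelled as a hidden Markov chain over discrete activity states with two
disjoint repertoires — one expressed during baseline (and post), one during
the pellet-drop period — and state-dependent Poisson spiking per unit.

The chain is simulated directly at the 500 ms analysis bin width: the
downstream HMM operates on 500 ms rate bins, so finer within-bin dynamics
would be unidentifiable anyway.  One drop-repertoire state is preferentially
active in a short window around each consumption event, giving the session a
recoverable consumption state in peri-event analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (
    DEFAULT_BIN_WIDTH,
    EpochDefinition,
    EventSchedule,
    RateMatrix,
    SpikeTrainSet,
    write_epochs,
    write_events,
    write_json,
    write_spikes,
)


@dataclass
class SessionConfig:
    """Simulation parameters; defaults reproduce the study's task schedule.

    15 min event-free baseline, 15 min of 90 pellet drops at 10 s intervals,
    5 min post period; ~20 units at ~1.8 spikes/s grand mean; consumption
    latency 4.39 +/- 0.65 s after each drop.
    """

    n_units: int = 20
    baseline_dur: float = 900.0
    drop_period_dur: float = 900.0
    post_dur: float = 300.0
    n_drops: int = 90
    drop_interval: float = 10.0
    consume_latency_mean: float = 4.39
    consume_latency_sd: float = 0.65
    mean_rate_target: float = 1.8
    q_baseline: int = 6
    q_drop: int = 2
    dwell_mean: float = 5.0  # s; mean state dwell time of the hidden chain
    seed: int = 0
    bin_width: float = DEFAULT_BIN_WIDTH
    # rate structure: per-unit base rates are log-normal (sigma=rate_sigma);
    # each state multiplies them by a log-normal gain whose spread differs by
    # repertoire — exploration states are subtle modulations of a common
    # profile, reward-period states are strongly contrasted, with a fraction
    # of near-silent (state, unit) pairs so abrupt on/off units appear
    rate_sigma: float = 0.7
    baseline_mod_sigma: float = 0.4
    drop_mod_sigma: float = 1.2
    p_silent: float = 0.25
    silent_factor: float = 0.02
    # consumption-state modulation: within this window around each consume
    # event the last drop-repertoire state is active, with this per-event
    # probability (the window occupies the state persistently, not bin-wise)
    consume_state_window: tuple[float, float] = (-1.0, 2.0)
    consume_state_prob: float = 0.85

    def __post_init__(self) -> None:
        if min(self.baseline_dur, self.drop_period_dur, self.post_dur) <= 0:
            raise ValueError("all durations must be positive")
        if self.q_baseline < 1 or self.q_drop < 1:
            raise ValueError("q_baseline and q_drop must be >= 1")
        if self.n_drops * self.drop_interval > self.drop_period_dur:
            raise ValueError("drop schedule overruns the drop period")
        if self.consume_latency_mean <= 0:
            raise ValueError("consume_latency_mean must be positive")
        if self.n_units < 1 or self.n_drops < 1:
            raise ValueError("n_units and n_drops must be >= 1")
        if self.dwell_mean <= self.bin_width:
            raise ValueError("dwell_mean must exceed the bin width")

    @property
    def epochs(self) -> EpochDefinition:
        b = self.baseline_dur
        d = b + self.drop_period_dur
        return EpochDefinition((0.0, b), (b, d), (d, d + self.post_dur))

    @property
    def q_total(self) -> int:
        return self.q_baseline + self.q_drop


@dataclass
class GroundTruth:
    """What the simulator actually did, for scoring recovery downstream."""

    state_sequence: np.ndarray          # state index per 500 ms bin
    state_repertoire_label: list[str]   # per state: 'baseline' or 'drop'
    true_rates: np.ndarray              # Q_total x N, spikes/s
    event_times: np.ndarray             # drop times, s
    consume_times: np.ndarray           # consumption times, s

    @property
    def consume_state(self) -> int:
        """Index of the designated consumption state (last drop state)."""
        return len(self.state_repertoire_label) - 1


def make_event_schedule(config: SessionConfig,
                        rng: np.random.Generator | None = None) -> EventSchedule:
    """Pellet drops at fixed intervals from baseline end, each followed by a
    consumption event at a truncated-normal latency.

    Latencies are drawn from N(consume_latency_mean, consume_latency_sd)
    truncated to (0.5, drop_interval) so each pellet is consumed before the
    next one falls.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    drops = config.baseline_dur + config.drop_interval * np.arange(config.n_drops)
    lo, hi = 0.5, config.drop_interval
    if config.consume_latency_sd == 0:
        lat = np.full(config.n_drops, float(np.clip(config.consume_latency_mean, lo, hi)))
    else:
        lat = np.empty(config.n_drops)
        for i in range(config.n_drops):  # rejection sampling; window is wide
            while True:
                x = rng.normal(config.consume_latency_mean, config.consume_latency_sd)
                if lo < x < hi:
                    lat[i] = x
                    break
    times = np.concatenate([drops, drops + lat])
    labels = ["drop"] * config.n_drops + ["consume"] * config.n_drops
    order = np.argsort(times, kind="stable")
    return EventSchedule(tuple(labels[i] for i in order), times[order])


def _draw_state_rates(config: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-state per-unit rates with repertoire-dependent contrast.

    Each unit has a log-normal base rate; exploration (baseline) states apply
    weak log-normal gains so they overlap — many states share posterior mass
    during exploration — while reward-period states apply strong gains plus
    near-silencing of a fraction of (state, unit) pairs, so a few sharply
    contrasted states dominate and abrupt on/off units appear at the
    baseline -> drop boundary.  Rescaled so the grand mean over (state, unit)
    equals ``mean_rate_target``.
    """
    if config.mean_rate_target == 0:
        return np.zeros((config.q_total, config.n_units))
    base = rng.lognormal(mean=np.log(config.mean_rate_target),
                         sigma=config.rate_sigma, size=config.n_units)
    sig = np.concatenate([
        np.full(config.q_baseline, config.baseline_mod_sigma),
        np.full(config.q_drop, config.drop_mod_sigma),
    ])
    gains = rng.lognormal(mean=0.0, sigma=1.0,
                          size=(config.q_total, config.n_units)) ** sig[:, None]
    rates = base[None, :] * gains
    silent = rng.random((config.q_drop, config.n_units)) < config.p_silent
    rates[config.q_baseline:][silent] *= config.silent_factor
    rates *= config.mean_rate_target / rates.mean()
    return rates


def _sample_chain(config: SessionConfig, events: EventSchedule,
                  rng: np.random.Generator) -> np.ndarray:
    """Hidden-state index per bin: a Markov chain restricted per epoch to its
    repertoire, with consumption-window modulation in the drop period."""
    bw = config.bin_width
    epochs = config.epochs
    n_bins = int(round(epochs.session_end / bw))
    centers = (np.arange(n_bins) + 0.5) * bw

    base_states = np.arange(config.q_baseline)
    drop_states = config.q_baseline + np.arange(config.q_drop)
    consume_state = drop_states[-1]
    p_stay = 1.0 - bw / config.dwell_mean

    in_drop = (centers >= epochs.drop_period[0]) & (centers < epochs.drop_period[1])
    # bins inside the consumption window of events where consumption engages
    # the designated state (one persistent bout per event, not bin-wise
    # flicker), clipped to the drop period so the post epoch stays pure
    w_lo, w_hi = config.consume_state_window
    consume_mask = np.zeros(n_bins, dtype=bool)
    for ct in events.consume_times:
        if rng.random() < config.consume_state_prob:
            consume_mask |= (centers >= ct + w_lo) & (centers < ct + w_hi)
    consume_mask &= in_drop

    seq = np.empty(n_bins, dtype=int)
    state = rng.choice(base_states)
    for t in range(n_bins):
        repertoire = drop_states if in_drop[t] else base_states
        if state not in repertoire:  # epoch boundary: jump to a random member
            state = rng.choice(repertoire)
        elif t > 0 and not (rng.random() < p_stay):
            others = repertoire[repertoire != state]
            if others.size:
                state = rng.choice(others)
        seq[t] = consume_state if consume_mask[t] else state
    return seq


def simulate_session(config: SessionConfig) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate one full session: event schedule, hidden-state chain, and
    per-unit inhomogeneous Poisson spikes with state-dependent rates.

    Deterministic under ``config.seed``.
    """
    root = np.random.default_rng(config.seed)
    rng_ev, rng_rate, rng_chain, rng_spk = [
        np.random.default_rng(s) for s in root.integers(2**31, size=4)
    ]
    events = make_event_schedule(config, rng_ev)
    rates = _draw_state_rates(config, rng_rate)
    seq = _sample_chain(config, events, rng_chain)

    bw = config.bin_width
    epochs = config.epochs
    n_bins = seq.size
    lam = rates[seq, :] * bw                     # (T, N) expected counts per bin
    counts = rng_spk.poisson(lam)                # one draw, fixed order
    trains: list[np.ndarray] = []
    for u in range(config.n_units):
        cu = counts[:, u]
        total = int(cu.sum())
        if total == 0:
            trains.append(np.empty(0))
            continue
        bins = np.repeat(np.arange(n_bins), cu)
        times = (bins + rng_spk.random(total)) * bw
        trains.append(np.sort(times))

    labels = ["baseline"] * config.q_baseline + ["drop"] * config.q_drop
    spikes = SpikeTrainSet(
        unit_ids=[f"u{u:02d}" for u in range(config.n_units)],
        spikes=trains,
        session_start=0.0,
        session_end=epochs.session_end,
        epochs=epochs,
        events=events,
    )
    truth = GroundTruth(seq, labels, rates, events.drop_times, events.consume_times)
    return spikes, truth


def simulate_hmm_rates(params, T: int, seed: int) -> tuple[RateMatrix, np.ndarray]:
    """Sample a state path from an HMM and diagonal-Gaussian rate emissions.

    Direct emission-space sampler for exercising the HMM machinery with known
    parameters; negative Gaussian samples are clipped at 0 to keep the result
    a valid rate matrix (irrelevant when means are >= 3 sd above zero).
    """
    rng = np.random.default_rng(seed)
    Q, N = params.mu.shape
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(Q, p=params.pi)
    for t in range(1, T):
        path[t] = rng.choice(Q, p=params.A[path[t - 1]])
    obs = params.mu[path] + rng.standard_normal((T, N)) * np.sqrt(params.var[path])
    values = np.clip(obs.T, 0.0, None)
    return RateMatrix(values, DEFAULT_BIN_WIDTH, 0.0), path


def write_session(out_dir: str | Path, config: SessionConfig,
                  spikes: SpikeTrainSet, truth: GroundTruth) -> None:
    """Write spikes/events/epochs tables plus config and ground-truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spikes(out / "spikes.csv", spikes)
    write_events(out / "events.csv", spikes.events)
    write_epochs(out / "epochs.csv", spikes.epochs)
    cfg = asdict(config)
    cfg["consume_state_window"] = list(config.consume_state_window)
    write_json(out / "session_config.json", cfg)
    write_json(
        out / "ground_truth.json",
        {
            "state_sequence": truth.state_sequence,
            "state_repertoire_label": truth.state_repertoire_label,
            "true_rates": truth.true_rates,
            "event_times": truth.event_times,
            "consume_times": truth.consume_times,
        },
    )
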