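"""End-to-end reproducible run: simulate/ingest -> iFR -> HMM -> complexity
-> state analyses, with every stage's tables written as delimited text.

A single master seed deterministically spawns per-stage seeds (logged), so
the same config + seed reproduces every output table byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import complexity as cx
from . import core, hmm, preprocessing, state_analysis, synthetic

log = logging.getLogger("ensemblestates")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; either simulate a session or point
    ``spikes_path``/``events_path``/``epochs_path`` at existing tables."""

    out_dir: str = "run_out"
    seed: int = 0
    # input: simulation (default) or files
    simulate: bool = True
    session: synthetic.SessionConfig = field(default_factory=synthetic.SessionConfig)
    spikes_path: str | None = None
    events_path: str | None = None
    epochs_path: str | None = None
    # preprocessing
    bin_width: float = core.DEFAULT_BIN_WIDTH
    kernel_sd: float = preprocessing.DEFAULT_KERNEL_SD
    rate_threshold: float = 0.1
    # model selection / fitting
    q_grid: list[int] = field(default_factory=lambda: list(range(1, 11)))
    q_fixed: int | None = None       # skip selection when set
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 5
    # complexity
    entropy_smooth_bins: int = 3
    kc_window: float = 150.0
    kc_step: float = 5.0
    pca_coverage: float = 0.90
    pca_smooth_bins: int = 61
    # peri-event / regression
    perievent_half_window: float = 5.0
    pellet_drop_window: tuple[float, float] = state_analysis.PELLET_DROP_WINDOW
    consumption_window: tuple[float, float] = state_analysis.CONSUMPTION_WINDOW

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sess = raw.pop("session", None)
        cfg = cls(**raw)
        if sess is not None:
            if "consume_state_window" in sess:
                sess["consume_state_window"] = tuple(sess["consume_state_window"])
            cfg.session = synthetic.SessionConfig(**sess)
        for key in ("pellet_drop_window", "consumption_window"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {n: int(rng.integers(2**31)) for n in names}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed, ["simulate", "select_q", "fit"])
    stage = "setup"
    try:
        import ensemblestates
        log.info("ensemblestates %s; numpy %s; master seed %d; stage seeds %s",
                 getattr(ensemblestates, "__version__", "?"),
                 np.__version__, config.seed, seeds)

        stage = "ingest"
        truth = None
        if config.simulate:
            sess_cfg = synthetic.SessionConfig(
                **{**asdict(config.session),
                   "seed": seeds["simulate"],
                   "consume_state_window": config.session.consume_state_window})
            spikes, truth = synthetic.simulate_session(sess_cfg)
            synthetic.write_session(out / "session", sess_cfg, spikes, truth)
        else:
            for name in ("spikes_path", "events_path", "epochs_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            epochs = core.read_epochs(config.epochs_path)
            events = core.read_events(config.events_path)
            spikes = core.read_spikes(config.spikes_path, epochs.session_start,
                                      epochs.session_end, epochs, events)
        log.info("session: %d units, %.0f s", spikes.n_units, spikes.duration)

        stage = "preprocess"
        spikes = preprocessing.filter_low_rate(spikes, config.rate_threshold)
        rates = preprocessing.compute_ifr(spikes, config.bin_width, config.kernel_sd)
        core.write_rate_matrix(out / "rates.csv", rates)
        log.info("iFR: %d units x %d bins after %.2f Hz exclusion",
                 rates.n_units, rates.n_bins, config.rate_threshold)

        stage = "select_q"
        if config.q_fixed is not None:
            q_star = config.q_fixed
            selection = None
        else:
            selection = hmm.select_num_states(
                rates, config.q_grid, seeds["select_q"],
                config.max_iter, config.tol, config.n_restarts)
            q_star = selection.q_star
            core.write_json(out / "model_selection.json", {
                "q_grid": selection.q_grid, "bic": selection.bic,
                "bic_normalized": selection.bic_normalized,
                "q_star": selection.q_star, "rule_fired": selection.rule_fired,
            })
            log.info("BIC selection: q_star=%d (%s)", q_star, selection.rule_fired)

        stage = "fit"
        if selection is not None and q_star in selection.fits:
            fit = selection.fits[q_star]
        else:
            fit = hmm.fit_hmm(rates, q_star, seeds["fit"], config.max_iter,
                              config.tol, config.n_restarts)
        hmm.write_hmm_params(out / "hmm_params.json", fit)
        core.write_posteriors(out / "posteriors.csv", fit.posteriors)
        log.info("fit: Q=%d loglik=%.2f (%d EM iters, %d restarts)",
                 q_star, fit.final_loglik, fit.loglik_trace.size,
                 fit.n_restarts_used)

        stage = "complexity"
        epochs = spikes.epochs
        smoothed = cx.smooth_posteriors(fit.posteriors, config.entropy_smooth_bins)
        ent = cx.entropy_trace(smoothed)
        eff = cx.effective_state_count(ent)
        kc = cx.kolmogorov_trace(rates, config.kc_window, config.kc_step)
        pca = cx.pca_complexity_trace(rates, config.pca_coverage,
                                      config.pca_smooth_bins)
        for name, tr in (("entropy", ent), ("effective_states", eff),
                         ("kc", kc), ("pca", pca)):
            cx.write_trace(out / f"trace_{name}.csv", tr)
        change = cx.cusum_change_point(ent.values, ent.times)
        log.info("entropy change point: bin %d (t=%.1f s)", change.k,
                 -1.0 if change.time is None else change.time)

        stage = "state_analysis"
        cat = state_analysis.categorize_states(fit.posteriors, epochs)
        cat.to_frame().to_csv(out / "state_categorization.csv", index=False)
        summary_peri = state_analysis.perievent_average(
            fit.posteriors, spikes.events, epochs, config.perievent_half_window)
        top_idx, top_prof = state_analysis.top_perievent_states(
            summary_peri, min(3, fit.params.Q))
        np.savetxt(out / "perievent_top_states.csv",
                   np.column_stack([summary_peri.rel_times, top_prof.T]),
                   delimiter=",", fmt="%.9f",
                   header="rel_time_s," + ",".join(f"state{i}" for i in top_idx),
                   comments="")
        design = state_analysis.make_factor_design(
            rates, spikes.events, epochs,
            config.pellet_drop_window, config.consumption_window)
        reg = state_analysis.unit_factor_regression(rates, design)
        reg.to_csv(out / "unit_regression.csv", index=False, float_format="%.9g")
        try:
            ks_kc = state_analysis.epoch_distribution_test(kc, epochs)
        except ValueError as exc:  # too few KC windows in an epoch
            log.warning("KC epoch KS test skipped: %s", exc)
            ks_kc = {"skipped": str(exc)}

        stage = "summary"
        def epoch_means(tr):
            return {e: float(np.mean(tr.epoch_values(epochs, e)))
                    for e in ("baseline", "drop", "post")}
        summary = {
            "n_units": rates.n_units,
            "n_bins": rates.n_bins,
            "mean_rate_hz": float(rates.values.mean()),
            "q_star": int(q_star),
            "final_loglik": float(fit.final_loglik),
            "entropy_nats": epoch_means(ent),
            "effective_states": epoch_means(eff),
            "kc_bytes": epoch_means(kc),
            "pca_components": epoch_means(pca),
            "entropy_change_point": {"k": change.k, "time_s": change.time,
                                     "degenerate": change.degenerate},
            "dominance": {
                "n_baseline_dominant": int(cat.labels.count("baseline_dominant")),
                "n_drop_dominant": int(cat.labels.count("drop_dominant")),
            },
            "perievent_auc": state_analysis.perievent_entropy_auc(summary_peri),
            "top_perievent_states": [int(i) for i in top_idx],
            "ks_kc": ks_kc,
            "seeds": seeds,
        }
        if truth is not None:
            summary["ground_truth"] = {
                "q_true": len(truth.state_repertoire_label),
                "boundary_time_s": float(epochs.drop_period[0]),
            }
        core.write_json(out / "summary.json", summary)
        log.info("done")
        return summary
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
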