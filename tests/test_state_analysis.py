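"""State categorisation, peri-event analyses, factor regression, KS tests."""

import numpy as np
import pytest

import ensemblestates as es
from ensemblestates.core import EpochDefinition, EventSchedule
from ensemblestates.state_analysis import auc_comparison_across_sessions

EPOCHS = EpochDefinition((0.0, 100.0), (100.0, 220.0), (220.0, 260.0))


def _post(values, bw=0.5, t0=0.0):
    return es.PosteriorMatrix(np.asarray(values, float), bw, t0)


def _block_posteriors(levels_by_epoch, n_bins=520):
    """Posteriors constant within each epoch; levels_by_epoch is a dict of
    epoch -> per-state level vector (each summing to 1)."""
    centers = (np.arange(n_bins) + 0.5) * 0.5
    which = EPOCHS.epoch_of(centers)
    Q = len(next(iter(levels_by_epoch.values())))
    v = np.empty((Q, n_bins))
    for ep, lv in levels_by_epoch.items():
        v[:, which == ep] = np.asarray(lv)[:, None]
    return _post(v)


# ---------------------------------------------------------------------------
# categorisation
# ---------------------------------------------------------------------------

def test_categorize_clear_dominance():
    post = _block_posteriors({
        "baseline": [0.8, 0.2], "drop": [0.1, 0.9], "post": [0.8, 0.2]})
    cat = es.categorize_states(post, EPOCHS)
    assert cat.labels == ["baseline_dominant", "drop_dominant"]
    assert cat.baseline_mean[0] == pytest.approx(0.8)
    assert cat.drop_mean[0] == pytest.approx(0.1)
    assert cat.post_mean[0] == pytest.approx(0.8)


def test_categorize_tie_is_drop_dominant():
    post = _block_posteriors({
        "baseline": [0.5, 0.5], "drop": [0.5, 0.5], "post": [0.5, 0.5]})
    cat = es.categorize_states(post, EPOCHS)
    assert cat.labels == ["drop_dominant", "drop_dominant"]


def test_categorize_uses_equal_duration_drop_interval():
    """Dominance compares baseline against only the first baseline-length
    segment of the drop period."""
    n = 520
    centers = (np.arange(n) + 0.5) * 0.5
    v = np.full((2, n), 0.5)
    early = (centers >= 100.0) & (centers < 200.0)   # first 100 s of drop
    late = (centers >= 200.0) & (centers < 220.0)
    v[0, early], v[1, early] = 0.9, 0.1
    v[0, late], v[1, late] = 0.0, 1.0
    cat = es.categorize_states(_post(v), EPOCHS)
    assert cat.drop_mean[0] == pytest.approx(0.9)    # late bins ignored
    assert cat.labels[0] == "drop_dominant"


def test_categorization_is_exhaustive_and_exclusive():
    rng = np.random.default_rng(0)
    post = _post(rng.dirichlet(np.ones(6), size=520).T)
    cat = es.categorize_states(post, EPOCHS)
    assert len(cat.labels) == 6
    assert set(cat.labels) <= {"baseline_dominant", "drop_dominant"}


# ---------------------------------------------------------------------------
# epoch posterior comparison
# ---------------------------------------------------------------------------

def test_epoch_comparison_identical_epochs_gives_t0_p1():
    post = _block_posteriors({
        "baseline": [0.7, 0.3], "drop": [0.7, 0.3], "post": [0.7, 0.3]})
    cat = es.categorize_states(post, EPOCHS)
    out = es.epoch_posterior_comparison([cat])
    (lab,) = out.keys()
    assert out[lab]["t_baseline_vs_drop"] == pytest.approx(0.0, abs=1e-12)
    assert out[lab]["p_baseline_vs_drop"] == pytest.approx(1.0)


def test_epoch_comparison_hand_checked_paired_t():
    """Baseline means (0.8, 0.6) vs drop means (0.1, 0.1): differences
    (0.7, 0.5) give t = 6.0 with df = 1."""
    cat = es.StateCategorization(
        baseline_mean=np.array([0.8, 0.6]),
        drop_mean=np.array([0.1, 0.1]),
        post_mean=np.array([0.8, 0.6]),
        labels=["baseline_dominant", "baseline_dominant"],
    )
    out = es.epoch_posterior_comparison([cat])["baseline_dominant"]
    assert out["t_baseline_vs_drop"] == pytest.approx(6.0)
    assert out["df"] == 1
    assert out["baseline_mean"] == pytest.approx(0.7)
    assert out["dominance_ratio"] == pytest.approx(0.7 / 0.1)


# ---------------------------------------------------------------------------
# peri-event averaging and entropy AUC
# ---------------------------------------------------------------------------

def _drop_events(times):
    return EventSchedule(tuple(["drop"] * len(times)), np.asarray(times, float))


def test_perievent_constant_posteriors_average_to_constant():
    post = _block_posteriors({"baseline": [0.25] * 4, "drop": [0.25] * 4,
                              "post": [0.25] * 4})
    ev = _drop_events(np.arange(105.0, 215.0, 10.0))
    summary = es.perievent_average(post, ev, EPOCHS)
    assert summary.avg_posteriors.shape == (4, 20)
    assert np.allclose(summary.avg_posteriors, 0.25)
    assert np.allclose(summary.entropy_profile, np.log(4))


def test_perievent_all_90_windows_usable():
    """90 drops at 10 s spacing in a 900 s drop period: W=20, all used."""
    epochs = EpochDefinition((0.0, 900.0), (900.0, 1800.0), (1800.0, 2100.0))
    n = 4200
    post = _post(np.full((3, n), 1 / 3))
    ev = _drop_events(900.0 + 10.0 * np.arange(90))
    summary = es.perievent_average(post, ev, epochs)
    assert summary.n_events_used == 90
    assert summary.avg_posteriors.shape[1] == 20
    assert summary.auc_baseline_windows.size == 90


def test_perievent_uniform_auc_formula():
    """Uniform over Q=25: AUC = 20 ln 25 ~ 64.38; one-hot: AUC = 0."""
    epochs = EpochDefinition((0.0, 900.0), (900.0, 1800.0), (1800.0, 2100.0))
    post = _post(np.full((25, 4200), 1 / 25))
    ev = _drop_events(900.0 + 10.0 * np.arange(90))
    summary = es.perievent_average(post, ev, epochs)
    assert summary.auc_event == pytest.approx(20 * np.log(25))
    assert 20 * np.log(25) == pytest.approx(64.38, abs=5e-3)
    assert np.allclose(summary.auc_baseline_windows, 20 * np.log(25))

    v = np.zeros((25, 4200))
    v[3] = 1.0
    summary = es.perievent_average(_post(v), ev, epochs)
    assert summary.auc_event == 0.0


def test_perievent_requires_two_events():
    post = _post(np.full((2, 520), 0.5))
    with pytest.raises(ValueError, match="fewer than 2"):
        es.perievent_average(post, _drop_events([105.0]), EPOCHS)


def test_perievent_commutes_with_state_permutation():
    rng = np.random.default_rng(1)
    v = rng.dirichlet(np.ones(4), size=520).T
    ev = _drop_events(np.arange(105.0, 215.0, 10.0))
    perm = np.array([2, 0, 3, 1])
    s1 = es.perievent_average(_post(v), ev, EPOCHS)
    s2 = es.perievent_average(_post(v[perm]), ev, EPOCHS)
    assert np.allclose(s1.avg_posteriors[perm], s2.avg_posteriors)


def test_auc_comparison_across_sessions_paired_t():
    summaries = []
    for base, peri in [(10.0, 8.0), (11.0, 8.5), (9.5, 8.2)]:
        summaries.append(es.PeriEventSummary(
            half_window=5.0, avg_posteriors=np.full((2, 20), 0.5),
            rel_times=np.zeros(20), entropy_profile=np.zeros(20),
            auc_event=peri, auc_event_windows=np.array([peri]),
            auc_baseline_windows=np.array([base]), n_events_used=1))
    out = auc_comparison_across_sessions(summaries)
    from scipy import stats
    t_ref, p_ref = stats.ttest_rel([10.0, 11.0, 9.5], [8.0, 8.5, 8.2])
    assert out["t"] == pytest.approx(float(t_ref))
    assert out["df"] == 2


def test_top_states_by_constant_levels():
    post = _block_posteriors({"baseline": [0.5, 0.3, 0.1, 0.1],
                              "drop": [0.5, 0.3, 0.1, 0.1],
                              "post": [0.5, 0.3, 0.1, 0.1]})
    ev = _drop_events(np.arange(105.0, 215.0, 10.0))
    summary = es.perievent_average(post, ev, EPOCHS)
    idx, prof = es.top_perievent_states(summary, 3)
    assert list(idx[:2]) == [0, 1]
    assert prof.shape == (3, 20)
    idx_all, _ = es.top_perievent_states(summary, 4)
    assert list(idx_all[:2]) == [0, 1]
    with pytest.raises(ValueError):
        es.top_perievent_states(summary, 5)


# ---------------------------------------------------------------------------
# factor design and regression
# ---------------------------------------------------------------------------

def _design_fixture(n_bins=520):
    rng = np.random.default_rng(2)
    values = rng.uniform(0.5, 2.0, size=(3, n_bins))
    rm = es.RateMatrix(values, 0.5, 0.0, epochs=EPOCHS)
    ev = _drop_events(np.arange(100.0, 220.0, 10.0))
    design = es.make_factor_design(rm, ev, EPOCHS)
    return rm, ev, design


def test_factor_design_partitions_drop_bins():
    rm, _, design = _design_fixture()
    in_drop = (rm.bin_centers >= 100.0) & (rm.bin_centers < 220.0)
    assert design.bin_indices.size == in_drop.sum()
    assert np.all(design.indicators.sum(axis=1) == 1)  # exclusive, exhaustive
    assert np.all(design.indicators.sum(axis=0) > 0)


def test_factor_windows_relative_to_drops():
    rm, _, design = _design_fixture()
    centers = rm.bin_centers[design.bin_indices]
    rel = (centers - 100.0) % 10.0
    rel = np.where(rel >= 9.5, rel - 10.0, rel)      # wrap the -0.5 s lead-in
    is_pd = design.indicators[:, 1] == 1
    is_co = design.indicators[:, 2] == 1
    assert np.all((rel[is_pd] >= -0.5) & (rel[is_pd] < 1.5))
    assert np.all((rel[is_co] >= 3.0) & (rel[is_co] < 6.0))


def test_regression_exact_indicator_unit():
    """A unit firing exactly 1 on consumption bins recovers beta=(0,0,1)."""
    rm, _, design = _design_fixture()
    values = np.zeros((2, rm.n_bins))
    values[0, design.bin_indices] = design.indicators[:, 2]       # consumption
    values[1, design.bin_indices] = 0.5 * design.indicators[:, 1] # pellet drop
    rm2 = es.RateMatrix(values, 0.5, 0.0, epochs=EPOCHS)
    df = es.unit_factor_regression(rm2, design)
    u0 = df[df.unit == "u0"].set_index("factor")
    assert u0.loc["consumption", "beta"] == pytest.approx(1.0, abs=1e-12)
    assert u0.loc["intertrial", "beta"] == pytest.approx(0.0, abs=1e-12)
    assert u0.loc["consumption", "p"] < 1e-12
    u1 = df[df.unit == "u1"].set_index("factor")
    assert u1.loc["pellet_drop", "beta"] == pytest.approx(0.5, abs=1e-12)


def test_regression_negative_coefficient_unit():
    """A unit suppressed on pellet-drop bins yields a negative beta."""
    rm, _, design = _design_fixture()
    values = np.full((1, rm.n_bins), 2.0)
    sub = values[0, design.bin_indices]
    sub[design.indicators[:, 1] == 1] = 0.0   # silenced at the drop
    values[0, design.bin_indices] = sub
    rm2 = es.RateMatrix(values, 0.5, 0.0, epochs=EPOCHS)
    df = es.unit_factor_regression(rm2, design)
    row = df[(df.unit == "u0") & (df.factor == "pellet_drop")].iloc[0]
    # no intercept: the pellet-drop coefficient is that factor's mean rate,
    # far below the other factors' coefficients
    assert row.beta == pytest.approx(0.0, abs=1e-12)
    inter = df[(df.unit == "u0") & (df.factor == "intertrial")].iloc[0]
    assert inter.beta == pytest.approx(2.0, abs=1e-12)


def test_regression_residuals_orthogonal_to_design():
    rm, _, design = _design_fixture()
    y = rm.values[0, design.bin_indices]
    import statsmodels.api as sm
    res = sm.OLS(y, design.indicators).fit()
    assert np.allclose(design.indicators.T @ res.resid, 0.0, atol=1e-8)


def test_null_units_have_uniform_contrast_pvalues():
    """Units with no factor selectivity: factor-contrast p-values are
    indistinguishable from uniform (KS not rejected)."""
    from scipy import stats
    rng = np.random.default_rng(3)
    rm, _, design = _design_fixture()
    values = rng.uniform(0.0, 2.0, size=(200, rm.n_bins))
    rm2 = es.RateMatrix(values, 0.5, 0.0, epochs=EPOCHS)
    df = es.factor_contrasts(rm2, design)
    p = df[df.contrast == "consumption-intertrial"]["p"].to_numpy()
    assert p.size == 200
    assert stats.kstest(p, "uniform").pvalue > 0.01
    assert np.mean(np.abs(df["t"]) > 2.5) < 0.05  # |t| mostly small


# ---------------------------------------------------------------------------
# epoch distribution (KS) tests
# ---------------------------------------------------------------------------

def _trace(values, times):
    return es.ComplexityTrace("kc_bytes", np.asarray(times, float),
                              np.asarray(values, float))


def test_ks_identical_samples():
    times = np.linspace(1, 259, 200)
    vals = np.tile(np.arange(10.0), 20)
    out = es.epoch_distribution_test(_trace(vals, times), EPOCHS)
    assert out["baseline_vs_drop"]["statistic"] < 0.1
    assert out["baseline_vs_drop"]["p"] > 0.5


def test_ks_disjoint_supports():
    times = np.linspace(1, 259, 200)
    which = EPOCHS.epoch_of(times)
    vals = np.where(which == "baseline", 100.0, 0.0) + np.arange(200) * 1e-3
    out = es.epoch_distribution_test(_trace(vals, times), EPOCHS)
    assert out["baseline_vs_drop"]["statistic"] == pytest.approx(1.0)
    assert out["baseline_vs_drop"]["p"] < 1e-10


def test_ks_insufficient_samples():
    with pytest.raises(ValueError, match="fewer than 5"):
        es.epoch_distribution_test(_trace([1, 2, 3], [10.0, 110.0, 230.0]),
                                   EPOCHS)
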