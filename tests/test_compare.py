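import itertools

import numpy as np
import pytest

from hyraxnet.compare import (
    SimilarityMatrix,
    choose_threshold,
    combine_dependent_pvalues,
    context_correlations,
    cosine_similarity,
    daynight_contrast,
    paired_location_tests,
    portmanteau_autocorr,
    temporal_similarity,
    threshold_scan,
    weighted_vs_binary_test,
)
from hyraxnet.netbuild import AssociationMatrix
from hyraxnet.nullmodels import PermConfig
from hyraxnet.simulate import SimConfig, simulate_study
from hyraxnet.workflow import (
    build_context_networks,
    context_weight_stack,
    make_ensemble,
    null_calibration_config,
    prepare_study,
)


# ---------------------------------------------------------------------------
# cosine


def test_cosine_worked_examples():
    assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))
    assert np.isnan(cosine_similarity([0, 0], [0, 0]))
    assert cosine_similarity([0, 0], [1, 0]) == 0.0
    with pytest.raises(ValueError):
        cosine_similarity([1, 2], [1, 2, 3])


def test_temporal_similarity_diagonal_and_symmetry(period_nets):
    sim = temporal_similarity(period_nets, "weighted")
    nonempty = [i for i, m in enumerate(period_nets) if np.any(m.weights)]
    for i in nonempty:
        assert sim.cosine[i, i] == pytest.approx(1.0)
    finite = ~np.isnan(sim.cosine)
    assert np.allclose(sim.cosine[finite], sim.cosine.T[finite.T])


def test_temporal_similarity_attaches_bh_adjusted_pvalues(period_nets, study, ensemble):
    sim = temporal_similarity(period_nets, "weighted", ensemble)
    defined = ~np.isnan(sim.p_adj)
    assert np.all((sim.p_adj[defined] >= 0) & (sim.p_adj[defined] <= 1))
    # p_perm counts strictly-larger nulls, p_upper is tie-inclusive
    assert np.all(sim.p_perm + sim.p_upper >= 1 - 1e-12)
    counts = sim.counts
    assert counts["n_entries"] == sim.cosine.size
    total = (counts["n_higher_than_chance"] + counts["n_lower_than_chance"]
             + counts["n_not_significant"] + counts["n_undefined"])
    assert total == counts["n_entries"]


def test_temporal_similarity_rejects_unknown_mode(period_nets):
    with pytest.raises(ValueError):
        temporal_similarity(period_nets, "ranked")


# ---------------------------------------------------------------------------
# context correlations


def test_context_network_compared_to_itself_is_one(study):
    nets = build_context_networks(study)
    sim = context_correlations(nets)
    for i, lab in enumerate(sim.labels):
        if np.any(nets[lab].weights):
            assert sim.cosine[i, i] == pytest.approx(1.0)


def test_degenerate_single_permutation_gives_zero_or_one_p(study):
    nets = build_context_networks(study)
    ens = make_ensemble(study, PermConfig(n_perm=1, seed=0))
    sim = context_correlations(nets, ens)
    defined = ~np.isnan(sim.p_perm)
    assert set(np.unique(sim.p_perm[defined])) <= {0.0, 1.0}


def test_shared_preference_structure_beats_median_null_cosine():
    """Day and night networks built from the same partner preferences are
    more similar than the margin-preserving null in nearly all replicates."""
    hits = 0
    for i in range(20):
        cfg = null_calibration_config(
            3100 + i, shared_preferences=True,
            selectivity_day=0.05, selectivity_night=0.05,
            n_individuals=20, n_groups=2,
        )
        data = prepare_study(cfg)
        ens = make_ensemble(data, PermConfig(n_perm=40, seed=9100 + i))
        nets = build_context_networks(data)
        labels = list(nets)
        li, lj = labels.index("day_active"), labels.index("night_active")
        iu = np.triu_indices(len(nets["day_active"].roster), k=1)
        slots = {k: float(nets[k].n_slots) for k in labels}
        obs = cosine_similarity(
            nets["day_active"].weights[iu], nets["night_active"].weights[iu]
        )
        null_cos = []
        for r in range(ens.n_perm):
            W = context_weight_stack(ens, r, labels, slots)
            null_cos.append(cosine_similarity(W[li][iu], W[lj][iu]))
        hits += obs > np.nanmedian(null_cos)
    assert hits >= 18


# ---------------------------------------------------------------------------
# threshold scan


def test_choose_threshold_picks_candidate_before_largest_drop():
    thresholds = [300, 600, 1500, 2700, 3600]
    curve = [1.0, 0.98, 0.97, 0.50, 0.48]
    chosen, max_drop, no_drop = choose_threshold(thresholds, curve)
    assert (chosen, no_drop) == (1500.0, False)
    assert max_drop == pytest.approx(0.47)


def test_choose_threshold_largest_drop_after_25_minutes():
    chosen, _, no_drop = choose_threshold([600, 1500, 3600], [1.0, 0.95, 0.40])
    assert (chosen, no_drop) == (1500.0, False)


def test_choose_threshold_flags_flat_curves():
    chosen, max_drop, no_drop = choose_threshold([1, 2, 3], [0.9, 0.9, 0.9])
    assert chosen is None and no_drop
    with pytest.raises(ValueError):
        choose_threshold([1], [0.9])
    with pytest.raises(ValueError):
        choose_threshold([2, 1], [0.9, 0.8])


def test_identical_durations_give_no_drop():
    import pandas as pd

    cfg = SimConfig(n_individuals=8, n_groups=2, n_days=2, seed=0)
    records, _ = simulate_study(cfg)
    records = records.copy()
    records["duration_s"] = 600
    scan = threshold_scan(records, [700, 1400, 2100], cfg.phase_config())
    assert scan.no_drop and scan.chosen is None


def test_duration_mixture_scan_finds_threshold_between_modes():
    """Short mode ~5 min, long mode ~60 min: the chosen cut-off lands in the
    gap between the modes in nearly all replicates."""
    ok = 0
    candidates = [600, 900, 1500, 2400, 3600, 5400]
    for i in range(20):
        cfg = SimConfig(
            n_individuals=12, n_groups=3, n_days=6,
            dur_active=(300.0, 0.2), dur_passive=(3600.0, 0.2),
            p_passive_day=0.3, p_passive_night=0.5, seed=4000 + i,
        )
        records, _ = simulate_study(cfg)
        scan = threshold_scan(records, candidates, cfg.phase_config())
        ok += (not scan.no_drop) and scan.chosen is not None and 600 <= scan.chosen <= 2400
    assert ok >= 18


# ---------------------------------------------------------------------------
# dependent p-value combination


def test_single_p_combination_equals_its_empirical_rank():
    rng = np.random.default_rng(3)
    null_p = rng.uniform(size=(500, 1))
    obs = 0.3
    combined = combine_dependent_pvalues([obs], null_p)
    floor = 1.0 / 501
    expected = np.mean(np.maximum(null_p[:, 0], floor) <= max(obs, floor))
    assert combined == pytest.approx(expected)


def test_observed_smaller_than_every_null_gives_zero():
    null_p = np.full((100, 3), 0.8)
    assert combine_dependent_pvalues([0.01, 0.01, 0.01], null_p) == 0.0


def test_observed_equal_to_nulls_gives_one():
    null_p = np.full((100, 2), 0.5)
    assert combine_dependent_pvalues([0.5, 0.5], null_p) == 1.0


def test_zero_pvalues_are_floored_not_infinite():
    null_p = np.full((9, 2), 0.5)
    out = combine_dependent_pvalues([0.0, 0.0], null_p, n_perm=9)
    assert np.isfinite(out)


def test_analytic_mode_is_the_chisquare_fisher_p():
    from scipy import stats

    p = [0.02, 0.5, 0.9]
    s = -2 * np.sum(np.log(p))
    out = combine_dependent_pvalues(p, np.ones((10, 3)), analytic=True, n_perm=10**9)
    assert out == pytest.approx(stats.chi2.sf(s, df=6))


def test_all_nan_pvalues_rejected():
    with pytest.raises(ValueError):
        combine_dependent_pvalues([np.nan], np.ones((5, 1)))


# ---------------------------------------------------------------------------
# day/night contrast


def test_identical_day_night_traits_give_zero_transition_pvalues():
    obs = np.full(6, 3.0)
    rng = np.random.default_rng(0)
    nulls = 3.0 + rng.random((50, 6))  # strictly positive null |deltas|
    res = daynight_contrast(obs, nulls)
    assert len(res.transitions) == 5
    assert np.all(res.observed_abs_diff == 0.0)
    assert np.all(res.p_per_transition == 0.0)
    assert res.combined_p == 1.0  # changes are as small as they can be


def test_large_observed_changes_give_small_combined_p():
    obs = np.array([0.0, 10.0, 0.0, 10.0, 0.0, 10.0])
    rng = np.random.default_rng(1)
    nulls = rng.random((200, 6))
    res = daynight_contrast(obs, nulls)
    assert np.all(res.p_per_transition == 1.0)
    assert res.combined_p < 0.05


def test_undefined_periods_are_skipped():
    obs = np.array([1.0, 2.0, np.nan, 3.0, 4.0])
    nulls = np.tile([1.0, 1.5, 2.0, 2.5, 3.0], (20, 1))
    res = daynight_contrast(obs, nulls)
    assert res.transitions == [(0, 1), (3, 4)]


def test_contrast_requires_usable_transitions():
    with pytest.raises(ValueError):
        daynight_contrast([1.0], np.ones((5, 1)))
    with pytest.raises(ValueError):
        daynight_contrast([1.0, np.nan, 2.0], np.ones((5, 3)))


# ---------------------------------------------------------------------------
# paired tests


def test_paired_tests_match_exhaustive_sign_flip_enumeration():
    x = np.array([2.0, 3.0, 4.0, 0.5])
    y = np.array([1.0, 1.0, 1.0, 1.5])
    d = x - y
    out = paired_location_tests(x, y, alternative="greater")
    means = [
        np.mean(signs * d)
        for signs in itertools.product([-1.0, 1.0], repeat=4)
    ]
    expected = np.mean([m >= d.mean() for m in means])
    assert out["perm_p"] == pytest.approx(expected)
    assert 0 <= out["t_p"] <= 1 and 0 <= out["wilcoxon_p"] <= 1


def test_all_zero_differences_are_degenerate():
    out = paired_location_tests([1.0, 2.0], [1.0, 2.0])
    assert out["t_p"] == 1.0 and out["perm_p"] == 1.0
    assert np.isnan(out["wilcoxon_p"])
    with pytest.raises(ValueError):
        paired_location_tests([1.0], [1.0, 2.0])


def sim_matrix(cos):
    n = cos.shape[0]
    return SimilarityMatrix(labels=list(range(n)), mode="weighted", cosine=cos)


def test_weighted_vs_binary_identical_matrices_not_significant():
    c = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.6], [0.4, 0.6, 1.0]])
    assert weighted_vs_binary_test(sim_matrix(c), sim_matrix(c.copy())) == 1.0


def test_weighted_vs_binary_matches_three_pair_enumeration():
    cw = np.array([[1.0, 0.50, 0.40], [0.50, 1.0, 0.60], [0.40, 0.60, 1.0]])
    cb = np.array([[1.0, 0.70, 0.45], [0.70, 1.0, 0.90], [0.45, 0.90, 1.0]])
    d = np.array([0.20, 0.05, 0.30])
    means = [np.mean(s * d) for s in itertools.product([-1.0, 1.0], repeat=3)]
    expected = np.mean([abs(m) >= abs(d.mean()) for m in means])
    out = weighted_vs_binary_test(sim_matrix(cw), sim_matrix(cb))
    assert out == pytest.approx(expected)


def test_weighted_vs_binary_large_systematic_difference_significant():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.3, 0.5, size=(8, 8))
    cw = (base + base.T) / 2
    np.fill_diagonal(cw, 1.0)
    cb = np.minimum(cw + 0.3, 1.0)
    assert weighted_vs_binary_test(sim_matrix(cw), sim_matrix(cb)) < 0.05
    with pytest.raises(ValueError):
        weighted_vs_binary_test(sim_matrix(cw), sim_matrix(cb[:7, :7]))


# ---------------------------------------------------------------------------
# portmanteau


def test_ljung_box_statistic_matches_hand_formula():
    rng = np.random.default_rng(5)
    s = rng.standard_normal(40)
    stat, p = portmanteau_autocorr(s, 4)
    n = len(s)
    x = s - s.mean()
    denom = np.sum(x**2)
    q = 0.0
    for k in range(1, 5):
        r = np.sum(x[k:] * x[:-k]) / denom
        q += r**2 / (n - k)
    q *= n * (n + 2)
    assert stat == pytest.approx(q, abs=1e-8)
    assert 0 <= p <= 1


def test_ljung_box_white_noise_rejection_rate_is_calibrated():
    rng = np.random.default_rng(0)
    rejections = sum(
        portmanteau_autocorr(rng.standard_normal(60), 5)[1] < 0.05
        for _ in range(200)
    )
    assert 4 <= rejections <= 16  # binomial 95% interval at nominal 5%


def test_ljung_box_detects_strong_autocorrelation():
    rng = np.random.default_rng(1)
    power = 0
    for _ in range(20):
        e = rng.standard_normal(60)
        s = np.empty(60)
        s[0] = e[0]
        for t in range(1, 60):
            s[t] = 0.7 * s[t - 1] + e[t]
        power += portmanteau_autocorr(s, 5)[1] < 0.05
    assert power >= 18


def test_constant_series_is_undefined():
    stat, p = portmanteau_autocorr(np.full(30, 2.0), 3)
    assert np.isnan(stat) and np.isnan(p)
    with pytest.raises(ValueError):
        portmanteau_autocorr(np.arange(5.0), 5)
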