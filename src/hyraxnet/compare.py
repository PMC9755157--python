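"""Comparison machinery: cosine similarity across contexts and periods,
the active/passive threshold scan, day/night trait contrasts, dependent
p-value combination, and the basic paired location tests.

Cosine similarity between two networks is taken on their above-diagonal
weight vectors: u.v / (|u||v|).  Like the underlying association indices
it is only interpretable relative to the data-stream permutation null, so
every similarity here comes with a permutation p-value; p-values over
families of comparisons are Benjamini-Hochberg adjusted.

The day/night contrast measures, per consecutive period transition, the
observed absolute trait difference against its null distribution, and
combines the per-transition p-values with an *empirical* Fisher test: the
Fisher statistic S = -2 * sum(log p) of the observed list is ranked within
the S values of the null replicates themselves, which preserves the
dependence between transitions without modelling it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .netbuild import AssociationMatrix, check_conformable, vectorize_upper
from .nullmodels import fdr_adjust, perm_pvalue, upper_pvalue


def cosine_similarity(u, v) -> float:
    """u.v / (|u||v|); NaN (undefined) when both vectors are zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 and nv == 0:
        return float("nan")
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def _cosine_matrix(V: np.ndarray) -> np.ndarray:
    """Pairwise cosine across rows of V; NaN rows where both norms vanish."""
    norms = np.linalg.norm(V, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Vn = V / safe[:, None]
    C = Vn @ Vn.T
    zero = norms == 0
    C[zero, :] = np.where(zero[None, :], np.nan, 0.0)
    C[:, zero] = C[zero, :].T
    C[np.ix_(zero, zero)] = np.nan
    np.clip(C, -1.0, 1.0, out=C)
    return C


@dataclass
class SimilarityMatrix:
    """Cosine indices over a set of networks plus permutation p-values."""

    labels: list
    mode: str  # 'weighted' | 'binary'
    cosine: np.ndarray
    p_perm: np.ndarray = None  # convention: #(obs > null)/n_perm
    p_upper: np.ndarray = None  # #(null >= obs)/n_perm
    p_adj: np.ndarray = None  # BH-adjusted two-sided
    counts: dict = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return self.cosine.size


def _attach_pvalues(sim: SimilarityMatrix, null_C: np.ndarray) -> None:
    C = sim.cosine
    with np.errstate(invalid="ignore"):
        gt = np.nansum(null_C < C[None, :, :], axis=0)
        ge = np.nansum(null_C >= C[None, :, :], axis=0)
        le = np.nansum(null_C <= C[None, :, :], axis=0)
    R = null_C.shape[0]
    sim.p_perm = gt / R
    sim.p_upper = ge / R
    p_lower = le / R
    two = np.minimum(1.0, 2.0 * np.minimum(sim.p_upper, p_lower))
    undef = np.isnan(C)
    two = np.where(undef, np.nan, two)
    flat = two[~np.isnan(two)]
    adj = np.full(two.shape, np.nan)
    if flat.size:
        adj[~np.isnan(two)] = fdr_adjust(flat)
    sim.p_adj = adj
    higher = (adj <= 0.05) & (sim.p_upper < p_lower)
    lower = (adj <= 0.05) & (p_lower < sim.p_upper)
    sim.counts = {
        "n_entries": int(C.size),
        "n_higher_than_chance": int(np.nansum(higher)),
        "n_lower_than_chance": int(np.nansum(lower)),
        "n_not_significant": int(C.size - np.nansum(higher) - np.nansum(lower) - np.isnan(C).sum()),
        "n_undefined": int(np.isnan(C).sum()),
    }


def temporal_similarity(nets, mode: str, ensemble=None) -> SimilarityMatrix:
    """Full period-by-period cosine matrix (diagonal included).

    ``nets`` is the ordered list of per-period networks; ``mode`` selects
    weighted SRI vectors or their binarizations.  With an ensemble, each
    cell is compared to the cosines of the same cell over the permuted
    streams and BH-adjusted two-sided p-values are attached.
    """
    if mode not in ("weighted", "binary"):
        raise ValueError("mode must be 'weighted' or 'binary'")
    check_conformable(nets)
    V = np.vstack([vectorize_upper(m) for m in nets])
    if mode == "binary":
        V = (V > 0).astype(float)
    sim = SimilarityMatrix(
        labels=[m.period_id for m in nets], mode=mode, cosine=_cosine_matrix(V)
    )
    if ensemble is not None:
        from .workflow import period_weight_stack

        slots = np.array([m.n_slots for m in nets], dtype=float)
        iu = np.triu_indices(len(nets[0].roster), k=1)
        context = nets[0].context

        def vec(r):
            W = period_weight_stack(ensemble, r, len(nets), slots, context=context)
            Vr = W[:, iu[0], iu[1]]
            return (Vr > 0).astype(float) if mode == "binary" else Vr

        null_C = np.stack([_cosine_matrix(vec(r)) for r in range(ensemble.n_perm)])
        _attach_pvalues(sim, null_C)
    return sim


def context_correlations(nets: dict, ensemble=None) -> SimilarityMatrix:
    """Pairwise cosines between the four phase x context networks.

    ``nets`` maps labels (e.g. 'day_active') to conformable networks.
    p-values are BH-adjusted across the off-diagonal comparisons.
    """
    labels = list(nets)
    check_conformable(list(nets.values()))
    V = np.vstack([vectorize_upper(nets[k]) for k in labels])
    sim = SimilarityMatrix(labels=labels, mode="weighted", cosine=_cosine_matrix(V))
    if ensemble is not None:
        from .workflow import context_weight_stack

        iu = np.triu_indices(len(nets[labels[0]].roster), k=1)
        slots = {k: float(nets[k].n_slots) for k in labels}

        def vec(r):
            W = context_weight_stack(ensemble, r, labels, slots)
            return W[:, iu[0], iu[1]]

        null_C = np.stack([_cosine_matrix(vec(r)) for r in range(ensemble.n_perm)])
        _attach_pvalues(sim, null_C)
    return sim


@dataclass
class ThresholdScan:
    thresholds: np.ndarray
    mean_strength: np.ndarray
    cosine_to_baseline: np.ndarray
    chosen: float | None
    max_drop: float
    no_drop: bool


def choose_threshold(thresholds, cosine_curve, min_drop_frac: float = 0.5):
    """Candidate immediately before the largest single-step cosine drop.

    Flags 'no drop' when the largest step is less than ``min_drop_frac`` of
    the curve's total range (or the curve is flat).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    curve = np.asarray(cosine_curve, dtype=float)
    if thresholds.size < 2:
        raise ValueError("need at least two candidate thresholds")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    steps = -np.diff(curve)  # positive = drop
    rng = np.nanmax(curve) - np.nanmin(curve)
    max_drop = float(np.nanmax(steps)) if steps.size else 0.0
    if rng == 0 or max_drop <= 0 or max_drop < min_drop_frac * rng:
        return None, max_drop, True
    k = int(np.nanargmax(steps))
    return float(thresholds[k]), max_drop, False


def threshold_scan(
    records,
    candidate_thresholds,
    phase_config,
    phase: str | None = None,
    min_drop_frac: float = 0.5,
    interval_s: int = 300,
) -> ThresholdScan:
    """Scan candidate duration cut-offs for the active/passive boundary.

    For each candidate T a full-study network is built from encounters of
    duration <= T (optionally restricted to one phase); the scan records
    its mean strength and its cosine similarity to the baseline network of
    the smallest candidate.  A sudden cosine drop marks the duration after
    which long, sleep-like contacts start reshaping the network.
    """
    from .netbuild import build_sri
    from .preprocess import discretize, label_phase

    thresholds = np.asarray(sorted(set(candidate_thresholds)), dtype=float)
    if thresholds.size < 2:
        raise ValueError("need at least two candidate thresholds")
    roster = tuple(sorted(set(records["reporter"]) | set(records["partner"])))
    if phase is None:
        n_slots = sum(
            phase_config.n_slots(p) for p in range(phase_config.n_periods)
        )
    else:
        n_slots = sum(
            phase_config.n_slots(p)
            for p in range(phase_config.n_periods)
            if (p % 2 == 0) == (phase == "day")
        )
    strengths = []
    vectors = []
    for t in thresholds:
        sub = records[records["duration_s"] <= t]
        ev = discretize(sub, phase_config.epoch, interval_s)
        if phase is not None and len(ev):
            ev = label_phase(ev, phase_config, interval_s)
            ev = ev[ev["phase"] == phase]
        net = build_sri(ev, None, "all", roster, n_slots)
        strengths.append(net.weights.sum(axis=1).mean())
        vectors.append(vectorize_upper(net))
    base = vectors[0]
    curve = np.array([cosine_similarity(base, v) if np.any(v) or np.any(base) else np.nan
                      for v in vectors])
    chosen, max_drop, no_drop = choose_threshold(thresholds, curve, min_drop_frac)
    return ThresholdScan(
        thresholds=thresholds,
        mean_strength=np.array(strengths),
        cosine_to_baseline=curve,
        chosen=chosen,
        max_drop=max_drop,
        no_drop=no_drop,
    )


# ---------------------------------------------------------------------------
# dependent p-value combination and the day/night contrast


def combine_dependent_pvalues(
    pvals, null_pvals, n_perm: int | None = None, analytic: bool = False
) -> float:
    """Fisher combination calibrated on the null replicates' own p-values.

    ``null_pvals`` has one row per null replicate, columns aligned with
    ``pvals``; the combined p is the fraction of replicates whose Fisher
    statistic is at least the observed one, so the dependence between the
    component tests is inherited from the replicates.  With
    ``analytic=True`` the independent-Fisher chi-square reference is used
    instead (cross-check only).  Zero p-values are floored at
    1 / (n_perm + 1) before taking logs.
    """
    p = np.asarray(pvals, dtype=float)
    keep = ~np.isnan(p)
    p = p[keep]
    if p.size == 0:
        raise ValueError("no defined p-values to combine")
    null_p = np.asarray(null_pvals, dtype=float)[:, keep]
    if n_perm is None:
        n_perm = null_p.shape[0]
    floor = 1.0 / (n_perm + 1)
    s_obs = float(-2.0 * np.sum(np.log(np.maximum(p, floor))))
    if analytic:
        return float(stats.chi2.sf(s_obs, df=2 * p.size))
    s_null = -2.0 * np.sum(np.log(np.maximum(null_p, floor)), axis=1)
    return float(np.mean(s_null >= s_obs))


@dataclass
class DayNightContrast:
    transitions: list  # (period_from, period_to)
    observed_abs_diff: np.ndarray
    p_per_transition: np.ndarray  # #(obs > null)/n_perm (reporting convention)
    p_upper: np.ndarray  # #(null >= obs)/n_perm, fed to the combination
    combined_p: float


def daynight_contrast(observed_series, null_series) -> DayNightContrast:
    """Are trait changes across consecutive periods larger than chance?

    ``observed_series`` holds one trait value per ordered aggregation
    period (day 0, night 0, day 1, ...); ``null_series`` is the
    (replicates x periods) matrix of the same series on the permuted
    streams.  Transitions with an undefined endpoint are skipped.  Small
    combined p = day/night differences larger than the space-use null.
    """
    obs = np.asarray(observed_series, dtype=float)
    nulls = np.asarray(null_series, dtype=float)
    if nulls.ndim != 2 or nulls.shape[1] != obs.size:
        raise ValueError("null_series must be (replicates, periods)")
    R = nulls.shape[0]
    transitions = []
    obs_d = []
    null_d = []
    for t in range(obs.size - 1):
        if np.isnan(obs[t]) or np.isnan(obs[t + 1]):
            continue
        ok = ~(np.isnan(nulls[:, t]) | np.isnan(nulls[:, t + 1]))
        if ok.sum() == 0:
            continue
        transitions.append((t, t + 1))
        obs_d.append(abs(obs[t + 1] - obs[t]))
        nd = np.full(R, np.nan)
        nd[ok] = np.abs(nulls[ok, t + 1] - nulls[ok, t])
        null_d.append(nd)
    if not transitions:
        raise ValueError("no usable consecutive-period transitions")
    obs_d = np.asarray(obs_d)
    null_d = np.vstack(null_d).T  # (R, T)
    T = null_d.shape[1]
    p_perm = np.empty(T)
    p_up = np.empty(T)
    pooled_obs = np.empty(T)
    null_p_up = np.empty((R, T))
    for t in range(T):
        col = null_d[:, t]
        defined = col[~np.isnan(col)]
        p_perm[t] = perm_pvalue(obs_d[t], defined)
        p_up[t] = upper_pvalue(obs_d[t], defined)
        # pooled upper-tail ranks: observed and every replicate are ranked
        # within the same R+1 values, making the Fisher statistics of the
        # observed and null lists exchangeable under the null
        pool = np.sort(np.append(defined, obs_d[t]))
        m = pool.size

        def up(v):
            return (m - np.searchsorted(pool, v, side="left")) / m

        pooled_obs[t] = up(obs_d[t])
        null_p_up[:, t] = up(col)
        null_p_up[np.isnan(col), t] = np.nan
    combined = combine_dependent_pvalues(pooled_obs, null_p_up, n_perm=R)
    return DayNightContrast(
        transitions=transitions,
        observed_abs_diff=obs_d,
        p_per_transition=p_perm,
        p_upper=p_up,
        combined_p=combined,
    )


# ---------------------------------------------------------------------------
# paired tests


def _signflip_pvalues(d: np.ndarray, rng=None, n_resample: int = 10000,
                      exhaustive_max: int = 20):
    """Distribution of mean(d) under independent sign flips.

    Exhaustive over all 2^n assignments when n <= exhaustive_max, Monte
    Carlo otherwise.  Returns the array of permuted means.
    """
    n = d.size
    if n <= exhaustive_max:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        return (signs * d[None, :]).mean(axis=1)
    if rng is None:
        rng = np.random.default_rng()
    signs = rng.integers(0, 2, size=(n_resample, n)) * 2 - 1
    return (signs * d[None, :]).mean(axis=1)


def paired_location_tests(x, y, alternative: str = "greater", seed: int = 0) -> dict:
    """Paired t, Wilcoxon signed-rank and sign-flip permutation p-values.

    One-sided with ``alternative='greater'`` testing mean(x) > mean(y).
    All-zero differences leave the Wilcoxon undefined (NaN) and the other
    tests at p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    d = x - y
    out = {}
    if np.all(d == 0):
        out["t_p"] = 1.0
        out["wilcoxon_p"] = float("nan")
        out["perm_p"] = 1.0
        return out
    out["t_p"] = float(stats.ttest_rel(x, y, alternative=alternative).pvalue)
    try:
        out["wilcoxon_p"] = float(
            stats.wilcoxon(d[d != 0], alternative=alternative).pvalue
        )
    except ValueError:
        out["wilcoxon_p"] = float("nan")
    perm_means = _signflip_pvalues(d, rng=np.random.default_rng(seed))
    obs = d.mean()
    if alternative == "greater":
        out["perm_p"] = float(np.mean(perm_means >= obs))
    elif alternative == "less":
        out["perm_p"] = float(np.mean(perm_means <= obs))
    else:
        out["perm_p"] = float(np.mean(np.abs(perm_means) >= abs(obs)))
    return out


def weighted_vs_binary_test(
    simW: SimilarityMatrix, simB: SimilarityMatrix, seed: int = 0
) -> float:
    """Two-sided sign-flip test on paired cell differences (diagonal excluded)."""
    if simW.labels != simB.labels:
        raise ValueError("similarity matrices must share the period grid")
    n = simW.cosine.shape[0]
    iu = np.triu_indices(n, k=1)
    d = simB.cosine[iu] - simW.cosine[iu]
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    if np.all(d == 0):
        return 1.0
    perm_means = _signflip_pvalues(d, rng=np.random.default_rng(seed))
    return float(np.mean(np.abs(perm_means) >= abs(d.mean())))


def portmanteau_autocorr(series, max_lag: int) -> tuple[float, float]:
    """Ljung-Box statistic and p-value over lags 1..max_lag."""
    import statsmodels.api as sm

    s = np.asarray(series, dtype=float)
    if s.size <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if np.all(s == s[0]):
        return float("nan"), float("nan")
    res = sm.stats.acorr_ljungbox(s, lags=[max_lag], return_df=True)
    return float(res["lb_stat"].iloc[0]), float(res["lb_pvalue"].iloc[0])
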