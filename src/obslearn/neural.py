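"""Spike-train analysis: PSTHs, sliding GLMs, cluster permutation tests.

The core quantity is a trials x time-bins firing-rate matrix aligned to
an event, estimated with a 300 ms moving window stepped by 10 ms. A
nine-regressor GLM (a main effect per player role plus that role's
expected-value and amount modulators) is fitted per time bin by
ordinary least squares; contrasts pool the observed players' modulators
(observed EV, observed amount, and observed PE = amount - EV). Group
inference over units uses a cluster permutation test: consecutive mean
t-statistic values beyond +/-0.2 are summed into cluster masses and
compared to the 99th percentile of masses from datasets rebuilt from
randomly drawn area units with randomly shuffled trial labels.

Unit selection mirrors the analysis logic: outcome-responsive units by
a pre/post paired t-test and an h-coefficient-style response score;
amount-coding units by a positive observed-amount effect after outcome;
tripartite candidates by a positive observed-EV effect during the
choice period (which leaves outcome-window tests selection-unbiased).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

log = logging.getLogger(__name__)

#: moving-average PSTH parameters (seconds)
PSTH_WINDOW = 0.3
PSTH_STEP = 0.01
PSTH_SPAN = (-3.0, 2.0)
GLM_SPAN = (-1.0, 1.5)

PRE_OUTCOME = (-0.9, -0.3)
POST_OUTCOME = (0.3, 0.9)
CHOICE_WINDOW = (-0.9, -0.3)
BASELINE_WINDOW = (-3.0, -1.0)

DESIGN_COLUMNS = [
    "main_self", "self_ev", "self_amount",
    "main_obs1", "obs1_ev", "obs1_amount",
    "main_obs2", "obs2_ev", "obs2_amount",
]


# ---------------------------------------------------------------------------
# PSTH

@dataclass
class RateMatrix:
    """Trials x time-bins firing-rate estimates aligned to an event."""

    unit_id: str
    align_event: str
    times: np.ndarray          # bin centers, s relative to event
    rates: np.ndarray          # (n_trials, n_bins), Hz
    window: float
    step: float
    trial_index: np.ndarray    # join key into the trial table

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Per-trial mean rate over bins whose centers fall in *window*."""
        mask = (self.times >= window[0]) & (self.times < window[1])
        if not mask.any():
            raise ValueError(f"no bins inside window {window}")
        return self.rates[:, mask].mean(axis=1)

    def bin_slice(self, window: tuple[float, float]) -> np.ndarray:
        return (self.times >= window[0]) & (self.times < window[1])


def compute_psth(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    span: tuple[float, float] = PSTH_SPAN,
    window: float = PSTH_WINDOW,
    step: float = PSTH_STEP,
    unit_id: str = "",
    align_event: str = "outcome",
    trial_index: np.ndarray | None = None,
) -> RateMatrix:
    """Moving-average firing rate around each event.

    The rate at a bin center c is the spike count in the half-open
    window [c - w/2, c + w/2) divided by w, so a spike exactly on a bin
    edge is counted in exactly one bin.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("empty event list")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    n_bins = int(np.floor((span[1] - span[0] - window) / step + 1e-9)) + 1
    centers = span[0] + window / 2 + np.arange(n_bins) * step
    left = centers - window / 2
    right = centers + window / 2
    counts = np.empty((events.size, n_bins))
    for i, ev in enumerate(events):
        counts[i] = (np.searchsorted(spikes, ev + right, side="left")
                     - np.searchsorted(spikes, ev + left, side="left"))
    if trial_index is None:
        trial_index = np.arange(events.size)
    return RateMatrix(unit_id=unit_id, align_event=align_event, times=centers,
                      rates=counts / window, window=window, step=step,
                      trial_index=np.asarray(trial_index))


# ---------------------------------------------------------------------------
# outcome-responsiveness selection

@dataclass
class SelectionResult:
    table: pd.DataFrame                 # unit_id + criterion flags
    selected_ids: list
    windows: dict
    excluded: list = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)


def h_coefficient_surrogate(pre: np.ndarray, post: np.ndarray,
                            n_boot: int = 200,
                            rng: np.random.Generator | None = None) -> float:
    """Bootstrap-standardized pre/post response-magnitude score.

    h is the mean post-minus-pre rate change divided by the bootstrap
    standard deviation of that mean — a response-strength z-score that
    grows with both effect size and consistency. It is the package's
    default h-coefficient; selection functions accept any callable with
    this signature, so alternative definitions can be plugged in.
    """
    rng = rng or np.random.default_rng(0)
    d = np.asarray(post) - np.asarray(pre)
    if d.size < 2:
        return 0.0
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot_means = d[idx].mean(axis=1)
    sd = boot_means.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / sd)


def select_outcome_responsive(
    rates: list[RateMatrix],
    pre_window: tuple[float, float] = PRE_OUTCOME,
    post_window: tuple[float, float] = POST_OUTCOME,
    alpha_strict: float = 0.01,
    alpha_loose: float = 0.05,
    h_thresholds: tuple[float, float] = (1.0, 1.5),
    h_fn=h_coefficient_surrogate,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Outcome-responsive units by the three-way union criterion.

    A unit is selected if (1) the one-tailed paired t-test between
    pre-outcome and post-outcome window rates has p < 0.01, or (2)
    p < 0.05 and h >= 1, or (3) h >= 1.5.
    """
    rng = rng or np.random.default_rng(0)
    rows, excluded = [], []
    for rm in rates:
        pre = rm.window_mean(pre_window)
        post = rm.window_mean(post_window)
        d = post - pre
        if np.ptp(d) == 0:
            excluded.append((rm.unit_id, "zero-variance pre/post difference"))
            continue
        t, p_two = stats.ttest_rel(post, pre)
        p = p_two / 2 if t > 0 else 1 - p_two / 2
        h = h_fn(pre, post, rng=rng)
        crit1 = p < alpha_strict
        crit2 = (p < alpha_loose) and (h >= h_thresholds[0])
        crit3 = h >= h_thresholds[1]
        rows.append({"unit_id": rm.unit_id, "t": float(t), "p": float(p),
                     "h": h, "crit1": crit1, "crit2": crit2, "crit3": crit3,
                     "selected": crit1 or crit2 or crit3})
    table = pd.DataFrame(rows, columns=["unit_id", "t", "p", "h",
                                        "crit1", "crit2", "crit3", "selected"])
    selected = table.loc[table["selected"], "unit_id"].tolist()
    return SelectionResult(table=table, selected_ids=selected,
                           windows={"pre": pre_window, "post": post_window},
                           excluded=excluded)


# ---------------------------------------------------------------------------
# response envelopes

@dataclass
class EnvelopeResult:
    times: np.ndarray
    envelope: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    onset: float
    onset_ci: tuple[float, float]
    amplitude: float
    amplitude_ci: tuple[float, float]
    n_flagged: int              # replicates with no peak above baseline


def _onset_amplitude(course: np.ndarray, times: np.ndarray,
                     baseline_window: tuple[float, float],
                     search_window: tuple[float, float]) -> tuple[float, float]:
    base_mask = (times >= baseline_window[0]) & (times < baseline_window[1])
    search_mask = (times >= search_window[0]) & (times < search_window[1])
    baseline = course[base_mask].mean()
    seg = course[search_mask]
    seg_t = times[search_mask]
    peak = seg.max()
    amplitude = peak - baseline
    if amplitude <= 0:
        return np.nan, amplitude
    half = baseline + amplitude / 2.0
    above = np.flatnonzero(seg >= half)
    return float(seg_t[above[0]]), float(amplitude)


def bootstrap_envelope(
    rates: list[RateMatrix],
    n_boot: int = 10_000,
    smooth_sd: float = 0.05,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    search_window: tuple[float, float] = (0.0, 1.5),
    rng: np.random.Generator | None = None,
) -> EnvelopeResult:
    """Unit-resampled smoothed mean envelope with onset/amplitude CIs.

    Each replicate resamples units with replacement, smooths the mean
    course with a Gaussian kernel, and reads off the response onset
    (first crossing of half the peak-above-baseline level) and the
    amplitude (peak minus baseline). 95% CIs are replicate percentiles.
    """
    if len(rates) < 2:
        raise ValueError("need at least 2 units for a bootstrap envelope")
    rng = rng or np.random.default_rng(0)
    times = rates[0].times
    unit_means = np.stack([rm.rates.mean(axis=0) for rm in rates])
    sigma_bins = smooth_sd / rates[0].step
    mean_env = gaussian_filter1d(unit_means.mean(axis=0), sigma_bins)
    onset0, amp0 = _onset_amplitude(mean_env, times, baseline_window, search_window)
    boot_env = np.empty((n_boot, times.size))
    onsets = np.empty(n_boot)
    amps = np.empty(n_boot)
    n_units = unit_means.shape[0]
    for b in range(n_boot):
        pick = rng.integers(0, n_units, n_units)
        env = gaussian_filter1d(unit_means[pick].mean(axis=0), sigma_bins)
        boot_env[b] = env
        onsets[b], amps[b] = _onset_amplitude(env, times, baseline_window,
                                              search_window)
    flagged = int(np.sum(~np.isfinite(onsets)))
    if flagged:
        log.info("bootstrap envelope: %d/%d replicates had no peak above "
                 "baseline", flagged, n_boot)
    finite = onsets[np.isfinite(onsets)]
    onset_ci = (float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5))) \
        if finite.size else (np.nan, np.nan)
    return EnvelopeResult(
        times=times, envelope=mean_env,
        ci_low=np.percentile(boot_env, 2.5, axis=0),
        ci_high=np.percentile(boot_env, 97.5, axis=0),
        onset=onset0, onset_ci=onset_ci,
        amplitude=amp0,
        amplitude_ci=(float(np.percentile(amps, 2.5)),
                      float(np.percentile(amps, 97.5))),
        n_flagged=flagged,
    )


# ---------------------------------------------------------------------------
# win/lose response differences

@dataclass
class ResponseDifferenceResult:
    times: np.ndarray
    per_unit: np.ndarray          # (n_units, n_bins), baseline-subtracted |diff|
    exceed_fraction: np.ndarray   # fraction of units beyond their pre-outcome bound
    mean_course: np.ndarray
    mean_pre_bound: float         # bootstrap 95% bound of pre-outcome mean
    binomial_p: np.ndarray        # per-bin population binomial test p


def mean_response_difference(
    rates: list[RateMatrix],
    win_labels: list[np.ndarray],
    pre_subtract_window: tuple[float, float] = (-1.5, 0.0),
    pre_bound_window: tuple[float, float] = (-1.0, 0.0),
    n_boot: int = 10_000,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> ResponseDifferenceResult:
    """Baseline-subtracted |win - lose| mean-rate difference time-courses.

    Per unit: the absolute difference of win and lose mean rates per
    bin, minus its own mean over the pre-outcome subtraction window.
    Exceedance flags compare each bin against the unit's 95th
    percentile over the second before outcome; the population fraction
    of flagged units is tested per bin against 5% with a binomial test.
    """
    rng = rng or np.random.default_rng(0)
    times = rates[0].times
    courses = []
    for rm, labels in zip(rates, win_labels):
        labels = np.asarray(labels, dtype=bool)
        if labels.all() or (~labels).all():
            raise ValueError(f"unit {rm.unit_id}: missing win or lose trials")
        diff = np.abs(rm.rates[labels].mean(axis=0) - rm.rates[~labels].mean(axis=0))
        base = diff[(times >= pre_subtract_window[0])
                    & (times < pre_subtract_window[1])].mean()
        courses.append(diff - base)
    per_unit = np.stack(courses)
    pre_mask = (times >= pre_bound_window[0]) & (times < pre_bound_window[1])
    unit_bounds = np.percentile(per_unit[:, pre_mask], 95, axis=1)
    exceed = per_unit > unit_bounds[:, None]
    exceed_fraction = exceed.mean(axis=0)
    n_units = per_unit.shape[0]
    binomial_p = np.array([
        stats.binomtest(int(k), n_units, 0.05, alternative="greater").pvalue
        for k in exceed.sum(axis=0)])
    mean_course = per_unit.mean(axis=0)
    idx = rng.integers(0, n_units, size=(n_boot, n_units))
    boot_pre = per_unit[:, pre_mask][idx].mean(axis=1).mean(axis=1)
    return ResponseDifferenceResult(
        times=times, per_unit=per_unit, exceed_fraction=exceed_fraction,
        mean_course=mean_course,
        mean_pre_bound=float(np.percentile(boot_pre, 95)),
        binomial_p=binomial_p,
    )


def response_difference_correlation(
    diffs: dict[str, np.ndarray],
    times: np.ndarray,
    window: tuple[float, float] = POST_OUTCOME,
    alpha: float = 0.01 / 3,
) -> pd.DataFrame:
    """Across-unit correlations of response differences between trial types.

    *diffs* maps a trial-type label (e.g. self / observed / slot) to a
    (n_units, n_bins) array from :func:`mean_response_difference`, with
    the same units in the same order. Returns one row per pairing with
    the window-averaged Pearson r and p plus the per-bin r course.
    """
    keys = list(diffs)
    n_units = diffs[keys[0]].shape[0]
    if n_units < 3:
        raise ValueError("need at least 3 units for across-unit correlation")
    for k in keys:
        if diffs[k].shape[0] != n_units:
            raise ValueError("all trial types must cover the same unit set")
    mask = (times >= window[0]) & (times < window[1])
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = diffs[keys[i]], diffs[keys[j]]
            course = np.array([stats.pearsonr(a[:, t], b[:, t]).statistic
                               for t in range(a.shape[1])])
            wa, wb = a[:, mask].mean(axis=1), b[:, mask].mean(axis=1)
            r, p = stats.pearsonr(wa, wb)
            rows.append({"pair": f"{keys[i]}_vs_{keys[j]}", "r": float(r),
                         "p": float(p), "significant": bool(p < alpha),
                         "n_units": n_units, "r_course": course})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design matrix and sliding GLM

@dataclass
class DesignMatrix:
    X: np.ndarray                       # (n_trials, 9)
    columns: list
    contrasts: dict                     # name -> length-9 vector
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.columns):
            raise ValueError("design width does not match column names")


def build_design_matrix(trials: pd.DataFrame,
                        learner_output: pd.DataFrame) -> DesignMatrix:
    """Nine-regressor design: per-role main effects and EV/amount modulators.

    Each trial event loads exactly one main effect (its player role);
    the role's EV modulator carries the subject's expected value of the
    deck that player chose and the amount modulator the signed dollars
    won or lost, both mean-centered within their trial type so the main
    effects capture trial-type means. Contrasts pool the observed
    players: observed_ev, observed_amount, and observed_pe =
    observed_amount - observed_ev (the amount obtained minus the
    expected value, averaged over the two observed players).
    """
    if len(trials) != len(learner_output):
        raise ValueError("trials and learner output have different lengths")
    ev = learner_output["chosen_ev"].to_numpy()
    if np.any(~np.isfinite(ev)):
        raise ValueError("missing learner EV for some events")
    amount = trials["amount"].to_numpy(dtype=float)
    players = trials["player"].to_numpy()
    n = len(trials)
    X = np.zeros((n, 9))
    for k, role in enumerate(("self", "obs1", "obs2")):
        mask = players == role
        X[mask, 3 * k] = 1.0
        X[mask, 3 * k + 1] = ev[mask] - ev[mask].mean()
        X[mask, 3 * k + 2] = amount[mask] - amount[mask].mean()
    cols = DESIGN_COLUMNS
    def vec(*names):
        v = np.zeros(9)
        for nm in names:
            v[cols.index(nm)] = 1.0
        return v
    contrasts = {
        "self_ev": vec("self_ev"),
        "self_amount": vec("self_amount"),
        "observed_ev": vec("obs1_ev", "obs2_ev"),
        "observed_amount": vec("obs1_amount", "obs2_amount"),
    }
    contrasts["observed_pe"] = contrasts["observed_amount"] - contrasts["observed_ev"]
    return DesignMatrix(X=X, columns=list(cols), contrasts=contrasts,
                        trial_index=np.arange(n))


@dataclass
class GLMResult:
    unit_id: str
    times: np.ndarray
    beta: np.ndarray               # (9, n_bins)
    tstats: np.ndarray             # (9, n_bins)
    contrast_t: dict               # name -> (n_bins,)
    dof: int


def _collinear_columns(X: np.ndarray, columns: list) -> list:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([others, X[:, j]])) == \
                np.linalg.matrix_rank(others):
            bad.append(columns[j])
    return bad


def fit_sliding_glm(rate: RateMatrix, design: DesignMatrix,
                    span: tuple[float, float] = GLM_SPAN) -> GLMResult:
    """Per-bin OLS of firing rate on the nine-regressor design.

    Returns t-statistics per regressor and per contrast across the bins
    whose centers fall within *span* (relative to the outcome).
    """
    X = design.X
    if rate.rates.shape[0] != X.shape[0]:
        raise ValueError("design rows do not align with rate trials")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.columns)
        raise ValueError(f"rank-deficient design (rank {rank}): "
                         f"collinear columns {bad}")
    mask = (rate.times >= span[0]) & (rate.times <= span[1])
    times = rate.times[mask]
    Y = rate.rates[:, mask]
    return _glm_core(rate.unit_id, X, Y, times, design.contrasts)


def _glm_core(unit_id: str, X: np.ndarray, Y: np.ndarray, times: np.ndarray,
              contrasts: dict) -> GLMResult:
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ Y                                   # (p, n_bins)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof        # (n_bins,)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        tstats = np.where(se > 0, beta / se, 0.0)
        contrast_t = {}
        for name, c in contrasts.items():
            num = c @ beta
            den = np.sqrt(sigma2 * float(c @ XtX_inv @ c))
            contrast_t[name] = np.where(den > 0, num / den, 0.0)
    return GLMResult(unit_id=unit_id, times=times, beta=beta, tstats=tstats,
                     contrast_t=contrast_t, dof=dof)


def permuted_contrast_tstats(
    rate: RateMatrix, design: DesignMatrix, contrast_names: list,
    n_perm: int, rng: np.random.Generator,
    span: tuple[float, float] = GLM_SPAN,
) -> dict:
    """Per-permutation contrast t-courses under shuffled trial labels.

    Returns {contrast: (n_perm, n_bins)}; permutation k shuffles the
    assignment of design rows to trials.
    """
    X = design.X
    mask = (rate.times >= span[0]) & (rate.times <= span[1])
    Y = rate.rates[:, mask]
    times = rate.times[mask]
    out = {nm: np.empty((n_perm, times.size)) for nm in contrast_names}
    sub = {nm: design.contrasts[nm] for nm in contrast_names}
    for k in range(n_perm):
        perm = rng.permutation(X.shape[0])
        res = _glm_core(rate.unit_id, X[perm], Y, times, sub)
        for nm in contrast_names:
            out[nm][k] = res.contrast_t[nm]
    return out


# ---------------------------------------------------------------------------
# cluster permutation inference

@dataclass
class Cluster:
    start: int
    end: int          # inclusive bin indices
    mass: float
    sign: int
    significant: bool = False


@dataclass
class ClusterTestResult:
    times: np.ndarray
    course: np.ndarray             # observed mean t-course
    threshold: float
    clusters: list
    null_pos: np.ndarray           # max positive cluster mass per shuffle
    null_neg: np.ndarray           # min negative cluster mass per shuffle
    n_shuffle: int
    percentile: float

    @property
    def significant_positive(self) -> bool:
        return any(c.significant and c.sign > 0 for c in self.clusters)

    @property
    def significant_negative(self) -> bool:
        return any(c.significant and c.sign < 0 for c in self.clusters)

    def significant_positive_in(self, window: tuple[float, float]) -> bool:
        return self._sig_in(window, +1)

    def significant_negative_in(self, window: tuple[float, float]) -> bool:
        return self._sig_in(window, -1)

    def _sig_in(self, window: tuple[float, float], sign: int) -> bool:
        for c in self.clusters:
            if c.significant and c.sign == sign:
                t0, t1 = self.times[c.start], self.times[c.end]
                if t1 >= window[0] and t0 < window[1]:
                    return True
        return False


def find_clusters(course: np.ndarray, threshold: float) -> list[Cluster]:
    """Runs of consecutive supra-threshold values and their signed masses."""
    clusters = []
    for sign in (+1, -1):
        above = sign * course > threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1))
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [course.size - 1]
        for s, e in zip(starts, ends):
            clusters.append(Cluster(start=int(s), end=int(e),
                                    mass=float(course[s:e + 1].sum()), sign=sign))
    return sorted(clusters, key=lambda c: c.start)


def _max_cluster_masses(course: np.ndarray, threshold: float) -> tuple[float, float]:
    """(largest positive mass, most negative mass) of one course."""
    pos_best, neg_best = 0.0, 0.0
    for c in find_clusters(course, threshold):
        if c.sign > 0:
            pos_best = max(pos_best, c.mass)
        else:
            neg_best = min(neg_best, c.mass)
    return pos_best, neg_best


def cluster_permutation_test(
    observed: np.ndarray,
    pool_permuted: np.ndarray,
    times: np.ndarray,
    threshold: float = 0.2,
    n_shuffle: int = 10_000,
    percentile: float = 99.0,
    rng: np.random.Generator | None = None,
    replace: bool | None = None,
) -> ClusterTestResult:
    """Cluster-mass permutation test on mean t-statistic time-courses.

    *observed* is (n_selected, n_bins): per-unit contrast t-courses of
    the selected set. *pool_permuted* is (n_pool, n_perm, n_bins):
    label-shuffled t-courses for every unit in the same area. Each of
    the *n_shuffle* null datasets draws n_selected pool units, one
    random permutation each, and records its extreme cluster masses;
    observed clusters are significant when their mass lies outside the
    sign-matched 99th percentile.
    """
    rng = rng or np.random.default_rng(0)
    if n_shuffle < 100:
        warnings.warn("n_shuffle < 100 gives an unstable null percentile",
                      stacklevel=2)
    observed = np.atleast_2d(observed)
    n_sel, n_bins = observed.shape
    n_pool, n_perm, _ = pool_permuted.shape
    if replace is None:
        replace = n_pool < n_sel
    course = observed.mean(axis=0)
    clusters = find_clusters(course, threshold)
    null_pos = np.empty(n_shuffle)
    null_neg = np.empty(n_shuffle)
    chunk = max(1, int(5e7 // (n_sel * n_bins)))
    done = 0
    while done < n_shuffle:
        m = min(chunk, n_shuffle - done)
        if replace:
            unit_idx = rng.integers(0, n_pool, size=(m, n_sel))
        else:
            unit_idx = np.stack([rng.choice(n_pool, n_sel, replace=False)
                                 for _ in range(m)])
        perm_idx = rng.integers(0, n_perm, size=(m, n_sel))
        null_courses = pool_permuted[unit_idx, perm_idx].mean(axis=1)
        for i in range(m):
            null_pos[done + i], null_neg[done + i] = _max_cluster_masses(
                null_courses[i], threshold)
        done += m
    pos_crit = np.percentile(null_pos, percentile)
    neg_crit = np.percentile(null_neg, 100.0 - percentile)
    for c in clusters:
        c.significant = (c.mass > pos_crit) if c.sign > 0 else (c.mass < neg_crit)
    return ClusterTestResult(times=times, course=course, threshold=threshold,
                             clusters=clusters, null_pos=null_pos,
                             null_neg=null_neg, n_shuffle=n_shuffle,
                             percentile=percentile)


# ---------------------------------------------------------------------------
# selection + cluster-test orchestrators

def _window_selection(glms: list[GLMResult], contrast: str,
                      window: tuple[float, float], dof: int,
                      alpha: float = 0.05 / 2, sign: int = +1) -> list[int]:
    """Units with a sign-matched effect in any bin of *window*.

    alpha is Bonferroni-halved for testing the two signs separately;
    the criterion is one-tailed in the requested direction.
    """
    t_crit = stats.t.ppf(1.0 - alpha, dof)
    picked = []
    for i, g in enumerate(glms):
        mask = (g.times >= window[0]) & (g.times < window[1])
        tc = sign * g.contrast_t[contrast][mask]
        if np.any(tc > t_crit):
            picked.append(i)
    return picked


@dataclass
class ContrastClusterReport:
    selection: SelectionResult
    cluster_results: dict          # contrast name -> ClusterTestResult


def _run_cluster(glms, perms, picked, contrast, times, threshold, n_shuffle,
                 percentile, rng):
    observed = np.stack([glms[i].contrast_t[contrast] for i in picked])
    pool = np.stack([p[contrast] for p in perms])
    return cluster_permutation_test(observed, pool, times, threshold=threshold,
                                    n_shuffle=n_shuffle, percentile=percentile,
                                    rng=rng)


def select_and_test_amount_coding(
    glms: list[GLMResult],
    perms: list[dict],
    unit_ids: list,
    selection_window: tuple[float, float] = POST_OUTCOME,
    alpha: float = 0.05 / 2,
    threshold: float = 0.2,
    n_shuffle: int = 10_000,
    percentile: float = 99.0,
    rng: np.random.Generator | None = None,
) -> ContrastClusterReport:
    """Observed-amount selection, then self-amount cluster test.

    Selects units whose observed-amount effect is positive in at least
    one post-outcome bin (one-tailed p < alpha), then runs the cluster
    permutation test on the *self*-amount contrast in the selected set
    — a contrast the selection did not touch, so it carries no
    selection bias.
    """
    rng = rng or np.random.default_rng(0)
    picked = _window_selection(glms, "observed_amount", selection_window,
                               glms[0].dof, alpha=alpha, sign=+1)
    table = pd.DataFrame({"unit_id": unit_ids,
                          "selected": [i in set(picked) for i in range(len(glms))]})
    sel = SelectionResult(table=table,
                          selected_ids=[unit_ids[i] for i in picked],
                          windows={"selection": selection_window})
    results = {}
    if picked:
        for contrast in ("self_amount", "observed_amount"):
            results[contrast] = _run_cluster(glms, perms, picked, contrast,
                                             glms[0].times, threshold,
                                             n_shuffle, percentile, rng)
    else:
        log.info("amount-coding selection empty; cluster tests skipped")
    return ContrastClusterReport(selection=sel, cluster_results=results)


def tripartite_pe_test(
    glms: list[GLMResult],
    perms: list[dict],
    unit_ids: list,
    choice_window: tuple[float, float] = CHOICE_WINDOW,
    outcome_window: tuple[float, float] = POST_OUTCOME,
    alpha: float = 0.05 / 2,
    threshold: float = 0.2,
    n_shuffle: int = 10_000,
    percentile: float = 99.0,
    rng: np.random.Generator | None = None,
) -> ContrastClusterReport:
    """Choice-window EV selection, then outcome-window PE cluster tests.

    Units are selected for a positive observed-EV effect during the
    choice period; because selection happens before the outcome, tests
    of post-outcome contrasts in the selected set are unbiased. Cluster
    tests then ask for a positive observed-amount and a negative
    observed-EV effect after outcome (their difference being the full
    prediction error), plus the combined observed-PE contrast.
    """
    rng = rng or np.random.default_rng(0)
    picked = _window_selection(glms, "observed_ev", choice_window,
                               glms[0].dof, alpha=alpha, sign=+1)
    table = pd.DataFrame({"unit_id": unit_ids,
                          "selected": [i in set(picked) for i in range(len(glms))]})
    sel = SelectionResult(table=table,
                          selected_ids=[unit_ids[i] for i in picked],
                          windows={"selection": choice_window,
                                   "outcome": outcome_window})
    results = {}
    if picked:
        for contrast in ("observed_amount", "observed_ev", "observed_pe"):
            results[contrast] = _run_cluster(glms, perms, picked, contrast,
                                             glms[0].times, threshold,
                                             n_shuffle, percentile, rng)
    else:
        log.info("tripartite selection empty; cluster tests skipped")
    return ContrastClusterReport(selection=sel, cluster_results=results)


# ---------------------------------------------------------------------------
# model-derived PE checks and the model-free analysis

def quartile_pe_check(
    rate: RateMatrix,
    pe: np.ndarray,
    response_window: tuple[float, float] = POST_OUTCOME,
) -> bool:
    """Upper vs lower PE-quartile separation by non-overlapping s.e.m.

    Flags the unit if any response-period bin has the upper-quartile
    mean minus its s.e.m. above the lower-quartile mean plus its s.e.m.
    """
    pe = np.asarray(pe, dtype=float)
    if pe.size < 8:
        raise ValueError("need >= 8 trials for quartile split")
    if np.ptp(pe) == 0:
        raise ValueError("constant PE: quartiles undefined")
    order = np.argsort(pe, kind="stable")
    k = pe.size // 4
    lower, upper = order[:k], order[-k:]
    mask = rate.bin_slice(response_window)
    lo = rate.rates[np.ix_(lower, np.flatnonzero(mask))]
    hi = rate.rates[np.ix_(upper, np.flatnonzero(mask))]
    lo_m, lo_s = lo.mean(axis=0), lo.std(axis=0, ddof=1) / np.sqrt(k)
    hi_m, hi_s = hi.mean(axis=0), hi.std(axis=0, ddof=1) / np.sqrt(k)
    return bool(np.any(hi_m - hi_s > lo_m + lo_s))


def quartile_population_test(
    flags: np.ndarray,
    null_rate: float | None = None,
    rates: list[RateMatrix] | None = None,
    pes: list[np.ndarray] | None = None,
    n_null: int = 200,
    rng: np.random.Generator | None = None,
    response_window: tuple[float, float] = POST_OUTCOME,
) -> dict:
    """Binomial test of the flagged-unit count against a chance rate.

    The chance rate defaults to an empirical estimate from PE-label
    shuffles of the same units; pass *null_rate* to override.
    """
    flags = np.asarray(flags, dtype=bool)
    if null_rate is None:
        if rates is None or pes is None:
            raise ValueError("need rates and pes to estimate the null rate")
        rng = rng or np.random.default_rng(0)
        hits = 0
        total = 0
        for rm, pe in zip(rates, pes):
            for _ in range(n_null):
                hits += quartile_pe_check(rm, rng.permutation(pe), response_window)
                total += 1
        null_rate = max(hits / total, 1.0 / total)
    test = stats.binomtest(int(flags.sum()), flags.size, null_rate,
                           alternative="greater")
    return {"n_flagged": int(flags.sum()), "n_units": int(flags.size),
            "null_rate": float(null_rate), "p": float(test.pvalue)}


def pe_tercile_summary(rate: RateMatrix, pe: np.ndarray,
                       response_window: tuple[float, float] = POST_OUTCOME) -> dict:
    """Mean response-period rate per PE tercile, with monotonicity flag."""
    pe = np.asarray(pe, dtype=float)
    if pe.size < 9:
        raise ValueError("need >= 3 trials per tercile")
    order = np.argsort(pe, kind="stable")
    thirds = np.array_split(order, 3)
    means = [float(rate.window_mean(response_window)[ix].mean()) for ix in thirds]
    increasing = means[0] < means[1] < means[2]
    decreasing = means[0] > means[1] > means[2]
    return {"tercile_means": means, "monotone_increasing": bool(increasing),
            "monotone_decreasing": bool(decreasing)}


def model_free_early_late(
    rates: list[RateMatrix],
    trials_list: list[pd.DataFrame],
    response_window: tuple[float, float] = POST_OUTCOME,
    early_rounds: tuple[int, int] = (1, 2),
    late_rounds: tuple[int, int] = (4, 5),
) -> pd.DataFrame:
    """Early-minus-late win firing differences, amount-matched per game.

    For each unit and player class (self vs observed) the mean
    response-window rate for wins in the first two rounds of a game
    minus that for wins in the last two rounds, computed separately for
    +$10 and +$100 wins within each game and averaged over games (round
    3 never enters). Positive values mean less-expected (early) wins
    fire more.
    """
    rows = []
    for rm, trials in zip(rates, trials_list):
        resp = rm.window_mean(response_window)
        tr = trials.iloc[rm.trial_index].reset_index(drop=True)
        for cls, mask in (("self", tr["player"] == "self"),
                          ("observed", tr["player"] != "self")):
            diffs = []
            for game, g in tr[mask & (tr["outcome"] == "win")].groupby("game"):
                for mag in (10.0, 100.0):
                    cell = g[g["amount"] == mag]
                    early = cell[cell["round"].isin(early_rounds)].index
                    late = cell[cell["round"].isin(late_rounds)].index
                    if len(early) == 0 or len(late) == 0:
                        log.debug("unit %s game %d %s $%.0f: missing early or "
                                  "late wins, skipped", rm.unit_id, game, cls, mag)
                        continue
                    pos = {idx: i for i, idx in enumerate(tr.index)}
                    e = np.mean([resp[pos[i]] for i in early])
                    l = np.mean([resp[pos[i]] for i in late])
                    diffs.append(e - l)
            rows.append({"unit_id": rm.unit_id, "player_class": cls,
                         "early_minus_late": float(np.mean(diffs)) if diffs else np.nan,
                         "n_games_used": len(diffs)})
    return pd.DataFrame(rows)


def early_late_group_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Group t-tests of early-minus-late differences per class and paired."""
    wide = table.pivot(index="unit_id", columns="player_class",
                       values="early_minus_late").dropna()
    rows = []
    for cls in ("self", "observed"):
        t, p = stats.ttest_1samp(wide[cls], 0.0)
        rows.append({"test": f"{cls}_early_minus_late", "statistic": float(t),
                     "p": float(p), "mean": float(wide[cls].mean()),
                     "n": int(len(wide))})
    t, p = stats.ttest_rel(wide["observed"], wide["self"])
    rows.append({"test": "observed_vs_self_paired", "statistic": float(t),
                 "p": float(p),
                 "mean": float((wide["observed"] - wide["self"]).mean()),
                 "n": int(len(wide))})
    return pd.DataFrame(rows)
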