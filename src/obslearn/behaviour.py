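"""Behavioural statistics on model-derived terms.

Per-subject regressions link choices and choice times to the Bayesian
learner's expected-value difference (V_L-R) and choice entropy (CE),
and to lagged outcomes and prediction errors; group-level inference is
a one-sample t-test across per-subject coefficients (df = n_subjects -
1), one-tailed in the direction the learning account predicts.

The round structure (self, obs1, obs2) means that, counting back from a
self trial, lags t-3 and t-6 are the subject's own previous outcomes
while lags t-1, t-2, t-4 and t-5 are observed ones; the lag-role
assignment is always derived from the player column, never assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

SELF_LAGS = (3, 6)
OBSERVED_LAGS = (1, 2, 4, 5)


@dataclass
class RegressionResult:
    """Per-subject coefficients plus the group-level one-sample t-test."""

    terms: list
    per_subject: pd.DataFrame      # subject, term, beta, se, n
    group: pd.DataFrame            # term, mean_beta, t, p_one_tailed, df
    excluded: list = field(default_factory=list)   # (subject, reason)

    @property
    def n_subjects(self) -> int:
        return self.per_subject["subject"].nunique()


def merge_learner(trials: pd.DataFrame, learner_output: pd.DataFrame) -> pd.DataFrame:
    """Join a trial table with its aligned learner output (positional)."""
    if len(trials) != len(learner_output):
        raise ValueError("trials and learner output have different lengths")
    merged = trials.reset_index(drop=True).copy()
    for col in ("ev1", "ev2", "chosen_ev", "ce", "pe_binary", "pe_amount"):
        merged[col] = learner_output[col].to_numpy()
    merged["v_lr"] = merged["ev1"] - merged["ev2"]
    merged["ct"] = merged["t_choice"] - merged["t_present"]
    merged["chose_left"] = (merged["chosen_deck"] == "left").astype(float)
    merged["won"] = (merged["outcome"] == "win").astype(float)
    return merged


def _group_table(per_subject: pd.DataFrame, terms, directions) -> pd.DataFrame:
    rows = []
    for term in terms:
        betas = per_subject.loc[per_subject["term"] == term, "beta"].to_numpy()
        n = betas.size
        mean = float(np.mean(betas)) if n else np.nan
        if n >= 2 and np.std(betas, ddof=1) > 0:
            t, p_two = stats.ttest_1samp(betas, 0.0)
            direction = directions.get(term, "positive")
            if direction == "positive":
                p = p_two / 2 if t > 0 else 1 - p_two / 2
            elif direction == "negative":
                p = p_two / 2 if t < 0 else 1 - p_two / 2
            else:
                p = p_two
        else:
            t, p = np.nan, np.nan
        rows.append({"term": term, "mean_beta": mean, "t": float(t),
                     "p_one_tailed": float(p), "df": n - 1, "n_subjects": n})
    return pd.DataFrame(rows)


def _check_variation(X: pd.DataFrame) -> None:
    for col in X.columns:
        if col != "const" and np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"predictor {col!r} is constant across trials: "
                             "coefficient unidentifiable")


def fit_choice_model(merged: pd.DataFrame,
                     directions: dict | None = None) -> RegressionResult:
    """Logistic regression of left-deck choice on V_L-R and CE, self trials.

    Coefficients are log-odds changes. Subjects with complete
    separation are flagged and excluded from the group test.
    """
    directions = directions or {"v_lr": "positive", "ce": "two_sided"}
    terms = ["const", "v_lr", "ce"]
    rows, excluded = [], []
    for subject, df in merged.groupby("subject_id"):
        d = df[df["player"] == "self"]
        X = sm.add_constant(d[["v_lr", "ce"]], has_constant="add")
        _check_variation(X)
        y = d["chose_left"].to_numpy()
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
                raise np.linalg.LinAlgError("separation")
        except Exception as exc:  # separation / non-convergence
            log.warning("subject %s excluded from choice model: %s", subject, exc)
            excluded.append((subject, f"separation or fit failure: {exc}"))
            continue
        for term in terms:
            rows.append({"subject": subject, "term": term,
                         "beta": float(fit.params[term]),
                         "se": float(fit.bse[term]), "n": int(len(d))})
    per_subject = pd.DataFrame(rows, columns=["subject", "term", "beta", "se", "n"])
    return RegressionResult(terms, per_subject,
                            _group_table(per_subject, terms, directions), excluded)


def fit_choice_time_model(merged: pd.DataFrame,
                          directions: dict | None = None) -> RegressionResult:
    """Linear regression of choice time on V_L-R and CE (positive = slowing)."""
    directions = directions or {"v_lr": "two_sided", "ce": "positive"}
    terms = ["const", "v_lr", "ce"]
    rows, excluded = [], []
    for subject, df in merged.groupby("subject_id"):
        d = df[df["player"] == "self"]
        bad = ~(np.isfinite(d["ct"]) & (d["ct"] > 0))
        if bad.any():
            log.info("subject %s: rejected %d non-positive choice times",
                     subject, int(bad.sum()))
            d = d[~bad]
        X = sm.add_constant(d[["v_lr", "ce"]], has_constant="add")
        _check_variation(X)
        fit = sm.OLS(d["ct"].to_numpy(), X).fit()
        for term in terms:
            rows.append({"subject": subject, "term": term,
                         "beta": float(fit.params[term]),
                         "se": float(fit.bse[term]), "n": int(len(d))})
    per_subject = pd.DataFrame(rows, columns=["subject", "term", "beta", "se", "n"])
    return RegressionResult(terms, per_subject,
                            _group_table(per_subject, terms, directions), excluded)


def _lag_roles(players: np.ndarray, t: int, lags) -> dict:
    return {j: players[t - j] for j in lags}


def _deck_evidence_beta(fit_params: pd.Series, lag: int) -> float:
    """Pro-left evidence weight at one lag: (beta_left - beta_right) / 2."""
    return (fit_params[f"rL_{lag}"] - fit_params[f"rR_{lag}"]) / 2.0


def lagged_outcome_regression(merged: pd.DataFrame, max_lag: int = 6,
                              model: str = "linear") -> RegressionResult:
    """Choice regression on the past six per-deck win indicators.

    Predicts left-deck choice on self trials from win (1) / no-win (0)
    indicators of the left and right decks at lags 1..6, fitted as a
    linear probability model (``model="logistic"`` for the robust
    variant). Aggregates: the self effect averages the pro-choice
    evidence weight (beta_left - beta_right)/2 over lags {3, 6} and the
    observed effect over lags {1, 2, 4, 5}.
    """
    assert set(SELF_LAGS) | set(OBSERVED_LAGS) == set(range(1, max_lag + 1))
    agg_terms = ["self_outcomes", "observed_outcomes"]
    rows, excluded = [], []
    for subject, df in merged.groupby("subject_id"):
        df = df.reset_index(drop=True)
        players = df["player"].to_numpy()
        chose_left = df["chose_left"].to_numpy()
        won = df["won"].to_numpy()
        X_rows, y = [], []
        for t in np.flatnonzero(players == "self"):
            if t < max_lag:
                continue
            roles = _lag_roles(players, t, range(1, max_lag + 1))
            # lag roles follow from the fixed round structure
            assert all(roles[j] == "self" for j in SELF_LAGS)
            assert all(roles[j] != "self" for j in OBSERVED_LAGS)
            feat = {}
            for j in range(1, max_lag + 1):
                feat[f"rL_{j}"] = won[t - j] if chose_left[t - j] else 0.0
                feat[f"rR_{j}"] = won[t - j] if not chose_left[t - j] else 0.0
            X_rows.append(feat)
            y.append(chose_left[t])
        X = pd.DataFrame(X_rows)
        y = np.asarray(y)
        if len(X) < X.shape[1] + 2:
            excluded.append((subject, "too few eligible trials"))
            continue
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            excluded.append((subject, "collinear outcome regressors"))
            log.warning("subject %s: collinear lagged-outcome design", subject)
            continue
        if model == "logistic":
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        else:
            fit = sm.OLS(y, Xc).fit()
        self_agg = float(np.mean([_deck_evidence_beta(fit.params, j)
                                  for j in SELF_LAGS]))
        obs_agg = float(np.mean([_deck_evidence_beta(fit.params, j)
                                 for j in OBSERVED_LAGS]))
        for term, beta in (("self_outcomes", self_agg), ("observed_outcomes", obs_agg)):
            rows.append({"subject": subject, "term": term, "beta": beta,
                         "se": np.nan, "n": int(len(y))})
    per_subject = pd.DataFrame(rows, columns=["subject", "term", "beta", "se", "n"])
    directions = {t: "positive" for t in agg_terms}
    return RegressionResult(agg_terms, per_subject,
                            _group_table(per_subject, agg_terms, directions), excluded)


def lagged_pe_regression(merged: pd.DataFrame, pe_column: str = "pe_amount",
                         ) -> RegressionResult:
    """Choice regression on the most recent per-player prediction errors.

    For each self trial t the most recent self PE is at lag 3 and the
    most recent observed PEs at lags 1 (Obs2 of the previous round) and
    2 (Obs1). PEs enter signed per chosen deck (left/right columns).
    """
    if pe_column not in merged.columns:
        raise ValueError(f"learner output column {pe_column!r} missing")
    lags = (1, 2, 3)
    agg_terms = ["self_pe", "observed_pe"]
    rows, excluded = [], []
    for subject, df in merged.groupby("subject_id"):
        df = df.reset_index(drop=True)
        players = df["player"].to_numpy()
        chose_left = df["chose_left"].to_numpy()
        pe = df[pe_column].to_numpy()
        if np.ptp(pe) == 0:
            excluded.append((subject, "zero-variance prediction errors"))
            log.warning("subject %s: degenerate (constant) PE column", subject)
            continue
        X_rows, y = [], []
        for t in np.flatnonzero(players == "self"):
            if t < max(lags):
                continue
            assert players[t - 3] == "self" and players[t - 1] != "self"
            feat = {}
            for j in lags:
                feat[f"dL_{j}"] = pe[t - j] if chose_left[t - j] else 0.0
                feat[f"dR_{j}"] = pe[t - j] if not chose_left[t - j] else 0.0
            X_rows.append(feat)
            y.append(chose_left[t])
        X = sm.add_constant(pd.DataFrame(X_rows), has_constant="add")
        fit = sm.OLS(np.asarray(y), X).fit()
        self_agg = (fit.params["dL_3"] - fit.params["dR_3"]) / 2.0
        obs_agg = float(np.mean([(fit.params[f"dL_{j}"] - fit.params[f"dR_{j}"]) / 2.0
                                 for j in (1, 2)]))
        for term, beta in (("self_pe", self_agg), ("observed_pe", obs_agg)):
            rows.append({"subject": subject, "term": term, "beta": float(beta),
                         "se": np.nan, "n": int(len(y))})
    per_subject = pd.DataFrame(rows, columns=["subject", "term", "beta", "se", "n"])
    directions = {t: "positive" for t in agg_terms}
    return RegressionResult(agg_terms, per_subject,
                            _group_table(per_subject, agg_terms, directions), excluded)


def _coherent_run_length(df: pd.DataFrame, t: int) -> int:
    """Consecutive previous outcomes coherently pointing at one deck."""
    chose_left = df["chose_left"].to_numpy()
    won = df["won"].to_numpy()

    def points_left(i: int) -> bool:
        return bool(chose_left[i]) == bool(won[i])

    if t == 0:
        return 0
    target = points_left(t - 1)
    run = 0
    for i in range(t - 1, -1, -1):
        if points_left(i) == target:
            run += 1
        else:
            break
    return run


def rt_descriptive_tests(merged: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Descriptive choice-time tests on self trials (pooled by default).

    Two-tailed t-tests: objectively better vs worse deck, after an
    observed win vs loss, and left vs right side; a Spearman rank
    correlation of CT with the count of coherent previous outcomes; and
    one-way ANOVAs of CT across rounds 1-5 and rounds 2-5.
    """
    if not pooled:
        parts = [rt_descriptive_tests(d, pooled=True).assign(subject=s)
                 for s, d in merged.groupby("subject_id")]
        return pd.concat(parts, ignore_index=True)

    merged = merged.reset_index(drop=True)
    is_self = merged["player"] == "self"
    d = merged[is_self]
    out = []

    def _ttest(name, a, b):
        if len(a) < 2 or len(b) < 2:
            log.info("rt test %s skipped: empty or tiny cell", name)
            return
        t, p = stats.ttest_ind(a, b)
        out.append({"test": name, "statistic": float(t), "p": float(p),
                    "n1": len(a), "n2": len(b)})

    better = d["chosen_deck"] == d["good_deck"]
    _ttest("better_vs_worse_deck", d.loc[better, "ct"], d.loc[~better, "ct"])

    prev_won = []
    for t in d.index:
        prev_won.append(merged["won"].iloc[t - 1] if t > 0 else np.nan)
    prev_won = np.asarray(prev_won)
    valid = np.isfinite(prev_won)
    _ttest("after_observed_win_vs_loss",
           d.loc[valid & (prev_won == 1), "ct"], d.loc[valid & (prev_won == 0), "ct"])

    left = d["chosen_deck"] == "left"
    _ttest("left_vs_right_side", d.loc[left, "ct"], d.loc[~left, "ct"])

    runs = np.array([_coherent_run_length(merged, t) for t in d.index])
    if np.ptp(runs) > 0 and len(d) >= 3:
        rho, p = stats.spearmanr(runs, d["ct"])
        out.append({"test": "ct_vs_coherent_outcomes", "statistic": float(rho),
                    "p": float(p), "n1": len(d), "n2": 0})

    for name, rounds in (("anova_rounds_1_5", range(1, 6)),
                         ("anova_rounds_2_5", range(2, 6))):
        groups = [d.loc[d["round"] == r, "ct"].to_numpy() for r in rounds]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            f, p = stats.f_oneway(*groups)
            out.append({"test": name, "statistic": float(f), "p": float(p),
                        "n1": int(sum(len(g) for g in groups)), "n2": 0})
        else:
            log.info("rt test %s skipped: empty cells", name)
    return pd.DataFrame(out)
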