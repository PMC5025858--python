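"""Hierarchical Bayesian reversal-learning observer.

The learner tracks the probability q that the left deck pays off, on a
discrete grid over q in [0, 1], jointly with the per-opportunity
reversal hazard v, itself unknown and carried on its own grid. Because
a single observed outcome fully determines the contingency on that
trial (the decks are inversely related), every trial — self-experienced
or observed — updates the belief with likelihood q (left win / right
loss) or 1-q (left loss / right win).

Between trials the belief mixes with its own mirror image over q with
weight v at each reversal opportunity: by default only at game
boundaries, matching the task instructions that contingencies could
reverse every 15 trials with probability 0.5; a per-trial hazard mode
is also available.

The marginal posterior mean of q is the expected value (EV) of the left
deck; the right deck's EV is its complement. Choices follow a softmax
over the two EVs with temperature tau, and the choice entropy (bits) of
the EV pair measures choice difficulty. Prediction errors are obtained
minus expected reward, in binary (win=1/loss=0) or dollar-amount units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

from .task import SessionRecord

#: columns of the serialized learner output
LEARNER_COLUMNS = ["session_id", "trial_index", "ev1", "ev2", "chosen_ev",
                   "ce", "pe_binary", "pe_amount", "posterior_mean_q"]

#: dollar value of one unit of win probability: the mean winning magnitude
AMOUNT_SCALE = 55.0


@dataclass(frozen=True)
class GridConfig:
    n_q: int = 101
    n_v: int = 21

    def __post_init__(self) -> None:
        if self.n_q < 2 or self.n_v < 2:
            raise ValueError("grid sizes must be >= 2")


@dataclass
class BeliefState:
    """Joint probability mass over (reward contingency q, hazard v)."""

    q_grid: np.ndarray
    v_grid: np.ndarray
    mass: np.ndarray  # shape (n_q, n_v)

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.v_grid = np.asarray(self.v_grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.q_grid.size, self.v_grid.size):
            raise ValueError("mass shape does not match grids")
        if np.any(np.diff(self.q_grid) <= 0) or np.any(np.diff(self.v_grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        if np.any(self.mass < 0):
            raise ValueError("negative probability mass")
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"mass sums to {total}, expected 1")

    @property
    def q_marginal(self) -> np.ndarray:
        return self.mass.sum(axis=1)

    @property
    def posterior_mean_q(self) -> float:
        return float(self.q_marginal @ self.q_grid)

    def copy(self) -> "BeliefState":
        return BeliefState(self.q_grid, self.v_grid, self.mass.copy())


def init_belief(grid: GridConfig = GridConfig()) -> BeliefState:
    """Uniform joint prior over (q, v)."""
    q = np.linspace(0.0, 1.0, grid.n_q)
    v = np.linspace(0.0, 1.0, grid.n_v)
    mass = np.full((grid.n_q, grid.n_v), 1.0 / (grid.n_q * grid.n_v))
    return BeliefState(q, v, mass)


def transition(belief: BeliefState, at_reversal_opportunity: bool = True) -> BeliefState:
    """Propagate the belief across one trial boundary.

    At a reversal opportunity the mass over q mixes with its mirror
    image with weight v (columnwise on the hazard grid); elsewhere the
    belief passes through unchanged.
    """
    if not at_reversal_opportunity:
        return belief.copy()
    # q grid is a symmetric linspace on [0,1]; mirroring q -> 1-q is a flip
    mirrored = belief.mass[::-1, :]
    v = belief.v_grid[np.newaxis, :]
    new_mass = (1.0 - v) * belief.mass + v * mirrored
    new_mass /= new_mass.sum()
    return BeliefState(belief.q_grid, belief.v_grid, new_mass)


def update(belief: BeliefState, observed_deck: str, observed_outcome: str) -> BeliefState:
    """Bayes update from one trial's (deck, outcome) observation.

    Likelihood is q for a left-deck win (equivalently a right-deck
    loss) and 1-q otherwise.
    """
    if observed_deck not in ("left", "right"):
        raise ValueError(f"unknown deck {observed_deck!r}")
    if observed_outcome not in ("win", "lose"):
        raise ValueError(f"unknown outcome {observed_outcome!r}")
    left_win_evidence = (observed_deck == "left") == (observed_outcome == "win")
    lik = belief.q_grid if left_win_evidence else 1.0 - belief.q_grid
    new_mass = belief.mass * lik[:, np.newaxis]
    total = new_mass.sum()
    if total <= 0.0:
        raise ValueError("zero total likelihood: degenerate belief/observation")
    return BeliefState(belief.q_grid, belief.v_grid, new_mass / total)


def expected_value(belief: BeliefState) -> tuple[float, float]:
    """(EV of left deck, EV of right deck) = (E[q], 1 - E[q])."""
    ev1 = belief.posterior_mean_q
    return ev1, 1.0 - ev1


def choice_entropy(ev_pair) -> float:
    """Shannon entropy (bits) of the two-deck win-probability pair."""
    p = np.asarray(ev_pair, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"EVs must lie in [0, 1], got {ev_pair}")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("EV pair must be normalized")
    pos = p[p > 0]  # 0 log 0 taken as 0
    return float(-(pos * np.log2(pos)).sum())


@dataclass(frozen=True)
class SoftmaxParams:
    tau: float
    n_decks: int = 2

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")


def choice_probability(ev_pair, params: SoftmaxParams) -> float:
    """Softmax probability of choosing deck 1 (left), overflow-safe."""
    ev1, ev2 = float(ev_pair[0]), float(ev_pair[1])
    z = (ev1 - ev2) / params.tau
    # logistic in the EV difference; clip the exponent for safety
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))))


def prediction_error(outcome: str, amount: float, chosen_ev: float,
                     coding: str = "binary", scale: float = AMOUNT_SCALE) -> float:
    """Reward prediction error: obtained minus expected reward.

    Binary coding uses win=1/loss=0; amount coding uses signed dollars
    with the EV converted to dollars through *scale* (the mean winning
    magnitude, so a fully expected mean win is zero error).
    """
    if not 0.0 <= chosen_ev <= 1.0:
        raise ValueError(f"chosen_ev must lie in [0, 1], got {chosen_ev}")
    if coding == "binary":
        return float(outcome == "win") - chosen_ev
    if coding == "amount":
        return float(amount) - chosen_ev * scale
    raise ValueError(f"unknown prediction-error coding {coding!r}")


class BayesianRevLearner(BaseEstimator, TransformerMixin):
    """Grid-based Bayesian reversal-learning observer over a trial table.

    A stateless sklearn-style transformer: ``transform`` propagates the
    belief through a session's trials in chronological order (self and
    observed alike) and emits per-trial expected values, choice entropy
    and prediction errors, each evaluated *before* that trial's outcome
    update.

    Parameters
    ----------
    n_q, n_v:
        Grid resolutions for the reward contingency q and the reversal
        hazard v.
    hazard_mode:
        ``"game_boundary"`` applies the reversal transition only at the
        start of each new game (the task's stated reversal schedule);
        ``"per_trial"`` applies it before every trial.
    amount_scale:
        Dollars per unit win-probability for amount-coded prediction
        errors.
    """

    def __init__(self, n_q: int = 101, n_v: int = 21,
                 hazard_mode: str = "game_boundary",
                 amount_scale: float = AMOUNT_SCALE):
        self.n_q = n_q
        self.n_v = n_v
        self.hazard_mode = hazard_mode
        self.amount_scale = amount_scale

    def fit(self, X=None, y=None) -> "BayesianRevLearner":
        if self.hazard_mode not in ("game_boundary", "per_trial"):
            raise ValueError(f"unknown hazard_mode {self.hazard_mode!r}")
        self.grid_ = GridConfig(self.n_q, self.n_v)
        return self

    def transform(self, trials: pd.DataFrame) -> pd.DataFrame:
        """Run the observer over a chronologically ordered trial table."""
        self.fit()
        if not trials["t_outcome"].is_monotonic_increasing:
            raise ValueError("trials must be in chronological order")
        belief = init_belief(self.grid_)
        rows = []
        prev_game = None
        for idx, tr in enumerate(trials.itertuples(index=False)):
            if self.hazard_mode == "per_trial":
                belief = transition(belief, True)
            elif prev_game is not None and tr.game != prev_game:
                belief = transition(belief, True)
            prev_game = tr.game
            ev1, ev2 = expected_value(belief)
            chosen_ev = ev1 if tr.chosen_deck == "left" else ev2
            ce = choice_entropy((ev1, ev2))
            rows.append({
                "session_id": tr.session_id,
                "trial_index": idx,
                "ev1": ev1,
                "ev2": ev2,
                "chosen_ev": chosen_ev,
                "ce": ce,
                "pe_binary": prediction_error(tr.outcome, tr.amount, chosen_ev,
                                              "binary"),
                "pe_amount": prediction_error(tr.outcome, tr.amount, chosen_ev,
                                              "amount", self.amount_scale),
                "posterior_mean_q": belief.posterior_mean_q,
            })
            belief = update(belief, tr.chosen_deck, tr.outcome)
        self.final_belief_ = belief
        return pd.DataFrame(rows, columns=LEARNER_COLUMNS)


def run_model_on_session(session: SessionRecord | pd.DataFrame,
                         grid: GridConfig = GridConfig(),
                         hazard_mode: str = "game_boundary") -> pd.DataFrame:
    """Convenience wrapper around :class:`BayesianRevLearner`."""
    trials = session.trials if isinstance(session, SessionRecord) else session
    model = BayesianRevLearner(n_q=grid.n_q, n_v=grid.n_v, hazard_mode=hazard_mode)
    return model.transform(trials)


@dataclass
class TemperatureFit:
    tau: float
    log_likelihood: float
    at_lower_bound: bool
    at_upper_bound: bool
    flat_likelihood: bool   # likelihood at the upper bound ~ likelihood at tau
    n_trials: int


class SoftmaxTemperature(BaseEstimator):
    """Maximum-likelihood softmax temperature from observed choices.

    ``fit(ev_pairs, choices)`` takes per-trial (EV_left, EV_right) rows
    and binary indicators of left-deck choices and estimates the
    temperature tau by bounded 1-D likelihood maximization seeded from
    a coarse grid scan (a cheap stand-in for multi-restart search in a
    unimodal 1-D problem).

    Attributes (after fit): ``tau_``, ``loglik_``, ``diagnostics_``.
    """

    def __init__(self, bounds: tuple[float, float] = (1e-3, 20.0)):
        self.bounds = bounds

    @staticmethod
    def _negloglik(tau: float, dv: np.ndarray, chose_left: np.ndarray) -> float:
        z = dv / tau
        # log p(chosen) = -log(1 + exp(-sign * z))
        s = np.where(chose_left, z, -z)
        return float(np.logaddexp(0.0, -s).sum())

    def fit(self, ev_pairs, choices) -> "SoftmaxTemperature":
        ev = np.asarray(ev_pairs, dtype=float)
        chose_left = np.asarray(choices).astype(bool)
        if ev.ndim != 2 or ev.shape[1] != 2:
            raise ValueError("ev_pairs must be (n_trials, 2)")
        if len(chose_left) != len(ev):
            raise ValueError("choices and ev_pairs length mismatch")
        if len(ev) < 10:
            raise ValueError(f"need >= 10 choices to fit tau, got {len(ev)}")
        dv = ev[:, 0] - ev[:, 1]
        lo, hi = self.bounds
        # coarse log-spaced scan to seed the bounded minimizer
        grid = np.geomspace(lo, hi, 25)
        nll = [self._negloglik(t, dv, chose_left) for t in grid]
        t0 = grid[int(np.argmin(nll))]
        span = (max(lo, t0 / 4), min(hi, t0 * 4))
        res = minimize_scalar(self._negloglik, bounds=span, args=(dv, chose_left),
                              method="bounded", options={"xatol": 1e-6})
        cand = [(res.fun, res.x)] + list(zip(nll, grid))
        best_nll, best_tau = min(cand, key=lambda p: p[0])
        self.tau_ = float(best_tau)
        self.loglik_ = -float(best_nll)
        # choices carrying no EV information leave the likelihood flat
        # between tau-hat and the random-choice limit at the upper bound
        flat = self._negloglik(hi, dv, chose_left) - best_nll < 2.0
        self.diagnostics_ = TemperatureFit(
            tau=self.tau_,
            log_likelihood=self.loglik_,
            at_lower_bound=self.tau_ <= lo * 1.05,
            at_upper_bound=self.tau_ >= hi * 0.95,
            flat_likelihood=bool(flat),
            n_trials=len(ev),
        )
        return self

    def predict_proba(self, ev_pairs) -> np.ndarray:
        ev = np.asarray(ev_pairs, dtype=float)
        z = (ev[:, 0] - ev[:, 1]) / self.tau_
        p_left = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        return np.column_stack([p_left, 1.0 - p_left])


def fit_temperature(choices, ev_trajectory,
                    bounds: tuple[float, float] = (1e-3, 20.0)) -> TemperatureFit:
    """Functional wrapper over :class:`SoftmaxTemperature`."""
    est = SoftmaxTemperature(bounds=bounds).fit(ev_trajectory, choices)
    return est.diagnostics_
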