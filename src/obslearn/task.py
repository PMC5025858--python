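"""Generative model of the card-game and slot-machine tasks.

Subjects play 12 games of 5 rounds; each round is one self-experienced
trial followed by two observed trials, so a full session holds
12 x 5 x 3 = 180 card trials (60 self, 120 observed). One deck pays off
with probability 0.7, the other with 0.3, and the identity of the good
deck may flip at each game boundary with probability 0.5. Win/loss
amounts are +/-$10 or +/-$100, equiprobable within sign. After the card
game a slot machine pays off with probability 0.5; a win doubles the
running total and a loss halves it, floored at $0.

Trial timing follows the on-screen sequence: the chosen card is
highlighted for 1 s before the outcome is shown for 3 s. All event
times are on a per-session clock in seconds with the outcome onset as
the natural t=0 anchor for aligned analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLAYERS = ("self", "obs1", "obs2")
DECKS = ("left", "right")

#: fixed column order of the on-disk trial table
TRIAL_COLUMNS = [
    "subject_id", "session_id", "game", "round", "trial_in_game",
    "player", "chosen_deck", "outcome", "amount", "good_deck",
    "t_present", "t_choice", "t_outcome", "t_offset",
]


class TaskConfigError(ValueError):
    """Raised for invalid task configurations."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the card-game / slot-machine session."""

    n_games: int = 12
    rounds_per_game: int = 5
    players: tuple[str, ...] = PLAYERS
    p_good: float = 0.7
    p_reversal: float = 0.5
    amounts: tuple[float, ...] = (10.0, 100.0)
    slot_p_win: float = 0.5
    #: pacing of the trial sequence (seconds)
    highlight_duration: float = 1.0
    outcome_duration: float = 3.0
    inter_trial_interval: float = 1.0
    nominal_choice_time: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_good < 1.0:
            raise TaskConfigError(f"p_good must be in (0, 1), got {self.p_good}")
        if not 0.0 <= self.p_reversal <= 1.0:
            raise TaskConfigError(
                f"p_reversal must be in [0, 1], got {self.p_reversal}")
        if not 0.0 <= self.slot_p_win <= 1.0:
            raise TaskConfigError(
                f"slot_p_win must be in [0, 1], got {self.slot_p_win}")
        if self.n_games < 1 or self.rounds_per_game < 1:
            raise TaskConfigError("n_games and rounds_per_game must be >= 1")
        if any(a <= 0 for a in self.amounts):
            raise TaskConfigError("amounts must be strictly positive magnitudes")

    @property
    def n_trials(self) -> int:
        return self.n_games * self.rounds_per_game * len(self.players)


@dataclass(frozen=True)
class SlotTrial:
    trial: int
    outcome: str          # "win" | "lose"
    total_before: float
    total_after: float
    t_outcome: float


@dataclass
class SessionRecord:
    """One recorded session: 180 card trials plus optional slot trials."""

    subject_id: str
    session_id: str
    config: TaskConfig
    trials: pd.DataFrame
    slot_trials: list[SlotTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials[TRIAL_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: TaskConfig | None = None) -> "SessionRecord":
        trials = pd.read_csv(path)
        missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
        if missing:
            raise ValueError(f"trial table at {path} missing columns: {missing}")
        return cls(
            subject_id=str(trials["subject_id"].iloc[0]),
            session_id=str(trials["session_id"].iloc[0]),
            config=config or TaskConfig(),
            trials=trials.reset_index(drop=True),
        )


def _observed_choice(policy: str, rng: np.random.Generator, trial_in_game: int) -> str:
    if policy == "uniform":
        return DECKS[rng.integers(2)]
    if policy == "variance_seeking":
        # Balanced alternation keeps choice and amount variance high over a
        # game, mimicking the confederates' scripted behaviour.
        return DECKS[(trial_in_game + int(rng.integers(2) == 0)) % 2]
    raise TaskConfigError(f"unknown observed policy {policy!r}")


def generate_session(
    config: TaskConfig,
    seed: int | np.random.Generator,
    observed_policy: str = "uniform",
    self_policy: str = "uniform",
    subject_id: str = "S01",
    session_id: str = "sess01",
) -> SessionRecord:
    """Simulate one full card-game session with known ground truth.

    Choices are drawn from simple placeholder policies; realistic
    (softmax, entropy-dependent) self behaviour is layered on by
    :func:`obslearn.synth.simulate_behaviour`.
    """
    rng = np.random.default_rng(seed)
    good_deck = DECKS[rng.integers(2)]
    rows = []
    clock = 0.0
    for game in range(1, config.n_games + 1):
        if game > 1 and rng.random() < config.p_reversal:
            good_deck = DECKS[1 - DECKS.index(good_deck)]
        trial_in_game = 0
        for rnd in range(1, config.rounds_per_game + 1):
            for player in config.players:
                trial_in_game += 1
                if player == "self":
                    choice = _observed_choice(self_policy, rng, trial_in_game)
                else:
                    choice = _observed_choice(observed_policy, rng, trial_in_game)
                p_win = config.p_good if choice == good_deck else 1.0 - config.p_good
                win = rng.random() < p_win
                magnitude = float(config.amounts[rng.integers(len(config.amounts))])
                amount = magnitude if win else -magnitude
                t_present = clock
                t_choice = t_present + config.nominal_choice_time
                t_outcome = t_choice + config.highlight_duration
                t_offset = t_outcome + config.outcome_duration
                clock = t_offset + config.inter_trial_interval
                rows.append({
                    "subject_id": subject_id,
                    "session_id": session_id,
                    "game": game,
                    "round": rnd,
                    "trial_in_game": trial_in_game,
                    "player": player,
                    "chosen_deck": choice,
                    "outcome": "win" if win else "lose",
                    "amount": amount,
                    "good_deck": good_deck,
                    "t_present": t_present,
                    "t_choice": t_choice,
                    "t_outcome": t_outcome,
                    "t_offset": t_offset,
                })
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionRecord(subject_id=subject_id, session_id=session_id,
                         config=config, trials=trials)


def generate_slot_session(
    config: TaskConfig,
    n_trials: int,
    starting_total: float,
    seed: int | np.random.Generator,
    t_start: float = 0.0,
    inter_trial_interval: float = 4.0,
) -> list[SlotTrial]:
    """Simulate the slot-machine block: win doubles, loss halves, floor $0."""
    if n_trials < 1:
        raise TaskConfigError(f"n_trials must be >= 1, got {n_trials}")
    if starting_total < 0:
        raise TaskConfigError(
            f"starting total must be non-negative, got {starting_total}")
    rng = np.random.default_rng(seed)
    total = float(starting_total)
    out = []
    t = t_start
    for i in range(n_trials):
        win = rng.random() < config.slot_p_win
        new_total = total * 2.0 if win else total / 2.0
        new_total = max(new_total, 0.0)
        out.append(SlotTrial(trial=i + 1, outcome="win" if win else "lose",
                             total_before=total, total_after=new_total,
                             t_outcome=t))
        total = new_total
        t += inter_trial_interval
    return out


def with_trials(session: SessionRecord, trials: pd.DataFrame) -> SessionRecord:
    """Return a copy of *session* carrying a replacement trial table."""
    return SessionRecord(subject_id=session.subject_id,
                         session_id=session.session_id,
                         config=session.config,
                         trials=trials.reset_index(drop=True),
                         slot_trials=list(session.slot_trials))
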