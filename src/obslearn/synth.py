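"""Synthetic cohorts: softmax behaviour, choice times, and spike trains.

This module layers realistic behaviour and neural signals onto the bare
task generator so the whole analysis pipeline can be exercised without
any recorded data:

* self choices drawn from a softmax over the Bayesian learner's
  expected values, with choice times that grow linearly with choice
  entropy (harder choices are slower) plus a first-round surcharge;
* spike trains sampled from inhomogeneous Poisson processes whose rate
  is a baseline plus event-locked half-cosine bumps scaled by planted
  regressor values (outcome sign, signed amount, expected value), with
  a choice of coding profiles including the tripartite
  prediction-error scheme (+EV at observed choice, +amount and -EV at
  outcome) and a "schadenfreude" profile whose outcome sign flips
  between self and observed trials.

Defaults emulate the recorded populations: baseline rates near
2-2.5 Hz, response onset ~250 ms and a 300-900 ms response window, ten
subjects contributing 31 sessions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import learner as lrn
from .task import (SessionRecord, TaskConfig, generate_session,
                   generate_slot_session, with_trials)

AREAS = ("AMY", "rmPFC", "rACC")
CODING_PROFILES = ("null", "outcome", "amount", "tripartite_PE", "shadenfreude")


@dataclass(frozen=True)
class BehaviourParams:
    """Planted behavioural effect sizes."""

    tau: float = 0.2                 # softmax temperature
    ct_intercept: float = 1.0        # s
    ct_entropy_slope: float = 0.4    # s per bit of choice entropy
    ct_noise_sd: float = 0.3         # s
    ct_round1_extra: float = 0.5     # s, first round of each game
    ct_floor: float = 0.15           # s, truncation floor

    def __post_init__(self) -> None:
        if self.ct_noise_sd <= 0:
            raise ValueError("ct_noise_sd must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class ResponseKernel:
    """Half-cosine response bump locked to a trial event."""

    onset: float = 0.25      # s after the event
    duration: float = 0.6    # s

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel value at times *t* relative to the event (peak 1)."""
        x = (np.asarray(t, dtype=float) - self.onset) / self.duration
        return np.where((x >= 0) & (x <= 1), np.sin(np.pi * np.clip(x, 0, 1)), 0.0)


@dataclass(frozen=True)
class SpikeModel:
    """Planted coding scheme of one synthetic unit."""

    unit_id: str
    area: str = "rACC"
    baseline_rate: float = 2.0          # Hz
    coding_profile: str = "null"
    betas: dict = field(default_factory=dict)   # Hz per unit regressor
    kernel: ResponseKernel = ResponseKernel()
    refractory_floor: float = 0.003     # s
    response_gain: float = 0.0          # Hz, unsigned outcome-locked bump

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be non-negative")
        if self.coding_profile not in CODING_PROFILES:
            raise ValueError(f"unknown coding profile {self.coding_profile!r}")


@dataclass
class SpikeTrain:
    unit_id: str
    area: str
    times: np.ndarray  # seconds, strictly increasing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class SimulatedBehaviour:
    """A session rewritten with softmax self behaviour."""

    session: SessionRecord
    learner_output: pd.DataFrame
    self_trials: pd.DataFrame  # per self trial: ct, ce, ev diff, choice


def simulate_behaviour(
    session: SessionRecord,
    params: BehaviourParams,
    seed: int | np.random.Generator,
    grid: lrn.GridConfig = lrn.GridConfig(),
    hazard_mode: str = "game_boundary",
) -> SimulatedBehaviour:
    """Redraw self choices from the learner's softmax, with choice times.

    The belief is propagated sequentially: on self trials a deck is
    drawn from the softmax over current EVs and its outcome from the
    true contingency, so the returned learner output is consistent with
    the simulated choices. Observed trials keep the session-defined
    choices and outcomes. Event times are rebuilt so that the choice
    time (t_choice - t_present) carries the planted entropy effect.
    """
    rng = np.random.default_rng(seed)
    cfg = session.config
    trials = session.trials
    belief = lrn.init_belief(grid)
    sm = lrn.SoftmaxParams(tau=params.tau)
    clock = 0.0
    new_rows, lrn_rows, self_rows = [], [], []
    prev_game = None
    for idx, tr in enumerate(trials.itertuples(index=False)):
        if hazard_mode == "per_trial" or (prev_game is not None and tr.game != prev_game):
            belief = lrn.transition(belief, True)
        prev_game = tr.game
        ev1, ev2 = lrn.expected_value(belief)
        ce = lrn.choice_entropy((ev1, ev2))
        row = tr._asdict()
        if tr.player == "self":
            p_left = lrn.choice_probability((ev1, ev2), sm)
            choice = "left" if rng.random() < p_left else "right"
            p_win = cfg.p_good if choice == tr.good_deck else 1.0 - cfg.p_good
            win = rng.random() < p_win
            magnitude = float(cfg.amounts[rng.integers(len(cfg.amounts))])
            ct = (params.ct_intercept + params.ct_entropy_slope * ce
                  + (params.ct_round1_extra if tr.round == 1 else 0.0)
                  + rng.normal(0.0, params.ct_noise_sd))
            ct = max(ct, params.ct_floor)
            row.update(chosen_deck=choice, outcome="win" if win else "lose",
                       amount=magnitude if win else -magnitude)
        else:
            choice, ct = tr.chosen_deck, cfg.nominal_choice_time
        t_present = clock
        t_choice = t_present + ct
        t_outcome = t_choice + cfg.highlight_duration
        t_offset = t_outcome + cfg.outcome_duration
        clock = t_offset + cfg.inter_trial_interval
        row.update(t_present=t_present, t_choice=t_choice,
                   t_outcome=t_outcome, t_offset=t_offset)
        new_rows.append(row)
        chosen_ev = ev1 if row["chosen_deck"] == "left" else ev2
        lrn_rows.append({
            "session_id": tr.session_id, "trial_index": idx,
            "ev1": ev1, "ev2": ev2, "chosen_ev": chosen_ev, "ce": ce,
            "pe_binary": lrn.prediction_error(row["outcome"], row["amount"],
                                              chosen_ev, "binary"),
            "pe_amount": lrn.prediction_error(row["outcome"], row["amount"],
                                              chosen_ev, "amount"),
            "posterior_mean_q": belief.posterior_mean_q,
        })
        if tr.player == "self":
            self_rows.append({
                "trial_index": idx, "game": tr.game, "round": tr.round,
                "chosen_deck": row["chosen_deck"], "outcome": row["outcome"],
                "ct": ct, "ce": ce, "v_lr": ev1 - ev2,
            })
        belief = lrn.update(belief, row["chosen_deck"], row["outcome"])
    new_trials = pd.DataFrame(new_rows)
    return SimulatedBehaviour(
        session=with_trials(session, new_trials),
        learner_output=pd.DataFrame(lrn_rows, columns=lrn.LEARNER_COLUMNS),
        self_trials=pd.DataFrame(self_rows),
    )


def _planted_events(model: SpikeModel, trials: pd.DataFrame,
                    learner_output: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(event times, bump amplitudes in Hz) for a unit's coding profile."""
    b = model.betas
    times, amps = [], []
    ev = learner_output["chosen_ev"].to_numpy()
    amount = trials["amount"].to_numpy() / 100.0   # scaled dollars
    win = (trials["outcome"] == "win").to_numpy()
    is_self = (trials["player"] == "self").to_numpy()
    t_choice = trials["t_choice"].to_numpy()
    t_outcome = trials["t_outcome"].to_numpy()
    for i in range(len(trials)):
        gain_outcome = 0.0
        if model.response_gain:
            gain_outcome += model.response_gain
        if model.coding_profile == "outcome":
            gain_outcome += b.get("outcome", 0.0) * (1.0 if win[i] else -1.0)
        elif model.coding_profile == "amount":
            key = "amount_self" if is_self[i] else "amount_observed"
            gain_outcome += b.get(key, b.get("amount", 0.0)) * amount[i]
        elif model.coding_profile == "shadenfreude":
            sign = 1.0 if win[i] == is_self[i] else -1.0
            gain_outcome += b.get("outcome", 0.0) * sign
        elif model.coding_profile == "tripartite_PE":
            if not is_self[i]:
                gain_choice = b.get("ev_choice", 0.0) * ev[i]
                if gain_choice:
                    times.append(t_choice[i])
                    amps.append(gain_choice)
                gain_outcome += (b.get("amount", 0.0) * amount[i]
                                 - b.get("ev_outcome", 0.0) * ev[i])
        if gain_outcome:
            times.append(t_outcome[i])
            amps.append(gain_outcome)
    return np.asarray(times, dtype=float), np.asarray(amps, dtype=float)


def _slot_events(model: SpikeModel, slot_trials) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-locked bumps on slot-machine trials (win/lose coding only)."""
    b = model.betas
    times, amps = [], []
    for st in slot_trials:
        gain = model.response_gain
        if model.coding_profile in ("outcome", "shadenfreude"):
            sign = 1.0 if st.outcome == "win" else -1.0
            if model.coding_profile == "shadenfreude":
                sign = -sign if not b.get("slot_as_self", True) else sign
            gain += b.get("outcome", 0.0) * sign
        if gain:
            times.append(st.t_outcome)
            amps.append(gain)
    return np.asarray(times, dtype=float), np.asarray(amps, dtype=float)


def simulate_unit(
    model: SpikeModel,
    session: SessionRecord,
    learner_output: pd.DataFrame,
    seed: int | np.random.Generator,
    dt: float = 0.002,
    pad: float = 5.0,
) -> SpikeTrain:
    """Sample an inhomogeneous Poisson spike train for one unit.

    The rate is baseline + sum of event-locked kernel bumps, clipped at
    zero, evaluated on a *dt*-resolution grid; spikes are drawn by
    thinning a homogeneous process at the grid maximum and a hard
    refractory floor is enforced afterwards.
    """
    rng = np.random.default_rng(seed)
    trials = session.trials
    duration = float(trials["t_offset"].iloc[-1]) + pad
    if session.slot_trials:
        duration = max(duration, session.slot_trials[-1].t_outcome + pad)
    grid = np.arange(0.0, duration, dt)
    rate = np.full(grid.size, model.baseline_rate)
    ev_times, ev_amps = _planted_events(model, trials, learner_output)
    if session.slot_trials:
        st_times, st_amps = _slot_events(model, session.slot_trials)
        ev_times = np.concatenate([ev_times, st_times])
        ev_amps = np.concatenate([ev_amps, st_amps])
    k = model.kernel
    support = int(np.ceil((k.onset + k.duration) / dt)) + 1
    rel = np.arange(support) * dt
    bump = k.evaluate(rel)
    for t0, a in zip(ev_times, ev_amps):
        i0 = int(np.floor(t0 / dt))
        i1 = min(i0 + support, grid.size)
        rate[i0:i1] += a * bump[: i1 - i0]
    np.clip(rate, 0.0, None, out=rate)
    rate_max = float(rate.max())
    if rate_max <= 0.0:
        return SpikeTrain(model.unit_id, model.area, np.empty(0))
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    accept = rng.uniform(0.0, rate_max, n_cand) < np.interp(cand, grid, rate)
    spikes = cand[accept]
    if spikes.size and model.refractory_floor > 0:
        keep = [0]
        for i in range(1, spikes.size):
            if spikes[i] - spikes[keep[-1]] > model.refractory_floor:
                keep.append(i)
        spikes = spikes[keep]
    return SpikeTrain(model.unit_id, model.area, spikes)


# ---------------------------------------------------------------------------
# cohort generation

#: per-subject session counts emulating 31 sessions across 10 subjects
DEFAULT_SESSIONS_PER_SUBJECT = (4, 3, 3, 3, 3, 3, 3, 3, 3, 3)

#: planted population: counts per coding profile per area, echoing the
#: recorded population sizes (125 AMY / 95 rmPFC / 138 rACC units, with a
#: 22-unit tripartite subpopulation in rACC)
DEFAULT_POPULATION_SPEC = {
    "AMY": {"null": 75, "outcome": 30, "amount": 20},
    "rmPFC": {"null": 61, "outcome": 19, "amount": 15},
    "rACC": {"null": 76, "outcome": 20, "amount": 20, "tripartite_PE": 22},
}

DEFAULT_BETAS = {
    "outcome": {"outcome": 1.5},
    "amount": {"amount_observed": 1.5, "amount_self": 1.5},
    "tripartite_PE": {"ev_choice": 5.0, "amount": 3.0, "ev_outcome": 5.0},
    "shadenfreude": {"outcome": 1.5},
    "null": {},
}


def build_unit_models(population_spec: dict, rng: np.random.Generator,
                      betas: dict | None = None,
                      baseline_rates: dict | None = None) -> list[SpikeModel]:
    """Expand a population spec into per-unit :class:`SpikeModel` objects."""
    betas = betas or DEFAULT_BETAS
    baseline_rates = baseline_rates or {"AMY": 2.51, "rmPFC": 1.72, "rACC": 2.28}
    models = []
    for area, profiles in population_spec.items():
        i = 0
        for profile, count in profiles.items():
            for _ in range(count):
                i += 1
                models.append(SpikeModel(
                    unit_id=f"{area}_{i:03d}",
                    area=area,
                    baseline_rate=float(baseline_rates.get(area, 2.0)),
                    coding_profile=profile,
                    betas=dict(betas.get(profile, {})),
                    response_gain=1.0 if profile != "null" else 0.0,
                ))
    return models


@dataclass
class CohortBundle:
    """In-memory synthetic dataset: one entry per session plus unit map."""

    sessions: dict            # session_id -> SessionRecord
    learner_outputs: dict     # session_id -> DataFrame
    behaviour: dict           # session_id -> self-trial DataFrame
    spike_trains: dict        # unit_id -> SpikeTrain
    unit_table: pd.DataFrame  # unit_id, area, profile, session_id
    seed: int


def simulate_cohort(
    n_subjects: int = 10,
    sessions_per_subject=None,
    population_spec: dict | None = None,
    seed: int = 0,
    task_config: TaskConfig = TaskConfig(),
    behaviour_params: BehaviourParams = BehaviourParams(),
    units_per_session: bool = False,
) -> CohortBundle:
    """Simulate a full cohort in memory.

    Units are distributed round-robin over sessions; each unit's spike
    train is sampled on its host session. All randomness descends from
    *seed* via independent child streams, so the bundle is reproducible.
    """
    if population_spec is None:
        population_spec = DEFAULT_POPULATION_SPEC
    if sessions_per_subject is None:
        sessions_per_subject = (DEFAULT_SESSIONS_PER_SUBJECT
                                if n_subjects == 10 else 3)
    if np.isscalar(sessions_per_subject):
        sessions_per_subject = (int(sessions_per_subject),) * n_subjects
    if len(sessions_per_subject) != n_subjects:
        raise ValueError("sessions_per_subject length must equal n_subjects")
    root = np.random.default_rng(seed)
    session_ids = []
    sessions, louts, behaviour = {}, {}, {}
    for s in range(n_subjects):
        for k in range(sessions_per_subject[s]):
            sid = f"sub{s + 1:02d}_sess{k + 1:02d}"
            base = generate_session(task_config, root.integers(2**31),
                                    subject_id=f"sub{s + 1:02d}", session_id=sid)
            sim = simulate_behaviour(base, behaviour_params, root.integers(2**31))
            sim.session.slot_trials = generate_slot_session(
                task_config, n_trials=80, starting_total=100.0,
                seed=root.integers(2**31),
                t_start=float(sim.session.trials["t_offset"].iloc[-1]) + 10.0)
            sessions[sid] = sim.session
            louts[sid] = sim.learner_output
            behaviour[sid] = sim.self_trials
            session_ids.append(sid)
    models = build_unit_models(population_spec, root)
    spike_trains = {}
    unit_rows = []
    for i, m in enumerate(models):
        sid = session_ids[i % len(session_ids)]
        spike_trains[m.unit_id] = simulate_unit(
            m, sessions[sid], louts[sid], root.integers(2**31))
        unit_rows.append({"unit_id": m.unit_id, "area": m.area,
                          "profile": m.coding_profile, "session_id": sid})
    return CohortBundle(sessions=sessions, learner_outputs=louts,
                        behaviour=behaviour, spike_trains=spike_trains,
                        unit_table=pd.DataFrame(unit_rows), seed=int(seed))


def generate_cohort(
    outdir,
    n_subjects: int = 10,
    sessions_per_subject=None,
    population_spec: dict | None = None,
    seed: int = 0,
    task_config: TaskConfig = TaskConfig(),
    behaviour_params: BehaviourParams = BehaviourParams(),
) -> dict:
    """Simulate a cohort and write it to *outdir*; returns the manifest.

    Layout: one trial table and learner-output CSV per session, one
    spike-time CSV per area (unit_id, area, spike_time_s), and a JSON
    manifest listing every file with its SHA-256 checksum and the seed.
    """
    bundle = simulate_cohort(n_subjects, sessions_per_subject, population_spec,
                             seed, task_config, behaviour_params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _write(name: str, write_fn) -> None:
        path = outdir / name
        write_fn(path)
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    for sid, sess in bundle.sessions.items():
        _write(f"trials_{sid}.csv", sess.to_csv)
        _write(f"learner_{sid}.csv",
               lambda p, sid=sid: bundle.learner_outputs[sid].to_csv(p, index=False))
    if len(bundle.spike_trains):
        rows = []
        for uid, st in bundle.spike_trains.items():
            for t in st.times:
                rows.append((uid, st.area, t))
        spikes = pd.DataFrame(rows, columns=["unit_id", "area", "spike_time_s"])
        _write("spikes.csv", lambda p: spikes.to_csv(p, index=False, float_format="%.6f"))
        _write("units.csv", lambda p: bundle.unit_table.to_csv(p, index=False))
    manifest = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "sessions_per_subject": [int(x) for x in
                                 np.atleast_1d(sessions_per_subject
                                               if sessions_per_subject is not None
                                               else (DEFAULT_SESSIONS_PER_SUBJECT
                                                     if n_subjects == 10 else 3))],
        "population_spec": population_spec or DEFAULT_POPULATION_SPEC,
        "behaviour_params": asdict(behaviour_params),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
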