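"""Composition of the synthetic cohort with the neural analysis engine.

Glue used by the CLI, the test-bench and downstream scripts: given an
in-memory cohort bundle, compute each unit's outcome-aligned rate
matrix, its sliding-GLM contrast t-courses and the label-shuffled
permutation courses that feed the cluster statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import neural as neu
from .synth import CohortBundle

DEFAULT_CONTRASTS = ("observed_ev", "observed_amount", "observed_pe",
                     "self_ev", "self_amount")


@dataclass
class CohortGLMs:
    unit_ids: list
    glms: list            # per-unit GLMResult
    perms: list           # per-unit {contrast: (n_perm, n_bins)}
    rates: list           # per-unit RateMatrix
    trials: list          # per-unit host-session trial table
    learner_outputs: list
    times: np.ndarray


def cohort_unit_glms(
    bundle: CohortBundle,
    area: str | None = None,
    span: tuple[float, float] = neu.GLM_SPAN,
    psth_span: tuple[float, float] = neu.PSTH_SPAN,
    n_perm: int = 200,
    seed: int = 0,
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
) -> CohortGLMs:
    """Fit the sliding GLM (and its permutations) for every cohort unit."""
    rng = np.random.default_rng(seed)
    units = bundle.unit_table
    if area is not None:
        units = units[units["area"] == area]
    designs: dict = {}
    unit_ids, glms, perms, rates, trials, louts = [], [], [], [], [], []
    for row in units.itertuples(index=False):
        sess = bundle.sessions[row.session_id]
        lout = bundle.learner_outputs[row.session_id]
        if row.session_id not in designs:
            designs[row.session_id] = neu.build_design_matrix(sess.trials, lout)
        design = designs[row.session_id]
        st = bundle.spike_trains[row.unit_id]
        rm = neu.compute_psth(st.times, sess.trials["t_outcome"].to_numpy(),
                              span=psth_span, unit_id=row.unit_id)
        glms.append(neu.fit_sliding_glm(rm, design, span=span))
        if n_perm:
            perms.append(neu.permuted_contrast_tstats(
                rm, design, list(contrasts), n_perm, rng, span=span))
        unit_ids.append(row.unit_id)
        rates.append(rm)
        trials.append(sess.trials)
        louts.append(lout)
    return CohortGLMs(unit_ids=unit_ids, glms=glms, perms=perms, rates=rates,
                      trials=trials, learner_outputs=louts,
                      times=glms[0].times if glms else np.array([]))


def merged_behaviour_table(bundle: CohortBundle) -> pd.DataFrame:
    """Pool every session's trials + learner output into one tidy table."""
    from .behaviour import merge_learner
    parts = [merge_learner(sess.trials, bundle.learner_outputs[sid])
             for sid, sess in bundle.sessions.items()]
    return pd.concat(parts, ignore_index=True)
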