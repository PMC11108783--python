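"""End-to-end validation experiments on synthetic ground truth.

These harnesses quantify what the pipeline recovers from data whose truth
is known by construction: closed-loop truncation-factor recovery through
the full generate -> stream-detect -> intervene -> re-segment -> summarize
chain, and type-I / power calibration of the mixed model on table-level
simulations.

Problem sizes are package choices documented in the methods note: recovery
sessions are ~2,200 s at 500 Hz per animal and condition (about 55 seizures
each, >= 100 per animal), with a 20 s postictal minimum gap and a 15 s
trigger lockout so consecutive seizures remain independently triggerable.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import closedloop, intervention_stats, synthgen

RECOVERY_SESSION = dict(
    duration=2200.0,
    seizure_rate=1.0 / 25.0,
    seizure_min_gap=20.0,
)
RECOVERY_POLICY = dict(lockout=15.0)


def _session_config(base_seed: int, animal: int, light_on: bool) -> synthgen.GenConfig:
    seed = (base_seed * 9973 + animal * 101 + int(light_on)) % (2**31 - 1)
    return synthgen.GenConfig(seed=seed, **RECOVERY_SESSION)


def simulate_cohort(
    truncation_factor: float,
    base_seed: int,
    n_animals: int = 4,
    group: str = "opsin",
) -> pd.DataFrame:
    """One cohort: per animal, a light-on and a light-off session."""
    policy = closedloop.TriggerPolicy(**RECOVERY_POLICY)
    tables = []
    for a in range(n_animals):
        for light_on in (False, True):
            cfg = _session_config(base_seed, a, light_on)
            tab, _, _ = closedloop.run_closed_loop_session(
                cfg,
                policy=policy,
                stimulation=light_on,
                truncation_factor=truncation_factor,
                animal=f"m{a}",
                group=group,
            )
            tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def recovery_experiment(
    factors=(1.0, 0.75, 0.5),
    n_seeds: int = 20,
    n_animals: int = 4,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Truncation-factor recovery across replicate seed batches.

    For each factor and seed batch, runs a full cohort and summarizes the
    group normalized duration (mean +- s.e.m. across animals).  Returns one
    row per (factor, seed batch) with the summary and whether the
    generator truth (factor x 100%) lies within mean +- 2 s.e.m.
    """
    rows = []
    for factor in factors:
        for k in range(n_seeds):
            table = simulate_cohort(factor, base_seed + 1000 * k + 1,
                                    n_animals=n_animals)
            summ = intervention_stats.normalized_duration(table)
            truth_pct = 100.0 * factor
            rows.append(
                {
                    "factor": factor,
                    "seed_batch": k,
                    "mean_pct": summ.mean,
                    "sem_pct": summ.sem,
                    "n_animals": summ.n_animals,
                    "n_seizures": int(
                        table["duration_from_trigger"].count()
                    ),
                    "covers_truth": bool(
                        abs(summ.mean - truth_pct) <= 2.0 * summ.sem
                    ),
                }
            )
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame) -> dict:
    """Monotonicity and coverage summary of a recovery experiment."""
    by_factor = results.groupby("factor")["mean_pct"].mean().sort_index()
    return {
        "means_by_factor": by_factor.to_dict(),
        "monotone": bool(by_factor.is_monotonic_increasing),
        "coverage": float(results["covers_truth"].mean()),
    }


def type_one_error(
    n_replicates: int = 500,
    alpha: float = 0.05,
    n_animals: int = 4,
    n_per_condition: int = 100,
    seed: int = 0,
) -> float:
    """Mixed-model null rejection rate on table-level simulations."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        table = intervention_stats.simulate_duration_table(
            n_animals, n_per_condition, truncation_factor=1.0, rng=rng
        )
        res = intervention_stats.mixed_model_duration(table)
        rejections += res.p_value < alpha
    return rejections / n_replicates


def power_at_factor(
    truncation_factor: float = 0.5,
    n_replicates: int = 100,
    alpha: float = 0.01,
    n_animals: int = 4,
    n_per_condition: int = 100,
    seed: int = 1,
) -> float:
    """Mixed-model detection rate at a given truncation factor."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_replicates):
        table = intervention_stats.simulate_duration_table(
            n_animals, n_per_condition, truncation_factor, rng=rng
        )
        res = intervention_stats.mixed_model_duration(table)
        detected += res.p_value < alpha
    return detected / n_replicates
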