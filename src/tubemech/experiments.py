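"""Reference experiments: cohort-level parameter recovery.

The study's stiffness statistics come from unreleased recordings, so the
reproducible experiment is parameter recovery: generate cohorts whose truth
distribution is matched to the printed statistics, push the raw curves
through the full measurement pipeline, and pool the recovered statistics.

A single cohort of 19 tubes carries substantial between-tube Monte-Carlo
spread (the pooled loading mean has a standard error of ~0.4 N/m), so the
experiment averages over seed replicates and reports the replicate mean
with its standard error.
"""

from __future__ import annotations

import numpy as np

from .curves import cohort_statistics, process_cohort
from .presets import get_preset
from .synth import simulate_cohort


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def recover_group_statistics(
    seed: int,
    n_replicates: int = 20,
    groups: tuple[str, ...] = ("growing", "non_growing"),
) -> dict:
    """Pooled statistics recovered by the full pipeline, per group.

    For each replicate seed, a cohort at the printed group size is
    simulated in empirical mode and processed end to end; pooled
    per-indentation statistics are then averaged across replicates.

    Returns a flat mapping like ``{"growing_load_mean": {"value", "se",
    "n", "n_replicates"}, ...}`` where ``se`` is the between-replicate
    standard error of the reported average.
    """
    species = get_preset("lily").species
    per_stat: dict[str, list[float]] = {}
    m_used: dict[str, int] = {}
    for group in groups:
        for rep_seed in replicate_seeds(seed, n_replicates):
            curves, _ = simulate_cohort(species, group, seed=rep_seed)
            stats = cohort_statistics(process_cohort(curves), group)
            for phase_key, value in (
                ("load_mean", stats.load_mean),
                ("load_median", stats.load_median),
                ("unload_mean", stats.unload_mean),
                ("unload_median", stats.unload_median),
            ):
                per_stat.setdefault(f"{group}_{phase_key}", []).append(value)
            m_used[group] = stats.m_indentations
    out = {}
    for key, values in per_stat.items():
        arr = np.asarray(values)
        group = key.rsplit("_load", 1)[0].rsplit("_unload", 1)[0]
        out[key] = {
            "value": float(arr.mean()),
            "se": float(arr.std(ddof=1) / np.sqrt(arr.size)),
            "n": m_used[group],
            "n_replicates": int(arr.size),
        }
    return out
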