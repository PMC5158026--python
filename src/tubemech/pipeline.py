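"""End-to-end pipeline: process -> stats -> compare -> invert.

Given a cohort directory (curve TSVs + manifest) the pipeline produces,
deterministically for a fixed config:

* ``records.csv``    — one row per indentation (both phases, diagnostics)
* ``stats.csv``      — pooled per-group statistics
* ``comparison.json``— permutation test between the first two groups
* ``compatible_set.csv`` / ``inversion.json`` — moduli compatible with the
  first group's mean loading stiffness (optional)
* ``run.json``       — schema version, config hash, seeds, stage status

Any stage failure aborts with a stage-labeled error; ``run.json`` marks
which artifacts were completed.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as tio
from .config import RunConfig
from .curves import cohort_statistics, compare_groups, process_cohort
from .invert import compatible_set
from .synth import SCHEMA_VERSION

logger = logging.getLogger("tubemech")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, input_dir, output_dir) -> dict:
    """Run the full analysis on one cohort directory.

    Returns the run summary (also written to ``run.json``).
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"schema": SCHEMA_VERSION, "config_hash": chash, "seed": config.seed}
    summary: dict = {
        "schema": SCHEMA_VERSION,
        "config_hash": chash,
        "config": config.to_dict(),
        "input_dir": str(input_dir),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        summary["stages"][stage] = f"failed: {exc}"
        tio.write_json(summary, output_dir / "run.json")
        raise PipelineError(stage, exc)

    # -- load ---------------------------------------------------------------
    try:
        curves, manifest = tio.read_cohort(input_dir)
        if not curves:
            raise ValueError("cohort contains no curves")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("load", exc)
    summary["stages"]["load"] = f"ok: {len(curves)} curves"
    logger.info("loaded %d curves from %s", len(curves), input_dir)

    # -- process ------------------------------------------------------------
    try:
        records = process_cohort(
            curves,
            window_fraction=config.window_fraction,
            baseline_fraction=config.baseline_fraction,
            threshold_sd=config.contact_threshold_sd,
            min_run=config.contact_min_run,
        )
        tio.write_table(records, output_dir / "records.csv", meta)
    except Exception as exc:  # noqa: BLE001
        fail("process", exc)
    summary["stages"]["process"] = f"ok: {len(records)} records"

    # -- stats --------------------------------------------------------------
    try:
        groups = sorted(records["group"].unique())
        stats_rows = [cohort_statistics(records, g).to_dict() for g in groups]
        import pandas as pd

        tio.write_table(pd.DataFrame(stats_rows), output_dir / "stats.csv", meta)
    except Exception as exc:  # noqa: BLE001
        fail("stats", exc)
    summary["stages"]["stats"] = f"ok: groups {groups}"

    # -- compare ------------------------------------------------------------
    if len(groups) >= 2:
        try:
            a = records.loc[records["group"] == groups[0], "k_load_N_per_m"].to_numpy()
            b = records.loc[records["group"] == groups[1], "k_load_N_per_m"].to_numpy()
            comp = compare_groups(a, b, n_perm=config.n_perm, seed=config.seed)
            comp.update({"group_a": groups[0], "group_b": groups[1], **meta})
            tio.write_json(comp, output_dir / "comparison.json")
            summary["stages"]["compare"] = f"ok: p={comp['p_value']:.4g}"
        except Exception as exc:  # noqa: BLE001
            fail("compare", exc)
    else:
        summary["stages"]["compare"] = "skipped: single group"

    # -- invert -------------------------------------------------------------
    if config.run_inversion:
        try:
            target_stats = cohort_statistics(records, groups[0])
            cs = compatible_set(
                target_stats.load_mean,
                ranges=config.ranges(),
                tolerance=config.inversion_tolerance,
                nu=config.nu,
            )
            tio.write_table(cs.table, output_dir / "compatible_set.csv", meta)
            inv = cs.summary()
            inv.update({"group": groups[0], **meta})
            tio.write_json(inv, output_dir / "inversion.json")
            summary["stages"]["invert"] = (
                f"ok: {inv['n_compatible']} compatible combinations"
            )
        except Exception as exc:  # noqa: BLE001
            fail("invert", exc)
    else:
        summary["stages"]["invert"] = "skipped: disabled in config"

    tio.write_json(summary, output_dir / "run.json")
    return summary
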