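"""Force-curve processing and cohort statistics.

Turns raw stage-displacement/force recordings into true force-indentation
curves and apparent-stiffness records, then pools them into the group
statistics used to compare growing and non-growing tubes.

Processing steps, per curve:

1. :func:`detect_contact` — fit a baseline line to the early approach
   (removes the capillary background slope), then find the first sustained
   excursion of the detrended force above 5 baseline standard deviations
   and walk back to the contact point.
2. :func:`cancel_sensor` — remove the sensor's own deflection: the sample
   indentation is ``delta = (z - z0) - F / k_sensor`` (series spring), and
   the baseline line is subtracted from the force so the true
   force-indentation curve starts at zero.  Loading and unloading are split
   at the global force maximum.
3. :func:`apparent_stiffness` — ordinary least-squares slope of F against
   delta restricted to the maximum-load region (samples with
   ``F >= (1 - w) F_max``, default w = 0.2), per phase.

Statistics are pooled over indentations, not tube averages, matching the
convention in which a group is summarized by n tubes and m indentations
drawn from a single distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .synth import RawCurve


class NoContactError(ValueError):
    """No sustained force rise above baseline was found."""


class ProcessingError(ValueError):
    """A curve violates the assumptions of a processing step."""


@dataclass(frozen=True)
class ContactPoint:
    index: int
    z0: float
    baseline_intercept: float
    baseline_slope: float
    baseline_sd: float


@dataclass
class ProcessedCurve:
    """True force-indentation curve with phase bounds."""

    delta: np.ndarray  # µm, 0 at contact
    force: np.ndarray  # µN, baseline-corrected
    contact_index: int  # index into the raw curve
    i_max: int  # split point: global force maximum (into delta/force)
    meta: dict

    @property
    def loading(self) -> tuple[np.ndarray, np.ndarray]:
        return self.delta[: self.i_max + 1], self.force[: self.i_max + 1]

    @property
    def unloading(self) -> tuple[np.ndarray, np.ndarray]:
        return self.delta[self.i_max :], self.force[self.i_max :]


def detect_contact(
    curve: RawCurve,
    baseline_fraction: float = 0.2,
    threshold_sd: float = 5.0,
    min_run: int = 5,
) -> ContactPoint:
    """Locate the tip-sample contact on the approach segment.

    A line is fitted to the first ``baseline_fraction`` of the approach
    (stage moving up) to capture offset and capillary slope; contact is the
    first index from which the detrended force stays above
    ``threshold_sd`` baseline standard deviations for at least ``min_run``
    samples, walked back to where the force last sat within one standard
    deviation of the baseline.

    For very compliant samples the indentation depth can dominate the
    approach, so a fixed fraction of it would reach past the contact point
    and the "baseline" fit would swallow part of the force rise.  The
    detection therefore runs twice: a first pass with the window capped
    below a crude force-rise estimate, and a second pass with the baseline
    refitted strictly before the first-pass contact.  For curves whose
    20%-of-approach window is genuinely pre-contact this reduces to the
    plain single-pass rule.
    """
    z = curve.z_stage
    f = curve.force
    i_apex = int(np.argmax(z))
    n_base0 = int(baseline_fraction * (i_apex + 1))

    def one_pass(n_base: int) -> ContactPoint:
        if n_base < 20:
            raise ProcessingError(
                f"need >= 20 baseline samples, got {n_base}; curve too short"
            )
        coef = np.polyfit(z[:n_base], f[:n_base], 1)
        resid_base = f[:n_base] - np.polyval(coef, z[:n_base])
        sd = max(float(np.std(resid_base)), 1e-12)  # guard: noiseless curves
        det = f[: i_apex + 1] - np.polyval(coef, z[: i_apex + 1])
        above = det > threshold_sd * sd
        run = 0
        start = None
        for i in range(n_base, i_apex + 1):
            run = run + 1 if above[i] else 0
            if run >= min_run:
                start = i - min_run + 1
                break
        if start is None:
            raise NoContactError("no sustained force rise above baseline found")
        i0 = start
        while i0 > 0 and det[i0 - 1] > sd:
            i0 -= 1
        # refine: fit a line to the early force rise and intersect it with
        # the baseline; a single-sample walk-back is noise-limited, the
        # fitted crossing is not
        hi = min(start + 4 * min_run, i_apex + 1)
        rise = np.polyfit(z[i0:hi], det[i0:hi], 1)
        if rise[0] > 0:
            z0 = -rise[1] / rise[0]
            z0 = float(np.clip(z0, z[max(i0 - min_run, 0)], z[start]))
            i0 = int(np.searchsorted(z[: i_apex + 1], z0))
        else:
            z0 = float(z[i0])
        return ContactPoint(
            index=i0,
            z0=z0,
            baseline_intercept=float(coef[1]),
            baseline_slope=float(coef[0]),
            baseline_sd=sd,
        )

    # crude cap: first sustained excursion above 2% of the force range
    n_base = n_base0
    f_range = float(np.max(f[: i_apex + 1]) - np.min(f[: i_apex + 1]))
    rough = f[: i_apex + 1] > np.min(f[: i_apex + 1]) + 0.02 * f_range
    run = 0
    for i in range(i_apex + 1):
        run = run + 1 if rough[i] else 0
        if run >= min_run:
            n_base = min(n_base, int(0.9 * (i - min_run + 1)))
            break
    if n_base < 20 <= n_base0:
        # the crude cap fired on what is probably noise (no real rise that
        # early); fall back to the plain window
        n_base = n_base0
    first = one_pass(n_base)
    n_refit = min(n_base0, first.index - min_run)
    if n_refit >= 20 and n_refit != n_base:
        return one_pass(n_refit)
    return first


def cancel_sensor(
    curve: RawCurve,
    contact: ContactPoint,
    k_sensor: float,
) -> ProcessedCurve:
    """Cancel the series sensor compliance to get the true F(delta) curve.

    ``k_sensor = inf`` is the rigid-sensor identity correction.  A warning
    flag is set in the metadata when more than 10% of post-contact samples
    end up at negative indentation — symptomatic of a wrong sensor
    stiffness or contact point.
    """
    if not k_sensor > 0:
        raise ValueError("k_sensor must be positive (use np.inf for rigid)")
    z = curve.z_stage[contact.index :]
    f = curve.force[contact.index :]
    f_corr = f - (contact.baseline_intercept + contact.baseline_slope * z)
    delta = (z - contact.z0) - (f_corr / k_sensor if np.isfinite(k_sensor) else 0.0)
    i_max = int(np.argmax(f_corr))
    meta = dict(curve.meta)
    frac_neg = float(np.mean(delta[: i_max + 1] < 0))
    meta["negative_delta_fraction"] = frac_neg
    meta["suspect_correction"] = frac_neg > 0.10
    return ProcessedCurve(
        delta=delta, force=f_corr, contact_index=contact.index, i_max=i_max, meta=meta
    )


def apparent_stiffness(
    delta: np.ndarray,
    force: np.ndarray,
    window_fraction: float = 0.2,
    min_samples: int = 10,
) -> tuple[float, float, int]:
    """OLS slope (N/m) of force vs indentation in the maximum-load window.

    Uses the samples with ``F >= (1 - w) * F_max``.  Returns
    ``(k, r_squared, n_used)``.
    """
    if not 0 < window_fraction < 1:
        raise ValueError("window_fraction must lie in (0, 1)")
    f_max = float(np.max(force))
    mask = force >= (1.0 - window_fraction) * f_max
    n_used = int(np.sum(mask))
    if n_used < min_samples:
        raise ProcessingError(
            f"only {n_used} samples in the maximum-load window (need {min_samples})"
        )
    x, y = delta[mask], force[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), min(max(r2, 0.0), 1.0), n_used


def process_curve(
    curve: RawCurve,
    k_sensor: float | None = None,
    window_fraction: float = 0.2,
    **detect_kwargs,
) -> dict:
    """Full per-curve pipeline: contact, sensor cancellation, both slopes.

    ``k_sensor`` defaults to the value recorded in the curve metadata.
    Returns a flat record dictionary (one row of the records table).
    """
    if k_sensor is None:
        k_sensor = curve.meta.get("k_sensor_N_per_m")
        if k_sensor is None:
            raise ValueError("k_sensor not given and absent from curve metadata")
    contact = detect_contact(curve, **detect_kwargs)
    proc = cancel_sensor(curve, contact, k_sensor)
    d_l, f_l = proc.loading
    d_u, f_u = proc.unloading
    k_load, r2_load, n_l = apparent_stiffness(d_l, f_l, window_fraction)
    k_unload, r2_unload, n_u = apparent_stiffness(d_u, f_u, window_fraction)
    return {
        "curve_id": curve.meta.get("curve_id", ""),
        "tube_id": curve.meta.get("tube_id", ""),
        "group": curve.meta.get("group", ""),
        "distance_from_tip_um": curve.meta.get("distance_from_tip_um", np.nan),
        "k_load_N_per_m": k_load,
        "k_unload_N_per_m": k_unload,
        "r2_load": r2_load,
        "r2_unload": r2_unload,
        "n_window_load": n_l,
        "n_window_unload": n_u,
        "window_fraction": window_fraction,
        "z0_um": contact.z0,
        "suspect_correction": proc.meta["suspect_correction"],
    }


def process_cohort(
    curves: list[RawCurve],
    k_sensor: float | None = None,
    window_fraction: float = 0.2,
    **detect_kwargs,
) -> pd.DataFrame:
    """Process every curve of a cohort into a records table."""
    if not curves:
        raise ValueError("no curves to process")
    rows = [
        process_curve(c, k_sensor=k_sensor, window_fraction=window_fraction,
                      **detect_kwargs)
        for c in curves
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortStats:
    """Pooled per-indentation statistics of one group."""

    group: str
    n_tubes: int
    m_indentations: int
    load_mean: float
    load_median: float
    load_sd: float
    unload_mean: float
    unload_median: float
    unload_sd: float

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_tubes": self.n_tubes,
            "m_indentations": self.m_indentations,
            "load_mean_N_per_m": self.load_mean,
            "load_median_N_per_m": self.load_median,
            "load_sd_N_per_m": self.load_sd,
            "unload_mean_N_per_m": self.unload_mean,
            "unload_median_N_per_m": self.unload_median,
            "unload_sd_N_per_m": self.unload_sd,
        }


def cohort_statistics(records: pd.DataFrame, group: str | None = None) -> CohortStats:
    """Pooled mean/median/sd per phase over indentations.

    Pooling is over indentations (each record weighs equally), not over
    per-tube averages.  Requires at least two records.
    """
    df = records if group is None else records[records["group"] == group]
    if len(df) == 0:
        raise ValueError(f"no records for group {group!r}")
    if len(df) < 2:
        raise ValueError("cohort statistics need at least 2 records")
    kl = df["k_load_N_per_m"].to_numpy()
    ku = df["k_unload_N_per_m"].to_numpy()
    return CohortStats(
        group=group if group is not None else "all",
        n_tubes=int(df["tube_id"].nunique()),
        m_indentations=int(len(df)),
        load_mean=float(np.mean(kl)),
        load_median=float(np.median(kl)),
        load_sd=float(np.std(kl, ddof=1)),
        unload_mean=float(np.mean(ku)),
        unload_median=float(np.median(ku)),
        unload_sd=float(np.std(ku, ddof=1)),
    )


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 9999,
    seed=0,
) -> dict:
    """Two-sided permutation test for a difference in group means.

    Labels are shuffled at the indentation level; the p-value uses the
    add-one correction ``(b + 1) / (n_perm + 1)``.  A permutation test is
    used (rather than a t-test) because the stiffness distributions are
    right-skewed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = float(np.mean(a) - np.mean(b))
    pooled = np.concatenate([a, b])
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = np.mean(perm[:n_a]) - np.mean(perm[n_a:])
        if abs(d) >= abs(observed) - 1e-15:
            count += 1
    return {
        "difference_of_means": observed,
        "p_value": (count + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "n_a": int(n_a),
        "n_b": int(b.size),
    }


def apex_profile(
    records: pd.DataFrame,
    bin_width: float = 2.0,
    column: str = "k_unload_N_per_m",
) -> tuple[pd.DataFrame, dict]:
    """Apparent stiffness binned by distance from the tube tip.

    Profiles the unloading stiffness by default (the phase used for the
    apex-gradient figure).  Returns the binned table (distance bin center,
    mean, sd, n) and a trend report: Spearman rho of bin means against
    distance with its p-value.  Needs at least two populated bins.
    """
    if "distance_from_tip_um" not in records:
        raise ValueError("records lack distance_from_tip_um")
    d = records["distance_from_tip_um"].to_numpy(dtype=float)
    k = records[column].to_numpy(dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    idx = np.digitize(d, edges) - 1
    rows = []
    for i in range(len(edges) - 1):
        sel = idx == i
        if not np.any(sel):
            continue
        rows.append(
            {
                "distance_um": 0.5 * (edges[i] + edges[i + 1]),
                "k_mean_N_per_m": float(np.mean(k[sel])),
                "k_sd_N_per_m": float(np.std(k[sel], ddof=1)) if sel.sum() > 1 else np.nan,
                "n": int(sel.sum()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("all records fall into a single distance bin")
    rho, p = spearmanr(table["distance_um"], table["k_mean_N_per_m"])
    trend = {"spearman_rho": float(rho), "p_value": float(p), "n_bins": int(len(table))}
    return table, trend
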