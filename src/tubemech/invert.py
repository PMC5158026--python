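"""Inverse estimation of the cell-wall Young's modulus.

A single measured apparent stiffness does not pin down the wall modulus:
turgor, wall thickness and tube diameter all feed into the indentation
response.  This module quantifies that degeneracy.  :func:`invert_E` finds
the unique modulus reproducing a target stiffness at fixed (t, p, d) — the
forward model is strictly increasing in E, so the root is unique —
and :func:`compatible_set` sweeps a physiological parameter box to collect
every (E, t, p, d) combination whose modeled stiffness matches the target,
reporting the implied modulus range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .shell import ShellProblem, stiffness_fourier


@dataclass(frozen=True)
class ParamRanges:
    """Physiological parameter box for the inversion sweep.

    Ranges follow the lily pollen-tube literature: wall thickness
    0.1–0.3 µm, turgor 0.1–0.4 MPa, diameter mean ± 2 sd (12.4–22.4 µm).
    ``E_bracket`` is the search interval for the modulus root.
    """

    t_range: tuple[float, float] = (0.1, 0.3)
    p_range: tuple[float, float] = (0.1, 0.4)
    d_range: tuple[float, float] = (12.4, 22.4)
    E_bracket: tuple[float, float] = (1.0, 1000.0)
    n_t: int = 10
    n_p: int = 10
    n_d: int = 10

    def __post_init__(self) -> None:
        for name in ("t_range", "p_range", "d_range", "E_bracket"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy min < max, got ({lo}, {hi})")
        if min(self.n_t, self.n_p, self.n_d) < 1:
            raise ValueError("grid counts must be >= 1")

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        def axis(rng: tuple[float, float], n: int) -> np.ndarray:
            if n == 1:
                return np.array([0.5 * (rng[0] + rng[1])])
            return np.linspace(rng[0], rng[1], n)

        return (
            axis(self.t_range, self.n_t),
            axis(self.p_range, self.n_p),
            axis(self.d_range, self.n_d),
        )


@dataclass(frozen=True)
class InversionResult:
    """Outcome of a single modulus inversion at fixed (t, p, d)."""

    E: float | None
    status: str  # "ok" | "below_range" | "above_range"
    k_lo: float
    k_hi: float


def _forward_k(E: float, t: float, p: float, d: float, **shell_kwargs) -> float:
    prob = ShellProblem.from_tube(d, t, p, E, **shell_kwargs)
    return stiffness_fourier(prob).k_model


def invert_E(
    k_target: float,
    t: float,
    p: float,
    d: float,
    bracket: tuple[float, float] = (1.0, 1000.0),
    rtol: float = 1.0e-4,
    **shell_kwargs,
) -> InversionResult:
    """Solve ``k_model(E) = k_target`` for the modulus at fixed (t, p, d).

    Because ``k_model`` is continuous and strictly increasing in E, the
    bracketing root is unique; it is located by Brent's method to relative
    tolerance ``rtol``.  When the target lies outside the attainable
    stiffness interval ``[k(E_lo), k(E_hi)]`` no exception is raised: the
    geometry is reported as incompatible via ``status`` (a high-turgor thin
    tube can be stiffer than the target at any modulus).
    """
    if k_target <= 0:
        raise ValueError("k_target must be positive")
    e_lo, e_hi = bracket
    k_lo = _forward_k(e_lo, t, p, d, **shell_kwargs)
    k_hi = _forward_k(e_hi, t, p, d, **shell_kwargs)
    if k_target < k_lo:
        return InversionResult(None, "below_range", k_lo, k_hi)
    if k_target > k_hi:
        return InversionResult(None, "above_range", k_lo, k_hi)
    root = brentq(
        lambda E: _forward_k(E, t, p, d, **shell_kwargs) - k_target,
        e_lo,
        e_hi,
        rtol=rtol,
    )
    return InversionResult(float(root), "ok", k_lo, k_hi)


@dataclass
class CompatibleSet:
    """Grid of parameter combinations matching a stiffness target.

    ``table`` has one row per compatible (E, t, p, d) with the modeled
    stiffness; every row satisfies ``|k_model - k_target| <=
    tolerance * k_target``.  ``diagnostics`` counts grid cells whose
    attainable stiffness interval misses the target entirely.
    """

    k_target: float
    tolerance: float
    table: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.table.empty

    @property
    def E_min(self) -> float:
        if self.empty:
            raise ValueError("compatible set is empty")
        return float(self.table["E_MPa"].min())

    @property
    def E_max(self) -> float:
        if self.empty:
            raise ValueError("compatible set is empty")
        return float(self.table["E_MPa"].max())

    def summary(self) -> dict:
        out = {
            "k_target_N_per_m": self.k_target,
            "tolerance": self.tolerance,
            "n_compatible": int(len(self.table)),
            "diagnostics": self.diagnostics,
        }
        if not self.empty:
            out["E_min_MPa"] = self.E_min
            out["E_max_MPa"] = self.E_max
            out["E_spread_ratio"] = self.E_max / self.E_min
        return out


def compatible_set(
    k_target: float,
    ranges: ParamRanges | None = None,
    tolerance: float = 0.10,
    **shell_kwargs,
) -> CompatibleSet:
    """Sweep the parameter box and collect stiffness-compatible moduli.

    For every (t, p, d) grid point an exact inversion is attempted; when
    the target is outside the attainable range but a bracket endpoint still
    matches within ``tolerance`` (relative), the endpoint modulus is kept —
    the invariant that every row matches the target within tolerance is
    preserved either way.
    """
    ranges = ranges or ParamRanges()
    t_axis, p_axis, d_axis = ranges.grid()
    rows = []
    n_below = n_above = 0
    # diameter outermost: the cached Fourier mode geometry depends only on
    # the tube geometry, so this order reuses it across the whole (t, p) face
    for d in d_axis:
        for t in t_axis:
            for p in p_axis:
                res = invert_E(
                    k_target, t, p, d, bracket=ranges.E_bracket, **shell_kwargs
                )
                if res.status == "ok":
                    rows.append(
                        {"E_MPa": res.E, "t_um": t, "p_MPa": p, "d_um": d,
                         "k_model_N_per_m": k_target}
                    )
                    continue
                if res.status == "below_range":
                    n_below += 1
                    k_edge, e_edge = res.k_lo, ranges.E_bracket[0]
                else:
                    n_above += 1
                    k_edge, e_edge = res.k_hi, ranges.E_bracket[1]
                if abs(k_edge - k_target) <= tolerance * k_target:
                    rows.append(
                        {"E_MPa": e_edge, "t_um": t, "p_MPa": p, "d_um": d,
                         "k_model_N_per_m": k_edge}
                    )
    table = pd.DataFrame(
        rows, columns=["E_MPa", "t_um", "p_MPa", "d_um", "k_model_N_per_m"]
    )
    diag = {
        "n_grid": int(t_axis.size * p_axis.size * d_axis.size),
        "n_below_range": n_below,
        "n_above_range": n_above,
    }
    return CompatibleSet(k_target, tolerance, table, diag)


def stiffness_to_modulus_report(
    stats,
    ranges: ParamRanges | None = None,
    tolerance: float = 0.10,
    **shell_kwargs,
) -> dict:
    """Modulus-compatibility report at a cohort's mean and median stiffness.

    ``stats`` is a :class:`tubemech.curves.CohortStats` (or any object with
    ``load_mean`` and ``load_median`` attributes); only the loading phase
    is inverted.  The report deliberately carries the caveat that a
    single-value modulus attribution is unsupported: the same stiffness is
    produced by an order-of-magnitude range of moduli across the
    physiological box.
    """
    ranges = ranges or ParamRanges()
    report: dict = {
        "caveat": (
            "A single-value Young's modulus attribution is unsupported: "
            "within physiological variability of wall thickness, turgor and "
            "diameter, widely different moduli reproduce the same apparent "
            "stiffness. Report the compatible range, not a point estimate."
        ),
        "ranges": {
            "t_um": ranges.t_range,
            "p_MPa": ranges.p_range,
            "d_um": ranges.d_range,
            "E_bracket_MPa": ranges.E_bracket,
        },
    }
    for label, k_val in (("at_mean", stats.load_mean), ("at_median", stats.load_median)):
        if k_val is None or not np.isfinite(k_val):
            report[label] = {"skipped": "statistic unavailable"}
            continue
        cs = compatible_set(k_val, ranges=ranges, tolerance=tolerance, **shell_kwargs)
        sub = cs.summary()
        if not cs.empty:
            # per-parameter sensitivity: modulus span along each axis
            sens = {}
            for col, name in (("t_um", "t"), ("p_MPa", "p"), ("d_um", "d")):
                grouped = cs.table.groupby(col)["E_MPa"].mean()
                sens[name] = {
                    "E_at_min": float(grouped.iloc[0]),
                    "E_at_max": float(grouped.iloc[-1]),
                }
            sub["sensitivity"] = sens
        report[label] = sub
    return report
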