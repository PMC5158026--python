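"""Synthetic CFM cohorts: virtual pollen tubes and raw force-displacement curves.

The study's raw micro-indentation recordings are not public, so this module
generates cohorts with a known answer key.  Two truth modes are supported:

empirical
    Per-tube apparent-stiffness pairs (loading, unloading) are drawn from a
    bivariate lognormal whose loading marginal is matched exactly to the
    printed group statistics (mean and median fix the two lognormal
    parameters) and whose unloading marginal is the pointwise maximum of
    the loading value and a correlated lognormal, with its location
    parameter calibrated in closed form so the unloading mean matches the
    printed value.  The maximum enforces the observed hysteresis direction
    (unloading at least as stiff as loading) for every tube.

mechanistic
    Truth stiffness is computed from the pressurized thin-shell forward
    model at a prescribed wall modulus, so pipeline + inversion can be
    checked for modulus recovery.

Raw curves emulate the CFM protocol: constant-speed stage ramp to a 5 µN
maximum load and back, a series force sensor (the stage displacement is
sample indentation plus sensor deflection F/k_sensor), a weak capillary
background slope, additive Gaussian force noise, and a mild loading
nonlinearity.  The truth stiffness is defined as the apparent stiffness a
downstream fit would read in the maximum-load window; the generator
rescales the curve's linear coefficient by the closed-form window factor
so that definition holds for any curvature setting (and reduces to an
exactly linear ramp at ``beta = 0``).

Units: µm, µN, MPa, N/m, seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .layout import GrainSpec


class UnreachableForceError(RuntimeError):
    """The protocol's maximum force cannot be reached within stage travel."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesParams:
    """Tube-geometry distribution for one species."""

    label: str
    tube_diameter_mean: float  # µm
    tube_diameter_sd: float  # µm
    grain: GrainSpec | None = None

    def __post_init__(self) -> None:
        if self.tube_diameter_sd < 0:
            raise ValueError("tube_diameter_sd must be >= 0")
        if self.tube_diameter_sd > 0 and not (
            self.tube_diameter_mean > 3 * self.tube_diameter_sd
        ):
            raise ValueError("require mean > 3 sd so truncation at 0 is negligible")


@dataclass(frozen=True)
class GroupStiffnessStats:
    """Printed apparent-stiffness statistics of one tube group (N/m).

    Medians may be None (the non-growing group is printed as means only);
    the missing log-scale spread is then reused from a reference group.
    """

    label: str
    load_mean: float
    load_median: float | None
    unload_mean: float
    unload_median: float | None
    n_tubes: int
    m_indent: int


#: Growing-tube shank statistics: n = 19 tubes, m = 135 indentations.
GROWING = GroupStiffnessStats("growing", 2.20, 1.73, 3.28, 2.98, 19, 135)
#: Naturally growth-arrested tubes: n = 11 tubes, m = 71 indentations.
NON_GROWING = GroupStiffnessStats("non_growing", 0.69, None, 1.67, None, 11, 71)

_GROUPS = {g.label: g for g in (GROWING, NON_GROWING)}


def group_stats(label: str) -> GroupStiffnessStats:
    try:
        return _GROUPS[label]
    except KeyError:
        raise KeyError(f"unknown group {label!r}; known: {sorted(_GROUPS)}") from None


@dataclass(frozen=True)
class TubeSample:
    """One virtual tube with its hidden truth."""

    id: str
    diameter: float  # µm
    wall_thickness: float  # µm
    turgor: float  # MPa
    growing: bool
    k_load_true: float  # N/m, apparent stiffness in the max-load window
    k_unload_true: float  # N/m
    E_true: float | None = None  # MPa, mechanistic mode only

    def __post_init__(self) -> None:
        for name in ("diameter", "wall_thickness", "turgor", "k_load_true",
                     "k_unload_true"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k_unload_true < self.k_load_true * (1 - 1e-12):
            raise ValueError("hysteresis direction requires k_unload >= k_load")


@dataclass(frozen=True)
class SensorSpec:
    """Force-sensor characteristics of the virtual CFM."""

    k_sensor: float = 10.0  # N/m
    force_noise_sd_nN: float = 10.0
    capillary_slope: float = 0.0173  # N/m; ~1% of the growing median stiffness

    def __post_init__(self) -> None:
        if self.k_sensor <= 0:
            raise ValueError("k_sensor must be positive")
        if self.force_noise_sd_nN < 0 or self.capillary_slope < 0:
            raise ValueError("noise and capillary slope must be >= 0")

    @property
    def force_noise_sd_uN(self) -> float:
        return self.force_noise_sd_nN * 1e-3


@dataclass(frozen=True)
class IndentationProtocol:
    """Stage-drive protocol of one indentation."""

    max_force: float = 5.0  # µN
    speed: float = 2.0  # µm/s
    sample_rate: float = 500.0  # Hz
    tip_diameter_nm: float = 800.0
    max_travel: float = 100.0  # µm piezo-stage range

    def __post_init__(self) -> None:
        if min(self.max_force, self.speed, self.sample_rate,
               self.tip_diameter_nm, self.max_travel) <= 0:
            raise ValueError("all protocol fields must be positive")

    @property
    def tip_radius_um(self) -> float:
        return self.tip_diameter_nm * 1e-3 / 2.0


@dataclass
class RawCurve:
    """One raw indentation recording (what the instrument would log)."""

    time: np.ndarray  # s
    z_stage: np.ndarray  # µm, monotone up then down
    force: np.ndarray  # µN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if n < 50:
            raise ValueError("curve must have at least 50 samples")
        if len(self.z_stage) != n or len(self.force) != n:
            raise ValueError("time, z_stage and force must have equal length")


# ---------------------------------------------------------------------------
# Truth distributions
# ---------------------------------------------------------------------------


def empirical_truth_params(mean: float, median: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) with the given mean and median.

    ``exp(mu) = median`` and ``exp(mu + sigma^2/2) = mean`` give
    ``sigma^2 = 2 ln(mean / median)``; the solution exists iff
    ``mean >= median > 0`` and is unique.
    """
    if not median > 0:
        raise ValueError("median must be positive")
    if mean < median:
        raise ValueError("no lognormal has mean < median")
    return math.log(median), math.sqrt(2.0 * math.log(mean / median))


def _lognormal_max_mean(
    mu_x: float, s_x: float, mu_y: float, s_y: float, rho: float
) -> float:
    """E[max(X, Y)] for jointly lognormal X, Y (Gaussian copula ``rho``)."""
    ex = math.exp(mu_x + s_x**2 / 2.0)
    ey = math.exp(mu_y + s_y**2 / 2.0)
    var_d = s_x**2 + s_y**2 - 2.0 * rho * s_x * s_y
    mu_d = mu_x - mu_y
    if var_d <= 1e-24:
        return ex if mu_d > 0 else ey
    s_d = math.sqrt(var_d)
    d_x = (mu_d + s_x**2 - rho * s_x * s_y) / s_d
    d_y = (mu_d + rho * s_x * s_y - s_y**2) / s_d
    return ey + ex * norm.cdf(d_x) - ey * norm.cdf(d_y)


@dataclass(frozen=True)
class TruthParams:
    """Log-scale parameters of the per-tube truth sampler."""

    mu_load: float
    sigma_load: float
    mu_unload: float  # location of the pre-maximum unloading draw
    sigma_unload: float
    rho: float


def truth_params_for_group(
    stats: GroupStiffnessStats,
    rho: float = 0.8,
    reference: GroupStiffnessStats = GROWING,
) -> TruthParams:
    """Resolve sampler parameters from printed group statistics.

    Groups printed without medians reuse the reference group's log-scale
    sigma per phase, with ``mu = ln(mean) - sigma^2 / 2``.  The unloading
    location is then calibrated (closed-form mean of the bivariate
    lognormal maximum + root finding) so that the mean of
    ``max(k_load, k_unload')`` equals the printed unloading mean exactly.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if stats.load_median is not None:
        mu_l, s_l = empirical_truth_params(stats.load_mean, stats.load_median)
    else:
        _, s_l = empirical_truth_params(reference.load_mean, reference.load_median)
        mu_l = math.log(stats.load_mean) - s_l**2 / 2.0
    if stats.unload_median is not None:
        mu_u0, s_u = empirical_truth_params(stats.unload_mean, stats.unload_median)
    else:
        _, s_u = empirical_truth_params(reference.unload_mean, reference.unload_median)
        mu_u0 = math.log(stats.unload_mean) - s_u**2 / 2.0

    if s_l == 0.0 and s_u == 0.0:
        # degenerate point masses; the max is deterministic
        mu_u = math.log(max(stats.unload_mean, 1e-300))
        return TruthParams(mu_l, s_l, mu_u, s_u, rho)

    target = stats.unload_mean

    def gap(mu_u: float) -> float:
        return _lognormal_max_mean(mu_l, s_l, mu_u, s_u, rho) - target

    lo, hi = mu_u0 - 3.0, mu_u0 + 1.0
    if gap(lo) > 0:
        # even a tiny unloading draw leaves E[max] >= target: the clip at
        # k_load already exceeds the printed unloading mean
        raise ValueError(
            "unloading mean below what the loading marginal alone implies"
        )
    mu_u = brentq(gap, lo, hi, xtol=1e-12)
    return TruthParams(mu_l, s_l, float(mu_u), s_u, rho)


def sample_truth_pairs(
    params: TruthParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (k_load, k_unload) truth pairs; unloading >= loading always."""
    z1 = rng.standard_normal(n)
    z2 = params.rho * z1 + math.sqrt(1.0 - params.rho**2) * rng.standard_normal(n)
    k_load = np.exp(params.mu_load + params.sigma_load * z1)
    k_un = np.exp(params.mu_unload + params.sigma_unload * z2)
    return k_load, np.maximum(k_load, k_un)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_cohort(
    species: SpeciesParams,
    n_tubes: int,
    ranges=None,
    mode: str = "empirical",
    seed=0,
    group: str = "growing",
    stats: GroupStiffnessStats | None = None,
    rho: float = 0.8,
    E_true: float | None = None,
    hysteresis_ratio: float | None = None,
    nu: float = 0.3,
) -> list[TubeSample]:
    """Draw a cohort of virtual tubes with known truth.

    Diameters are i.i.d. truncated-normal (truncated at zero) with the
    species mean/sd; wall thickness and turgor are uniform over the
    configured physiological ranges (``ranges`` is a
    :class:`tubemech.invert.ParamRanges`; its t and p intervals are used).
    Truth stiffness follows ``mode``: "empirical" (group statistics) or
    "mechanistic" (shell forward model at ``E_true``, with the unloading
    value a fixed multiple of loading; default multiple is the ratio of
    the printed growing means, 3.28/2.20).
    """
    if n_tubes < 1:
        raise ValueError("n_tubes must be >= 1")
    if mode not in ("empirical", "mechanistic"):
        raise ValueError("mode must be 'empirical' or 'mechanistic'")
    from .invert import ParamRanges  # local import to avoid cycles at import time

    ranges = ranges or ParamRanges()
    rng = _as_rng(seed)

    m, sd = species.tube_diameter_mean, species.tube_diameter_sd
    if sd == 0:
        diam = np.full(n_tubes, m)
    else:
        diam = truncnorm.rvs((0 - m) / sd, np.inf, loc=m, scale=sd,
                             size=n_tubes, random_state=rng)
    t_lo, t_hi = ranges.t_range
    p_lo, p_hi = ranges.p_range
    thick = rng.uniform(t_lo, t_hi, n_tubes)
    turgor = rng.uniform(p_lo, p_hi, n_tubes)

    growing = group == "growing"
    if mode == "empirical":
        stats = stats or group_stats(group)
        tp = truth_params_for_group(stats, rho=rho)
        k_load, k_unload = sample_truth_pairs(tp, n_tubes, rng)
        e_true = [None] * n_tubes
    else:
        if E_true is None:
            raise ValueError("mechanistic mode requires E_true (MPa)")
        from .shell import ShellProblem, stiffness_fourier

        ratio = (
            hysteresis_ratio
            if hysteresis_ratio is not None
            else GROWING.unload_mean / GROWING.load_mean
        )
        k_load = np.array(
            [
                stiffness_fourier(
                    ShellProblem.from_tube(d, t, p, E_true, nu=nu)
                ).k_model
                for d, t, p in zip(diam, thick, turgor)
            ]
        )
        k_unload = ratio * k_load
        e_true = [E_true] * n_tubes

    prefix = "g" if growing else "n"
    return [
        TubeSample(
            id=f"{prefix}{i:03d}",
            diameter=float(diam[i]),
            wall_thickness=float(thick[i]),
            turgor=float(turgor[i]),
            growing=growing,
            k_load_true=float(k_load[i]),
            k_unload_true=float(k_unload[i]),
            E_true=e_true[i],
        )
        for i in range(n_tubes)
    ]


def apex_attenuation(distance_from_tip, tube_radius: float):
    """Contact-angle attenuation of the axial reaction near the apical dome.

    On the hemispherical apex the indentation axis meets the wall at an
    angle; only the cos^2 projection of the reaction acts along the sensor
    axis.  With ``cos(phi) = min(distance / R, 1)`` the factor is
    ``(distance / R)^2`` on the dome and 1 on the shank.
    """
    if tube_radius <= 0:
        raise ValueError("tube_radius must be positive")
    d = np.asarray(distance_from_tip, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_from_tip must be >= 0")
    out = np.minimum(d / tube_radius, 1.0) ** 2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Curve synthesis
# ---------------------------------------------------------------------------


def window_slope_factor(beta: float, window_fraction: float, phase: str) -> float:
    """Ratio of the top-window OLS slope to the curve's linear coefficient.

    For the quadratic force law ``F = k_e d (1 + beta d / d_max)`` the
    least-squares slope over the force window ``F >= (1 - w) F_max`` is
    ``k_e (1 + beta (1 + x))`` on loading and ``k_e (1 + beta x_u)`` on
    unloading, with x, x_u the window-edge roots.  The generator divides
    truth by this factor so the windowed slope equals truth.
    """
    if phase not in ("load", "unload"):
        raise ValueError("phase must be 'load' or 'unload'")
    w = window_fraction
    if not 0 < w < 1:
        raise ValueError("window_fraction must lie in (0, 1)")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return 1.0
    if phase == "load":
        x = (-1.0 + math.sqrt(1.0 + 4.0 * beta * (1.0 - w) * (1.0 + beta))) / (2.0 * beta)
        return 1.0 + beta * (1.0 + x)
    x_u = (-1.0 + math.sqrt(1.0 + 4.0 * beta * w * (1.0 + beta))) / (2.0 * beta)
    return 1.0 + beta * x_u


def _solve_quadratic_monotone(a2: float, a1: float, rhs: np.ndarray) -> np.ndarray:
    """Positive root of ``a2 x^2 + a1 x = rhs`` (a2 >= 0, a1 > 0, rhs >= 0)."""
    rhs = np.maximum(rhs, 0.0)
    if a2 == 0.0:
        return rhs / a1
    return (-a1 + np.sqrt(a1 * a1 + 4.0 * a2 * rhs)) / (2.0 * a2)


def synthesize_curve(
    tube: TubeSample,
    sensor: SensorSpec,
    protocol: IndentationProtocol,
    contact_offset: float,
    seed=0,
    distance_from_tip: float = 100.0,
    beta: float = 0.1,
    cal_window: float = 0.2,
    attenuation: bool = True,
) -> RawCurve:
    """Generate one raw stage-displacement/force recording.

    The stage advances at constant speed from z = 0; the tip meets the
    sample at ``z = contact_offset``.  In contact the sample force follows
    the quadratic law around the truth stiffness (see module docstring),
    the stage displacement is indentation plus sensor deflection
    ``F / k_sensor`` (series spring), a capillary background
    ``capillary_slope * z`` and Gaussian force noise are added, and the
    ramp reverses when the noiseless measured force reaches the protocol
    maximum.  Unloading follows the analogous quadratic at the unloading
    truth stiffness, leaving a residual indentation at pull-off.

    Raises
    ------
    UnreachableForceError
        If the maximum force is not reached within the stage travel.
    """
    if contact_offset <= 0:
        raise ValueError("contact_offset must be positive")
    rng = _as_rng(seed)
    att = apex_attenuation(distance_from_tip, tube.diameter / 2.0) if attenuation else 1.0
    if att <= 0:
        raise ValueError("attenuation factor is zero at the exact apex; "
                         "use a positive distance_from_tip")
    k_l = tube.k_load_true * att
    k_u = tube.k_unload_true * att
    ks = sensor.k_sensor
    c = sensor.capillary_slope
    f_max = protocol.max_force
    z0 = contact_offset

    k_le = k_l / window_slope_factor(beta, cal_window, "load")
    d_l = f_max / (k_le * (1.0 + beta))  # indentation where F_contact = f_max

    a2_l = k_le * beta / (d_l * ks) if beta > 0 else 0.0
    a1_l = 1.0 + k_le / ks

    def f_contact_load(delta):
        return k_le * delta * (1.0 + beta * delta / d_l)

    def measured_load(z):
        delta = _solve_quadratic_monotone(a2_l, a1_l, z - z0)
        return f_contact_load(delta) + c * z

    z_nat = z0 + d_l + f_max / ks  # turn point ignoring capillary
    if c > 0:
        z_turn = brentq(lambda z: measured_load(z) - f_max, z0, z_nat + 1e-9)
    else:
        z_turn = z_nat
    if z_turn > protocol.max_travel:
        raise UnreachableForceError(
            f"max force needs stage travel {z_turn:.2f} µm "
            f"> limit {protocol.max_travel:.2f} µm (k_load={k_l:.3g} N/m)"
        )

    d_top = float(_solve_quadratic_monotone(a2_l, a1_l, np.array([z_turn - z0]))[0])
    f_top = f_contact_load(d_top)

    k_ue = k_u / window_slope_factor(beta, cal_window, "unload")
    u_l = f_top / (k_ue * (1.0 + beta))  # unloading depth where contact force -> 0
    a2_u = k_ue * beta / (u_l * ks) if beta > 0 else 0.0
    a1_u = 1.0 + k_ue / ks

    dz = protocol.speed / protocol.sample_rate
    z_up = np.arange(0.0, z_turn, dz)
    z_up = np.append(z_up, z_turn)
    z_down = z_turn - np.arange(dz, z_turn + dz / 2.0, dz)
    z_down = np.clip(z_down, 0.0, None)

    f_up = np.where(z_up < z0, 0.0, 0.0)
    in_contact = z_up >= z0
    delta_up = _solve_quadratic_monotone(a2_l, a1_l, z_up[in_contact] - z0)
    f_up = np.zeros_like(z_up)
    f_up[in_contact] = f_contact_load(delta_up)

    u = _solve_quadratic_monotone(a2_u, a1_u, z_turn - z_down)
    f_down = np.where(u < u_l, f_top - k_ue * u * (1.0 + beta * u / u_l), 0.0)
    f_down = np.maximum(f_down, 0.0)

    z = np.concatenate([z_up, z_down])
    f_contact = np.concatenate([f_up, f_down])
    path = np.concatenate([z_up, z_turn + (z_turn - z_down)])
    time = path / protocol.speed
    force = f_contact + c * z
    if sensor.force_noise_sd_uN > 0:
        force = force + rng.normal(0.0, sensor.force_noise_sd_uN, size=z.size)

    meta = {
        "tube_id": tube.id,
        "group": "growing" if tube.growing else "non_growing",
        "distance_from_tip_um": float(distance_from_tip),
        "k_sensor_N_per_m": ks,
        "contact_offset_um": float(z0),
        "beta": beta,
        "cal_window": cal_window,
    }
    return RawCurve(time=time, z_stage=z, force=force, meta=meta)


# ---------------------------------------------------------------------------
# Cohort-level synthesis
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "tubemech-cohort/1"


def _indent_counts(n_tubes: int, m_indent: int) -> list[int]:
    base, extra = divmod(m_indent, n_tubes)
    return [base + (1 if i < extra else 0) for i in range(n_tubes)]


def simulate_cohort(
    species: SpeciesParams,
    group: str = "growing",
    n_tubes: int | None = None,
    m_indent: int | None = None,
    mode: str = "empirical",
    seed: int = 0,
    sensor: SensorSpec | None = None,
    protocol: IndentationProtocol | None = None,
    distance_mode: str = "shank",
    beta: float = 0.1,
    cal_window: float = 0.2,
    ranges=None,
    rho: float = 0.8,
    E_true: float | None = None,
    attenuation: bool = True,
    on_unreachable: str = "skip",
) -> tuple[list[RawCurve], dict]:
    """Simulate a full cohort: tubes, indentations, raw curves, manifest.

    Cohort sizes default to the printed group sizes (19/135 growing,
    11/71 non-growing).  ``distance_mode`` places indentations on the
    shank (uniform 50–150 µm from the tip, where the apex attenuation is
    exactly 1) or across the apex region (uniform 4–14 µm, concentrating
    indentations on the contact-angle gradient of the dome).  The capillary slope defaults to 1%
    of the group's median truth stiffness.  The returned manifest carries
    the full hidden answer key and everything needed to process the curves
    (sensor stiffness, protocol, schema version).

    Determinism: all randomness derives from ``seed`` through a
    SeedSequence tree, so a fixed seed reproduces the cohort bit-for-bit.
    """
    stats = group_stats(group) if mode == "empirical" else None
    n_tubes = n_tubes if n_tubes is not None else (stats.n_tubes if stats else 19)
    m_indent = m_indent if m_indent is not None else (stats.m_indent if stats else 7 * n_tubes)
    if m_indent < n_tubes:
        raise ValueError("m_indent must be >= n_tubes")
    if distance_mode not in ("shank", "apex"):
        raise ValueError("distance_mode must be 'shank' or 'apex'")
    if on_unreachable not in ("raise", "skip"):
        raise ValueError("on_unreachable must be 'raise' or 'skip'")

    root = np.random.SeedSequence(seed)
    ss_cohort, ss_place, ss_curves = root.spawn(3)
    tubes = sample_cohort(
        species,
        n_tubes,
        ranges=ranges,
        mode=mode,
        seed=np.random.default_rng(ss_cohort),
        group=group,
        rho=rho,
        E_true=E_true,
    )

    if sensor is None:
        med = float(np.median([t.k_load_true for t in tubes]))
        sensor = SensorSpec(capillary_slope=round(0.01 * med, 6))
    protocol = protocol or IndentationProtocol()
    med_truth = float(np.median([t.k_load_true for t in tubes]))
    if sensor.capillary_slope > 0.02 * med_truth:
        raise ValueError(
            f"capillary slope {sensor.capillary_slope} exceeds 2% of the "
            f"median sample stiffness {med_truth:.3g}"
        )

    rng_place = np.random.default_rng(ss_place)
    counts = _indent_counts(n_tubes, m_indent)
    curve_seeds = ss_curves.spawn(m_indent)

    curves: list[RawCurve] = []
    curve_entries = []
    n_skipped = 0
    idx = 0
    for tube, n_ind in zip(tubes, counts):
        for j in range(n_ind):
            if distance_mode == "shank":
                dist = float(rng_place.uniform(50.0, 150.0))
            else:
                dist = float(rng_place.uniform(4.0, 14.0))
            offset = float(rng_place.uniform(1.0, 2.0))
            try:
                curve = synthesize_curve(
                    tube,
                    sensor,
                    protocol,
                    contact_offset=offset,
                    seed=np.random.default_rng(curve_seeds[idx]),
                    distance_from_tip=dist,
                    beta=beta,
                    cal_window=cal_window,
                    attenuation=attenuation,
                )
            except UnreachableForceError:
                if on_unreachable == "raise":
                    raise
                n_skipped += 1
                idx += 1
                continue
            curve.meta["curve_id"] = f"{tube.id}_i{j:02d}"
            curves.append(curve)
            curve_entries.append(
                {
                    "curve_id": curve.meta["curve_id"],
                    "tube_id": tube.id,
                    "distance_from_tip_um": dist,
                    "contact_offset_um": offset,
                }
            )
            idx += 1

    manifest = {
        "schema": SCHEMA_VERSION,
        "species": species.label,
        "group": group,
        "mode": mode,
        "seed": seed,
        "beta": beta,
        "cal_window": cal_window,
        "attenuation": attenuation,
        "distance_mode": distance_mode,
        "n_unreachable_skipped": n_skipped,
        "sensor": {
            "k_sensor_N_per_m": sensor.k_sensor,
            "force_noise_sd_nN": sensor.force_noise_sd_nN,
            "capillary_slope_N_per_m": sensor.capillary_slope,
        },
        "protocol": {
            "max_force_uN": protocol.max_force,
            "speed_um_per_s": protocol.speed,
            "sample_rate_hz": protocol.sample_rate,
            "tip_diameter_nm": protocol.tip_diameter_nm,
            "max_travel_um": protocol.max_travel,
        },
        "tubes": [
            {
                "id": t.id,
                "diameter_um": t.diameter,
                "wall_thickness_um": t.wall_thickness,
                "turgor_MPa": t.turgor,
                "growing": t.growing,
                "k_load_true_N_per_m": t.k_load_true,
                "k_unload_true_N_per_m": t.k_unload_true,
                "E_true_MPa": t.E_true,
            }
            for t in tubes
        ],
        "curves": curve_entries,
    }
    return curves, manifest
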