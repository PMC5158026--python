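"""Run configuration: validated parameters, YAML round-trip, config hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .invert import ParamRanges


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Defaults reproduce the standard analysis: top-20% force window,
    5-sigma contact threshold, 10% stiffness-matching tolerance for the
    inversion over the default physiological box.
    """

    window_fraction: float = 0.2
    baseline_fraction: float = 0.2
    contact_threshold_sd: float = 5.0
    contact_min_run: int = 5
    n_perm: int = 9999
    inversion_tolerance: float = 0.10
    t_range: tuple[float, float] = (0.1, 0.3)
    p_range: tuple[float, float] = (0.1, 0.4)
    d_range: tuple[float, float] = (12.4, 22.4)
    E_bracket: tuple[float, float] = (1.0, 1000.0)
    inversion_grid: tuple[int, int, int] = (10, 10, 10)
    nu: float = 0.3
    shell_tol: float = 1.0e-4
    seed: int = 0
    run_inversion: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction < 1:
            raise ValueError("window_fraction must lie in (0, 1)")
        if not 0 < self.baseline_fraction < 1:
            raise ValueError("baseline_fraction must lie in (0, 1)")
        if self.contact_threshold_sd <= 0 or self.contact_min_run < 1:
            raise ValueError("invalid contact-detection thresholds")
        if self.n_perm < 999:
            raise ValueError("n_perm must be >= 999")
        if not 0 < self.inversion_tolerance < 1:
            raise ValueError("inversion_tolerance must lie in (0, 1)")
        self.ranges()  # validates intervals and grid counts

    def ranges(self) -> ParamRanges:
        n_t, n_p, n_d = self.inversion_grid
        return ParamRanges(
            t_range=tuple(self.t_range),
            p_range=tuple(self.p_range),
            d_range=tuple(self.d_range),
            E_bracket=tuple(self.E_bracket),
            n_t=n_t,
            n_p=n_p,
            n_d=n_d,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
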