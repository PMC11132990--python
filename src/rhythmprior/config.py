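"""Pipeline configuration: protocol constants and analysis parameters.

The fast-tempo variant halves the cycle period; the protocol constants
expressed in ms (seed floor 300, response floor 285, match window 150)
scale linearly with the period, while the 80 ms onset-merge gap is a human
motor limit and stays fixed.  The inner-region fraction f is always
min_seed_interval_ms / period_ms (0.15).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    period_ms: float = 2000.0
    min_seed_interval_ms: float = 300.0
    response_floor_ms: float = 285.0
    match_window_ms: float = 150.0
    merge_gap_ms: float = 80.0
    gamma_ms: float = 15.0
    bin_width: float = 0.006
    em_tol: float = 1e-6
    aspect_bound: float = 0.2
    gamma_cat: float = 7.0
    iso_boost: float = 3.0
    n_boot: int = 1000
    n_iterations: int = 5
    max_invalid: int = 3
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "period_ms",
            "min_seed_interval_ms",
            "response_floor_ms",
            "match_window_ms",
            "merge_gap_ms",
            "gamma_ms",
            "bin_width",
            "em_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.aspect_bound < 0.5:
            raise ValueError("aspect_bound must be in (0, 0.5)")

    @property
    def f(self) -> float:
        return self.min_seed_interval_ms / self.period_ms

    def scaled(self, period_ms: float) -> "PipelineConfig":
        """Re-parameterize for another tempo (ms thresholds scale; the
        merge gap does not)."""
        k = period_ms / self.period_ms
        return dataclasses.replace(
            self,
            period_ms=period_ms,
            min_seed_interval_ms=self.min_seed_interval_ms * k,
            response_floor_ms=self.response_floor_ms * k,
            match_window_ms=self.match_window_ms * k,
        )

    # -- flat key=value round-trip ------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for field in dataclasses.fields(self):
                fh.write(f"{field.name}={getattr(self, field.name)!r}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kind = known[key]
                values[key] = int(raw) if kind == "int" else float(raw)
        return cls(**values)

    def digest(self) -> str:
        text = "|".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self)
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]
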