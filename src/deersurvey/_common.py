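"""Shared result types used by all three estimators."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DensityEstimate:
    """A point density estimate with a 95% interval.

    Attributes
    ----------
    method : str
        One of ``"mark_resight"``, ``"nmixture"``, ``"drone"``.
    period : str
        Label for the time window the estimate refers to (e.g. a season).
    density : float
        Point estimate in deer per square kilometre.
    ci_low, ci_high : float
        95% interval bounds (confidence or credible, per method).
    area_km2 : float
        Area the estimate was scaled by.
    """

    method: str
    period: str
    density: float
    ci_low: float
    ci_high: float
    area_km2: float
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.method not in {"mark_resight", "nmixture", "drone"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.area_km2 <= 0:
            raise ValueError("area_km2 must be positive")
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if not (self.ci_low <= self.density <= self.ci_high):
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] does not bracket "
                f"the point estimate {self.density}"
            )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "period": self.period,
            "density": self.density,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "area_km2": self.area_km2,
        }
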