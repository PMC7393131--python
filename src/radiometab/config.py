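"""Run configuration: the thresholds that parameterize the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """Thresholds and options for a pipeline run.

    Defaults mirror the analysis this package reimplements: metabolite
    replicate groups must average >= 3000 ion counts with a triplicate
    CV <= 0.5 to be kept; regulation is called outside z of [-1, +1];
    pathway correlations are controlled at Benjamini-Hochberg FDR 0.1;
    Dmid is integrated to the maximum assayed dose (8 Gy).
    """

    z_lower: float = -1.0
    z_upper: float = 1.0
    min_ion_area: float = 3000.0
    max_cv: float = 0.5
    fdr_threshold: float = 0.1
    p_threshold: float = 0.05
    dose_max: float = 8.0
    seed: int = 0
    unit_of_analysis: str = "cell_line_mean"
    normalization: str = "none"
    dmid_method: str = "fitted"
    max_missing_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.z_lower >= self.z_upper:
            raise ConfigurationError("z_lower must be strictly below z_upper")
        if self.max_cv <= 0:
            raise ConfigurationError("max_cv must be > 0")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ConfigurationError("fdr_threshold must lie in (0, 1)")
        if self.dose_max <= 0:
            raise ConfigurationError("dose_max must be > 0")
        if self.unit_of_analysis not in ("cell_line_mean", "replicate"):
            raise ConfigurationError(
                f"unknown unit_of_analysis {self.unit_of_analysis!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
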