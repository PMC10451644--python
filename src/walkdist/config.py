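"""Pipeline configuration and placement vocabulary."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

PLACEMENTS = ("Animal", "Indoor", "Outdoor")
STATIC_PLACEMENTS = ("Indoor", "Outdoor")
ALGORITHMS = ("RawDist", "CorrectedDist", "CorrectedDist_Act")

#: Default column-name dialect of the delimited inputs.  Keys are canonical
#: names used internally, values the column headers expected in files; a
#: user-supplied dialect maps canonical -> actual header.
DEFAULT_DIALECT = {
    "tracker_id": "tracker_id",
    "timestamp": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "motion_index": "motion_index",
    "placement": "placement",
}


@dataclass
class PipelineConfig:
    """Knobs shared across the processing stages.

    ``day_timezone`` controls how fixes are binned into calendar days; the
    default (UTC) favours reproducibility, the study-site value would be
    ``America/Denver``.
    """

    z_threshold: float = 4.5
    utm_zone: int = 13
    northern_hemisphere: bool = True
    day_timezone: str = "UTC"
    min_fixes_per_day: int = 2
    rng_seed: int = 0
    use_sample_sd: bool = True
    degenerate_day_as_zero: bool = True

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.min_fixes_per_day < 2:
            raise ValueError("min_fixes_per_day must be >= 2")
        if not 1 <= self.utm_zone <= 60:
            raise ValueError("utm_zone must be in 1..60")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)
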