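"""Single analysis configuration object, serialisable to/from YAML or JSON.

Defaults follow the method as published where it is stated (10 mm outward
exclusion, signed segmental means, midpoint cutting plane, equal-variance
group t-test, α = 0.05, no multiplicity correction); everything else is an
explicit, documented choice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .atlas import BandConfig
from .stats import AssociationConfig


@dataclass
class AnalysisConfig:
    exclusion_threshold: float = 10.0  # mm
    exclusion_mode: str = "outward"  # or "absolute"
    area_weighted: bool = True
    # refit-after-exclusion: re-estimate the sphere on included vertices
    # until the exclusion mask stabilises (at most this many passes); keeps
    # the fitted sphere describing the atrial body rather than PV/LAA
    # protrusions.  0 disables (fit once on all vertices).
    refit_passes: int = 2
    plane_offset: float = 0.5  # 0 = PV centroid, 1 = LAA ostium
    bands: BandConfig = field(default_factory=BandConfig)
    stats: AssociationConfig = field(default_factory=AssociationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.refit_passes <= 5:
            raise ValueError("refit_passes must be in 0..5")
        if not 0.0 <= self.plane_offset <= 1.0:
            raise ValueError("plane_offset must be in [0, 1]")
        if self.exclusion_mode not in ("outward", "absolute"):
            raise ValueError("exclusion_mode must be 'outward' or 'absolute'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        if "bands" in data and isinstance(data["bands"], dict):
            data["bands"] = BandConfig(**data["bands"])
        if "stats" in data and isinstance(data["stats"], dict):
            s = dict(data["stats"])
            if "comparator_counts" in s:
                s["comparator_counts"] = tuple(s["comparator_counts"])
            data["stats"] = AssociationConfig(**s)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise IOError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
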