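"""Run configuration: every pipeline threshold in one serialisable place.

Defaults are the screening and clustering cut-offs used throughout the
package (10 kb length gate, 30 nt terminal repeats, 90%/20% VC edges,
99% MAVG merging, 95%/99% recruitment identities, 10 RPKG detection
floor, 75%/50% best-hit host rule, 60%/80% protein clustering).  The
config is serialised into every output directory so results are
auditable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    length_min: int = 10_000
    repeat_min: int = 30
    vc_identity: float = 0.90
    vc_coverage: float = 0.20
    mavg_identity: float = 0.99
    mavg_overlap_min_bp: int = 500
    recruit_identities: tuple[float, ...] = (0.95, 0.99)
    rpkg_floor: float = 10.0
    best_hit_identity: float = 0.75
    best_hit_coverage: float = 0.50
    protein_cluster_identity: float = 0.60
    protein_cluster_coverage: float = 0.80
    min_hallmarks: int = 2
    # reserved for read-level taxonomy (not used by the pipeline stages)
    read_taxonomy_identity: float = 0.50
    read_taxonomy_alignment: float = 0.50
    input_dir: Optional[str] = None
    synthetic: bool = True

    def validate(self) -> None:
        fractions = {
            "vc_identity": self.vc_identity,
            "vc_coverage": self.vc_coverage,
            "mavg_identity": self.mavg_identity,
            "best_hit_identity": self.best_hit_identity,
            "best_hit_coverage": self.best_hit_coverage,
            "protein_cluster_identity": self.protein_cluster_identity,
            "protein_cluster_coverage": self.protein_cluster_coverage,
            "read_taxonomy_identity": self.read_taxonomy_identity,
            "read_taxonomy_alignment": self.read_taxonomy_alignment,
            **{f"recruit_identity_{i}": v for i, v in enumerate(self.recruit_identities)},
        }
        for name, value in fractions.items():
            if not (0 < value <= 1):
                raise ValueError(f"{name}={value} outside (0, 1]")
        for name, value in (
            ("length_min", self.length_min),
            ("repeat_min", self.repeat_min),
            ("mavg_overlap_min_bp", self.mavg_overlap_min_bp),
        ):
            if value <= 0:
                raise ValueError(f"{name}={value} must be positive")
        if self.rpkg_floor < 0:
            raise ValueError("rpkg_floor must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["recruit_identities"] = list(self.recruit_identities)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["recruit_identities"] = tuple(data.get("recruit_identities", (0.95, 0.99)))
        cfg = cls(**data)
        cfg.validate()
        return cfg
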