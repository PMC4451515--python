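"""Analysis configuration: native hydrogen-bond list, CV definitions, basins.

The basin rectangles are deliberately part of the configuration rather than
detected automatically: basins of attraction on a landscape are identified by
inspection, and writing them down as axis-aligned rectangles in CV space is
the reproducible form of that step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

from .errors import ConfigError

SCHEMA_VERSION = 1


class HBondId(NamedTuple):
    """Identity of a (possible) hydrogen bond: residues are 1-based."""

    donor_res: int
    acceptor_res: int
    donor_atom: str
    acceptor_atom: str

    @property
    def pair(self) -> tuple[int, int]:
        return (self.donor_res, self.acceptor_res)


@dataclass
class CVDefinition:
    """A named collective variable: either a native-HB subset count or Rg."""

    name: str
    hb_subset: list[tuple[int, int]] = field(default_factory=list)
    rg: bool = False

    def __post_init__(self) -> None:
        self.hb_subset = [tuple(p) for p in self.hb_subset]
        if self.rg and self.hb_subset:
            raise ConfigError(f"CV {self.name!r}: cannot be both an HB count and Rg")
        if not self.rg and not self.hb_subset:
            raise ConfigError(f"CV {self.name!r}: empty definition")


@dataclass
class AnalysisConfig:
    temperature: float = 300.0
    native_hb_list: list[HBondId] = field(default_factory=list)
    cv_definitions: list[CVDefinition] = field(default_factory=list)
    basin_definitions: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    ion_cutoff: float = 0.4  # nm
    bridge_min_separation: int = 4  # nucleotides
    rmsd_threshold: float = 0.1  # nm
    hb_distance_cutoff: float = 0.35  # nm, donor-acceptor heavy atoms
    hb_angle_min_deg: float = 150.0  # D-H...A, applied only when H present
    bin_widths: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.native_hb_list = [HBondId(*hb) for hb in self.native_hb_list]
        self.cv_definitions = [
            cv if isinstance(cv, CVDefinition) else CVDefinition(**cv)
            for cv in self.cv_definitions
        ]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0 K")
        for attr in ("ion_cutoff", "rmsd_threshold", "hb_distance_cutoff"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"{attr} must be > 0")
        if self.bridge_min_separation < 1:
            raise ConfigError("bridge_min_separation must be >= 1")
        native_pairs = {hb.pair for hb in self.native_hb_list}
        for cv in self.cv_definitions:
            extra = set(cv.hb_subset) - native_pairs
            if extra:
                raise ConfigError(
                    f"CV {cv.name!r} references HBs not in native_hb_list: {sorted(extra)}"
                )
        _check_disjoint(self.basin_definitions)

    # ------------------------------------------------------------------
    def cv(self, name: str) -> CVDefinition:
        for cv in self.cv_definitions:
            if cv.name == name:
                return cv
        raise ConfigError(f"no CV named {name!r}")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["native_hb_list"] = [list(hb) for hb in self.native_hb_list]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        payload = json.loads(Path(path).read_text())
        version = payload.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema version {version}")
        payload["basin_definitions"] = {
            name: {cv: tuple(bounds) for cv, bounds in rect.items()}
            for name, rect in payload.get("basin_definitions", {}).items()
        }
        return cls(**payload)


def _check_disjoint(basins: dict[str, dict[str, tuple[float, float]]]) -> None:
    """Axis-aligned rectangles are pairwise disjoint (half-open intervals)."""
    names = list(basins)
    for name, rect in basins.items():
        for cv, (lo, hi) in rect.items():
            if not hi > lo:
                raise ConfigError(f"basin {name!r}: empty interval on {cv!r}")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = set(basins[a]) & set(basins[b])
            if not shared:
                continue
            overlap = all(
                basins[a][cv][0] < basins[b][cv][1]
                and basins[b][cv][0] < basins[a][cv][1]
                for cv in shared
            )
            if overlap:
                raise ConfigError(f"basins {a!r} and {b!r} overlap")
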