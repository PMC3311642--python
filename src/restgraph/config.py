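"""Run configuration: one serializable object for an end-to-end run.

Defaults encode the study conditions: 0.01–0.08 Hz band, 3 mm / 3° motion
screening, density grid 4%–40% step 2%, alpha 0.05 with 10,000 permutation
trials, nodal retention threshold 10 and fixed density 22%.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidSpecError
from .types import CohortSpec, DensityGrid, GroupSpec

__all__ = ["RunConfig", "load_config", "save_config"]


def _default_grid() -> list[float]:
    return [round(c / 100, 2) for c in range(4, 41, 2)]


@dataclass
class RunConfig:
    """All knobs of a pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    cohort: CohortSpec | None = None  # synthetic mode
    manifest_path: str | None = None  # files mode
    sampling_interval_s: float = 2.0  # files mode (synthetic: from cohort spec)

    do_regress: bool = True
    # None = auto: band-pass real (files-mode) data, skip it for synthetic
    # cohorts, whose series are temporally white with no drift to remove
    do_bandpass: bool | None = None
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    filter_method: str = "butterworth"  # or "fft"
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 3.0

    grid: list[float] = field(default_factory=_default_grid)
    n_nulls: int = 100
    swaps_per_edge: int = 10
    # densities at which the null ensemble (and gamma/lambda/sigma) is built;
    # None means every grid cost
    smallworld_costs: list[float] | None = field(default_factory=lambda: [0.22])

    alpha: float = 0.05
    n_perm: int = 10_000
    retention_threshold: int = 10
    fixed_cost: float = 0.22
    welch: bool = False
    include_nodal: bool = True

    seed: int = 0
    outdir: str = "restgraph_run"
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise InvalidSpecError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha <= 1:
            raise InvalidSpecError("alpha must lie in (0, 1]")
        self.density_grid()  # validates the grid

    def density_grid(self) -> DensityGrid:
        return DensityGrid(costs=list(self.grid))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort is not None:
            d["cohort"] = asdict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.get("cohort")
        if cohort is not None:
            cohort = dict(cohort)
            cohort["groups"] = [GroupSpec(**g) for g in cohort.get("groups", [])]
            d["cohort"] = CohortSpec(**cohort)
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
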