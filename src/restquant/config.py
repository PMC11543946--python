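"""Run configuration for the command-line pipelines.

A single YAML file (flat keys plus optional ``cell`` and ``aggregate``
blocks) collects every tunable the commands use; all values are
validated against the library types before any stage runs, and every
command logs the resolved values into its output header so there are no
silent defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from restquant.imaging import AggregateParams
from restquant.synthgen import CellSimParams


@dataclass
class RunConfig:
    seed: int = 0
    n_cells: int = 10
    n_perm_genes: int = 10_000
    n_perm_regions: int = 3000
    padj_max: float = 0.05
    lfc_min: float = 1.5
    q_max: float = 1e-5
    tss_window_bp: int = 3000
    min_support: int = 2
    summit_window_bp: int = 250
    ring_threshold: float = 0.0
    pixel_size_um: float = 0.2
    cell: dict = field(default_factory=dict)  # CellSimParams overrides
    aggregate: dict = field(default_factory=dict)  # AggregateParams overrides

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in ("n_cells", "n_perm_genes", "n_perm_regions", "tss_window_bp",
                     "min_support", "summit_window_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.padj_max <= 1) or not (0 <= self.q_max <= 1):
            raise ValueError("padj_max and q_max must lie in [0, 1]")
        # instantiating the parameter types runs their invariants
        self.cell_params()
        self.aggregate_params()

    def cell_params(self, **overrides) -> CellSimParams:
        kwargs = dict(self.cell)
        kwargs.update(overrides)
        for key in ("image_size_px", "condensate_area_range_um2"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("pixel_size_um", self.pixel_size_um)
        return CellSimParams(**kwargs)

    def aggregate_params(self, **overrides) -> AggregateParams:
        kwargs = dict(self.aggregate)
        kwargs.update(overrides)
        kwargs.setdefault("pixel_size_um", self.pixel_size_um)
        return AggregateParams(**kwargs)

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text())
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ValueError("config file must hold a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        stray = set(data) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        return cls(**data)

    def header_lines(self, **extra) -> list[str]:
        """Comment lines recording the resolved parameters for output files."""
        items = {
            "seed": self.seed,
            "n_perm_genes": self.n_perm_genes,
            "n_perm_regions": self.n_perm_regions,
            "padj_max": self.padj_max,
            "lfc_min": self.lfc_min,
            "q_max": self.q_max,
            "tss_window_bp": self.tss_window_bp,
            "min_support": self.min_support,
            "summit_window_bp": self.summit_window_bp,
            "ring_threshold": self.ring_threshold,
            "pixel_size_um": self.pixel_size_um,
        }
        items.update(extra)
        return [f"# {k}={v}" for k, v in items.items()]
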