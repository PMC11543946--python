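"""Synthetic generators planting known ground truth for every estimator.

The generators emulate the statistical structure the analysis assumes:

* cells as a filled nuclear disk (DAPI), a Gaussian annulus at the
  nuclear boundary (Lamin B), and a REST channel mixing ring-localized,
  diffuse-nuclear and cytoplasmic components plus Poisson-count
  cytoplasmic condensates;
* gene universes with a planted common core across sets;
* toy genomes with base peak sets, replicate sets derived by dropout and
  summit jitter, and annotation domains with a planted overlap fraction;
* expression profiles with a planted Pearson correlation to an anchor.

Every generator takes one integer seed and is bit-deterministic: the
same parameters and seed always produce identical outputs.  Ground truth
(realized counts, centers, base peaks) travels with each fixture so
downstream tests can score recovery exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from restquant.geneset_stats import GeneSet, GeneUniverse
from restquant.imaging import LineProfile
from restquant.region_stats import Genome, PlacementError, RegionSet

# intensity conventions: 16-bit-like raw units so the aggregate-counter
# thresholds (15000..65535) are meaningful on simulated data
DAPI_AMPLITUDE = 20000.0
LAMINB_AMPLITUDE = 30000.0
REST_AMPLITUDE = 30000.0
CONDENSATE_INTENSITY = 45000.0  # above the detection lower threshold by design


@dataclass(frozen=True)
class CellSimParams:
    """Geometry, composition and noise of one simulated cell.

    The three REST weights partition the REST signal between the lamina
    ring, the diffuse nuclear pool, and the cytoplasm; their sum must not
    exceed 1.  ``condensate_rate`` is the expected (Poisson) number of
    cytoplasmic condensates per cell; condensate areas are uniform within
    ``condensate_area_range_um2`` and painted above the aggregate
    detection threshold so planted counts are exactly recoverable.
    """

    image_size_px: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.2
    nucleus_radius_px: float = 38.0
    cell_radius_px: float = 75.0
    ring_weight: float = 0.8
    ring_sigma_px: float = 3.0
    diffuse_nuclear_weight: float = 0.15
    cytoplasm_weight: float = 0.05
    condensate_rate: float = 0.0
    condensate_area_range_um2: tuple[float, float] = (0.5, 3.0)
    noise_sd: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        weights = (self.ring_weight, self.diffuse_nuclear_weight, self.cytoplasm_weight)
        vals = weights + (
            self.pixel_size_um,
            self.nucleus_radius_px,
            self.cell_radius_px,
            self.ring_sigma_px,
            self.noise_sd,
            self.condensate_rate,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("parameters must be finite")
        if any(w < 0 or w > 1 for w in weights):
            raise ValueError("weights must lie in [0, 1]")
        if sum(weights) > 1 + 1e-12:
            raise ValueError("ring + diffuse + cytoplasm weights must be <= 1")
        if min(self.pixel_size_um, self.nucleus_radius_px, self.ring_sigma_px) <= 0:
            raise ValueError("widths and radii must be positive")
        if self.cell_radius_px <= self.nucleus_radius_px:
            raise ValueError("cell radius must exceed nucleus radius")
        if self.noise_sd < 0 or self.condensate_rate < 0:
            raise ValueError("noise_sd and condensate_rate must be >= 0")
        lo, hi = self.condensate_area_range_um2
        if not (0 < lo <= hi):
            raise ValueError("condensate area range must satisfy 0 < lo <= hi")

    def replace(self, **kwargs) -> "CellSimParams":
        return dataclasses.replace(self, **kwargs)


def wt_preset(seed: int = 0, **overrides) -> CellSimParams:
    """A lamina-ring-dominant cell (the SIRT6-proficient phenotype)."""
    base = dict(
        ring_weight=0.8,
        diffuse_nuclear_weight=0.15,
        cytoplasm_weight=0.05,
        condensate_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return CellSimParams(**base)


def ko_preset(seed: int = 0, **overrides) -> CellSimParams:
    """A diffuse/cytoplasmic cell with condensates (SIRT6-deficient)."""
    base = dict(
        ring_weight=0.2,
        diffuse_nuclear_weight=0.45,
        cytoplasm_weight=0.3,
        condensate_rate=3.0,
        seed=seed,
    )
    base.update(overrides)
    return CellSimParams(**base)


@dataclass
class SimulatedCell:
    """Three channels, masks, and the ground truth that produced them."""

    channels: dict[str, np.ndarray]
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    truth: dict = field(default_factory=dict)


def _radial_components(r: np.ndarray, params: CellSimParams):
    nucleus = (r <= params.nucleus_radius_px).astype(float)
    cell = (r <= params.cell_radius_px).astype(float)
    annulus = np.exp(
        -((r - params.nucleus_radius_px) ** 2) / (2.0 * params.ring_sigma_px**2)
    )
    cytoplasm = cell - nucleus
    return nucleus, cell, annulus, cytoplasm


def _rest_mixture(nucleus, annulus, cytoplasm, params: CellSimParams) -> np.ndarray:
    return REST_AMPLITUDE * (
        params.ring_weight * annulus
        + params.diffuse_nuclear_weight * nucleus
        + params.cytoplasm_weight * cytoplasm
    )


def simulate_cell_image(params: CellSimParams) -> SimulatedCell:
    """Render one three-channel cell image with ground truth.

    DAPI is the filled nuclear disk, Lamin B a Gaussian annulus at the
    nuclear boundary, and REST the weighted mixture of annulus, nuclear
    disk and cytoplasm plus condensates and Gaussian noise (clipped at 0).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(rows - cy, cols - cx)
    nucleus, cell, annulus, cytoplasm = _radial_components(r, params)
    nucleus_mask = nucleus > 0
    cell_mask = cell > 0

    dapi = DAPI_AMPLITUDE * nucleus
    laminb = LAMINB_AMPLITUDE * annulus * cell
    rest = _rest_mixture(nucleus, annulus, cytoplasm, params) * cell

    # condensates are placed fully inside the cytoplasm and pairwise
    # disjoint, so the planted count is the detection ceiling exactly
    n_cond = int(rng.poisson(params.condensate_rate))
    centers, areas, radii = [], [], []
    lo, hi = params.condensate_area_range_um2
    for _ in range(n_cond):
        area_um2 = float(rng.uniform(lo, hi))
        rad_px = np.sqrt(area_um2 / np.pi) / params.pixel_size_um
        for _ in range(10_000):
            cr = int(rng.integers(0, h))
            cc = int(rng.integers(0, w))
            rc = np.hypot(cr - cy, cc - cx)
            # stay clear of the lamina annulus (3 sigma) so a condensate
            # never fuses with the ring signal under thresholding
            fits = (
                rc - rad_px > params.nucleus_radius_px + 3 * params.ring_sigma_px
                and rc + rad_px < params.cell_radius_px - 1
            )
            separated = all(
                np.hypot(cr - pr, cc - pc) > rad_px + prad + 2.0
                for (pr, pc), prad in zip(centers, radii)
            )
            if fits and separated:
                break
        else:  # pragma: no cover - cytoplasm too crowded
            break
        disk = np.hypot(rows - cr, cols - cc) <= rad_px
        rest[disk] = CONDENSATE_INTENSITY
        centers.append((cr, cc))
        areas.append(area_um2)
        radii.append(rad_px)

    if params.noise_sd > 0:
        for ch in (dapi, laminb, rest):
            ch += rng.normal(0.0, params.noise_sd, size=ch.shape)
    channels = {
        "dapi": np.clip(dapi, 0.0, None),
        "laminb": np.clip(laminb, 0.0, None),
        "rest": np.clip(rest, 0.0, None),
    }
    truth = {
        "params": dataclasses.asdict(params),
        "n_condensates": len(centers),
        "condensate_centers": centers,
        "condensate_areas_um2": areas,
    }
    return SimulatedCell(
        channels=channels, nucleus_mask=nucleus_mask, cell_mask=cell_mask, truth=truth
    )


def simulate_line_profile(params: CellSimParams) -> LineProfile:
    """1-D three-channel profile along a diameter through the nucleus.

    Built from the same radial model as :func:`simulate_cell_image`
    (condensates excluded: a random diameter almost never crosses one),
    sampled at 1 px spacing with Gaussian noise clipped at 0.
    """
    rng = np.random.default_rng(params.seed)
    half = int(np.ceil(params.cell_radius_px))
    position = np.arange(2 * half + 1, dtype=float)
    r = np.abs(position - half)
    nucleus, cell, annulus, cytoplasm = _radial_components(r, params)
    dapi = DAPI_AMPLITUDE * nucleus
    laminb = LAMINB_AMPLITUDE * annulus * cell
    rest = _rest_mixture(nucleus, annulus, cytoplasm, params) * cell
    if params.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, params.noise_sd, dapi.shape)
        laminb = laminb + rng.normal(0.0, params.noise_sd, laminb.shape)
        rest = rest + rng.normal(0.0, params.noise_sd, rest.shape)
    return LineProfile(
        position=position,
        channels={
            "dapi": np.clip(dapi, 0.0, None),
            "laminb": np.clip(laminb, 0.0, None),
            "rest": np.clip(rest, 0.0, None),
        },
    )


@dataclass(frozen=True)
class OverlapDesign:
    """A planted multi-set overlap over a finite gene universe.

    Exactly ``planted_overlap`` genes form a core common to every set;
    the remaining members of each set are drawn disjointly from the rest
    of the universe, so the realized intersection of all sets equals the
    planted core exactly.
    """

    universe_size: int
    set_sizes: tuple[int, ...]
    planted_overlap: int
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_sizes", tuple(int(s) for s in self.set_sizes))
        if self.universe_size < 1 or not self.set_sizes:
            raise ValueError("need a non-empty universe and at least one set")
        if any(s < 1 for s in self.set_sizes):
            raise ValueError("set sizes must be positive")
        if not (0 <= self.planted_overlap <= min(self.set_sizes)):
            raise ValueError("planted overlap must be <= the smallest set")
        if max(self.set_sizes) > self.universe_size:
            raise ValueError("set sizes must not exceed the universe")
        needed = self.planted_overlap + sum(
            s - self.planted_overlap for s in self.set_sizes
        )
        if needed > self.universe_size:
            raise ValueError(
                "universe too small for disjoint remainders "
                f"(need {needed}, have {self.universe_size})"
            )


def simulate_gene_sets(design: OverlapDesign) -> tuple[GeneUniverse, list[GeneSet]]:
    """Draw gene sets containing exactly the planted common core."""
    rng = np.random.default_rng(design.seed)
    genes = np.array([f"G{i:05d}" for i in range(design.universe_size)])
    perm = rng.permutation(design.universe_size)
    core = genes[perm[: design.planted_overlap]]
    pool = perm[design.planted_overlap :]
    sets = []
    cursor = 0
    for i, size in enumerate(design.set_sizes):
        extra = size - design.planted_overlap
        members = np.concatenate([core, genes[pool[cursor : cursor + extra]]])
        cursor += extra
        sets.append(GeneSet(f"set{i + 1}", members))
    return GeneUniverse(genes), sets


@dataclass
class RegionSimResult:
    """Replicate peak sets plus the planted truth."""

    replicates: list[RegionSet]
    domains: RegionSet
    base_peaks: RegionSet


def simulate_region_replicates(
    genome: Genome,
    n_peaks: int,
    peak_len: int,
    k: int = 3,
    dropout: float = 0.0,
    summit_jitter_sd: float = 0.0,
    domain_cover_frac: float = 0.2,
    planted_overlap_frac: float = 0.0,
    min_spacing_bp: int = 600,
    seed: int = 0,
) -> RegionSimResult:
    """Plant base peaks (partly inside annotation domains) and derive replicates.

    One domain block per chromosome covers ``domain_cover_frac`` of it; a
    ``planted_overlap_frac`` fraction of base-peak summits is placed
    inside domains, the rest outside.  Each of the ``k`` replicates keeps
    every base peak independently with probability ``1 - dropout`` and
    jitters its summit by a rounded Normal(0, summit_jitter_sd); peak
    lengths are preserved exactly.  Base-peak summits are kept at least
    ``min_spacing_bp`` apart so distinct planted peaks never collapse
    into one summit cluster downstream.
    """
    for frac, label in (
        (dropout, "dropout"),
        (summit_jitter_sd, "summit_jitter_sd"),
        (domain_cover_frac, "domain_cover_frac"),
        (planted_overlap_frac, "planted_overlap_frac"),
    ):
        if frac < 0:
            raise ValueError(f"{label} must be >= 0")
    if not (0 <= dropout <= 1 and 0 <= domain_cover_frac <= 1 and 0 <= planted_overlap_frac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if peak_len < 1 or n_peaks < 1 or k < 1:
        raise ValueError("n_peaks, peak_len and k must be positive")
    if all(length < peak_len for length in genome.sizes.values()):
        raise PlacementError("peak_len exceeds every chromosome")
    rng = np.random.default_rng(seed)
    chroms = list(genome.sizes)
    lengths = np.array([genome.sizes[c] for c in chroms], dtype=np.int64)

    # one domain block per chromosome at a random valid start
    dom_rows = []
    for c, clen in zip(chroms, lengths):
        dlen = int(round(domain_cover_frac * clen))
        if dlen < 1:
            continue
        start = int(rng.integers(0, clen - dlen + 1))
        dom_rows.append((c, start, start + dlen))
    domains = RegionSet(
        pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])
        if dom_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    dom_by_chrom = {c: (s, e) for c, s, e in dom_rows}

    half = peak_len // 2
    n_inside = int(round(planted_overlap_frac * n_peaks))
    usable = lengths >= peak_len
    weights = np.where(usable, lengths, 0).astype(float)
    weights /= weights.sum()
    rows = []
    summits_by_chrom: dict[str, list[int]] = {}
    for i in range(n_peaks):
        want_inside = i < n_inside
        for _ in range(10_000):
            ci = int(rng.choice(len(chroms), p=weights))
            c, clen = chroms[ci], int(lengths[ci])
            summit = int(rng.integers(half, clen - (peak_len - half) + 1))
            dom = dom_by_chrom.get(c)
            inside = dom is not None and dom[0] <= summit < dom[1]
            spaced = all(
                abs(summit - s) >= min_spacing_bp
                for s in summits_by_chrom.get(c, ())
            )
            if inside == want_inside and spaced:
                break
        else:  # pragma: no cover - pathological cover fractions
            raise PlacementError("could not place a peak with the requested overlap")
        summits_by_chrom.setdefault(c, []).append(summit)
        rows.append((c, summit - half, summit - half + peak_len, summit))
    base = RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"]))

    replicates = []
    for _ in range(k):
        keep = rng.random(n_peaks) >= dropout
        rep_rows = []
        for (c, s, e, summit), kept in zip(rows, keep):
            if not kept:
                continue
            clen = genome.sizes[c]
            if summit_jitter_sd > 0:
                summit = summit + int(round(rng.normal(0.0, summit_jitter_sd)))
            summit = int(np.clip(summit, half, clen - (peak_len - half)))
            start = summit - half
            rep_rows.append((c, start, start + peak_len, summit))
        replicates.append(
            RegionSet(
                pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "summit"])
                if rep_rows
                else pd.DataFrame(columns=["chrom", "start", "end"])
            )
        )
    return RegionSimResult(replicates=replicates, domains=domains, base_peaks=base)


def simulate_expression_profiles(
    n_structures: int,
    rho: float,
    n_tf: int = 3,
    seed: int = 0,
    anchor_name: str = "SIRT6",
) -> pd.DataFrame:
    """Anchor profile plus targets with planted Pearson correlation ``rho``.

    Gaussian construction: target_i = rho * z + sqrt(1 - rho^2) * e_i with
    z, e_i independent standard normals over structures, so the population
    correlation with the anchor is exactly ``rho`` (sample correlation is
    exactly +/-1 at rho = +/-1).  Returns a genes x structures DataFrame.
    """
    if n_structures < 3:
        raise ValueError("need at least 3 structures for a correlation")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if n_tf < 1:
        raise ValueError("n_tf must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_structures)
    rows = {anchor_name: z}
    resid = float(np.sqrt(max(0.0, 1.0 - rho**2)))
    for i in range(n_tf):
        e = rng.standard_normal(n_structures)
        rows[f"TF{i + 1:02d}"] = rho * z + resid * e
    cols = [f"S{j + 1:02d}" for j in range(n_structures)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
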