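"""Quantification of REST localization in three-channel immunofluorescence.

The central readout is a *laminar co-localization score* computed from a
line profile drawn across a nucleus.  Each channel (DAPI, Lamin B, REST)
is normalized to unit maximum intensity and unit length, and the area
under each normalized curve is taken.  A REST distribution hugging the
nuclear lamina has an area close to the Lamin B area and far from the
DAPI area, so the score

    score = log10(|area_rest - area_dapi| / |area_rest - area_laminb|)

is large for lamina-ring cells and negative for diffuse-nuclear cells.
Both numerator and denominator are clamped at ``eps`` so the score stays
finite when two areas coincide.

The module also measures the thickness (FWHM) of the lamina-adjacent REST
peak, classifies ring-positive cells, reports compartment mean
intensities, and counts cytoplasmic/perinuclear aggregates with the
standard intensity-threshold + size-gate recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

CHANNEL_ROLES = ("dapi", "laminb", "rest")


class GeometryError(ValueError):
    """Line-profile endpoints outside the image or degenerate."""


@dataclass(frozen=True)
class LineProfile:
    """Per-channel intensities sampled along a nuclear cross-section.

    ``position`` is strictly increasing (pixels from the first endpoint);
    ``channels`` maps each role in :data:`CHANNEL_ROLES` to a non-negative
    intensity array of the same length.
    """

    position: np.ndarray
    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("position must be 1-D with at least 2 samples")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("position must be strictly increasing")
        chans = {}
        for role, y in dict(self.channels).items():
            arr = np.asarray(y, dtype=float)
            if arr.shape != pos.shape:
                raise ValueError(f"channel {role!r} length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"channel {role!r} has negative intensities")
            chans[role] = arr
        object.__setattr__(self, "channels", chans)

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass(frozen=True)
class ChannelSpectrum:
    """A normalized line profile for one channel.

    ``x`` spans [0, 1] (distance / total length), ``y`` is intensity
    divided by its maximum (all zeros for an all-zero channel, flagged
    ``degenerate``), and ``area`` is the trapezoidal area under (x, y).
    """

    x: np.ndarray
    y: np.ndarray
    area: float
    degenerate: bool = False


@dataclass(frozen=True)
class LaminarResult:
    """Per-cell lamina co-localization summary."""

    score: float
    thickness: float  # NaN when undefined
    ring_positive: bool
    areas: tuple[float, float, float]  # (red=REST, green=LaminB, blue=DAPI)


def extract_line_profile(
    image,
    endpoints: Sequence[Sequence[float]],
    spacing_px: float = 1.0,
) -> LineProfile:
    """Sample all three channels along a segment.

    Parameters
    ----------
    image
        Either a mapping of channel role -> 2-D array, or an object with a
        ``channels`` attribute of that form (e.g. a simulated cell).
    endpoints
        Two (row, col) points inside the image.
    spacing_px
        Sample spacing along the segment; must be <= 1 px.
    """
    channels = getattr(image, "channels", image)
    if not all(role in channels for role in CHANNEL_ROLES):
        raise ValueError(f"image must provide channels {CHANNEL_ROLES}")
    if spacing_px <= 0 or spacing_px > 1:
        raise ValueError("spacing_px must be in (0, 1]")
    (r0, c0), (r1, c1) = (np.asarray(p, dtype=float) for p in endpoints)
    shape = np.asarray(next(iter(channels.values()))).shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise GeometryError("endpoint outside image")
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise GeometryError("zero-length segment")
    n = int(np.ceil(length / spacing_px)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    sampled = {
        role: ndimage.map_coordinates(
            np.asarray(channels[role], dtype=float),
            np.vstack([rows, cols]),
            order=1,
            mode="nearest",
        )
        for role in CHANNEL_ROLES
    }
    # linear interpolation of non-negative data can only produce >= 0;
    # clip guards against tiny negative round-off
    sampled = {k: np.clip(v, 0.0, None) for k, v in sampled.items()}
    return LineProfile(position=t * length, channels=sampled)


def normalize_spectrum(position, intensity) -> ChannelSpectrum:
    """Normalize one channel of a profile to unit length and unit maximum.

    Distance is rescaled to [0, 1] by the total length; intensity is
    divided by its maximum.  The area under the normalized curve is the
    trapezoidal integral; a constant channel therefore has area exactly 1.
    An all-zero channel yields ``y == 0``, area 0, and the degenerate flag.
    """
    pos = np.asarray(position, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least 2 samples")
    if pos.shape != y.shape:
        raise ValueError("position/intensity length mismatch")
    span = pos[-1] - pos[0]
    if span <= 0:
        raise ValueError("position must be increasing")
    x = (pos - pos[0]) / span
    peak = float(y.max())
    if peak <= 0:
        return ChannelSpectrum(x=x, y=np.zeros_like(y), area=0.0, degenerate=True)
    yn = y / peak
    area = float(np.trapezoid(yn, x))
    return ChannelSpectrum(x=x, y=yn, area=area)


def laminar_score(
    red_area: float,
    green_area: float,
    blue_area: float,
    eps: float = 1e-6,
) -> float:
    """Laminar co-localization score from normalized channel areas.

    ``red`` is the REST (Flag) area, ``green`` the Lamin B area, ``blue``
    the DAPI area.  Larger scores mean the REST profile is closer in area
    to Lamin B than to DAPI, i.e. more lamina-ring-like.
    """
    for a in (red_area, green_area, blue_area):
        if not np.isfinite(a) or a < 0:
            raise ValueError("areas must be finite and non-negative")
    num = max(abs(red_area - blue_area), eps)
    den = max(abs(red_area - green_area), eps)
    return float(np.log10(num / den))


def profile_laminar_result(
    profile: LineProfile,
    ring_threshold: float | None = None,
    eps: float = 1e-6,
    thickness_window: float = 0.25,
) -> LaminarResult:
    """Full per-cell pipeline: normalize, score, thickness, classify."""
    spectra = {
        role: normalize_spectrum(profile.position, profile[role])
        for role in CHANNEL_ROLES
    }
    red = spectra["rest"].area
    green = spectra["laminb"].area
    blue = spectra["dapi"].area
    score = laminar_score(red, green, blue, eps=eps)
    lamina_pos = _two_main_peaks(spectra["laminb"])
    if lamina_pos is None:
        thickness = float("nan")
    else:
        thickness = lamina_peak_thickness(
            spectra["rest"], lamina_pos, window=thickness_window
        )
    ring = bool(score >= ring_threshold) if ring_threshold is not None else False
    return LaminarResult(
        score=score, thickness=thickness, ring_positive=ring, areas=(red, green, blue)
    )


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1-D array."""
    n = y.size
    if n < 3:
        return np.array([], dtype=int)
    idx = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j == n - 1 or y[j + 1] < y[j]:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def _two_main_peaks(spectrum: ChannelSpectrum) -> tuple[float, float] | None:
    """Positions of the two dominant local maxima (the lamina crossings)."""
    peaks = _local_maxima(spectrum.y)
    if peaks.size < 2:
        return None
    order = peaks[np.argsort(spectrum.y[peaks])[::-1][:2]]
    xs = np.sort(spectrum.x[order])
    return float(xs[0]), float(xs[1])


def lamina_peak_thickness(
    spectrum: ChannelSpectrum,
    lamina_positions: Sequence[float],
    window: float = 0.25,
    center: float = 0.5,
) -> float:
    """FWHM of the REST peaks adjacent to the nuclear lamina.

    For each of the two lamina positions (on the normalized axis), the
    nearest REST local maximum within ``window`` is found; its width is the
    full width at half maximum above a local baseline, the minimum of the
    profile between the peak and the nucleus center.  The mean of the
    defined widths is returned; NaN if no qualifying peak exists at either
    lamina position (flat or diffuse profiles).
    """
    x, y = spectrum.x, spectrum.y
    if spectrum.degenerate or np.ptp(y) == 0:
        return float("nan")
    maxima = _local_maxima(y)
    if maxima.size == 0:
        return float("nan")
    spacing = float(np.median(np.diff(x)))
    widths = []
    for lam in lamina_positions:
        dist = np.abs(x[maxima] - lam)
        j = int(np.argmin(dist))
        if dist[j] > window:
            continue
        p = maxima[j]
        widths.append(_fwhm_at(x, y, p, center, spacing))
    if not widths:
        return float("nan")
    return float(np.mean(widths))


def _fwhm_at(x, y, p: int, center: float, spacing: float) -> float:
    """FWHM of the peak at index ``p`` above its center-side baseline."""
    c = int(np.argmin(np.abs(x - center)))
    lo, hi = (p, c) if p <= c else (c, p)
    baseline = float(y[lo : hi + 1].min()) if hi > lo else float(y[p])
    half = baseline + 0.5 * (y[p] - baseline)
    # walk left
    left = x[p]
    for i in range(p, 0, -1):
        if y[i - 1] < half:
            left = x[i - 1] + (x[i] - x[i - 1]) * (half - y[i - 1]) / (y[i] - y[i - 1])
            break
    else:
        left = x[0]
    right = x[p]
    n = y.size
    for i in range(p, n - 1):
        if y[i + 1] < half:
            right = x[i] + (x[i + 1] - x[i]) * (y[i] - half) / (y[i] - y[i + 1])
            break
    else:
        right = x[-1]
    return max(float(right - left), spacing)


def classify_ring(result: LaminarResult, threshold: float) -> bool:
    """Binary ring-positive call from the laminar score."""
    if not np.isfinite(result.score):
        raise ValueError("score must be finite")
    return bool(result.score >= threshold)


def ring_fraction(labels: Sequence[bool | int]) -> float:
    """Fraction of ring-positive cells among all scored cells.

    Accepts boolean calls or manual 0/1 labels (the original scoring was
    manual; manual labels are first-class inputs).
    """
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("ring fraction undefined for an empty cell list")
    return float(np.mean(arr.astype(float)))


@dataclass(frozen=True)
class AggregateParams:
    """Intensity and size gates for aggregate counting.

    Thresholds are raw 16-bit intensity units; sizes are µm² so an explicit
    ``pixel_size_um`` is required for the px→µm² conversion.
    """

    pixel_size_um: float
    lower_thresh: float = 15000.0
    upper_thresh: float = 65535.0
    perinuclear_distance_px: float = 10.0
    aggresome_size_um2: float = 4.0
    min_aggregate_um2: float = 0.2
    max_aggregate_um2: float = 20.0
    min_nuclei_um2: float = 40.0
    min_cell_um2: float = 75.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 < self.min_aggregate_um2 < self.max_aggregate_um2):
            raise ValueError("need 0 < min_aggregate_um2 < max_aggregate_um2")
        if not (0 <= self.lower_thresh <= self.upper_thresh):
            raise ValueError("thresholds must satisfy 0 <= lower <= upper")


@dataclass(frozen=True)
class AggregateRecord:
    area_um2: float
    centroid: tuple[float, float]
    compartment: str  # nuclear | perinuclear | cytoplasmic
    is_aggresome: bool


def quantify_aggregates(
    rest_channel,
    nucleus_mask,
    cell_mask,
    params: AggregateParams,
) -> tuple[list[AggregateRecord], dict]:
    """Count REST aggregates inside a cell.

    Pixels within [lower_thresh, upper_thresh] inside the cell are
    binarized, 8-connected components are measured, component areas are
    converted to µm² and gated to [min_aggregate_um2, max_aggregate_um2].
    A component is *nuclear* if its centroid falls in the nucleus mask,
    *perinuclear* if the centroid lies outside but within
    ``perinuclear_distance_px`` of the nucleus boundary (Euclidean distance
    transform), otherwise *cytoplasmic*.  Components of at least
    ``aggresome_size_um2`` are flagged as aggresomes.
    """
    if nucleus_mask is None or cell_mask is None:
        raise ValueError("nucleus_mask and cell_mask are required")
    ch = np.asarray(rest_channel, dtype=float)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not (ch.shape == nuc.shape == cell.shape):
        raise ValueError("channel and masks must share a shape")
    binary = cell & (ch >= params.lower_thresh) & (ch <= params.upper_thresh)
    labels = measure.label(binary, connectivity=2)
    dist_to_nucleus = ndimage.distance_transform_edt(~nuc)
    records: list[AggregateRecord] = []
    px_area = params.pixel_size_um**2
    for prop in measure.regionprops(labels):
        area = prop.area * px_area
        if not (params.min_aggregate_um2 <= area <= params.max_aggregate_um2):
            continue
        cr, cc = prop.centroid
        ri, ci = int(round(cr)), int(round(cc))
        ri = min(max(ri, 0), nuc.shape[0] - 1)
        ci = min(max(ci, 0), nuc.shape[1] - 1)
        if nuc[ri, ci]:
            compartment = "nuclear"
        elif dist_to_nucleus[ri, ci] < params.perinuclear_distance_px:
            compartment = "perinuclear"
        else:
            compartment = "cytoplasmic"
        records.append(
            AggregateRecord(
                area_um2=float(area),
                centroid=(float(cr), float(cc)),
                compartment=compartment,
                is_aggresome=bool(area >= params.aggresome_size_um2),
            )
        )
    summary = {
        "n_aggregates": len(records),
        "n_aggresomes": sum(r.is_aggresome for r in records),
        "n_nuclear": sum(r.compartment == "nuclear" for r in records),
        "n_perinuclear": sum(r.compartment == "perinuclear" for r in records),
        "n_cytoplasmic": sum(r.compartment == "cytoplasmic" for r in records),
        "total_area_um2": float(sum(r.area_um2 for r in records)),
    }
    return records, summary


def compartment_intensities(channel, nucleus_mask, cell_mask) -> tuple[float, float, float]:
    """Mean intensity over the whole cell, the nucleus, and the cytoplasm.

    The cytoplasm is ``cell_mask`` minus ``nucleus_mask``.  An empty
    compartment yields NaN for that entry.
    """
    ch = np.asarray(channel, dtype=float)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not (ch.shape == nuc.shape == cell.shape):
        raise ValueError("channel and masks must share a shape")
    if np.any(nuc & ~cell):
        raise ValueError("nucleus_mask must be contained in cell_mask")
    cyto = cell & ~nuc

    def _mean(mask):
        return float(ch[mask].mean()) if mask.any() else float("nan")

    return _mean(cell), _mean(nuc), _mean(cyto)


@dataclass
class CellQuantification:
    """Row-level container used by the CLI table writer."""

    cell_id: str
    score: float
    thickness: float
    ring_positive: bool
    n_aggregates: int = 0
    whole_cell_mean: float = float("nan")
    nuclear_mean: float = float("nan")
    cytoplasmic_mean: float = float("nan")
    group: str = ""
    extras: dict = field(default_factory=dict)
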