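"""Genomic interval statistics on 0-based half-open coordinates.

Covers the region-level machinery of the analysis: the fraction of peaks
overlapping annotation domains (LADs, H3K27me3 domains), size-preserving
genome-wide randomization of regions with a permutation overlap test
(3000 permutations by default), the at-least-2-of-3 consensus rule for
replicate peak sets matched by summit proximity, emerging/vanishing peak
calls between two replicate groups, the randomized-annotation one-sided
z-test, and TSS-window annotation of peaks to genes.

Intervals are [start, end) — adjacent intervals such as [a, b) and
[b, c) never overlap.  Interval arithmetic is done internally on sorted
merged numpy arrays (binary search), which is all these statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from restquant._common import PermutationResult, summarize_permutations

__all__ = [
    "Genome",
    "RegionSet",
    "CoordinateError",
    "PlacementError",
    "PermutationResult",
    "overlap_fraction",
    "randomize_regions",
    "permutation_overlap",
    "consensus_presence",
    "differential_presence",
    "annotation_ztest",
    "annotate_to_tss",
]


class CoordinateError(ValueError):
    """Interval coordinates inconsistent with the genome."""


class PlacementError(ValueError):
    """A region cannot be placed anywhere in the genome."""


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length (bp), as in a chrom.sizes file."""

    sizes: dict[str, int]

    def __init__(self, sizes: Mapping[str, int]):
        clean = {str(k): int(v) for k, v in sizes.items()}
        if not clean:
            raise ValueError("genome must have at least one chromosome")
        if any(v <= 0 for v in clean.values()):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "sizes", clean)

    def __len__(self) -> int:
        return len(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def total_bp(self) -> int:
        return sum(self.sizes.values())

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        sizes = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
        return cls(sizes)

    def to_chrom_sizes(self, path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{l}\n" for c, l in self.sizes.items())
        )


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_NARROWPEAK_COLS = _BED6_COLS + ["signal", "pvalue_log10", "qvalue_log10", "summit_offset"]


class RegionSet:
    """An ordered collection of genomic intervals backed by a DataFrame.

    Required columns: ``chrom`` (str), ``start``/``end`` (int, 0-based
    half-open).  Optional: ``name``, ``score``, ``strand``, ``summit``
    (absolute bp) and ``qvalue`` (linear scale).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"RegionSet requires a {col!r} column")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not np.all(df["start"].to_numpy() < df["end"].to_numpy()):
            raise ValueError("all intervals must satisfy start < end")
        if len(df) and np.any(df["start"].to_numpy() < 0):
            raise ValueError("starts must be >= 0")
        if "summit" in df.columns and len(df):
            s = df["summit"].to_numpy(dtype=np.int64)
            inside = (s >= df["start"].to_numpy()) & (s < df["end"].to_numpy())
            if not np.all(inside):
                raise ValueError("summits must lie inside their intervals")
        self.df = df.reset_index(drop=True)

    # -- basics -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def summits(self) -> np.ndarray:
        """Absolute summit positions, defaulting to interval midpoints."""
        if "summit" in self.df.columns:
            return self.df["summit"].to_numpy(dtype=np.int64)
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def sort(self) -> "RegionSet":
        out = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return RegionSet(out)

    def validate_against(self, genome: Genome) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise CoordinateError(f"chromosome {chrom!r} absent from genome")
            if grp["end"].max() > genome.sizes[chrom]:
                raise CoordinateError(f"interval beyond end of {chrom!r}")

    def merged(self) -> "RegionSet":
        """Union of the intervals (per chromosome, idempotent)."""
        rows = []
        for chrom, grp in sorted(self.df.groupby("chrom", sort=False), key=lambda kv: kv[0]):
            arr = grp[["start", "end"]].to_numpy()
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            cur_s, cur_e = None, None
            for s, e in arr:
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e))
        return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tuples(cls, intervals: Iterable[tuple]) -> "RegionSet":
        rows = list(intervals)
        cols = ["chrom", "start", "end", "summit"][: len(rows[0])] if rows else ["chrom", "start", "end"]
        return cls(pd.DataFrame(rows, columns=cols))

    @classmethod
    def read_bed(cls, path) -> "RegionSet":
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        ncol = raw.shape[1]
        if ncol < 3:
            raise ValueError("BED needs at least 3 columns")
        raw.columns = _BED6_COLS[:ncol] if ncol <= 6 else _NARROWPEAK_COLS[:ncol]
        raw["start"] = raw["start"].astype(np.int64)
        raw["end"] = raw["end"].astype(np.int64)
        return cls(raw)

    def write_bed(self, path) -> None:
        cols = [c for c in _BED6_COLS if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_narrowpeak(cls, path) -> "RegionSet":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        if raw.shape[1] != 10:
            raise ValueError("narrowPeak requires exactly 10 columns")
        raw.columns = _NARROWPEAK_COLS
        raw["start"] = raw["start"].astype(np.int64)
        raw["end"] = raw["end"].astype(np.int64)
        # summit offset is relative to start; q-value column is -log10
        raw["summit"] = raw["start"] + raw["summit_offset"].astype(np.int64)
        raw["qvalue"] = 10.0 ** (-raw["qvalue_log10"].astype(float))
        return cls(raw)

    def write_narrowpeak(self, path) -> None:
        out = self.df.copy()
        if "summit_offset" not in out.columns:
            out["summit_offset"] = self.summits() - out["start"]
        if "qvalue_log10" not in out.columns:
            q = out["qvalue"].to_numpy(dtype=float) if "qvalue" in out.columns else np.ones(len(out))
            out["qvalue_log10"] = -np.log10(np.maximum(q, np.finfo(float).tiny))
        for col, default in (
            ("name", "."), ("score", 0), ("strand", "."),
            ("signal", 0.0), ("pvalue_log10", -1.0),
        ):
            if col not in out.columns:
                out[col] = default
        out[_NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


# -- overlap machinery ----------------------------------------------------

def _merged_domain_arrays(domains: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = domains.merged()
    out = {}
    for chrom, grp in merged.df.groupby("chrom", sort=False):
        out[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def peak_overlap_mask(peaks: RegionSet, domains: RegionSet) -> np.ndarray:
    """Boolean mask: does each peak intersect >= 1 bp of the domain union?"""
    dom = _merged_domain_arrays(domains)
    hit = np.zeros(len(peaks), dtype=bool)
    for chrom, grp in peaks.df.groupby("chrom", sort=False):
        if chrom not in dom:
            continue
        starts, ends = dom[chrom]
        p_start = grp["start"].to_numpy()
        p_end = grp["end"].to_numpy()
        # last merged domain starting before the peak end; disjoint sorted
        # domains mean it is the only overlap candidate
        idx = np.searchsorted(starts, p_end, side="left") - 1
        ok = idx >= 0
        ok[ok] = ends[idx[ok]] > p_start[ok]
        hit[grp.index.to_numpy()] = ok
    return hit


def overlap_fraction(
    peaks: RegionSet, domains: RegionSet, genome: Genome | None = None
) -> float:
    """Fraction of peaks intersecting the (merged) domain union."""
    if genome is not None:
        peaks.validate_against(genome)
        domains.validate_against(genome)
    if len(peaks) == 0:
        raise ValueError("overlap fraction undefined for an empty peak set")
    return float(peak_overlap_mask(peaks, domains).mean())


def _global_layout(genome: Genome) -> tuple[list[str], np.ndarray, np.ndarray]:
    chroms = list(genome.sizes)
    lengths = np.array([genome.sizes[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return chroms, lengths, offsets


def _sample_starts(
    length: int,
    n: int,
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform (chrom index, start) pairs for ``n`` regions of one length."""
    valid = np.maximum(chrom_lengths - length + 1, 0)
    total = int(valid.sum())
    if total == 0:
        raise PlacementError(f"no chromosome can hold a region of length {length}")
    cum = np.cumsum(valid)
    u = rng.integers(0, total, size=n)
    ci = np.searchsorted(cum, u, side="right")
    starts = u - (cum[ci] - valid[ci])
    return ci, starts


def randomize_regions(
    regions: RegionSet,
    genome: Genome,
    seed: int | np.random.Generator | None = None,
    per_chromosome: bool = False,
) -> RegionSet:
    """Place each region at a uniformly random valid position.

    Region lengths are preserved exactly (the output length multiset
    equals the input's for every seed).  By default placement is
    genome-wide over all valid (chrom, start) pairs; ``per_chromosome``
    keeps each region on its original chromosome.  Overlaps among the
    randomized regions are allowed.  Only region lengths matter for
    genome-wide placement, so source coordinates need not fit the target
    genome; a region longer than every chromosome raises
    :class:`PlacementError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms, chrom_lengths, _ = _global_layout(genome)
    lengths = regions.lengths
    out_chrom = np.empty(len(regions), dtype=object)
    out_start = np.zeros(len(regions), dtype=np.int64)
    if per_chromosome:
        for chrom, grp in regions.df.groupby("chrom", sort=False):
            ln = (grp["end"] - grp["start"]).to_numpy()
            size = genome.sizes[chrom]
            if np.any(ln > size):
                raise PlacementError(f"region longer than chromosome {chrom!r}")
            idx = grp.index.to_numpy()
            out_chrom[idx] = chrom
            out_start[idx] = rng.integers(0, size - ln + 1)
    else:
        for length in np.unique(lengths):
            idx = np.flatnonzero(lengths == length)
            ci, starts = _sample_starts(int(length), idx.size, chrom_lengths, rng)
            out_chrom[idx] = np.array(chroms, dtype=object)[ci]
            out_start[idx] = starts
    return RegionSet(
        pd.DataFrame(
            {"chrom": out_chrom, "start": out_start, "end": out_start + lengths}
        )
    )


def permutation_overlap(
    peaks: RegionSet,
    domains: RegionSet,
    genome: Genome,
    n_perm: int = 3000,
    seed: int | np.random.Generator | None = None,
    statistic: str = "count",
) -> PermutationResult:
    """Permutation test of peak/domain overlap with size-preserving nulls.

    The observed statistic is the number (or fraction) of peaks with
    >= 1 bp intersection with the merged domains; the null redraws all
    peak positions uniformly (lengths preserved, genome-wide) ``n_perm``
    times.  The null is evaluated vectorized in a concatenated-genome
    coordinate space; randomized regions never span a chromosome
    boundary, so global binary search against the domain union is exact.
    """
    if statistic not in ("count", "fraction"):
        raise ValueError("statistic must be 'count' or 'fraction'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    peaks.validate_against(genome)
    domains.validate_against(genome)
    observed_hits = int(peak_overlap_mask(peaks, domains).sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms, chrom_lengths, offsets = _global_layout(genome)
    offset_of = {c: offsets[i] for i, c in enumerate(chroms)}

    dom = domains.merged().df
    if len(dom):
        g_start = np.sort(
            dom["start"].to_numpy() + np.array([offset_of[c] for c in dom["chrom"]])
        )
        order = np.argsort(
            dom["start"].to_numpy() + np.array([offset_of[c] for c in dom["chrom"]])
        )
        g_end = (
            dom["end"].to_numpy() + np.array([offset_of[c] for c in dom["chrom"]])
        )[order]
    else:
        g_start = np.array([], dtype=np.int64)
        g_end = np.array([], dtype=np.int64)

    lengths = peaks.lengths
    counts = np.zeros(n_perm, dtype=np.int64)
    if len(g_start):
        for length in np.unique(lengths):
            m = int((lengths == length).sum())
            ci, starts = _sample_starts(int(length), n_perm * m, chrom_lengths, rng)
            g = offsets[ci] + starts
            idx = np.searchsorted(g_start, g + length, side="left") - 1
            ok = idx >= 0
            ok[ok] = g_end[idx[ok]] > g[ok]
            counts += ok.reshape(n_perm, m).sum(axis=1)
    else:
        # still consume randomness so results are seed-stable across
        # empty/non-empty domain calls of the same shape
        for length in np.unique(lengths):
            m = int((lengths == length).sum())
            _sample_starts(int(length), n_perm * m, chrom_lengths, rng)
    if statistic == "fraction":
        n = len(peaks)
        return summarize_permutations(observed_hits / n, counts / n)
    return summarize_permutations(observed_hits, counts)


# -- consensus across replicates ------------------------------------------

def _cluster_scaffold(
    replicates: Sequence[RegionSet], summit_window_bp: int
) -> pd.DataFrame:
    """Single-linkage summit clustering across replicates.

    Returns one row per (cluster, replicate) retained peak, with at most
    one peak per replicate per cluster (the peak nearest the cluster
    median summit wins).
    """
    if summit_window_bp < 0:
        raise ValueError("summit window must be non-negative")
    frames = []
    for ri, rep in enumerate(replicates):
        if len(rep) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": rep.df["chrom"],
                    "start": rep.df["start"],
                    "end": rep.df["end"],
                    "summit": rep.summits(),
                    "replicate": ri,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "summit", "replicate", "cluster"]
        )
    allp = pd.concat(frames, ignore_index=True)
    allp = allp.sort_values(
        ["chrom", "summit", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
    cluster_ids = np.zeros(len(allp), dtype=np.int64)
    cid = -1
    prev_chrom, prev_summit = None, None
    for i, (chrom, summit) in enumerate(zip(allp["chrom"], allp["summit"])):
        # boundary at exactly the window still joins the chain (inclusive)
        if chrom != prev_chrom or summit - prev_summit > summit_window_bp:
            cid += 1
        cluster_ids[i] = cid
        prev_chrom, prev_summit = chrom, summit
    allp["cluster"] = cluster_ids
    # nearest-to-median dedup within (cluster, replicate)
    med = allp.groupby("cluster")["summit"].transform("median")
    allp["_dist"] = (allp["summit"] - med).abs()
    allp = allp.sort_values(
        ["cluster", "replicate", "_dist", "summit"], kind="mergesort"
    )
    allp = allp.drop_duplicates(["cluster", "replicate"], keep="first")
    return allp.drop(columns="_dist").sort_values(
        ["cluster", "replicate"], kind="mergesort"
    ).reset_index(drop=True)


def consensus_presence(
    replicates: Sequence[RegionSet],
    min_support: int = 2,
    summit_window_bp: int = 250,
) -> tuple[RegionSet, pd.DataFrame]:
    """Consensus peaks supported by at least ``min_support`` replicates.

    Peaks from all replicates are clustered by summit proximity
    (single-linkage per chromosome, gaps <= ``summit_window_bp`` join a
    cluster; at most one peak per replicate per cluster).  A cluster is
    *present* if it holds peaks from >= ``min_support`` distinct
    replicates; its consensus interval is the merged span of its member
    peaks.  Also returns the full cluster x replicate presence matrix.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(replicates) < min_support:
        raise ValueError("need at least min_support replicates")
    scaffold = _cluster_scaffold(replicates, summit_window_bp)
    n_rep = len(replicates)
    if len(scaffold) == 0:
        presence = pd.DataFrame(columns=list(range(n_rep)), dtype=bool)
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end"])), presence
    presence = (
        scaffold.assign(v=True)
        .pivot_table(index="cluster", columns="replicate", values="v", fill_value=False, aggfunc="any")
        .reindex(columns=range(n_rep), fill_value=False)
        .astype(bool)
    )
    support = presence.sum(axis=1)
    spans = scaffold.groupby("cluster").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    spans["support"] = support
    keep = spans[support >= min_support].reset_index(drop=True)
    consensus = RegionSet(keep[["chrom", "start", "end", "support"]]).sort()
    return consensus, presence


def differential_presence(
    group_a: Sequence[RegionSet],
    group_b: Sequence[RegionSet],
    min_support: int = 2,
    summit_window_bp: int = 250,
) -> tuple[RegionSet, RegionSet]:
    """Emerging and vanishing peaks between two replicate groups.

    All replicates of both groups are clustered on one shared summit
    scaffold; presence within each group follows the >= ``min_support``
    rule (< ``min_support`` means absent).  *Emerging* peaks are present
    in B and absent in A; *vanishing* peaks are present in A and absent
    in B.
    """
    for grp, label in ((group_a, "A"), (group_b, "B")):
        if len(grp) < min_support:
            raise ValueError(f"group {label} needs >= min_support replicates")
    replicates = list(group_a) + list(group_b)
    scaffold = _cluster_scaffold(replicates, summit_window_bp)
    empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    if len(scaffold) == 0:
        return empty, empty
    n_a = len(group_a)
    scaffold["group"] = np.where(scaffold["replicate"] < n_a, "A", "B")
    support = (
        scaffold.groupby(["cluster", "group"])["replicate"].nunique().unstack(fill_value=0)
    )
    for g in ("A", "B"):
        if g not in support.columns:
            support[g] = 0
    present_a = support["A"] >= min_support
    present_b = support["B"] >= min_support
    spans = scaffold.groupby("cluster").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )

    def _subset(mask: pd.Series) -> RegionSet:
        sel = spans[mask.reindex(spans.index, fill_value=False)]
        if len(sel) == 0:
            return empty
        return RegionSet(sel.reset_index(drop=True)).sort()

    emerging = _subset(present_b & ~present_a)
    vanishing = _subset(present_a & ~present_b)
    return emerging, vanishing


def annotation_ztest(
    observed: Mapping[str, int],
    randomized: Mapping[str, Sequence[int]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided z-test of observed annotation counts vs randomized ones.

    For each annotation, the expected distribution comes from repeated
    region randomizations (10 in the original procedure); the observed
    count is assumed to share the randomized standard deviation, giving
    z = (observed - mean) / sd with the sample (ddof=1) sd, and a
    one-sided normal p (upper tail for enrichment, lower for depletion).
    A zero randomized sd flags the row degenerate, with p floored at
    1/(n_randomizations + 1).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rows = []
    for annot, obs in observed.items():
        rand = np.asarray(randomized[annot], dtype=float)
        if rand.size < 2:
            raise ValueError(f"annotation {annot!r} needs >= 2 randomizations")
        mean = float(rand.mean())
        sd = float(rand.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            diff = obs - mean
            if diff == 0:
                z, p = 0.0, 0.5
            else:
                z = float(np.copysign(np.inf, diff))
                favored = (diff > 0) == (alternative == "greater")
                floor = 1.0 / (rand.size + 1)
                p = floor if favored else 1.0 - floor
        else:
            z = float((obs - mean) / sd)
            p = float(stats.norm.sf(z) if alternative == "greater" else stats.norm.cdf(z))
        rows.append(
            {
                "annotation": annot,
                "observed": obs,
                "expected_mean": mean,
                "expected_sd": sd,
                "z": z,
                "p": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def annotate_to_tss(
    peaks: RegionSet,
    tss_table: pd.DataFrame,
    window_bp: int = 3000,
    q_max: float | None = 1e-5,
    name: str = "tss_annotated",
):
    """Genes whose TSS lies within ``window_bp`` of a kept peak summit.

    Peaks are first filtered to ``qvalue < q_max`` (strict; q exactly at
    the threshold is excluded); a missing ``qvalue`` column with a q
    filter requested is a schema error.  A gene is returned iff some kept
    peak's summit (midpoint when no summit is recorded) lies within the
    closed window [tss - window_bp, tss + window_bp], strand-independent.
    """
    from restquant.geneset_stats import GeneSet

    missing = {"gene", "chrom", "tss"} - set(tss_table.columns)
    if missing:
        raise KeyError(f"TSS table missing columns {sorted(missing)}")
    df = peaks.df
    if q_max is not None:
        if "qvalue" not in df.columns:
            raise KeyError("peaks carry no q-values but a q_max filter was requested")
        df = df[df["qvalue"].to_numpy(dtype=float) < q_max]
    kept = RegionSet(df) if len(df) else None
    genes: set[str] = set()
    if kept is not None:
        pos_by_chrom = {
            chrom: np.sort(kept.summits()[kept.df["chrom"].to_numpy() == chrom])
            for chrom in kept.df["chrom"].unique()
        }
        for row in tss_table.itertuples(index=False):
            positions = pos_by_chrom.get(str(row.chrom))
            if positions is None:
                continue
            lo = np.searchsorted(positions, row.tss - window_bp, side="left")
            hi = np.searchsorted(positions, row.tss + window_bp, side="right")
            if hi > lo:
                genes.add(str(row.gene))
    return GeneSet(name, genes) if genes else GeneSet(name, [])
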