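"""Gene-set overlap statistics over a protein-coding background.

Two-set overlaps are tested with the upper-tail hypergeometric
probability P(X >= k).  Three-set overlaps are tested by permutation:
three sets of the observed sizes are drawn uniformly without replacement
from the universe, the triple-intersection size is recorded, and the
add-one-corrected upper-tail p-value is reported (10,000 permutations by
default).  Enrichment against a term library is per-term hypergeometric
with Benjamini-Hochberg FDR, and two enrichment analyses can be
meta-combined by intersecting their significant terms and applying
Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from restquant._common import PermutationResult, summarize_permutations

__all__ = [
    "GeneUniverse",
    "GeneSet",
    "MembershipError",
    "PermutationResult",
    "hypergeometric_overlap",
    "permutation_triple_overlap",
    "enrich",
    "combine_enrichment",
    "select_upregulated",
    "read_gene_list",
    "read_gmt",
]


class MembershipError(ValueError):
    """A gene set contains identifiers outside the bound universe."""


def _normalize_ids(ids: Iterable[str], uppercase: bool) -> frozenset[str]:
    out = frozenset(str(g).upper() if uppercase else str(g) for g in ids)
    if any(not g for g in out):
        raise ValueError("empty gene identifier")
    return out


@dataclass(frozen=True)
class GeneUniverse:
    """The background identifier set (e.g. all human protein-coding symbols).

    Matching is exact and case-sensitive; pass ``uppercase=True`` to map
    symbols to upper case on construction (the convention for human HGNC
    symbols).
    """

    identifiers: frozenset[str]

    def __init__(self, identifiers: Iterable[str], uppercase: bool = False):
        ids = _normalize_ids(identifiers, uppercase)
        if not ids:
            raise ValueError("universe must be non-empty")
        object.__setattr__(self, "identifiers", ids)

    def __len__(self) -> int:
        return len(self.identifiers)

    def __contains__(self, gene: str) -> bool:
        return gene in self.identifiers


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str], uppercase: bool = False):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "members", _normalize_ids(members, uppercase))

    def __len__(self) -> int:
        return len(self.members)


def _check_membership(gene_set: GeneSet, universe: GeneUniverse) -> None:
    stray = gene_set.members - universe.identifiers
    if stray:
        example = sorted(stray)[:3]
        raise MembershipError(
            f"set {gene_set.name!r} has {len(stray)} identifiers outside the "
            f"universe (e.g. {example})"
        )


def hypergeometric_overlap(
    set_a: GeneSet, set_b: GeneSet, universe: GeneUniverse
) -> float:
    """Upper-tail hypergeometric p-value for a two-set overlap.

    With ``N = |universe|``, ``a = |A|`` successes and ``b = |B|`` draws,
    returns ``P(X >= k)`` for the observed intersection size ``k``.
    """
    _check_membership(set_a, universe)
    _check_membership(set_b, universe)
    n = len(universe)
    k = len(set_a.members & set_b.members)
    return float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))


def permutation_triple_overlap(
    sets: Sequence[GeneSet],
    universe: GeneUniverse,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test for a three-set intersection.

    The null draws three sets of the observed sizes uniformly without
    replacement from the universe and records the triple-intersection
    size.  Drawing the sets independently is equivalent, in distribution,
    to chaining two hypergeometric draws — |A'∩B'| ~ HG(N, a, b) and then
    |A'∩B'∩C'| ~ HG(N, |A'∩B'|, c) — which is how the null is sampled
    here (vectorized, one pair of draws per permutation).

    Ties in the permutation counts are counted as >= observed (inclusive)
    and the add-one correction keeps p >= 1/(n_perm+1).
    """
    if len(sets) != 3:
        raise ValueError("exactly three gene sets are required")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for s in sets:
        _check_membership(s, universe)
        if len(s) > len(universe):
            raise ValueError(f"set {s.name!r} larger than the universe")
    n = len(universe)
    a, b, c = (len(s) for s in sets)
    observed = len(sets[0].members & sets[1].members & sets[2].members)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k_ab = rng.hypergeometric(a, n - a, b, size=n_perm) if min(a, b) > 0 else np.zeros(n_perm, dtype=int)
    if c > 0:
        k_abc = rng.hypergeometric(k_ab, n - k_ab, c)
    else:
        k_abc = np.zeros(n_perm, dtype=int)
    return summarize_permutations(observed, k_abc)


def enrich(
    query: GeneSet,
    library: Sequence[GeneSet],
    universe: GeneUniverse,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set against a term library.

    Returns one row per term with the overlap size, term/query/universe
    sizes, the upper-tail p-value and the Benjamini-Hochberg FDR across
    all terms, sorted by (p, term) for determinism.
    """
    if len(library) == 0:
        raise ValueError("term library must be non-empty")
    _check_membership(query, universe)
    rows = []
    for term in library:
        _check_membership(term, universe)
        k = len(query.members & term.members)
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(term), len(query))
        )
        rows.append(
            {
                "term": term.name,
                "overlap_k": k,
                "term_size": len(term),
                "query_size": len(query),
                "universe_size": len(universe),
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return table


def combine_enrichment(
    enrich_a: pd.DataFrame,
    enrich_b: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "fisher",
) -> pd.DataFrame:
    """Meta-combine two enrichment tables over a shared term namespace.

    Terms must pass ``fdr < alpha`` in *both* tables (the intersection
    rule); surviving terms get a combined p-value by Fisher's method
    (X² = −2(ln pA + ln pB), df = 4) or, optionally, Stouffer's method.
    Zero p-values are floored at the smallest positive float.  An empty
    intersection yields a valid empty table.
    """
    for tbl, label in ((enrich_a, "A"), (enrich_b, "B")):
        missing = {"term", "p", "fdr"} - set(tbl.columns)
        if missing:
            raise ValueError(f"enrichment table {label} missing columns {sorted(missing)}")
    sig_a = enrich_a.loc[enrich_a["fdr"] < alpha, ["term", "p", "fdr"]]
    sig_b = enrich_b.loc[enrich_b["fdr"] < alpha, ["term", "p", "fdr"]]
    merged = sig_a.merge(sig_b, on="term", suffixes=("_a", "_b"))
    tiny = np.finfo(float).tiny
    p_a = np.maximum(merged["p_a"].to_numpy(dtype=float), tiny)
    p_b = np.maximum(merged["p_b"].to_numpy(dtype=float), tiny)
    if method == "fisher":
        x2 = -2.0 * (np.log(p_a) + np.log(p_b))
        merged["statistic"] = x2
        merged["combined_p"] = stats.chi2.sf(x2, df=4)
    elif method == "stouffer":
        z = (stats.norm.isf(p_a) + stats.norm.isf(p_b)) / np.sqrt(2.0)
        merged["statistic"] = z
        merged["combined_p"] = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    merged = merged.sort_values(["combined_p", "term"], kind="mergesort").reset_index(
        drop=True
    )
    return merged


def select_upregulated(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 1.5,
    name: str = "upregulated",
) -> GeneSet:
    """Filter a differential-expression table to upregulated genes.

    Keeps genes with ``padj < padj_max`` AND ``log2fc > lfc_min``; both
    inequalities are strict, so boundary rows (padj exactly 0.05 or
    log2FC exactly 1.5) are excluded.
    """
    missing = {"gene", "log2fc", "padj"} - set(table.columns)
    if missing:
        raise KeyError(f"DE table missing columns {sorted(missing)}")
    padj = table["padj"].to_numpy(dtype=float)
    if np.any((padj < 0) | (padj > 1)):
        raise ValueError("padj values must lie in [0, 1]")
    keep = (padj < padj_max) & (table["log2fc"].to_numpy(dtype=float) > lfc_min)
    return GeneSet(name, table.loc[keep, "gene"].astype(str))


def read_gene_list(path, name: str | None = None, uppercase: bool = False) -> GeneSet:
    """Read a one-identifier-per-line gene set."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSet(name or path.stem, genes, uppercase=uppercase)


def read_gmt(path, uppercase: bool = False) -> list[GeneSet]:
    """Read a GMT term library (term, description, members...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets.append(GeneSet(parts[0], parts[2:], uppercase=uppercase))
    return sets


def write_gene_list(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")
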