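"""Anchor-vs-candidate expression correlation across brain structures.

Each sample (donor brain) contributes a genes x structures expression
matrix; for an anchor gene (SIRT6 in the motivating analysis) the Pearson
correlation with each candidate transcription factor is computed per
sample across structures, and the resulting sample x target R table is
hierarchically clustered for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


def per_sample_correlation(
    matrices: Mapping[str, pd.DataFrame],
    anchor: str,
    targets: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson R (and two-sided p) of anchor vs each target, per sample.

    ``matrices`` maps sample id -> genes x structures DataFrame.  For each
    correlation, structures where either profile is missing are dropped
    pairwise (microarray panels differ per brain); fewer than 3 shared
    structures, or a zero-variance profile, yields NaN for that cell.
    Returns (r_table, p_table), both sample x target.
    """
    r_rows, p_rows = {}, {}
    for sample, mat in matrices.items():
        if anchor not in mat.index:
            raise KeyError(f"anchor {anchor!r} missing from sample {sample!r}")
        a = mat.loc[anchor].to_numpy(dtype=float)
        r_row, p_row = {}, {}
        for target in targets:
            if target not in mat.index:
                raise KeyError(f"target {target!r} missing from sample {sample!r}")
            t = mat.loc[target].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(t)
            if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(t[ok]) == 0:
                r_row[target], p_row[target] = np.nan, np.nan
            else:
                res = stats.pearsonr(a[ok], t[ok])
                r_row[target], p_row[target] = float(res.statistic), float(res.pvalue)
        r_rows[sample] = r_row
        p_rows[sample] = p_row
    index = list(matrices)
    r_table = pd.DataFrame.from_dict(r_rows, orient="index").reindex(
        index=index, columns=list(targets)
    )
    p_table = pd.DataFrame.from_dict(p_rows, orient="index").reindex(
        index=index, columns=list(targets)
    )
    return r_table, p_table


@dataclass(frozen=True)
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def _linkage_order(data: np.ndarray, labels: Sequence) -> tuple[list, np.ndarray | None]:
    if data.shape[0] < 2:
        return list(labels), None
    link = hierarchy.linkage(data, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return [labels[i] for i in leaves], link


def cluster_correlations(r_table: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of the correlation table.

    Samples (rows) and targets (columns) are clustered independently with
    average linkage on Euclidean distances of their R vectors.  Rows and
    columns are pre-sorted by label so ties break deterministically by
    label order regardless of input ordering.  Requires finite R values.
    """
    if not np.all(np.isfinite(r_table.to_numpy(dtype=float))):
        raise ValueError("correlation table contains non-finite values")
    tbl = r_table.sort_index(axis=0).sort_index(axis=1)
    row_order, row_link = _linkage_order(tbl.to_numpy(dtype=float), list(tbl.index))
    col_order, col_link = _linkage_order(tbl.to_numpy(dtype=float).T, list(tbl.columns))
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def read_long_expression(path) -> dict[str, pd.DataFrame]:
    """Read a long-format TSV (sample, gene, structure, value) into matrices."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "gene", "structure", "value"} - set(df.columns)
    if missing:
        raise KeyError(f"expression table missing columns {sorted(missing)}")
    out = {}
    for sample, grp in df.groupby("sample", sort=True):
        out[str(sample)] = grp.pivot_table(
            index="gene", columns="structure", values="value"
        )
    return out


def write_long_expression(matrices: Mapping[str, pd.DataFrame], path) -> None:
    frames = []
    for sample, mat in matrices.items():
        long = mat.stack().rename("value").reset_index()
        long.columns = ["gene", "structure", "value"]
        long.insert(0, "sample", sample)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
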