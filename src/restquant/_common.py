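"""Shared result containers for permutation-style tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic against a permutation null.

    ``p`` uses the add-one correction ``(1 + #{perm >= obs}) / (n_perm + 1)``
    so it can never be 0; ``z`` standardizes the observed value against the
    permutation distribution.  When the null distribution is constant
    (``perm_sd == 0``) the result is flagged ``degenerate`` and ``z`` is
    ``+/-inf`` with the sign of ``observed - perm_mean`` (0 when equal).
    """

    observed: float
    perm_mean: float
    perm_sd: float
    n_perm: int
    p: float
    z: float
    degenerate: bool = False


def summarize_permutations(observed: float, perm_values: np.ndarray) -> PermutationResult:
    """Build a :class:`PermutationResult` from null samples (upper tail)."""
    perm = np.asarray(perm_values, dtype=float)
    n_perm = perm.size
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    p = float((1 + np.count_nonzero(perm >= observed)) / (n_perm + 1))
    mean = float(perm.mean())
    sd = float(perm.std(ddof=1)) if n_perm > 1 else 0.0
    if sd == 0.0:
        diff = observed - mean
        z = 0.0 if diff == 0 else float(np.copysign(np.inf, diff))
        return PermutationResult(
            observed=float(observed), perm_mean=mean, perm_sd=sd,
            n_perm=n_perm, p=p, z=z, degenerate=True,
        )
    z = float((observed - mean) / sd)
    return PermutationResult(
        observed=float(observed), perm_mean=mean, perm_sd=sd,
        n_perm=n_perm, p=p, z=z,
    )
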