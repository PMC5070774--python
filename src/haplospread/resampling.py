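"""Bootstrap comparison of within- vs between-group mean pairwise divergence.

The procedure fixes the observed pairwise p-distance matrix and resamples
*individuals* with replacement, independently within each group and at the
original group sizes.  For each replicate it recomputes the mean
cross-individual distance of a "within" pair of groups (the two focal
haplogroups) and of a "between" pair (one haplogroup against the sister
species), and counts how often the within-pair mean is equal to or greater
than the between-pair mean.  The reported p is that count over the number
of replicates; it is descriptive, not a calibrated test statistic, because
individuals that share a recent coalescent event are pseudoreplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import InputError
from .popgen import DistanceMatrix

__all__ = ["BootstrapResult", "bootstrap_divergence_comparison"]


@dataclass(frozen=True)
class BootstrapResult:
    n_boot: int
    count_ge: int      # replicates with mean within-divergence >= between
    p: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "count_ge": self.count_ge,
            "p": self.p,
            "seed": self.seed,
        }


def _check_group(dm: DistanceMatrix, ids, name: str) -> tuple[str, ...]:
    ids = tuple(ids)
    if len(ids) < 2:
        raise InputError(f"group {name} needs at least 2 members")
    unknown = [i for i in ids if i not in dm.ids]
    if unknown:
        raise InputError(f"group {name} ids not in distance matrix: {unknown}")
    return ids


def bootstrap_divergence_comparison(
    dm: DistanceMatrix,
    group_within: tuple,
    group_between: tuple,
    n_boot: int = 1_000_000,
    seed: int | None = None,
    batch: int = 50_000,
) -> BootstrapResult:
    """Count resamples where mean d(A,B) ≥ mean d(X,sister).

    ``group_within = (A_ids, B_ids)`` and ``group_between = (X_ids,
    sister_ids)``; all four may share members only where X *is* A or B
    (compared by identical id tuples) — otherwise groups must be disjoint.
    Each distinct group is resampled once per replicate, so a group
    appearing in both comparisons uses the same resample in both means.
    Deterministic for a fixed seed.

    The resample-with-replacement of ids is realised as a multinomial draw
    of per-id counts; the mean distance of a replicate is the
    count-weighted average of the fixed matrix entries, which is exactly
    the mean over the resampled id lists.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    if seed is None:
        raise InputError("a seed is required for reproducibility")
    a_ids = _check_group(dm, group_within[0], "A")
    b_ids = _check_group(dm, group_within[1], "B")
    x_ids = _check_group(dm, group_between[0], "X")
    s_ids = _check_group(dm, group_between[1], "sister")

    groups: list[tuple[str, ...]] = []
    for g in (a_ids, b_ids, x_ids, s_ids):
        if g not in groups:
            groups.append(g)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if set(groups[i]) & set(groups[j]):
                raise InputError("distinct groups must be disjoint")

    d_ab = dm.submatrix(list(a_ids), list(b_ids))
    d_xs = dm.submatrix(list(x_ids), list(s_ids))
    rng = np.random.default_rng(seed)
    which = [groups.index(g) for g in (a_ids, b_ids, x_ids, s_ids)]

    count_ge = 0
    done = 0
    while done < n_boot:
        r = min(batch, n_boot - done)
        # one multinomial count matrix per distinct group, in a fixed order
        counts = [
            rng.multinomial(len(g), np.full(len(g), 1.0 / len(g)), size=r)
            for g in groups
        ]
        ca, cb = counts[which[0]], counts[which[1]]
        cx, cs = counts[which[2]], counts[which[3]]
        mean_ab = np.einsum("ri,ij,rj->r", ca, d_ab, cb) / (len(a_ids) * len(b_ids))
        mean_xs = np.einsum("ri,ij,rj->r", cx, d_xs, cs) / (len(x_ids) * len(s_ids))
        count_ge += int((mean_ab >= mean_xs).sum())
        done += r
    return BootstrapResult(
        n_boot=n_boot, count_ge=count_ge, p=count_ge / n_boot, seed=seed
    )
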