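"""Pairwise linkage-disequilibrium scan with Fisher's exact test.

Every pair of polymorphic columns is cross-tabulated over the sequences
non-missing at both columns and tested with a two-tailed Fisher exact test.
P-values are binned into the figure-style significance tiers
``ns / p<0.05 / p<0.005 / p<0.0005`` with strict thresholds (p = 0.05
exactly is not significant).  No multiple-testing correction is applied —
the tiers display raw p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, InputError, extract_polymorphic_sites
from .popgen import fisher_exact_2x2

__all__ = ["LDMatrix", "TIER_NAMES", "ld_fisher_scan"]

logger = logging.getLogger(__name__)

#: tier codes 0..3 in order of increasing significance
TIER_NAMES = ("ns", "p<0.05", "p<0.005", "p<0.0005")
_THRESHOLDS = (0.05, 0.005, 0.0005)


def tier_of(p: float) -> int:
    """Strict-inequality tier code for a p-value (NaN → 0)."""
    if not np.isfinite(p):
        return 0
    t = 0
    for k, thr in enumerate(_THRESHOLDS, start=1):
        if p < thr:
            t = k
    return t


@dataclass(frozen=True)
class LDMatrix:
    """Symmetric matrix of pairwise-association p-values and tiers.

    ``sites`` are 1-based alignment columns; the diagonal is NaN/0 and a
    pair left untestable (one site monomorphic among their shared
    sequences) is NaN with tier 0.
    """

    sites: tuple[int, ...]
    p: np.ndarray
    tier: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site\t" + "\t".join(map(str, self.sites)) + "\n")
            for i, s in enumerate(self.sites):
                row = "\t".join(
                    "na" if not np.isfinite(v) else f"{v:.6g}" for v in self.p[i]
                )
                fh.write(f"{s}\t{row}\n")

    def tier_heatmap(self) -> np.ndarray:
        """Integer tier matrix ({0,1,2,3}) for plotting."""
        return self.tier.copy()


def _reduce_biallelic(col: np.ndarray, present: np.ndarray) -> np.ndarray | None:
    """Boolean major-allele indicator over present calls, or None if the
    column is monomorphic after reduction to its two most frequent alleles
    (count ties broken by alphabetical allele order)."""
    alleles, counts = np.unique(col[present], return_counts=True)
    if alleles.size < 2:
        return None
    # sort by (-count, allele) so the two most frequent, tie→alphabetical, lead
    order = np.lexsort((alleles, -counts))
    top2 = alleles[order[:2]]
    keep = present & np.isin(col, top2)
    return np.where(keep, col == top2[0], False), keep


def ld_fisher_scan(aln: Alignment, sites: list[int] | None = None) -> LDMatrix:
    """Scan all pairs of polymorphic sites for allelic association.

    *sites* (1-based columns) defaults to every polymorphic column under
    pairwise deletion.  Multi-allelic columns are collapsed to their two
    most frequent alleles; sequences missing (or carrying a dropped minor
    allele) at either site of a pair are excluded for that pair only.
    """
    if sites is None:
        sites = [c for c, _ in extract_polymorphic_sites(aln, "pairwise")]
    if len(sites) < 2:
        raise InputError("LD scan needs at least 2 polymorphic sites")
    miss = aln.missing_mask()

    reduced: list[tuple[int, np.ndarray, np.ndarray]] = []
    for c in sites:
        col = aln.matrix[:, c - 1]
        present = ~miss[:, c - 1]
        r = _reduce_biallelic(col, present)
        if r is None:
            logger.warning("site %d monomorphic after reduction; excluded", c)
            continue
        reduced.append((c, r[0], r[1]))

    k = len(reduced)
    if k < 2:
        raise InputError("fewer than 2 usable sites after biallelic reduction")
    p = np.full((k, k), np.nan)
    tier = np.zeros((k, k), dtype=np.int8)
    for i in range(k):
        _, ai, oki = reduced[i]
        for j in range(i + 1, k):
            _, aj, okj = reduced[j]
            ok = oki & okj
            table = np.array(
                [
                    [(ai & aj & ok).sum(), (ai & ~aj & ok).sum()],
                    [(~ai & aj & ok).sum(), (~ai & ~aj & ok).sum()],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                logger.warning(
                    "sites %d/%d untestable (zero margin after pairwise deletion)",
                    reduced[i][0],
                    reduced[j][0],
                )
                continue
            pij = fisher_exact_2x2(table)
            p[i, j] = p[j, i] = pij
            tier[i, j] = tier[j, i] = tier_of(pij)
    return LDMatrix(tuple(c for c, _, _ in reduced), p, tier)
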