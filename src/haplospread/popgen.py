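"""Core population-genetic statistics on alignments.

All statistics are uncorrected (p-distance based); no substitution-model
correction is applied.  Missing data (``N`` or ``-``) is handled by a *site
policy*:

``"complete"``
    complete deletion — any column with a gap/N anywhere in the analysis set
    is excluded globally, so every pair is compared over the same columns;
``"pairwise"``
    pairwise deletion — each pair is compared over its mutually non-missing
    columns.

Within-group diversity (π), between-group absolute divergence (Dxy) and net
divergence (Da = Dxy − (πX+πY)/2) are mean pairwise p-distances; Tajima's D
contrasts the mean pairwise difference count with the segregating-sites
estimator of θ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .alignment import Alignment, InputError

__all__ = [
    "DistanceMatrix",
    "DiversityStats",
    "DivergenceSummary",
    "SiteLabel",
    "classify_sites",
    "da",
    "divergence_summary",
    "dxy",
    "fisher_exact_2x2",
    "nucleotide_diversity",
    "pairwise_distances",
    "tajimas_d",
]


def _matrix_and_missing(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    return aln.matrix, aln.missing_mask()


def _complete_columns(*alns: Alignment) -> np.ndarray:
    """0-based indices of columns free of gaps/N across every alignment given."""
    lengths = {a.length for a in alns}
    if len(lengths) != 1:
        raise InputError("alignments must share the same length")
    missing_any = np.zeros(alns[0].length, dtype=bool)
    for a in alns:
        missing_any |= a.missing_mask().any(axis=0)
    return np.nonzero(~missing_any)[0]


# ---------------------------------------------------------------------------
# Pairwise distances and diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Proportion of differing compared sites for every sequence pair."""

    ids: tuple[str, ...]
    d: np.ndarray          # (n, n) float, symmetric, zero diagonal
    compared: np.ndarray   # (n, n) int, sites compared per pair

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = [self.ids.index(r) for r in rows]
        ci = [self.ids.index(c) for c in cols]
        return self.d[np.ix_(ri, ci)]


def pairwise_distances(aln: Alignment, site_policy: str = "complete") -> DistanceMatrix:
    """p-distance matrix over all sequence pairs under the site policy."""
    if aln.n_seqs < 2:
        raise InputError("need at least 2 sequences")
    m, miss = _matrix_and_missing(aln)
    if site_policy == "complete":
        cols = _complete_columns(aln)
        if cols.size == 0:
            raise InputError("no columns survive complete deletion")
        sub = m[:, cols]
        diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        compared = np.full(diff.shape, cols.size, dtype=np.int64)
        d = diff / cols.size
    elif site_policy == "pairwise":
        ok = ~miss
        compared = (ok[:, None, :] & ok[None, :, :]).sum(axis=2)
        neq = ((m[:, None, :] != m[None, :, :]) & ok[:, None, :] & ok[None, :, :]).sum(axis=2)
        zero = (compared == 0) & ~np.eye(aln.n_seqs, dtype=bool)
        if zero.any():
            i, j = map(int, np.argwhere(zero)[0])
            raise InputError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        with np.errstate(invalid="ignore"):
            d = np.where(compared > 0, neq / np.maximum(compared, 1), 0.0)
    else:
        raise InputError(f"unknown site policy {site_policy!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.ids, d, compared)


def nucleotide_diversity(group: Alignment, site_policy: str = "complete") -> float:
    """π: mean pairwise p-distance among all C(n,2) pairs within a group."""
    if group.n_seqs < 2:
        raise InputError("π requires at least 2 sequences")
    dm = pairwise_distances(group, site_policy)
    iu = np.triu_indices(group.n_seqs, k=1)
    return float(dm.d[iu].mean())


def dxy(x: Alignment, y: Alignment, site_policy: str = "complete") -> float:
    """Absolute divergence: mean p-distance over all between-group pairs."""
    return divergence_summary(x, y, site_policy).dxy


def da(x: Alignment, y: Alignment, site_policy: str = "complete") -> float:
    """Net divergence: Dxy − (πX + πY)/2 (π of a singleton group is 0)."""
    return divergence_summary(x, y, site_policy).da


# ---------------------------------------------------------------------------
# Site classification and the two-group divergence summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteLabel:
    """Classification of one variable column in a two-group comparison."""

    column: int                  # 1-based alignment column
    label: str                   # fixed | shared | private_x | private_y
    alleles_x: tuple[str, ...]
    alleles_y: tuple[str, ...]


@dataclass(frozen=True)
class DivergenceSummary:
    """π, Dxy, Da and fixed/shared/private site counts for a group pair.

    All quantities are computed on the same complete-deletion column set of
    the combined sample, so ``da == dxy - (pi_x + pi_y) / 2`` holds exactly.
    """

    pi_x: float
    pi_y: float
    dxy: float
    da: float
    fixed: int
    shared: int
    private_x: int
    private_y: int
    n_sites: int
    site_labels: tuple[SiteLabel, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "pi_x": self.pi_x,
            "pi_y": self.pi_y,
            "dxy": self.dxy,
            "da": self.da,
            "fixed": self.fixed,
            "shared": self.shared,
            "private_x": self.private_x,
            "private_y": self.private_y,
            "n_sites": self.n_sites,
        }


def _mean_pairwise_within(sub: np.ndarray, n_sites: int) -> float:
    n = sub.shape[0]
    if n < 2:
        return 0.0
    diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    return float(diff[iu].mean() / n_sites)


def divergence_summary(
    x: Alignment, y: Alignment, site_policy: str = "complete"
) -> DivergenceSummary:
    """Full two-group comparison on a shared column set.

    Under the default complete-deletion policy the column set excludes any
    column with missing data in *either* group; under pairwise deletion the
    pairwise distances honour per-pair columns but site classification still
    requires at least one non-missing call per group.
    """
    if x.n_seqs == 0 or y.n_seqs == 0:
        raise InputError("both groups must be non-empty")
    if x.length != y.length:
        raise InputError("groups must come from the same alignment length")
    if site_policy != "complete":
        raise InputError("divergence_summary supports the complete-deletion policy")
    cols = _complete_columns(x, y)
    if cols.size == 0:
        raise InputError("no columns survive complete deletion")
    mx = x.matrix[:, cols]
    my = y.matrix[:, cols]
    n_sites = cols.size

    pi_x = _mean_pairwise_within(mx, n_sites)
    pi_y = _mean_pairwise_within(my, n_sites)
    cross = (mx[:, None, :] != my[None, :, :]).sum(axis=2)
    dxy_ = float(cross.mean() / n_sites)
    da_ = dxy_ - (pi_x + pi_y) / 2.0

    labels: list[SiteLabel] = []
    counts = {"fixed": 0, "shared": 0, "private_x": 0, "private_y": 0}
    for k in range(n_sites):
        ax = np.unique(mx[:, k])
        ay = np.unique(my[:, k])
        if ax.size == 1 and ay.size == 1 and ax[0] == ay[0]:
            continue  # invariant column
        overlap = np.intersect1d(ax, ay).size > 0
        if not overlap:
            lab = "fixed"
        elif ax.size > 1 and ay.size > 1:
            lab = "shared"
        elif ax.size > 1:
            lab = "private_x"
        else:
            lab = "private_y"
        counts[lab] += 1
        labels.append(
            SiteLabel(
                column=int(cols[k]) + 1,
                label=lab,
                alleles_x=tuple(chr(a) for a in ax),
                alleles_y=tuple(chr(a) for a in ay),
            )
        )
    return DivergenceSummary(
        pi_x=pi_x,
        pi_y=pi_y,
        dxy=dxy_,
        da=da_,
        fixed=counts["fixed"],
        shared=counts["shared"],
        private_x=counts["private_x"],
        private_y=counts["private_y"],
        n_sites=int(n_sites),
        site_labels=tuple(labels),
    )


def classify_sites(
    x: Alignment, y: Alignment, site_policy: str = "complete"
) -> DivergenceSummary:
    """Alias of :func:`divergence_summary`; the site labels ride along."""
    return divergence_summary(x, y, site_policy)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    """Segregating sites, mean pairwise differences and Tajima's D."""

    n: int
    s: int
    k_hat: float          # mean pairwise difference count (raw counts)
    pi: float             # per-site, over the complete-deletion column set
    n_sites: int
    tajima_d: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(group: Alignment, site_policy: str = "complete") -> DiversityStats:
    """Tajima's D on the group's complete-deletion column set.

    Requires n ≥ 4 and at least one segregating site; k̂ and S are counted
    over the same columns, and multi-allelic columns count once toward S
    while contributing every differing pair to k̂.
    """
    n = group.n_seqs
    if n < 4:
        raise InputError("Tajima's D requires at least 4 sequences")
    cols = _complete_columns(group)
    if cols.size == 0:
        raise InputError("no columns survive complete deletion")
    sub = group.matrix[:, cols]
    seg = np.array([np.unique(sub[:, k]).size > 1 for k in range(sub.shape[1])])
    s = int(seg.sum())
    if s == 0:
        raise InputError("Tajima's D undefined with no segregating sites")
    diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    k_hat = float(diff[iu].mean())
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    d_stat = (k_hat - s / c["a1"]) / np.sqrt(var)
    return DiversityStats(
        n=n,
        s=s,
        k_hat=k_hat,
        pi=k_hat / cols.size,
        n_sites=int(cols.size),
        tajima_d=float(d_stat),
        **c,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2, two-tailed)
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p for a 2×2 count table.

    Two-tailed by the point-probability rule: the p-value sums the
    hypergeometric probabilities of every table with the same margins whose
    probability does not exceed (within relative tolerance 1e-7) that of the
    observed table.  All four margins must be positive.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InputError("Fisher test requires all margins positive")
    # scipy's two-sided convention is the same point-probability rule
    return float(_sps.fisher_exact(t, alternative="two-sided")[1])
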