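"""Synthetic three-species alignments with haplogroup structure.

The generator emulates a short, low-recombination X-linked locus sampled
from a focal species, its sister species and a single outgroup lineage,
under three scenarios:

``neutral``
    independent neutral coalescent samples within each species;
``sweep``
    one focal haplotype has recently spread to intermediate frequency
    within the focal species (a within-species spread: sweep in progress,
    new balanced polymorphism, or similar);
``introgression``
    one *sister* haplotype has recently spread to intermediate frequency
    inside the focal species.

Model, in order of application:

1. an ancestral sequence is drawn uniformly over ``{A,C,G,T}^L``;
2. species-tree substitutions are placed Poisson per branch at
   Jukes-Cantor-style random sites.  All interspecies divergence
   (``t_split``) accrues on the focal terminal branch and the outgroup
   divergence (``t_outgroup``) on the outgroup branch: the locus this
   generator emulates shows essentially every fixed interspecies
   difference polarizing as derived within the focal species, which
   corresponds to a sister lineage that retained the ancestral states;
3. within-species variation comes from a Kingman coalescent per species
   (mutations Poisson with rate ``theta/2`` per lineage per coalescent
   time unit, so a random pair differs at ``theta`` sites in expectation);
4. the scenario transform replaces ``round(f * n_focal)`` focal sequences
   with copies of one source haplotype (focal for ``sweep``, sister for
   ``introgression``), adds Poisson(``epsilon``) private mutations to each
   copy, and injects the diagnostic markers — two 15-bp deletion runs and
   seven SNPs, in complete linkage disequilibrium — onto the copies.

Every mutation (species-branch, coalescent, private) occupies a fresh
column drawn from a single global infinite-sites registry, with marker
columns reserved up front; no column is ever hit twice, so every variable
site is biallelic and polarization against the outgroup is exact.

A fixed seed reproduces the dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import Alignment, IndelMarker, InputError

__all__ = ["SimulationParams", "SimulatedDataset", "simulate"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate the study conditions.

    ``theta`` is the per-locus scaled mutation rate within each species;
    ``t_split`` and ``t_outgroup`` are expected substitutions per site for
    the focal–sister and outgroup divergences; ``f`` is the post-event
    frequency of the spread haplotype among focal samples; ``epsilon`` is
    the expected number of private mutations per spread copy.
    """

    n_focal: int = 37
    n_sister: int = 20
    n_outgroup: int = 1
    length: int = 900
    theta: float = 5.0
    t_split: float = 0.02
    t_outgroup: float = 0.05
    scenario: str = "neutral"
    f: float = 24 / 37
    epsilon: float = 0.1
    indel_spans: tuple[tuple[int, int], ...] = ((151, 165), (451, 465))
    snp_columns: tuple[int, ...] = (120, 240, 330, 420, 560, 680, 800)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("neutral", "sweep", "introgression"):
            raise InputError(f"unknown scenario {self.scenario!r}")
        if not (0.0 < self.f < 1.0):
            raise InputError("f must be in (0, 1)")
        if not (self.t_outgroup > self.t_split > 0):
            raise InputError("need t_outgroup > t_split > 0")
        if min(self.n_focal, self.n_sister, self.n_outgroup, self.length) < 1:
            raise InputError("counts and length must be positive")
        if self.theta < 0 or self.epsilon < 0:
            raise InputError("theta and epsilon must be non-negative")
        for a, b in self.indel_spans:
            if not (1 <= a <= b <= self.length):
                raise InputError(f"indel span {a}..{b} out of bounds")
        for c in self.snp_columns:
            if not (1 <= c <= self.length):
                raise InputError(f"snp column {c} out of bounds")

    @property
    def indel_markers(self) -> tuple[IndelMarker, ...]:
        return tuple(IndelMarker(a, b, "gap_run") for a, b in self.indel_spans)

    @property
    def n_event(self) -> int:
        return int(round(self.f * self.n_focal))


@dataclass(frozen=True)
class SimulatedDataset:
    """Alignment plus ground truth for one simulated locus."""

    alignment: Alignment
    group_of: dict[str, str]        # id -> focal | sister | outgroup
    event_ids: tuple[str, ...]      # focal ids replaced by the spread copies
    source_id: str | None           # haplotype the copies descend from
    params: SimulationParams
    truth: dict = field(default_factory=dict)

    def group(self, name: str) -> Alignment:
        ids = [i for i in self.alignment.ids if self.group_of[i] == name]
        return self.alignment.subset(ids)

    def focal_split(self) -> tuple[Alignment, Alignment]:
        """(event-copy group, untouched focal group) from the truth labels."""
        ev = [i for i in self.alignment.ids if i in set(self.event_ids)]
        anc = [
            i
            for i in self.alignment.ids
            if self.group_of[i] == "focal" and i not in set(self.event_ids)
        ]
        return self.alignment.subset(ev), self.alignment.subset(anc)


class _SiteRegistry:
    """Draws fresh 0-based columns without replacement (infinite sites)."""

    def __init__(self, length: int, reserved: np.ndarray, rng: np.random.Generator):
        self._free = np.nonzero(~reserved)[0]
        self._rng = rng

    def draw(self, k: int) -> np.ndarray:
        if k > self._free.size:
            raise InputError(
                "locus too short for the requested mutation load "
                "(infinite-sites registry exhausted)"
            )
        pick = self._rng.choice(self._free.size, size=k, replace=False)
        cols = self._free[pick]
        self._free = np.delete(self._free, pick)
        return cols


def _mutate(seq: np.ndarray, cols: np.ndarray, rng: np.random.Generator) -> None:
    """Substitute each column for a uniform different base, in place."""
    for j in cols:
        cur = seq[j]
        choices = _BASES[_BASES != cur]
        seq[j] = rng.choice(choices)


def _coalescent_sample(
    founder: np.ndarray,
    n: int,
    theta: float,
    registry: _SiteRegistry,
    rng: np.random.Generator,
) -> np.ndarray:
    """n sequences from a Kingman coalescent rooted at *founder*.

    Mutations are Poisson(theta/2 × branch length) per lineage, each at a
    fresh site, applied to every leaf the lineage subtends.
    """
    seqs = np.tile(founder, (n, 1))
    if n < 2 or theta == 0:
        return seqs
    lineages: list[list[int]] = [[i] for i in range(n)]
    while len(lineages) > 1:
        k = len(lineages)
        t = rng.exponential(2.0 / (k * (k - 1)))
        for leaf_set in lineages:
            m = rng.poisson(theta / 2.0 * t)
            if m:
                cols = registry.draw(m)
                for j in cols:
                    cur = founder[j]
                    new = rng.choice(_BASES[_BASES != cur])
                    seqs[leaf_set, j] = new
        i, j = rng.choice(k, size=2, replace=False)
        a, b = sorted((int(i), int(j)))
        merged = lineages[a] + lineages[b]
        lineages = [
            ln for idx, ln in enumerate(lineages) if idx not in (a, b)
        ] + [merged]
    return seqs


def simulate(params: SimulationParams, seed: int | None = None) -> SimulatedDataset:
    """Generate one dataset; *seed* overrides ``params.seed`` when given."""
    seed = params.seed if seed is None else seed
    if seed is None:
        raise InputError("a seed is required")
    params = replace(params, seed=seed)
    rng = np.random.default_rng(seed)
    L = params.length

    reserved = np.zeros(L, dtype=bool)
    for a, b in params.indel_spans:
        reserved[a - 1 : b] = True
    for c in params.snp_columns:
        if reserved[c - 1]:
            raise InputError(f"snp column {c} falls inside an indel span")
        reserved[c - 1] = True
    registry = _SiteRegistry(L, reserved, rng)

    ancestral = rng.choice(_BASES, size=L)
    focal_founder = ancestral.copy()
    _mutate(focal_founder, registry.draw(rng.poisson(params.t_split * L)), rng)
    sister_founder = ancestral.copy()  # sister retains the ancestral states
    outgroup_founder = ancestral.copy()
    _mutate(outgroup_founder, registry.draw(rng.poisson(params.t_outgroup * L)), rng)

    focal = _coalescent_sample(focal_founder, params.n_focal, params.theta, registry, rng)
    sister = _coalescent_sample(sister_founder, params.n_sister, params.theta, registry, rng)
    outgroup = _coalescent_sample(
        outgroup_founder, params.n_outgroup, params.theta, registry, rng
    )

    event_idx: np.ndarray = np.array([], dtype=int)
    source_id = None
    if params.scenario != "neutral":
        n_event = params.n_event
        if params.scenario == "sweep":
            src = int(rng.integers(params.n_focal))
            source_seq = focal[src].copy()
            source_id = f"pse{src + 1:02d}"
        else:
            src = int(rng.integers(params.n_sister))
            source_seq = sister[src].copy()
            source_id = f"per{src + 1:02d}"
        event_idx = rng.choice(params.n_focal, size=n_event, replace=False)
        # derived marker alleles, one fixed choice per diagnostic column
        marked = source_seq.copy()
        for c in params.snp_columns:
            cur = marked[c - 1]
            marked[c - 1] = rng.choice(_BASES[_BASES != cur])
        for a, b in params.indel_spans:
            marked[a - 1 : b] = _GAP
        for i in event_idx:
            copy = marked.copy()
            m = rng.poisson(params.epsilon)
            if m:
                _mutate(copy, registry.draw(m), rng)
            focal[i] = copy

    ids: list[str] = []
    rows: list[np.ndarray] = []
    group_of: dict[str, str] = {}
    for i in range(params.n_focal):
        name = f"pse{i + 1:02d}"
        ids.append(name)
        rows.append(focal[i])
        group_of[name] = "focal"
    for i in range(params.n_sister):
        name = f"per{i + 1:02d}"
        ids.append(name)
        rows.append(sister[i])
        group_of[name] = "sister"
    for i in range(params.n_outgroup):
        name = f"mir{i + 1:02d}"
        ids.append(name)
        rows.append(outgroup[i])
        group_of[name] = "outgroup"

    aln = Alignment(ids, np.vstack(rows))
    event_ids = tuple(f"pse{i + 1:02d}" for i in sorted(int(x) for x in event_idx))
    return SimulatedDataset(
        alignment=aln,
        group_of=group_of,
        event_ids=event_ids,
        source_id=source_id,
        params=params,
        truth={"scenario": params.scenario, "source_id": source_id},
    )
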