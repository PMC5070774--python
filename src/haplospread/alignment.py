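"""Aligned-FASTA input/output, validation, masking and indel-marker scoring.

Every analysis in this package operates on a multiple-sequence alignment of
haploid (here: hemizygous X-linked) DNA sequences.  The alignment is the
coordinate universe: columns are addressed 1-based and inclusive throughout,
matching how variable positions are reported on locus figures.

Alphabet after normalisation is ``{A, C, G, T, N, -}``; ``N`` and ``-`` are
treated as missing data everywhere downstream.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlignmentError",
    "IndelMarker",
    "InputError",
    "MISSING",
    "RegionMask",
    "code_indel_markers",
    "extract_polymorphic_sites",
    "mask_region",
    "read_fasta_alignment",
    "score_indel_marker",
    "write_fasta_alignment",
]

#: sentinel for a missing indel-marker call
MISSING = -1

_VALID = frozenset(b"ACGTN-")
_GAP = ord("-")
_N = ord("N")


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class AlignmentError(InputError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


@dataclass(frozen=True)
class RegionMask:
    """A closed 1-based column interval to remove from an alignment."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(f"invalid mask interval {self.start}..{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IndelMarker:
    """A diagnostic indel, scored as presence/absence of a gap run.

    ``presence_state`` names which physical state counts as marker allele 1:
    ``"gap_run"`` (the span is all gaps) or ``"no_gap"`` (the span is fully
    nucleotide).  A span that is partially gapped is ambiguous and scores
    :data:`MISSING`.
    """

    start: int
    end: int
    presence_state: str = "gap_run"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError(f"invalid marker span {self.start}..{self.end}")
        if self.presence_state not in ("gap_run", "no_gap"):
            raise InputError(f"unknown presence_state {self.presence_state!r}")


class Alignment:
    """An immutable set of equal-length named DNA sequences.

    Internally a 2-D ``uint8`` matrix of ASCII codes (rows = sequences,
    columns = alignment positions), which keeps all column-wise statistics
    vectorised.
    """

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        ids = list(ids)
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise AlignmentError("matrix shape does not match id count")
        if matrix.shape[1] == 0:
            raise AlignmentError("alignment has zero columns")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dup}")
        if any(not i for i in ids):
            raise InputError("empty sequence id")
        self._ids = tuple(ids)
        self._matrix = matrix
        self._matrix.setflags(write=False)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, rows = [], []
        length = None
        for name, seq in records:
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"sequence {name!r} has length {len(seq)}, expected {length}"
                )
            row = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            bad = [c for c in set(row.tolist()) if c not in _VALID]
            if bad:
                col = int(np.nonzero(np.isin(row, bad))[0][0]) + 1
                raise InputError(
                    f"illegal character {chr(bad[0])!r} in sequence {name!r} "
                    f"at column {col}"
                )
            ids.append(name)
            rows.append(row)
        if not rows:
            raise InputError("no sequences")
        return cls(ids, np.vstack(rows))

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    @property
    def n_seqs(self) -> int:
        return self._matrix.shape[0]

    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    def sequence(self, name: str) -> str:
        return self._matrix[self._ids.index(name)].tobytes().decode("ascii")

    def records(self) -> Iterator[tuple[str, str]]:
        for i, name in enumerate(self._ids):
            yield name, self._matrix[i].tobytes().decode("ascii")

    def __len__(self) -> int:
        return self.n_seqs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self._ids == other._ids and np.array_equal(
            self._matrix, other._matrix
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Alignment(n_seqs={self.n_seqs}, length={self.length})"

    # -- derived views ---------------------------------------------------
    def subset(self, names: Sequence[str]) -> "Alignment":
        """Row subset (order given by *names*)."""
        idx = [self._ids.index(n) for n in names]
        return Alignment(list(names), self._matrix[idx])

    def take_columns(self, cols: np.ndarray) -> "Alignment":
        """Column subset by 0-based index array (internal helper)."""
        return Alignment(self._ids, self._matrix[:, cols])

    def missing_mask(self) -> np.ndarray:
        """Boolean matrix marking gap or N cells."""
        return (self._matrix == _GAP) | (self._matrix == _N)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta_alignment(path) -> Alignment:
    """Read a multi-FASTA file as an :class:`Alignment`.

    Record order is preserved, sequences are upper-cased, and the alignment
    invariants (equal lengths, unique non-empty ids, legal alphabet) are
    enforced on the way in.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_fasta_alignment(aln: Alignment, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.records()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def mask_region(aln: Alignment, mask: RegionMask) -> Alignment:
    """Remove a column interval (e.g. a microinversion) from the alignment.

    Downstream coordinates refer to the *masked* alignment.  Removing every
    column is rejected as degenerate.
    """
    if mask.end > aln.length:
        raise InputError(
            f"mask {mask.start}..{mask.end} out of bounds for length {aln.length}"
        )
    if mask.span >= aln.length:
        raise InputError("mask would remove the entire alignment")
    keep = np.r_[0 : mask.start - 1, mask.end : aln.length]
    return aln.take_columns(keep)


def score_indel_marker(aln: Alignment, marker: IndelMarker) -> np.ndarray:
    """Score each sequence 1/0/:data:`MISSING` for a gap-run indel marker.

    A sequence scores 1 iff its span matches ``presence_state`` exactly
    (all-gap for ``gap_run``, gap-free for ``no_gap``); the opposite clean
    state scores 0; any partial gap run is ambiguous and scores MISSING, as
    is a span containing N.
    """
    if marker.end > aln.length:
        raise InputError(
            f"marker {marker.start}..{marker.end} out of bounds for length {aln.length}"
        )
    block = aln.matrix[:, marker.start - 1 : marker.end]
    all_gap = np.all(block == _GAP, axis=1)
    no_gap = np.all(block != _GAP, axis=1) & np.all(block != _N, axis=1)
    out = np.full(aln.n_seqs, MISSING, dtype=np.int8)
    if marker.presence_state == "gap_run":
        out[all_gap] = 1
        out[no_gap] = 0
    else:
        out[no_gap] = 1
        out[all_gap] = 0
    return out


def extract_polymorphic_sites(
    aln: Alignment, site_policy: str = "complete"
) -> list[tuple[int, dict[str, int]]]:
    """Return ``(column, allele_counts)`` for polymorphic columns, ascending.

    ``site_policy="complete"`` drops any column containing a gap or N in any
    sequence (complete deletion); ``"pairwise"`` keeps such columns and counts
    only non-missing alleles.  A column is polymorphic when it shows at least
    two distinct non-missing nucleotides.
    """
    if site_policy not in ("complete", "pairwise"):
        raise InputError(f"unknown site policy {site_policy!r}")
    m = aln.matrix
    missing = aln.missing_mask()
    out: list[tuple[int, dict[str, int]]] = []
    if site_policy == "complete":
        usable = ~missing.any(axis=0)
    else:
        usable = ~missing.all(axis=0)
    for j in np.nonzero(usable)[0]:
        col = m[~missing[:, j], j]
        alleles, counts = np.unique(col, return_counts=True)
        if alleles.size >= 2:
            out.append(
                (int(j) + 1, {chr(a): int(c) for a, c in zip(alleles, counts)})
            )
    return out


def code_indel_markers(
    aln: Alignment, markers: Sequence[IndelMarker], mode: str = "exclude"
) -> Alignment:
    """Rewrite indel-marker spans so sequence statistics can include or
    exclude indel events as single characters.

    ``mode="exclude"`` removes the marker columns outright.  ``mode="code"``
    replaces each marker span with one biallelic pseudo-column (marker allele
    1 → ``T``, allele 0 → ``A``, ambiguous → ``N``), so each indel event
    counts as exactly one site ("indels coded as SNPs").  Pseudo-columns are
    appended after the unmasked columns, in marker order.
    """
    if mode not in ("exclude", "code"):
        raise InputError(f"unknown indel mode {mode!r}")
    drop = np.zeros(aln.length, dtype=bool)
    for mk in markers:
        if mk.end > aln.length:
            raise InputError(f"marker {mk.start}..{mk.end} out of bounds")
        drop[mk.start - 1 : mk.end] = True
    kept = aln.matrix[:, ~drop]
    if mode == "exclude":
        if kept.shape[1] == 0:
            raise InputError("excluding markers would remove the entire alignment")
        return Alignment(aln.ids, kept)
    pseudo = np.empty((aln.n_seqs, len(markers)), dtype=np.uint8)
    lut = {1: ord("T"), 0: ord("A"), MISSING: ord("N")}
    for k, mk in enumerate(markers):
        scores = score_indel_marker(aln, mk)
        pseudo[:, k] = [lut[int(s)] for s in scores]
    return Alignment(aln.ids, np.hstack([kept, pseudo]))
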