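"""Diagnostic-marker discovery and haplogroup classification.

A haplogroup pair (here called psA/psB after the focal-species haplotypes
they model) is defined by a set of diagnostic traits — indel markers and SNP
columns — in complete linkage disequilibrium: every sequence carries either
all of the psA alleles or none of them.  Discovery starts from a single seed
indel marker and collects every polymorphic site and gap-run marker whose
alleles are perfectly concordant with it; classification then requires *all*
non-missing diagnostic traits to match for a psA call, so a sequence lacking
some or all psA traits is psB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import (
    MISSING,
    Alignment,
    IndelMarker,
    InputError,
    score_indel_marker,
)

__all__ = [
    "DiagnosticSet",
    "HaplogroupPartition",
    "classify",
    "find_diagnostic_set",
    "write_partition_tsv",
]


@dataclass(frozen=True)
class DiagnosticSet:
    """Traits that jointly define the psA haplogroup.

    ``snp_sites`` lists (1-based column, psA-diagnostic nucleotide);
    ``indel_markers`` lists (marker, psA-diagnostic 0/1 state).
    """

    snp_sites: tuple[tuple[int, str], ...]
    indel_markers: tuple[tuple[IndelMarker, int], ...]

    @property
    def n_traits(self) -> int:
        return len(self.snp_sites) + len(self.indel_markers)

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise InputError("diagnostic set must contain at least one trait")


@dataclass(frozen=True)
class HaplogroupPartition:
    """Assignment of every sequence id to psA/psB/unclassified."""

    assignment: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        out = {"psA": 0, "psB": 0, "unclassified": 0}
        for g in self.assignment.values():
            out[g] += 1
        return out

    def members(self, group: str) -> list[str]:
        return [i for i, g in self.assignment.items() if g == group]


def _trait_matrix(aln: Alignment, diag: DiagnosticSet) -> np.ndarray:
    """Per-sequence trait calls: 1 = psA allele, 0 = other, MISSING."""
    cols = []
    miss = aln.missing_mask()
    for col, allele in diag.snp_sites:
        vec = np.where(
            miss[:, col - 1],
            MISSING,
            (aln.matrix[:, col - 1] == ord(allele)).astype(np.int8),
        )
        cols.append(vec)
    for marker, state in diag.indel_markers:
        raw = score_indel_marker(aln, marker)
        vec = np.where(raw == MISSING, MISSING, (raw == state).astype(np.int8))
        cols.append(vec)
    return np.stack(cols, axis=1).astype(np.int8)


def _concordant(a: np.ndarray, b: np.ndarray) -> bool:
    """Complete LD between two 0/1/MISSING vectors over shared calls."""
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        return False
    return bool(np.all(a[ok] == b[ok])) and np.unique(a[ok]).size == 2


def _gap_run_markers(aln: Alignment) -> list[IndelMarker]:
    """Candidate indel markers: maximal column runs sharing one nonempty,
    non-universal gap pattern."""
    gaps = aln.matrix == ord("-")
    markers: list[IndelMarker] = []
    start = None
    prev = None
    for j in range(aln.length + 1):
        pat = tuple(gaps[:, j]) if j < aln.length else None
        informative = pat is not None and any(pat) and not all(pat)
        if informative and pat == prev:
            continue
        if start is not None and prev is not None:
            markers.append(IndelMarker(start + 1, j, "gap_run"))
        start, prev = (j, pat) if informative else (None, None)
    return markers


def find_diagnostic_set(aln: Alignment, seed_marker: IndelMarker) -> DiagnosticSet:
    """Collect the maximal trait set in complete LD with a seed indel marker.

    A SNP column joins the set when one of its alleles is perfectly
    concordant with the seed's presence allele across all sequences
    non-missing at both traits; a gap-run marker joins when its 0/1 scores
    are concordant.  The seed itself is always included.
    """
    seed = score_indel_marker(aln, seed_marker)
    informative = seed[seed != MISSING]
    if informative.size == 0 or np.unique(informative).size < 2:
        raise InputError("seed marker is monomorphic or uncalled in this alignment")

    snp_sites: list[tuple[int, str]] = []
    miss = aln.missing_mask()
    inside_seed = np.zeros(aln.length, dtype=bool)
    inside_seed[seed_marker.start - 1 : seed_marker.end] = True
    for j in range(aln.length):
        if inside_seed[j]:
            continue
        col = aln.matrix[:, j]
        present = ~miss[:, j]
        alleles = np.unique(col[present])
        if alleles.size < 2:
            continue
        for a in alleles:
            vec = np.where(present, (col == a).astype(np.int8), MISSING)
            if _concordant(vec, seed):
                snp_sites.append((j + 1, chr(a)))
                break

    indels: list[tuple[IndelMarker, int]] = [(seed_marker, 1)]
    for cand in _gap_run_markers(aln):
        if cand == seed_marker or (
            cand.start <= seed_marker.end and cand.end >= seed_marker.start
        ):
            continue
        sc = score_indel_marker(aln, cand)
        for state in (1, 0):
            vec = np.where(sc == MISSING, MISSING, (sc == state).astype(np.int8))
            if _concordant(vec, seed):
                indels.append((cand, state))
                break
    return DiagnosticSet(tuple(snp_sites), tuple(indels))


def classify(aln: Alignment, diag: DiagnosticSet) -> HaplogroupPartition:
    """Assign each sequence to psA, psB or unclassified.

    psA requires *every* non-missing diagnostic trait to carry the psA
    allele, with at least one non-missing trait; any non-missing mismatch
    makes the sequence psB ("absence of some or all" diagnostic traits);
    all-missing sequences are unclassified.  Deterministic and independent
    of sequence order.
    """
    traits = _trait_matrix(aln, diag)
    assignment: dict[str, str] = {}
    for i, name in enumerate(aln.ids):
        row = traits[i]
        called = row != MISSING
        if not called.any():
            assignment[name] = "unclassified"
        elif np.all(row[called] == 1):
            assignment[name] = "psA"
        else:
            assignment[name] = "psB"
    return HaplogroupPartition(assignment)


def write_partition_tsv(partition: HaplogroupPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for name, group in partition.assignment.items():
            fh.write(f"{name}\t{group}\n")
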