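"""End-to-end analysis: classify → divergence tables → LD → bootstrap →
expansion → polarization → adjudication.

:func:`analyze_alignments` is the library entry point used by the CLI and
by the synthetic-scenario studies; :func:`analyze_dataset` adapts a
simulated dataset.  All stages share one site policy (complete deletion)
and one indel policy, and every stochastic stage takes the single run
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adjudicate import AdjudicationReport, evaluate_models
from .alignment import (
    Alignment,
    IndelMarker,
    InputError,
    code_indel_markers,
)
from .expansion import ExpansionResult, expand_and_compare
from .haplogroups import (
    DiagnosticSet,
    HaplogroupPartition,
    classify,
    find_diagnostic_set,
)
from .polarize import PolarizationSummary, polarize_fixed_differences
from .popgen import (
    DivergenceSummary,
    DiversityStats,
    divergence_summary,
    nucleotide_diversity,
    pairwise_distances,
    tajimas_d,
)
from .resampling import BootstrapResult, bootstrap_divergence_comparison
from .simulate import SimulatedDataset

__all__ = ["PipelineResult", "analyze_alignments", "analyze_dataset"]


@dataclass(frozen=True)
class PipelineResult:
    partition: HaplogroupPartition
    diagnostic: DiagnosticSet
    candidate: str                      # "psA" or "psB"
    other: str
    cand_vs_sister: DivergenceSummary
    other_vs_sister: DivergenceSummary
    cand_vs_other: DivergenceSummary
    pi: dict[str, float]
    focal_diversity: DiversityStats | None
    expansion: ExpansionResult
    polarization: PolarizationSummary
    bootstrap: dict[str, BootstrapResult]
    report: AdjudicationReport

    def table1(self) -> list[dict]:
        """Rows mirroring the summary table: per haplogroup, fixed/shared
        counts and divergence vs the sister species, plus per-group π."""
        rows = []
        for label, summ in (
            (self.candidate, self.cand_vs_sister),
            (self.other, self.other_vs_sister),
        ):
            rows.append(
                {
                    "group": label,
                    "fixed_vs_sister": summ.fixed,
                    "shared_vs_sister": summ.shared,
                    "da_vs_sister": summ.da,
                    "dxy_vs_sister": summ.dxy,
                    "pi": self.pi["candidate" if label == self.candidate else "other"],
                }
            )
        rows.append(
            {
                "group": "sister",
                "fixed_vs_sister": None,
                "shared_vs_sister": None,
                "da_vs_sister": None,
                "dxy_vs_sister": None,
                "pi": self.pi["sister"],
            }
        )
        return rows


def _apply_indel_policy(
    aln: Alignment, markers: tuple[IndelMarker, ...], indel_policy: str
) -> Alignment:
    if not markers:
        return aln
    if indel_policy == "excluded":
        return code_indel_markers(aln, markers, "exclude")
    if indel_policy == "coded_as_snps":
        return code_indel_markers(aln, markers, "code")
    raise InputError(f"unknown indel policy {indel_policy!r}")


def analyze_alignments(
    focal: Alignment,
    sister: Alignment,
    outgroup: Alignment,
    seed_marker: IndelMarker | None = None,
    diagnostic: DiagnosticSet | None = None,
    indel_policy: str = "excluded",
    n_boot: int = 0,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full comparison on pre-aligned focal/sister/outgroup sets.

    The three alignments must share column coordinates (one multiple
    alignment, split by species).  Either a *diagnostic* trait set or a
    *seed_marker* from which to discover one must be supplied.  The
    candidate (introgression-suspect) haplogroup is the one with the lower
    net divergence Da to the sister species.  ``n_boot > 0`` adds the
    divergence bootstrap (requires *seed*).
    """
    if diagnostic is None:
        if seed_marker is None:
            raise InputError("supply a diagnostic set or a seed indel marker")
        diagnostic = find_diagnostic_set(focal, seed_marker)
    partition = classify(focal, diagnostic)
    ps_a_ids = partition.members("psA")
    ps_b_ids = partition.members("psB")
    if len(ps_a_ids) < 2 or len(ps_b_ids) < 2:
        raise InputError(
            f"degenerate haplogroup split psA={len(ps_a_ids)}, psB={len(ps_b_ids)}"
        )

    markers = tuple(m for m, _state in diagnostic.indel_markers)
    focal_p = _apply_indel_policy(focal, markers, indel_policy)
    sister_p = _apply_indel_policy(sister, markers, indel_policy)
    outgroup_p = _apply_indel_policy(outgroup, markers, indel_policy)

    ps_a = focal_p.subset(ps_a_ids)
    ps_b = focal_p.subset(ps_b_ids)

    a_vs_s = divergence_summary(ps_a, sister_p)
    b_vs_s = divergence_summary(ps_b, sister_p)
    if a_vs_s.da <= b_vs_s.da:
        candidate, other = "psA", "psB"
        cand_aln, other_aln = ps_a, ps_b
        cand_vs_sister, other_vs_sister = a_vs_s, b_vs_s
    else:
        candidate, other = "psB", "psA"
        cand_aln, other_aln = ps_b, ps_a
        cand_vs_sister, other_vs_sister = b_vs_s, a_vs_s
    cand_vs_other = divergence_summary(cand_aln, other_aln)

    pi = {
        "candidate": nucleotide_diversity(cand_aln),
        "other": nucleotide_diversity(other_aln),
        "sister": nucleotide_diversity(sister_p),
    }
    try:
        focal_div = tajimas_d(focal_p)
    except InputError:
        focal_div = None

    expansion = expand_and_compare(
        cand_aln,
        sister_p,
        copies=max(2, cand_aln.n_seqs),
        indel_policy=indel_policy,
    )

    fixed_sites = [s for s in other_vs_sister.site_labels if s.label == "fixed"]
    polarization = polarize_fixed_differences(fixed_sites, outgroup_p)

    bootstrap: dict[str, BootstrapResult] = {}
    if n_boot > 0:
        both = Alignment(
            list(focal_p.ids) + list(sister_p.ids),
            np.vstack([focal_p.matrix, sister_p.matrix]),
        )
        dm = pairwise_distances(both)
        for name, x_ids in (
            ("within_vs_candidate_sister", list(cand_aln.ids)),
            ("within_vs_other_sister", list(other_aln.ids)),
        ):
            bootstrap[name] = bootstrap_divergence_comparison(
                dm,
                (list(cand_aln.ids), list(other_aln.ids)),
                (x_ids, list(sister_p.ids)),
                n_boot=n_boot,
                seed=seed,
            )

    annotations = {
        "haplogroup_counts": partition.counts,
        "focal_tajima_d": None if focal_div is None else focal_div.tajima_d,
        "bootstrap": {k: v.to_dict() for k, v in bootstrap.items()},
    }
    report = evaluate_models(
        cand_vs_sister,
        other_vs_sister,
        cand_vs_other,
        pi,
        expansion,
        polarization,
        candidate=candidate,
        other=other,
        annotations=annotations,
    )
    return PipelineResult(
        partition=partition,
        diagnostic=diagnostic,
        candidate=candidate,
        other=other,
        cand_vs_sister=cand_vs_sister,
        other_vs_sister=other_vs_sister,
        cand_vs_other=cand_vs_other,
        pi=pi,
        focal_diversity=focal_div,
        expansion=expansion,
        polarization=polarization,
        bootstrap=bootstrap,
        report=report,
    )


def analyze_dataset(
    ds: SimulatedDataset,
    indel_policy: str = "excluded",
    n_boot: int = 0,
    seed: int | None = None,
) -> PipelineResult:
    """Run the pipeline on a simulated dataset, discovering the diagnostic
    set from the first injected indel marker."""
    focal = ds.group("focal")
    sister = ds.group("sister")
    outgroup = ds.group("outgroup")
    seed_marker = ds.params.indel_markers[0]
    return analyze_alignments(
        focal,
        sister,
        outgroup,
        seed_marker=seed_marker,
        indel_policy=indel_policy,
        n_boot=n_boot,
        seed=seed,
    )
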