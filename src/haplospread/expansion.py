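"""In-silico haplotype expansion.

To ask what the locus would look like if any single haplotype of the
putatively ancestral haplogroup had recently spread within the species,
each of its haplotypes is cloned into an artificial monomorphic haplogroup
and re-compared to the sister species.  Because a clone group carries no
internal variation, its net divergence satisfies
``dxy - da == pi(sister) / 2`` identically, and da/dxy/fixed/shared are
invariant to the number of copies; only the Tajima's D of the combined
sample (clones plus the original haplogroup) responds to copy number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, InputError
from .popgen import DiversityStats, divergence_summary, tajimas_d

__all__ = ["ExpansionResult", "expand_and_compare"]


@dataclass(frozen=True)
class ExpansionResult:
    """Per-haplotype artificial-spread statistics plus summaries.

    ``rows`` has one record per source haplotype with columns
    ``source_id, da, dxy, fixed, shared, combined_tajima_d``.
    """

    rows: pd.DataFrame
    summary: dict[str, float]
    copies: int
    indel_policy: str

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _clone_group(source: Alignment, name: str, copies: int) -> Alignment:
    row = source.matrix[source.ids.index(name)]
    ids = [f"{name}__copy{k + 1}" for k in range(copies)]
    return Alignment(ids, np.tile(row, (copies, 1)))


def expand_and_compare(
    ps_a: Alignment,
    sister: Alignment,
    copies: int = 13,
    indel_policy: str = "excluded",
) -> ExpansionResult:
    """Clone each haplotype of *ps_a* and compare the clone group to *sister*.

    The caller is responsible for any indel handling (exclusion or coding
    as single pseudo-sites) before the call; *indel_policy* records which
    was applied.  The combined Tajima's D is computed on the clone group
    plus the original *ps_a* sample under the same complete-deletion
    policy as every other statistic.
    """
    if ps_a.n_seqs < 1:
        raise InputError("psA group is empty")
    if sister.n_seqs < 2:
        raise InputError("sister group needs at least 2 sequences")
    if copies < 2:
        raise InputError("need at least 2 copies for a group comparison")
    if indel_policy not in ("excluded", "coded_as_snps"):
        raise InputError(f"unknown indel policy {indel_policy!r}")

    records = []
    for name in ps_a.ids:
        clones = _clone_group(ps_a, name, copies)
        summ = divergence_summary(clones, sister)
        combined = Alignment(
            list(clones.ids) + list(ps_a.ids),
            np.vstack([clones.matrix, ps_a.matrix]),
        )
        try:
            taj: DiversityStats | None = tajimas_d(combined)
            taj_d = taj.tajima_d
        except InputError:  # no segregating sites in the combined sample
            taj_d = float("nan")
        records.append(
            {
                "source_id": name,
                "da": summ.da,
                "dxy": summ.dxy,
                "fixed": summ.fixed,
                "shared": summ.shared,
                "pi_sister": summ.pi_y,
                "combined_tajima_d": taj_d,
            }
        )
    rows = pd.DataFrame.from_records(records)
    summary = {
        "min_da": float(rows["da"].min()),
        "max_da": float(rows["da"].max()),
        "median_da": float(rows["da"].median()),
        "mean_da": float(rows["da"].mean()),
        "mean_dxy": float(rows["dxy"].mean()),
        "mean_fixed": float(rows["fixed"].mean()),
        "min_fixed": float(rows["fixed"].min()),
        "max_fixed": float(rows["fixed"].max()),
        "max_combined_tajima_d": float(rows["combined_tajima_d"].max()),
    }
    return ExpansionResult(
        rows=rows, summary=summary, copies=copies, indel_policy=indel_policy
    )
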