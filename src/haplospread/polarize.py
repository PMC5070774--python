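"""Outgroup polarization of fixed differences.

At a site fixed between groups X and Y, the outgroup consensus allele tells
which side carries the derived state: if the outgroup matches Y's allele,
the X allele is derived (the change happened on X's side), and vice versa.
An outgroup carrying a third allele, a consensus tie, or an all-missing
outgroup column leaves the site unpolarized.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, InputError
from .popgen import SiteLabel

__all__ = ["PolarizationSummary", "PolarizedSite", "polarize_fixed_differences"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolarizedSite:
    column: int
    alleles_x: tuple[str, ...]
    alleles_y: tuple[str, ...]
    outgroup_allele: str | None
    call: str  # derived_in_x | derived_in_y | unpolarized


@dataclass(frozen=True)
class PolarizationSummary:
    sites: tuple[PolarizedSite, ...]
    derived_in_x: int
    derived_in_y: int
    unpolarized: int

    @property
    def n_fixed(self) -> int:
        return len(self.sites)

    def to_dict(self) -> dict:
        return {
            "n_fixed": self.n_fixed,
            "derived_in_x": self.derived_in_x,
            "derived_in_y": self.derived_in_y,
            "unpolarized": self.unpolarized,
        }


def _consensus(col: np.ndarray, missing: np.ndarray) -> str | None:
    """Strict-majority outgroup allele; ties and all-missing give None."""
    counts = Counter(chr(c) for c in col[~missing])
    if not counts:
        return None
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def polarize_fixed_differences(
    fixed_sites: list[SiteLabel] | tuple[SiteLabel, ...],
    outgroup: Alignment,
) -> PolarizationSummary:
    """Polarize fixed-difference sites against an outgroup alignment.

    *fixed_sites* are the ``label == "fixed"`` records of a two-group site
    classification; the outgroup must share the same column coordinates.
    With multi-allelic groups the rule generalises by allele-set
    membership: an outgroup allele inside exactly one group's allele set
    marks the *other* group as derived.
    """
    if outgroup.n_seqs == 0:
        raise InputError("outgroup is empty")
    miss = outgroup.missing_mask()
    sites: list[PolarizedSite] = []
    tally = Counter()
    for s in fixed_sites:
        if s.label != "fixed":
            raise InputError(f"site at column {s.column} is not a fixed difference")
        if s.column > outgroup.length:
            raise InputError(f"column {s.column} out of outgroup bounds")
        out_allele = _consensus(
            outgroup.matrix[:, s.column - 1], miss[:, s.column - 1]
        )
        if out_allele is None:
            call = "unpolarized"
            logger.warning("column %d: outgroup uninformative", s.column)
        elif out_allele in s.alleles_y and out_allele not in s.alleles_x:
            call = "derived_in_x"
        elif out_allele in s.alleles_x and out_allele not in s.alleles_y:
            call = "derived_in_y"
        else:
            call = "unpolarized"
        tally[call] += 1
        sites.append(
            PolarizedSite(
                column=s.column,
                alleles_x=s.alleles_x,
                alleles_y=s.alleles_y,
                outgroup_allele=out_allele,
                call=call,
            )
        )
    return PolarizationSummary(
        sites=tuple(sites),
        derived_in_x=tally["derived_in_x"],
        derived_in_y=tally["derived_in_y"],
        unpolarized=tally["unpolarized"],
    )
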