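"""Model adjudication: introgression vs within-species haplotype spread.

Two haplogroups segregate at intermediate frequency in the focal species,
and one of them — the *candidate*, identified as the group with the lower
net divergence (Da) to the sister species — looks introgression-like by
relative divergence.  Six directional predictions are scored from computed
statistics:

I1  Dxy(candidate, sister) < Dxy(other, sister)
I2  π(candidate) < π(sister)
I3  π(candidate) < π(other)
I4  mean in-silico expanded Da < Da(candidate, sister)
W1  Dxy(candidate, other) < Dxy(candidate, sister) and < Dxy(other, sister)
W2  every fixed difference between the other group and the sister species
    is derived in the other group (outgroup polarization)

I-predictions follow from introgression of the candidate; W-predictions
from a within-species spread.  All six are strict inequalities; ties are
scored unsupported.

The verdict weighs the predictions hierarchically rather than by unanimous
count.  W1 — both haplogroups mutually closer in absolute divergence than
either is to the sister species — is the decisive absolute-divergence
configuration: a haplogroup that truly entered from the sister species
cannot be closer to its within-species alternative than to its source
population.  W2 confirms that the divergent haplogroup's differences arose
on the focal lineage.  The I1–I3 diversity/divergence directions are
supporting evidence whose direction depends on which haplotype happened to
spread, and I4 is reported but structurally conservative (the mean
expanded Da equals Da(candidate, sister) + π(candidate)/2 identically, so
it can only fall below the observed Da when the candidate is internally
monomorphic).  Hence:

* ``within-species-consistent``  iff W1 and W2 are both supported;
* ``introgression-consistent``   iff I1, I2 and I3 are supported and W1 is not;
* otherwise ``mixed/inconclusive``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .expansion import ExpansionResult
from .polarize import PolarizationSummary
from .popgen import DivergenceSummary

__all__ = ["AdjudicationReport", "PredictionResult", "evaluate_models"]


@dataclass(frozen=True)
class PredictionResult:
    id: str
    description: str
    observed: dict[str, float | int | None]
    expected_direction: str
    support: bool | None  # None = not evaluated

    @property
    def support_text(self) -> str:
        return {True: "YES", False: "NO", None: "not evaluated"}[self.support]


@dataclass(frozen=True)
class AdjudicationReport:
    predictions: tuple[PredictionResult, ...]
    verdict: str
    candidate: str   # label of the introgression-suspect haplogroup
    other: str
    annotations: dict

    def prediction(self, pid: str) -> PredictionResult:
        return next(p for p in self.predictions if p.id == pid)

    def to_json(self, path=None) -> str:
        payload = {
            "candidate": self.candidate,
            "other": self.other,
            "verdict": self.verdict,
            "predictions": [
                {
                    "id": p.id,
                    "description": p.description,
                    "observed": p.observed,
                    "expected_direction": p.expected_direction,
                    "support": p.support,
                }
                for p in self.predictions
            ],
            "annotations": self.annotations,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"Candidate (introgression-suspect) haplogroup: {self.candidate}",
            f"Alternative haplogroup: {self.other}",
            "",
            "id  support  description",
        ]
        for p in self.predictions:
            obs = ", ".join(
                f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                for k, v in p.observed.items()
            )
            lines.append(f"{p.id:<3} {p.support_text:<8} {p.description}")
            lines.append(f"    observed: {obs}")
        lines += ["", f"Verdict: {self.verdict}"]
        return "\n".join(lines)


def _strict_less(a: float, b: float) -> bool:
    return a < b  # exact ties count as unsupported


def evaluate_models(
    cand_vs_sister: DivergenceSummary,
    other_vs_sister: DivergenceSummary,
    cand_vs_other: DivergenceSummary,
    pi: dict[str, float],
    expansion: ExpansionResult | None,
    polarization: PolarizationSummary | None,
    candidate: str = "psA",
    other: str = "psB",
    annotations: dict | None = None,
) -> AdjudicationReport:
    """Score the six predictions and return the verdict report.

    *pi* maps ``{"candidate", "other", "sister"}`` to per-group nucleotide
    diversities computed on each group's own complete-deletion column set.
    In *polarization*, group X must be the *other* (non-candidate)
    haplogroup and group Y the sister species.  A missing expansion or
    polarization input marks the affected prediction "not evaluated" and
    forces an inconclusive verdict.
    """
    preds: list[PredictionResult] = []

    preds.append(
        PredictionResult(
            "I1",
            f"Dxy({candidate}, sister) is less than Dxy({other}, sister)",
            {"dxy_cand_sister": cand_vs_sister.dxy, "dxy_other_sister": other_vs_sister.dxy},
            "less",
            _strict_less(cand_vs_sister.dxy, other_vs_sister.dxy),
        )
    )
    preds.append(
        PredictionResult(
            "I2",
            f"pi({candidate}) is less than pi(sister)",
            {"pi_cand": pi["candidate"], "pi_sister": pi["sister"]},
            "less",
            _strict_less(pi["candidate"], pi["sister"]),
        )
    )
    preds.append(
        PredictionResult(
            "I3",
            f"pi({candidate}) is less than pi({other})",
            {"pi_cand": pi["candidate"], "pi_other": pi["other"]},
            "less",
            _strict_less(pi["candidate"], pi["other"]),
        )
    )
    if expansion is not None:
        i4 = PredictionResult(
            "I4",
            "mean Da of in-silico expanded haplotypes vs sister is less than "
            f"Da({candidate}, sister)",
            {
                "mean_insilico_da": expansion.summary["mean_da"],
                "median_insilico_da": expansion.summary["median_da"],
                "da_cand_sister": cand_vs_sister.da,
            },
            "less",
            _strict_less(expansion.summary["mean_da"], cand_vs_sister.da),
        )
    else:
        i4 = PredictionResult(
            "I4", "mean in-silico Da comparison", {}, "less", None
        )
    preds.append(i4)

    w1 = PredictionResult(
        "W1",
        f"Dxy({candidate}, {other}) is less than both cross-species Dxy values",
        {
            "dxy_cand_other": cand_vs_other.dxy,
            "dxy_cand_sister": cand_vs_sister.dxy,
            "dxy_other_sister": other_vs_sister.dxy,
        },
        "less than both",
        _strict_less(cand_vs_other.dxy, cand_vs_sister.dxy)
        and _strict_less(cand_vs_other.dxy, other_vs_sister.dxy),
    )
    preds.append(w1)

    if polarization is not None:
        n_fixed = polarization.n_fixed
        w2_support = n_fixed >= 1 and polarization.derived_in_x == n_fixed
        w2 = PredictionResult(
            "W2",
            f"all fixed differences between {other} and sister are derived in {other}",
            {
                "n_fixed": n_fixed,
                "derived_in_other": polarization.derived_in_x,
                "derived_in_sister": polarization.derived_in_y,
                "unpolarized": polarization.unpolarized,
            },
            "all derived in non-candidate group",
            w2_support,
        )
    else:
        w2 = PredictionResult(
            "W2", "polarization of fixed differences", {}, "all derived", None
        )
    preds.append(w2)

    if any(p.support is None for p in preds):
        verdict = "mixed/inconclusive"
    elif w1.support and w2.support:
        verdict = "within-species-consistent"
    elif (
        preds[0].support and preds[1].support and preds[2].support and not w1.support
    ):
        verdict = "introgression-consistent"
    else:
        verdict = "mixed/inconclusive"

    return AdjudicationReport(
        predictions=tuple(preds),
        verdict=verdict,
        candidate=candidate,
        other=other,
        annotations=dict(annotations or {}),
    )
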