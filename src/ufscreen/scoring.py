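"""Screening statistics and the two-criterion ligand classifier.

For each compound the screen yields three baseline-corrected peak
areas: A_a (incubated with the enzyme source), A_b (incubated without
it) and, per target, A_c (incubated with the enzyme source after that
target's active site was blocked with a competitive probe).  Two
dimensionless ratios summarise them:

* signal-to-noise ratio           S/N   = A_a / A_b
* specific signal-to-noise ratio  S-S/N = (A_a - A_c) / A_b

S/N > 1 indicates binding affinity toward the enzyme pool; S-S/N > 0
indicates that the probe displaced part of the compound's binding at
the blocked target, i.e. the compound competes at that target's active
site.  A compound is called a specific ligand of a target exactly when
both strict inequalities hold.  A_b = 0 (compound absent from the
blank) leaves both ratios undefined; such compounds are flagged not
evaluable and receive no calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chrom_model import ScreenDesign, ValidationError
from .peakproc import PeakAreaTriple

__all__ = [
    "ScreenScore",
    "LigandCall",
    "NotEvaluable",
    "compute_sn",
    "compute_ssn",
    "classify",
    "score_screen",
    "plot_data",
    "scores_to_frame",
]


class NotEvaluable(ValueError):
    """Raised when A_b <= 0 makes the screening ratios undefined."""


@dataclass(frozen=True)
class ScreenScore:
    compound_id: str
    sn: float
    ssn_by_target: Mapping[str, float]
    evaluable: bool = True

    def __post_init__(self):
        object.__setattr__(self, "ssn_by_target", dict(self.ssn_by_target))
        if self.evaluable and self.sn < 0:
            raise ValidationError("S/N must be non-negative")


@dataclass(frozen=True)
class LigandCall:
    compound_id: str
    target: str
    is_binder: bool
    is_specific: bool

    def __post_init__(self):
        if self.is_specific and not self.is_binder:
            raise ValidationError("a specific ligand must also be a binder")


def compute_sn(A_a: float, A_b: float) -> float:
    """S/N = A_a / A_b."""
    if A_b <= 0:
        raise NotEvaluable(f"A_b must be positive, got {A_b}")
    return A_a / A_b


def compute_ssn(A_a: float, A_b: float, A_c: float) -> float:
    """S-S/N = (A_a - A_c) / A_b; negative when the control area exceeds
    the experimental area (probe blocking increased apparent binding)."""
    if A_b <= 0:
        raise NotEvaluable(f"A_b must be positive, got {A_b}")
    if A_a < 0 or A_c < 0:
        raise ValidationError("areas must be non-negative")
    return (A_a - A_c) / A_b


def classify(score: ScreenScore, target: str) -> LigandCall:
    """Apply the two strict selection criteria for one compound/target."""
    if not score.evaluable:
        raise NotEvaluable(f"{score.compound_id} is not evaluable")
    if target not in score.ssn_by_target:
        raise ValidationError(
            f"no S-S/N for target {target!r} on compound {score.compound_id!r}"
        )
    is_binder = score.sn > 1.0
    is_specific = is_binder and score.ssn_by_target[target] > 0.0
    return LigandCall(score.compound_id, target, is_binder, is_specific)


def score_screen(
    triples: Sequence[PeakAreaTriple], design: ScreenDesign
) -> tuple[list[ScreenScore], list[LigandCall]]:
    """Score every compound of a screen and call every compound/target pair.

    Compounds with A_b = 0 are reported with ``evaluable=False`` and
    produce no calls.
    """
    scores: list[ScreenScore] = []
    calls: list[LigandCall] = []
    for triple in triples:
        if set(triple.A_c_by_target) != set(design.targets):
            raise ValidationError(
                f"compound {triple.compound_id!r} has control areas for "
                f"{sorted(triple.A_c_by_target)} but design targets are "
                f"{sorted(design.targets)}"
            )
        if triple.A_b <= 0:
            scores.append(
                ScreenScore(triple.compound_id, float("nan"), {}, evaluable=False)
            )
            continue
        sn = compute_sn(triple.A_a, triple.A_b)
        ssn = {
            t: compute_ssn(triple.A_a, triple.A_b, triple.A_c_by_target[t])
            for t in design.targets
        }
        score = ScreenScore(triple.compound_id, sn, ssn)
        scores.append(score)
        calls.extend(classify(score, t) for t in design.targets)
    return scores, calls


def plot_data(scores: Sequence[ScreenScore], target: str) -> pd.DataFrame:
    """Scatter-plot table for one target: S/N vs S-S/N with the
    selection flag; criterion lines sit at S/N = 1 and S-S/N = 0."""
    rows = []
    for score in scores:
        if not score.evaluable:
            continue
        call = classify(score, target)
        rows.append(
            {
                "compound_id": score.compound_id,
                "sn": score.sn,
                "ssn": score.ssn_by_target[target],
                "selected": call.is_specific,
            }
        )
    return pd.DataFrame(rows, columns=["compound_id", "sn", "ssn", "selected"])


def scores_to_frame(
    scores: Sequence[ScreenScore],
    calls: Sequence[LigandCall],
    targets: Sequence[str],
) -> pd.DataFrame:
    """Report table: one row per compound with S/N, per-target S-S/N,
    the binder flag and per-target specific flags."""
    call_map = {(c.compound_id, c.target): c for c in calls}
    rows = []
    for score in scores:
        row: dict = {"compound_id": score.compound_id, "evaluable": score.evaluable}
        row["sn"] = score.sn if score.evaluable else float("nan")
        any_call = None
        for t in targets:
            if score.evaluable:
                row[f"ssn_{t}"] = score.ssn_by_target[t]
                call = call_map[(score.compound_id, t)]
                row[f"specific_{t}"] = call.is_specific
                any_call = call
            else:
                row[f"ssn_{t}"] = float("nan")
                row[f"specific_{t}"] = False
        row["binder"] = bool(any_call.is_binder) if any_call else False
        rows.append(row)
    cols = (
        ["compound_id", "evaluable", "sn", "binder"]
        + [f"ssn_{t}" for t in targets]
        + [f"specific_{t}" for t in targets]
    )
    return pd.DataFrame(rows, columns=cols)
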