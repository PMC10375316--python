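"""Direction-aware concordance evaluation against reference classifications.

Three comparison schemes are supported for each hormone family:

* ``vs_oecd`` — this assay's steroidogenesis calls against the
  multi-laboratory validation calls, direction-aware (an effect detected in
  the opposite direction counts as a false positive) with equivocal
  reference calls resolved positive only when >= 2 laboratories detected
  them;
* ``vs_known_invitro`` — both sides reinterpreted as "any endocrine
  activity" (steroidogenic or direct receptor-mediated), ignoring modality
  and direction; the reference combines the validation calls with published
  receptor-assay results;
* ``vs_invivo`` — direction-aware comparison against in vivo calls over the
  chemicals with in vivo data (either this assay's calls or the original
  validation calls on the test side).

Sensitivity, specificity and accuracy are only reported when their
denominator pools at least 4 substances.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "Call",
    "Outcome",
    "ReferenceRecord",
    "ConfusionMatrix",
    "load_reference_records",
    "resolve_equivocal",
    "match_calls",
    "build_matrix",
    "metrics",
    "round_metric",
    "MIN_SUBSTANCES",
]

MIN_SUBSTANCES = 4

Comparison = Literal["vs_oecd", "vs_known_invitro", "vs_invivo"]


class Call(str, Enum):
    UP = "up"
    DOWN = "down"
    DOWN_THEN_UP = "down_then_up"
    ND = "nd"
    UNKNOWN = "unknown"

    @property
    def positive(self) -> bool:
        return self in (Call.UP, Call.DOWN, Call.DOWN_THEN_UP)


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


@dataclass(frozen=True)
class ReferenceRecord:
    """Per-chemical encoded calls for one hormone family."""

    chemical: str
    family: str  # androgens | estrogens
    study_effect: Call
    study_direct: bool
    oecd_effect: Call
    oecd_equivocal_labs: int | None
    lit_receptor: str  # positive | nd | unknown
    invivo_effect: Call
    in_oecd_set: bool
    in_invivo_set: bool
    invitro_ref_override: str | None  # "negative" forces the combined
    # in-vitro reference negative despite the encoded columns


def _call(value: str) -> Call:
    return Call(value) if value else Call.UNKNOWN


def load_reference_records(path: str | Path | None = None) -> list[ReferenceRecord]:
    """Load the shipped (or a user-provided) reference-classification table."""
    if path is None:
        source = resources.files("steroidscreen.data").joinpath("reference_calls.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    records = []
    for row in csv.DictReader(text.splitlines()):
        records.append(ReferenceRecord(
            chemical=row["chemical"],
            family=row["family"],
            study_effect=_call(row["study_effect"]),
            study_direct=row["study_direct"] == "true",
            oecd_effect=_call(row["oecd_effect"]),
            oecd_equivocal_labs=(int(row["oecd_equivocal_labs"])
                                 if row["oecd_equivocal_labs"] else None),
            lit_receptor=row["lit_receptor"],
            invivo_effect=_call(row["invivo_effect"]),
            in_oecd_set=row["in_oecd_set"] == "true",
            in_invivo_set=row["in_invivo_set"] == "true",
            invitro_ref_override=row["invitro_ref_override"] or None,
        ))
    return records


def resolve_equivocal(effect: Call, labs: int | None) -> Call:
    """Equivocal validation calls are positive only with >= 2 detecting labs."""
    if labs is None:
        return effect
    return effect if labs >= 2 else Call.ND


def match_calls(test: Call, ref: Call) -> Outcome:
    """Direction-aware confusion-matrix cell for one chemical.

    Opposite-direction detections are false positives; a biphasic call on
    either side matches either single direction.
    """
    if not test.positive and not ref.positive:
        return Outcome.TN
    if not test.positive:
        return Outcome.FN
    if not ref.positive:
        return Outcome.FP
    if Call.DOWN_THEN_UP in (test, ref) or test is ref:
        return Outcome.TP
    return Outcome.FP


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, outcome: Outcome) -> None:
        if outcome is Outcome.TP:
            self.tp += 1
        elif outcome is Outcome.FP:
            self.fp += 1
        elif outcome is Outcome.TN:
            self.tn += 1
        else:
            self.fn += 1


def _invitro_reference_positive(r: ReferenceRecord) -> bool:
    if r.invitro_ref_override == "negative":
        return False
    oecd = resolve_equivocal(r.oecd_effect, r.oecd_equivocal_labs)
    return oecd.positive or r.lit_receptor == "positive"


def build_matrix(records: Iterable[ReferenceRecord],
                 comparison: Comparison,
                 family: str,
                 test_side: Literal["study", "oecd"] = "study",
                 ) -> ConfusionMatrix:
    """Build one confusion matrix over the included chemicals.

    ``test_side="oecd"`` substitutes the original validation calls as the
    test assay (only meaningful for ``vs_invivo``).
    """
    cm = ConfusionMatrix()
    for r in records:
        if r.family != family:
            continue
        if comparison in ("vs_oecd", "vs_known_invitro"):
            if not r.in_oecd_set:
                continue
        elif not r.in_invivo_set:
            continue

        if comparison == "vs_known_invitro":
            test_pos = r.study_effect.positive or r.study_direct
            ref_pos = _invitro_reference_positive(r)
            if test_pos and ref_pos:
                cm.add(Outcome.TP)
            elif test_pos:
                cm.add(Outcome.FP)
            elif ref_pos:
                cm.add(Outcome.FN)
            else:
                cm.add(Outcome.TN)
            continue

        if test_side == "oecd":
            test = resolve_equivocal(r.oecd_effect, r.oecd_equivocal_labs)
        else:
            test = r.study_effect
        if comparison == "vs_oecd":
            ref = resolve_equivocal(r.oecd_effect, r.oecd_equivocal_labs)
        else:
            ref = r.invivo_effect
            if ref is Call.UNKNOWN:
                raise ValueError(f"missing in vivo reference for {r.chemical}")
        cm.add(match_calls(test, ref))
    return cm


def metrics(cm: ConfusionMatrix,
            min_substances: int = MIN_SUBSTANCES,
            ) -> dict[str, float | None]:
    """Sensitivity, specificity and accuracy with the min-4 rule.

    Raw fractions are returned; rounding happens at the reporting layer.
    """
    out: dict[str, float | None] = {}
    out["sensitivity"] = (cm.tp / (cm.tp + cm.fn)
                          if cm.tp + cm.fn >= min_substances else None)
    out["specificity"] = (cm.tn / (cm.tn + cm.fp)
                          if cm.tn + cm.fp >= min_substances else None)
    out["accuracy"] = ((cm.tp + cm.tn) / cm.total
                       if cm.total >= min_substances else None)
    return out


def round_metric(value: float | None, ndigits: int = 2) -> float | None:
    """Half-up decimal rounding for report parity (0.005 -> 0.01)."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def performance_report(records: Sequence[ReferenceRecord]) -> dict:
    """All six matrices and their rounded metric triplets."""
    report: dict = {}
    for family in ("androgens", "estrogens"):
        fam: dict = {}
        for comparison in ("vs_oecd", "vs_known_invitro", "vs_invivo"):
            cm = build_matrix(records, comparison, family)
            fam[comparison] = {
                "matrix": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
                "metrics": {k: round_metric(v) for k, v in metrics(cm).items()},
            }
        cm = build_matrix(records, "vs_invivo", family, test_side="oecd")
        fam["oecd_vs_invivo"] = {
            "matrix": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "metrics": {k: round_metric(v) for k, v in metrics(cm).items()},
        }
        report[family] = fam
    return report
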