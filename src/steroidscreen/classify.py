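"""Per-chemical endocrine classification.

Turns per-concentration statistical calls, viability flags and sham-well
(direct receptor) activities into a classification per hormone family:
effect direction, LOEC, and whether an apparent steroidogenic effect is
explained away ("masked") by direct receptor activity at the same nominal
concentrations or by cytotoxicity of the hormone-producing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import DIRECT_REFERENCE_LEVEL
from .npstats import Direction, StatCall

__all__ = [
    "Effect",
    "MaskedBy",
    "ConcCall",
    "DirectObservation",
    "DirectActivity",
    "FamilyClassification",
    "ChemicalClassification",
    "CytotoxicityFlags",
    "flag_cytotoxicity",
    "positivity_rule",
    "loec",
    "direction_profile",
    "direct_receptor_calls",
    "masking_rule",
    "ci_overlap_diagnostic",
    "classify_chemical",
]

CYTOTOX_VIABILITY_THRESHOLD = 80.0
BIOLOGICAL_RELEVANCE_PCT = 10.0

class Effect(str, Enum):
    UP = "up"
    DOWN = "down"
    DOWN_THEN_UP = "down_then_up"
    ND = "nd"


class MaskedBy(str, Enum):
    NONE = "none"
    DIRECT_RECEPTOR = "direct_receptor"
    CYTOTOXICITY = "cytotoxicity"


@dataclass(frozen=True)
class ConcCall:
    """One tested concentration's steroidogenesis call (nominal mol/L)."""

    conc: float
    significant: bool
    direction: Direction


@dataclass(frozen=True)
class DirectObservation:
    """One tested concentration's sham-well (direct receptor) call."""

    conc_nominal: float
    conc_calux: float
    significant: bool
    #: |mean activity - no-activity reference| in %RI points
    mean_deviation: float
    calux_cytotoxic: bool = False

    @property
    def biologically_relevant(self) -> bool:
        return self.mean_deviation >= BIOLOGICAL_RELEVANCE_PCT


@dataclass
class DirectActivity:
    present: bool
    loec_calux: float | None = None
    loec_nominal: float | None = None
    #: nominal concentrations where the direct activity is both significant
    #: and biologically relevant (used by the masking rule)
    active_nominal_concs: frozenset[float] = frozenset()


@dataclass
class FamilyClassification:
    effect: Effect
    loec_h295r: float | None
    masked_by: MaskedBy
    #: candidate LOEC of a masked (demoted) apparent effect
    apparent_loec: float | None = None
    notes: str = ""

    def __post_init__(self):
        if (self.loec_h295r is not None) != (self.effect is not Effect.ND):
            raise ValueError("LOEC must be set exactly when an effect is called")
        if self.masked_by is not MaskedBy.NONE and self.effect is not Effect.ND:
            raise ValueError("a masked effect must be nd")


@dataclass
class ChemicalClassification:
    chemical_id: str
    families: dict[str, FamilyClassification]
    direct_estrogenicity: DirectActivity
    direct_antiandrogenicity: DirectActivity
    cytotoxic_concs_h295r: list[float] = field(default_factory=list)
    notes: str = ""


@dataclass
class CytotoxicityFlags:
    """Mean-of-means % viability and cytotoxicity per assay and concentration."""

    table: pd.DataFrame  # columns: assay, conc, mean_viability, cytotoxic, spurious

    def cytotoxic_concs(self, assay: str) -> frozenset[float]:
        sub = self.table[(self.table["assay"] == assay) & self.table["cytotoxic"]]
        return frozenset(sub["conc"].tolist())

    def is_cytotoxic(self, assay: str, conc: float) -> bool:
        return conc in self.cytotoxic_concs(assay)


def flag_cytotoxicity(viability: pd.DataFrame,
                      threshold: float = CYTOTOX_VIABILITY_THRESHOLD,
                      ) -> CytotoxicityFlags:
    """Flag concentrations whose mean-of-means viability drops below 80%.

    ``viability`` needs columns assay, conc, bio_rep, pct_viability.  The
    technical replicates of each biological replicate are averaged first;
    the mean of those per-replicate means decides the flag.  Isolated dips
    (a flagged concentration with unflagged ones above it) are annotated as
    possibly spurious but remain flagged.
    """
    rows = []
    for (assay, conc), sub in viability.groupby(["assay", "conc"]):
        rep_means = sub.groupby("bio_rep")["pct_viability"].mean()
        mean_of_means = float(rep_means.mean())
        rows.append({"assay": assay, "conc": float(conc),
                     "mean_viability": mean_of_means,
                     "cytotoxic": mean_of_means < threshold})
    table = pd.DataFrame(rows, columns=["assay", "conc", "mean_viability", "cytotoxic"])
    spurious = []
    for _, row in table.iterrows():
        higher = table[(table["assay"] == row["assay"]) & (table["conc"] > row["conc"])]
        spurious.append(bool(row["cytotoxic"]) and bool((~higher["cytotoxic"]).any()))
    table["spurious"] = spurious
    return CytotoxicityFlags(table=table)


def _runs(calls: Sequence[ConcCall]) -> list[list[ConcCall]]:
    """Maximal runs of consecutive significant same-direction calls."""
    runs: list[list[ConcCall]] = []
    current: list[ConcCall] = []
    for call in sorted(calls, key=lambda c: c.conc):
        if call.significant and call.direction in (Direction.UP, Direction.DOWN):
            if current and current[-1].direction is not call.direction:
                runs.append(current)
                current = []
            current.append(call)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def positivity_rule(calls: Sequence[ConcCall],
                    cytotoxic_concs: frozenset[float] = frozenset(),
                    ) -> list[list[ConcCall]]:
    """Qualifying evidence for a positive endpoint.

    A run qualifies when (a) it spans >= 2 consecutive tested
    concentrations with a consistent direction, or (b) it contains the
    highest noncytotoxic tested concentration.  Isolated significant
    concentrations meeting neither branch are discarded.
    """
    calls = sorted(calls, key=lambda c: c.conc)
    noncytotoxic = [c.conc for c in calls if c.conc not in cytotoxic_concs]
    top = max(noncytotoxic) if noncytotoxic else None
    qualifying = []
    for run in _runs(calls):
        if len(run) >= 2 or (top is not None and any(c.conc == top for c in run)):
            qualifying.append(run)
    return qualifying


def loec(qualifying_runs: Sequence[Sequence[ConcCall]]) -> float:
    """Lowest concentration of the qualifying evidence.

    Isolated-by-chance hits below the qualifying run were already discarded
    by the positivity rule and therefore never lower the LOEC.
    """
    if not qualifying_runs:
        raise ValueError("LOEC requested for a negative endpoint")
    return min(run[0].conc for run in qualifying_runs)


def direction_profile(qualifying_runs: Sequence[Sequence[ConcCall]]) -> Effect:
    """Effect direction over the qualifying runs.

    All runs up -> up, all down -> down; every down-run preceding every
    up-run -> biphasic down-then-up.
    """
    if not qualifying_runs:
        return Effect.ND
    runs = sorted(qualifying_runs, key=lambda r: r[0].conc)
    dirs = [run[0].direction for run in runs]
    if all(d is Direction.UP for d in dirs):
        return Effect.UP
    if all(d is Direction.DOWN for d in dirs):
        return Effect.DOWN
    down_concs = [run[-1].conc for run in runs if run[0].direction is Direction.DOWN]
    up_concs = [run[0].conc for run in runs if run[0].direction is Direction.UP]
    if down_concs and up_concs and max(down_concs) < min(up_concs):
        return Effect.DOWN_THEN_UP
    return Effect.ND


def direct_receptor_calls(observations: Sequence[DirectObservation],
                          ) -> DirectActivity:
    """Direct receptor activity from sham-well calls.

    CALUX-cytotoxic concentrations are excluded from the evidence, and a
    significant call only counts when it is also biologically relevant
    (>= 10 %RI points from the no-activity level).  The positivity rule
    then applies on the nominal concentration axis; the LOEC is reported
    in CALUX-well molarity.
    """
    usable = [o for o in observations if not o.calux_cytotoxic]
    calls = [ConcCall(o.conc_nominal,
                      o.significant and o.biologically_relevant,
                      Direction.UP) for o in usable]
    runs = positivity_rule(calls)
    active = frozenset(o.conc_nominal for o in usable
                       if o.significant and o.biologically_relevant)
    if not runs:
        return DirectActivity(present=False, active_nominal_concs=active)
    loec_nominal = loec(runs)
    by_nominal = {o.conc_nominal: o for o in usable}
    return DirectActivity(
        present=True,
        loec_calux=by_nominal[loec_nominal].conc_calux,
        loec_nominal=loec_nominal,
        active_nominal_concs=active)


def masking_rule(qualifying_runs: Sequence[Sequence[ConcCall]],
                 direct: DirectActivity,
                 h295r_cytotoxic: frozenset[float],
                 calux_cytotoxic_nominal: frozenset[float],
                 ) -> FamilyClassification:
    """Demote apparent steroidogenic effects explained by a confounder.

    A qualifying run is attributed to direct receptor activity when the
    direct call is significant and biologically relevant at any of the same
    nominal concentrations; a down-run is attributed to cytotoxicity when
    all of its concentrations are cytotoxic to the hormone-producing cells
    while the detection cells' viability there is normal.  Only runs
    surviving both attributions support a steroidogenesis call; demotion
    never promotes a negative.
    """
    surviving: list[Sequence[ConcCall]] = []
    masked_direct: list[Sequence[ConcCall]] = []
    masked_cytotox: list[Sequence[ConcCall]] = []
    for run in qualifying_runs:
        concs = {c.conc for c in run}
        if direct.active_nominal_concs & concs:
            masked_direct.append(run)
        elif (run[0].direction is Direction.DOWN
              and concs <= h295r_cytotoxic
              and not (concs & calux_cytotoxic_nominal)):
            masked_cytotox.append(run)
        else:
            surviving.append(run)
    if surviving:
        return FamilyClassification(
            effect=direction_profile(surviving),
            loec_h295r=loec(surviving),
            masked_by=MaskedBy.NONE)
    if masked_direct:
        return FamilyClassification(
            effect=Effect.ND, loec_h295r=None,
            masked_by=MaskedBy.DIRECT_RECEPTOR,
            apparent_loec=loec(masked_direct),
            notes="apparent effect co-occurs with direct receptor activity")
    if masked_cytotox:
        return FamilyClassification(
            effect=Effect.ND, loec_h295r=None,
            masked_by=MaskedBy.CYTOTOXICITY,
            notes="apparent decrease attributable to reduced cell viability")
    return FamilyClassification(effect=Effect.ND, loec_h295r=None,
                                masked_by=MaskedBy.NONE)


def ci_overlap_diagnostic(activity: Sequence[float], sham: Sequence[float],
                          n_boot: int = 2000, seed: int = 0,
                          ) -> dict:
    """Bootstrap 95% CIs of two group means plus overlap / separation flags.

    Reports whether the percentile CIs overlap and whether the gap between
    them exceeds the 10-point biological-relevance band.
    """
    a = np.asarray(activity, dtype=float)
    b = np.asarray(sham, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need n >= 3")
    rng = np.random.default_rng(seed)
    boots_a = rng.choice(a, size=(n_boot, len(a)), replace=True).mean(axis=1)
    boots_b = rng.choice(b, size=(n_boot, len(b)), replace=True).mean(axis=1)
    ci_a = tuple(np.percentile(boots_a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(boots_b, [2.5, 97.5]))
    overlap = ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]
    gap = max(0.0, max(ci_a[0] - ci_b[1], ci_b[0] - ci_a[1]))
    return {"ci_a": ci_a, "ci_b": ci_b, "overlap": overlap,
            "gap": gap, "delta_ge_10": gap >= BIOLOGICAL_RELEVANCE_PCT}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _conc_calls(calls: Iterable[StatCall]) -> list[ConcCall]:
    return [ConcCall(c.conc, c.significant, c.direction) for c in calls]


def direct_observations(calls: Iterable[StatCall],
                        mean_activity: Mapping[float, float],
                        fold_dilution: float,
                        calux_cytotoxic_nominal: frozenset[float] = frozenset(),
                        ) -> list[DirectObservation]:
    """Assemble sham-well observations from stat calls and group means.

    ``mean_activity`` maps nominal concentration to the group's mean %RI;
    the deviation from the endpoint's no-activity reference level feeds the
    biological-relevance test.
    """
    obs = []
    for c in calls:
        ref = DIRECT_REFERENCE_LEVEL[c.endpoint]
        obs.append(DirectObservation(
            conc_nominal=c.conc,
            conc_calux=c.conc / fold_dilution,
            significant=c.significant,
            mean_deviation=abs(mean_activity[c.conc] - ref),
            calux_cytotoxic=c.conc in calux_cytotoxic_nominal))
    return obs


def classify_chemical(chemical_id: str,
                      steroid_calls: Mapping[str, Sequence[ConcCall]],
                      direct_calls: Mapping[str, DirectActivity],
                      h295r_cytotoxic: frozenset[float],
                      calux_cytotoxic_nominal: Mapping[str, frozenset[float]] | None = None,
                      ) -> ChemicalClassification:
    """Classify one chemical across both hormone families.

    ``steroid_calls`` maps family ("estrogens"/"androgens") to its ordered
    per-concentration calls; ``direct_calls`` maps family to the matching
    direct receptor activity (ER agonism for estrogens, AR antagonism for
    androgens).  ``calux_cytotoxic_nominal`` lists nominal concentrations
    at which the detection cells themselves are cytotoxic.
    """
    families = {}
    for family, calls in steroid_calls.items():
        calux_cyto = (calux_cytotoxic_nominal or {}).get(family, frozenset())
        # Steroidogenesis readouts at concentrations cytotoxic to the
        # detection cells are unreliable and carry no evidential weight.
        usable = [c for c in calls if c.conc not in calux_cyto]
        runs = positivity_rule(usable, h295r_cytotoxic | calux_cyto)
        families[family] = masking_rule(
            runs, direct_calls.get(family, DirectActivity(False)),
            h295r_cytotoxic, calux_cyto)
    return ChemicalClassification(
        chemical_id=chemical_id,
        families=families,
        direct_estrogenicity=direct_calls.get("estrogens", DirectActivity(False)),
        direct_antiandrogenicity=direct_calls.get("androgens", DirectActivity(False)),
        cytotoxic_concs_h295r=sorted(h295r_cytotoxic))
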