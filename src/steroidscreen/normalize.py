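"""Raw RLU -> % viability, % relative induction and % of basal production.

Reporter signals are background-subtracted (mean of the standard-curve
vehicle wells) and scaled to a plate reference: in agonist mode the largest
per-concentration mean along the standard curve, in antagonist mode the
agonist-only wells of the antagonist curve.  The resulting % relative
induction (%RI) of hormone-producing wells is then re-normalized to the
vehicle-treated cells' own activity (% of basal production, 100% = no
effect).  Direct (sham-well) readouts stay on the %RI scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from statistics import fmean
from typing import Iterable, Sequence

import pandas as pd

from .plates import Assay, Mode, PlateSet, Role, WellMeasurement

__all__ = [
    "Endpoint",
    "NormalizedActivity",
    "percent_viability",
    "background_level",
    "relative_induction",
    "to_basal",
    "calux_concentration",
    "normalize_plate",
    "normalize_plate_set",
    "activities_frame",
]


class Endpoint(str, Enum):
    ESTROGEN_ACTIVITY = "estrogen_activity"
    ANDROGEN_ACTIVITY = "androgen_activity"
    DIRECT_ESTROGENICITY = "direct_estrogenicity"
    DIRECT_ANTIANDROGENICITY = "direct_antiandrogenicity"
    DIRECT_ANDROGENICITY = "direct_androgenicity"


#: Direct endpoints are compared against these %RI reference levels
#: (no-activity baseline): 0% for agonist-mode, 100% for antagonist-mode.
DIRECT_REFERENCE_LEVEL = {
    Endpoint.DIRECT_ESTROGENICITY: 0.0,
    Endpoint.DIRECT_ANDROGENICITY: 0.0,
    Endpoint.DIRECT_ANTIANDROGENICITY: 100.0,
}


@dataclass
class NormalizedActivity:
    """One well's normalized readout for one endpoint."""

    chemical_id: str | None
    conc_h295r: float | None
    conc_calux: float | None
    endpoint: Endpoint
    pct_viability: float
    pct_ri: float
    pct_of_basal: float | None  # None for direct endpoints
    bio_rep: int
    tech_rep: int
    plate_id: str
    role: Role
    assay: Assay
    control_name: str | None = None


def percent_viability(rlu: float, reference_mean: float) -> float:
    """Viability of one well as % of the reference-mean viability RLU."""
    if reference_mean <= 0:
        raise ValueError("viability reference mean must be positive")
    return 100.0 * rlu / reference_mean


def background_level(standard_vehicle_rlus: Sequence[float]) -> float:
    """Mean reporter RLU of the standard-curve vehicle wells (>= 2 wells)."""
    if len(standard_vehicle_rlus) < 2:
        raise ValueError("background needs at least 2 standard-curve vehicle wells")
    return fmean(standard_vehicle_rlus)


def relative_induction(rlu: float, background: float, reference: float) -> float:
    """%RI = 100 * (rlu - background) / (reference - background).

    May legitimately fall below 0 or exceed 100.  A reference at or below
    background indicates a flat/failed standard curve and is an error.
    """
    span = reference - background
    if span <= 0:
        raise ValueError("reference must exceed background (flat or failed curve)")
    return 100.0 * (rlu - background) / span


def to_basal(pct_ri: float, basal_ri: float) -> float:
    """Re-normalize a %RI value to the vehicle-treated cells' mean %RI.

    100% = basal production; above 100% is induction, below is inhibition.
    """
    if basal_ri <= 0:
        raise ValueError("basal %RI must be positive")
    return 100.0 * pct_ri / basal_ri


def calux_concentration(conc_h295r: float, folds: float | Sequence[float]) -> float:
    """Dilution-corrected concentration in the detection plate.

    ``folds`` is a single fold-dilution or the per-plate folds actually
    used, in which case their arithmetic mean is applied (this averaging
    can introduce up to ~23% error in reported concentrations).
    """
    if not isinstance(folds, (int, float)):
        folds = fmean(folds)
    if folds < 1:
        raise ValueError("fold dilution must be >= 1")
    return conc_h295r / folds


# ---------------------------------------------------------------------------
# Plate-level normalization
# ---------------------------------------------------------------------------

_ENDPOINT_BY_ASSAY = {
    Assay.ER_CALUX: (Endpoint.ESTROGEN_ACTIVITY, Endpoint.DIRECT_ESTROGENICITY),
    Assay.AR_CALUX: (Endpoint.ANDROGEN_ACTIVITY, Endpoint.DIRECT_ANTIANDROGENICITY),
}


def _is_curve_vehicle(w: WellMeasurement) -> bool:
    return (w.role is Role.STANDARD_CURVE and (w.conc_standard or 0.0) == 0.0
            and w.co_agonist_conc == 0.0)


def _is_agonist_only(w: WellMeasurement) -> bool:
    return (w.role is Role.STANDARD_CURVE and (w.conc_standard or 0.0) == 0.0
            and w.co_agonist_conc > 0.0)


def plate_reference(plate: Sequence[WellMeasurement], mode: Mode,
                    background: float) -> float:
    """Reporter reference RLU for %RI on one CALUX plate.

    Agonist mode: the largest per-concentration mean along the standard
    curve (the observed plateau, not a fitted top).  Antagonist mode: the
    mean of the agonist-only wells of the antagonist curve.
    """
    if mode is Mode.ANTAGONIST:
        wells = [w.rlu_reporter for w in plate if _is_agonist_only(w)]
        if not wells:
            raise ValueError("antagonist mode requires agonist-only curve wells")
        ref = fmean(wells)
    else:
        by_conc: dict[float, list[float]] = {}
        for w in plate:
            if w.role is Role.STANDARD_CURVE and (w.conc_standard or 0.0) > 0:
                by_conc.setdefault(w.conc_standard, []).append(w.rlu_reporter)
        if not by_conc:
            raise ValueError("no standard-curve wells on plate")
        ref = max(fmean(v) for v in by_conc.values())
    if ref <= background:
        raise ValueError("reference must exceed background (flat or failed curve)")
    return ref


def normalize_plate(plate: Sequence[WellMeasurement], assay: Assay,
                    fold_dilution: float) -> list[NormalizedActivity]:
    """Normalize one CALUX plate into per-well activity records.

    Wells whose supernatant came from hormone-producing wells yield the
    hormone-activity endpoint (with % of basal); sham wells yield the
    direct-receptor endpoint on the %RI scale.  Standard-curve wells are
    re-emitted as %RI records (role preserved) so QC can fit the curve.
    """
    activity_ep, direct_ep = _ENDPOINT_BY_ASSAY[assay]
    background = background_level([w.rlu_reporter for w in plate if _is_curve_vehicle(w)])
    viab_ref = fmean([w.rlu_viability for w in plate if _is_curve_vehicle(w)])

    # Sham wells of an agonist-mode AR plate measure direct androgenicity.
    modes = {w.mode for w in plate if w.role is Role.SHAM}
    if assay is Assay.AR_CALUX and modes == {Mode.AGONIST}:
        direct_ep = Endpoint.DIRECT_ANDROGENICITY

    basal_wells = [w for w in plate
                   if w.role is Role.VEHICLE_CONTROL and w.has_cells]

    def ri(w: WellMeasurement) -> float:
        ref = plate_reference(plate, w.mode, background)
        return relative_induction(w.rlu_reporter, background, ref)

    basal_ri = fmean([ri(w) for w in basal_wells]) if basal_wells else None

    out: list[NormalizedActivity] = []
    for w in plate:
        pct_v = percent_viability(w.rlu_viability, viab_ref)
        if w.role is Role.STANDARD_CURVE:
            out.append(NormalizedActivity(
                chemical_id=w.chemical_id, conc_h295r=None,
                conc_calux=w.conc_standard, endpoint=activity_ep,
                pct_viability=pct_v, pct_ri=ri(w), pct_of_basal=None,
                bio_rep=w.bio_rep, tech_rep=w.tech_rep, plate_id=w.plate_id,
                role=w.role, assay=assay))
            continue
        pct_ri = ri(w)
        conc_calux = (None if w.conc_h295r is None
                      else calux_concentration(w.conc_h295r, fold_dilution))
        if w.has_cells:
            basal = None
            if basal_ri is not None and basal_ri > 0:
                basal = to_basal(pct_ri, basal_ri)
            out.append(NormalizedActivity(
                chemical_id=w.chemical_id, conc_h295r=w.conc_h295r,
                conc_calux=conc_calux, endpoint=activity_ep,
                pct_viability=pct_v, pct_ri=pct_ri, pct_of_basal=basal,
                bio_rep=w.bio_rep, tech_rep=w.tech_rep, plate_id=w.plate_id,
                role=w.role, assay=assay,
                control_name=w.chemical_id if w.role is Role.POSITIVE_CONTROL else None))
        else:
            out.append(NormalizedActivity(
                chemical_id=w.chemical_id, conc_h295r=w.conc_h295r,
                conc_calux=conc_calux, endpoint=direct_ep,
                pct_viability=pct_v, pct_ri=pct_ri, pct_of_basal=None,
                bio_rep=w.bio_rep, tech_rep=w.tech_rep, plate_id=w.plate_id,
                role=w.role, assay=assay,
                control_name=w.chemical_id if w.role is Role.POSITIVE_CONTROL else None))
    return out


def h295r_viability(plate: Sequence[WellMeasurement]) -> pd.DataFrame:
    """Per-well % viability of the hormone-producing plate.

    Reference: mean viability RLU of the vehicle-treated wells with cells.
    Cell-free wells are skipped (no viability to speak of).
    """
    ref_wells = [w.rlu_viability for w in plate
                 if w.role is Role.VEHICLE_CONTROL and w.has_cells]
    if not ref_wells:
        raise ValueError("no vehicle-control wells with cells on the plate")
    ref = fmean(ref_wells)
    rows = []
    for w in plate:
        if not w.has_cells:
            continue
        rows.append({
            "plate_id": w.plate_id, "assay": Assay.H295R.value,
            "chemical_id": w.chemical_id, "conc_h295r": w.conc_h295r,
            "role": w.role.value, "bio_rep": w.bio_rep, "tech_rep": w.tech_rep,
            "pct_viability": percent_viability(w.rlu_viability, ref),
        })
    return pd.DataFrame(rows)


def normalize_plate_set(ps: PlateSet) -> tuple[list[NormalizedActivity], pd.DataFrame]:
    """Normalize all detection plates of one plate set.

    The per-chemical ER dilution factor is the arithmetic mean of the three
    ER plates' folds.  Returns (activity records, H295R viability table).
    """
    mean_er_fold = ps.dilution_scheme.er_mean_fold
    records: list[NormalizedActivity] = []
    for plate in ps.er_plates:
        records.extend(normalize_plate(plate, Assay.ER_CALUX, mean_er_fold))
    records.extend(normalize_plate(ps.ar_plate, Assay.AR_CALUX,
                                   ps.dilution_scheme.ar_fold))
    return records, h295r_viability(ps.h295r_plate)


def activities_frame(records: Iterable[NormalizedActivity]) -> pd.DataFrame:
    """Tidy table of normalized activities, one row per well per endpoint."""
    rows = []
    for r in records:
        rows.append({
            "chemical_id": r.chemical_id,
            "conc_h295r": math.nan if r.conc_h295r is None else r.conc_h295r,
            "conc_calux": math.nan if r.conc_calux is None else r.conc_calux,
            "endpoint": r.endpoint.value,
            "pct_viability": r.pct_viability,
            "pct_ri": r.pct_ri,
            "pct_of_basal": math.nan if r.pct_of_basal is None else r.pct_of_basal,
            "bio_rep": r.bio_rep, "tech_rep": r.tech_rep,
            "plate_id": r.plate_id, "role": r.role.value, "assay": r.assay.value,
            "control_name": r.control_name,
        })
    return pd.DataFrame(rows)
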