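"""End-to-end orchestration: normalize -> QC -> stats -> classify.

One analysis run covers a single test chemical's experiment: three
biological replicates, each a five-plate set.  Per biological replicate one
of the three ER detection plates is selected (the one whose basal signal
sits best inside the quantifiable window); QC criteria are evaluated at
experiment level for the curve statistics and per replicate for the
basal-window and CV checks, and failing replicates are excluded from
pooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from statistics import fmean, stdev
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc as qcmod
from .classify import (ChemicalClassification, ConcCall, CytotoxicityFlags,
                       DirectActivity, classify_chemical, direct_observations,
                       direct_receptor_calls, flag_cytotoxicity)
from .normalize import (Endpoint, NormalizedActivity, activities_frame,
                        normalize_plate_set)
from .npstats import StatCall, StatsConfig, calls_frame, compute_stat_calls
from .plates import Assay, PlateSet, Role, WellMeasurement
from .qc import (CriterionCheck, FitError, QCThresholds, Verdict, _check,
                 fit_standard_curve, induction_factor, loq, plate_verdict,
                 z_factor)

__all__ = ["AnalysisConfig", "AnalysisBundle", "analyze_experiment"]

FAMILY_STEROID_ENDPOINT = {
    "estrogens": Endpoint.ESTROGEN_ACTIVITY,
    "androgens": Endpoint.ANDROGEN_ACTIVITY,
}
FAMILY_DIRECT_ENDPOINT = {
    "estrogens": Endpoint.DIRECT_ESTROGENICITY,
    "androgens": Endpoint.DIRECT_ANTIANDROGENICITY,
}
FAMILY_ASSAY = {"estrogens": Assay.ER_CALUX, "androgens": Assay.AR_CALUX}


@dataclass(frozen=True)
class AnalysisConfig:
    stats: StatsConfig = field(default_factory=StatsConfig)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    exclude_failed_reps: bool = True


@dataclass
class AnalysisBundle:
    chemical_id: str
    qc: dict
    stat_calls: pd.DataFrame
    classification: ChemicalClassification
    cytotox: CytotoxicityFlags
    excluded_bio_reps: dict[str, list[int]]
    selected_er_plates: dict[int, str]

    def to_json(self) -> str:
        payload = {
            "chemical_id": self.chemical_id,
            "qc": self.qc,
            "stat_calls": self.stat_calls.to_dict(orient="records"),
            "classification": classification_to_dict(self.classification),
            "cytotox": self.cytotox.table.to_dict(orient="records"),
            "excluded_bio_reps": self.excluded_bio_reps,
            "selected_er_plates": self.selected_er_plates,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def classification_to_dict(c: ChemicalClassification) -> dict:
    return {
        "chemical_id": c.chemical_id,
        "families": {
            fam: {
                "effect": fc.effect.value,
                "loec_h295r": fc.loec_h295r,
                "masked_by": fc.masked_by.value,
                "apparent_loec": fc.apparent_loec,
                "notes": fc.notes,
            } for fam, fc in c.families.items()},
        "direct_estrogenicity": {
            "present": c.direct_estrogenicity.present,
            "loec_calux": c.direct_estrogenicity.loec_calux},
        "direct_antiandrogenicity": {
            "present": c.direct_antiandrogenicity.present,
            "loec_calux": c.direct_antiandrogenicity.loec_calux},
        "cytotoxic_concs_h295r": c.cytotoxic_concs_h295r,
        "notes": c.notes,
    }


# ---------------------------------------------------------------------------
# ER plate selection
# ---------------------------------------------------------------------------

def _basal_ri(records: Sequence[NormalizedActivity], plate_id: str) -> float | None:
    vals = [r.pct_ri for r in records
            if r.plate_id == plate_id and r.role is Role.VEHICLE_CONTROL
            and r.endpoint is Endpoint.ESTROGEN_ACTIVITY and r.pct_of_basal is not None]
    return fmean(vals) if vals else None


def select_er_plate(records: Sequence[NormalizedActivity],
                    er_plate_ids: Sequence[str],
                    window: tuple[float, float] = (20.0, 80.0)) -> str:
    """Pick the ER dilution whose basal %RI sits best inside the window.

    Preference: inside the window and nearest its midpoint; if none
    qualifies, nearest to the midpoint overall.
    """
    mid = (window[0] + window[1]) / 2.0
    scored = []
    for pid in er_plate_ids:
        basal = _basal_ri(records, pid)
        if basal is None:
            continue
        inside = window[0] <= basal <= window[1]
        scored.append((not inside, abs(basal - mid), pid))
    if not scored:
        raise ValueError("no ER plate with measurable basal signal")
    return min(scored)[2]


# ---------------------------------------------------------------------------
# QC evaluation
# ---------------------------------------------------------------------------

def _curve_wells(plates: Sequence[Sequence[WellMeasurement]]):
    for plate in plates:
        for w in plate:
            if w.role is Role.STANDARD_CURVE:
                yield w


def _family_qc(plates_by_rep: Mapping[int, Sequence[WellMeasurement]],
               records: Sequence[NormalizedActivity],
               family: str, antagonist: bool,
               thresholds: QCThresholds) -> tuple[dict, dict[int, dict]]:
    """Experiment-level curve criteria + per-replicate basal/CV checks."""
    fam_key = "antiandrogens" if antagonist else family
    curve = list(_curve_wells(plates_by_rep.values()))
    vehicle = [w for w in curve if (w.conc_standard or 0) == 0 and w.co_agonist_conc == 0]
    if antagonist:
        pos = [w for w in curve if (w.conc_standard or 0) == 0 and w.co_agonist_conc > 0]
    else:
        top = max(w.conc_standard for w in curve if w.conc_standard)
        pos = [w for w in curve if w.conc_standard == top]
    mu_pos, sd_pos = fmean([w.rlu_reporter for w in pos]), stdev([w.rlu_reporter for w in pos])
    mu_neg, sd_neg = fmean([w.rlu_reporter for w in vehicle]), stdev([w.rlu_reporter for w in vehicle])

    # %RI of curve wells, pooled across replicates (per-plate reference).
    plate_ids = {w.plate_id for w in curve}
    curve_points: list[tuple[float, float]] = []
    vehicle_ri: list[float] = []
    for pid in plate_ids:
        wells = [w for w in curve if w.plate_id == pid]
        bg = fmean([w.rlu_reporter for w in wells
                    if (w.conc_standard or 0) == 0 and w.co_agonist_conc == 0])
        if antagonist:
            ref = fmean([w.rlu_reporter for w in wells
                         if (w.conc_standard or 0) == 0 and w.co_agonist_conc > 0])
        else:
            by_conc: dict[float, list[float]] = {}
            for w in wells:
                if (w.conc_standard or 0) > 0:
                    by_conc.setdefault(w.conc_standard, []).append(w.rlu_reporter)
            ref = max(fmean(v) for v in by_conc.values())
        span = ref - bg
        for w in wells:
            ri = 100.0 * (w.rlu_reporter - bg) / span
            if (w.conc_standard or 0) > 0:
                curve_points.append((w.conc_standard, ri))
            elif w.co_agonist_conc == 0:
                vehicle_ri.append(ri)

    checks: dict[str, CriterionCheck] = {}
    the_loq = loq(vehicle_ri)
    checks["loq"] = _check("loq", the_loq, thresholds.loq_max[fam_key], "<=")
    checks["induction_factor"] = _check(
        "induction_factor", induction_factor(mu_pos, mu_neg),
        thresholds.induction_factor_min[fam_key], ">=")
    checks["z_factor"] = _check(
        "z_factor", z_factor(mu_pos, sd_pos, mu_neg, sd_neg),
        thresholds.z_factor_min[fam_key], ">=")
    fit_info = None
    try:
        fit = fit_standard_curve(*zip(*curve_points))
        checks["r_squared"] = _check("r_squared", fit.r_squared,
                                     thresholds.r_squared_min[fam_key], ">=")
        lo, hi = thresholds.ac50_window[fam_key]
        inside = lo <= fit.ac50 <= hi
        excess = 0.0 if inside else min(abs(fit.ac50 - lo) / lo, abs(fit.ac50 - hi) / hi)
        checks["ac50_window"] = CriterionCheck(
            "ac50_window", fit.ac50, lo if fit.ac50 < lo else hi,
            ">=" if fit.ac50 < lo else "<=", inside, excess)
        fit_info = asdict(fit)
    except FitError:
        checks["r_squared"] = CriterionCheck(
            "r_squared", None, thresholds.r_squared_min[fam_key], ">=", False, None)
        checks["ac50_window"] = CriterionCheck(
            "ac50_window", None, thresholds.ac50_window[fam_key][0], ">=", False, None)

    # Solvent-control production relative to LOQ (uses basal %RI pooled
    # over replicates) plus per-replicate basal-window and CV checks.
    basal_by_rep: dict[int, list[float]] = {}
    for r in records:
        if (r.role is Role.VEHICLE_CONTROL and r.pct_of_basal is not None
                and r.endpoint is FAMILY_STEROID_ENDPOINT[family]):
            basal_by_rep.setdefault(r.bio_rep, []).append(r.pct_ri)
    rep_checks: dict[int, dict[str, CriterionCheck]] = {}
    lo_w, hi_w = thresholds.basal_window_pct[fam_key]
    for rep, vals in sorted(basal_by_rep.items()):
        basal_mean = fmean(vals)
        inside = lo_w <= basal_mean <= hi_w
        excess = 0.0 if inside else min(abs(basal_mean - lo_w) / lo_w,
                                        abs(basal_mean - hi_w) / hi_w)
        window = CriterionCheck("basal_window", basal_mean,
                                lo_w if basal_mean < lo_w else hi_w,
                                ">=" if basal_mean < lo_w else "<=", inside, excess)
        cv = 100.0 * stdev(vals) / basal_mean if basal_mean > 0 else float("inf")
        rep_checks[rep] = {
            "basal_window": window,
            "cv_within": _check("cv_within", cv, thresholds.cv_within_max, "<="),
        }
    all_basal = [fmean(v) for v in basal_by_rep.values()]
    if len(all_basal) >= 2:
        cv_between = 100.0 * stdev(all_basal) / fmean(all_basal)
        checks["cv_between"] = _check("cv_between", cv_between,
                                      thresholds.cv_between_max, "<=")
    if the_loq > 0:
        pooled_basal = fmean([v for vals in basal_by_rep.values() for v in vals])
        checks["basal_over_loq"] = _check(
            "basal_over_loq", pooled_basal / the_loq,
            thresholds.basal_over_loq_min[fam_key], ">=")

    verdict, tolerated = plate_verdict(checks, thresholds.tolerance)
    report = {
        "family": fam_key,
        "loq": the_loq,
        "fit": fit_info,
        "checks": {k: asdict(v) for k, v in checks.items()},
        "verdict": verdict.value,
        "tolerated_criteria": tolerated,
        "replicates": {
            rep: {
                "checks": {k: asdict(v) for k, v in cs.items()},
                "verdict": plate_verdict(cs, thresholds.tolerance)[0].value,
            } for rep, cs in rep_checks.items()},
    }
    per_rep_verdicts = {rep: plate_verdict(cs, thresholds.tolerance)[0]
                        for rep, cs in rep_checks.items()}
    return report, per_rep_verdicts


def _control_value(df: pd.DataFrame, control: str, endpoint: Endpoint) -> float | None:
    sub = df[(df["control_name"] == control) & (df["endpoint"] == endpoint.value)
             & (df["role"] == Role.POSITIVE_CONTROL.value)]
    vals = sub["pct_of_basal"].dropna()
    return float(vals.mean()) if len(vals) else None


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def analyze_experiment(plate_sets: Sequence[PlateSet],
                       cfg: AnalysisConfig = AnalysisConfig()) -> AnalysisBundle:
    """Run the full analysis for one chemical's biological replicates."""
    all_records: list[NormalizedActivity] = []
    h295r_viability_frames = []
    selected: dict[int, str] = {}
    plates_by_rep_er: dict[int, list[WellMeasurement]] = {}
    plates_by_rep_ar: dict[int, list[WellMeasurement]] = {}

    for ps in plate_sets:
        records, viab = normalize_plate_set(ps)
        bio_rep = ps.h295r_plate[0].bio_rep
        er_ids = [plate[0].plate_id for plate in ps.er_plates]
        chosen = select_er_plate(records, er_ids)
        selected[bio_rep] = chosen
        kept = [r for r in records
                if r.assay is not Assay.ER_CALUX or r.plate_id == chosen]
        all_records.extend(kept)
        h295r_viability_frames.append(viab)
        plates_by_rep_er[bio_rep] = next(p for p in ps.er_plates
                                         if p[0].plate_id == chosen)
        plates_by_rep_ar[bio_rep] = ps.ar_plate

    df = activities_frame(all_records)
    chemicals = [c for c in df["chemical_id"].dropna().unique()
                 if c not in ("forskolin", "pfos", "prochloraz", "menadione")]
    if len(chemicals) != 1:
        raise ValueError(f"expected a single test chemical, found {chemicals}")
    chemical = chemicals[0]

    thresholds = cfg.thresholds
    ar_antagonist = any(r.endpoint is Endpoint.DIRECT_ANTIANDROGENICITY
                        for r in all_records)
    qc_report: dict = {}
    excluded: dict[str, list[int]] = {}
    qc_report["estrogens"], er_verdicts = _family_qc(
        plates_by_rep_er, all_records, "estrogens", False, thresholds)
    qc_report["androgens"], ar_verdicts = _family_qc(
        plates_by_rep_ar, all_records, "androgens", ar_antagonist, thresholds)

    # Control-substance checks (plate-level, pooled over replicates).
    ctrl = {
        "forskolin_estrogen_induction": _control_value(
            df, "forskolin", Endpoint.ESTROGEN_ACTIVITY),
        "pfos_androgen_induction": _control_value(
            df, "pfos", Endpoint.ANDROGEN_ACTIVITY),
        "prochloraz_inhibition": _control_value(
            df, "prochloraz", Endpoint.ESTROGEN_ACTIVITY),
    }
    h295r_viab = pd.concat(h295r_viability_frames, ignore_index=True)
    men = h295r_viab[h295r_viab["chemical_id"] == "menadione"]["pct_viability"]
    ctrl["menadione_viability"] = float(men.mean()) if len(men) else None
    control_report = qcmod.control_checks(ctrl, thresholds)
    qc_report["controls"] = {k: asdict(v) for k, v in control_report.items()}

    for family, verdicts in (("estrogens", er_verdicts), ("androgens", ar_verdicts)):
        excluded[family] = sorted(
            rep for rep, v in verdicts.items() if v is Verdict.FAIL
        ) if cfg.exclude_failed_reps else []

    # Cytotoxicity flags: H295R from its own plate, detection cells from
    # the normalized records (nominal concentration axis).
    viab_rows = []
    test_viab = h295r_viab[(h295r_viab["role"] == Role.H295R_TREATED.value)
                           & (h295r_viab["chemical_id"] == chemical)]
    for _, row in test_viab.iterrows():
        viab_rows.append({"assay": Assay.H295R.value, "conc": row["conc_h295r"],
                          "bio_rep": row["bio_rep"],
                          "pct_viability": row["pct_viability"]})
    calux = df[(df["chemical_id"] == chemical) & df["conc_h295r"].notna()]
    for _, row in calux.iterrows():
        viab_rows.append({"assay": row["assay"], "conc": row["conc_h295r"],
                          "bio_rep": row["bio_rep"],
                          "pct_viability": row["pct_viability"]})
    cytotox = flag_cytotoxicity(pd.DataFrame(viab_rows))
    h295r_cyto = cytotox.cytotoxic_concs(Assay.H295R.value)
    calux_cyto = {
        "estrogens": cytotox.cytotoxic_concs(Assay.ER_CALUX.value),
        "androgens": cytotox.cytotoxic_concs(Assay.AR_CALUX.value),
    }

    # Statistical calls per endpoint; failed replicates leave the pool.
    all_calls: list[StatCall] = []
    steroid_calls: dict[str, list[ConcCall]] = {}
    direct_acts: dict[str, DirectActivity] = {}
    for family in ("estrogens", "androgens"):
        keep = ~df["bio_rep"].isin(excluded[family])
        fam_df = df[keep & ((df["chemical_id"] == chemical) | df["chemical_id"].isna())]
        s_calls = compute_stat_calls(fam_df, FAMILY_STEROID_ENDPOINT[family], cfg.stats)
        d_endpoint = FAMILY_DIRECT_ENDPOINT[family]
        if family == "androgens" and not ar_antagonist:
            d_endpoint = Endpoint.DIRECT_ANDROGENICITY
        d_calls = compute_stat_calls(fam_df, d_endpoint, cfg.stats)
        all_calls.extend(s_calls)
        all_calls.extend(d_calls)
        steroid_calls[family] = [ConcCall(c.conc, c.significant, c.direction)
                                 for c in s_calls]
        sham = fam_df[(fam_df["endpoint"] == d_endpoint.value)
                      & (fam_df["role"] == Role.SHAM.value)]
        # Viability-corrected group means: a signal change fully explained
        # by reduced detection-cell viability is not receptor activity.
        grp = sham.groupby("conc_h295r")[["pct_ri", "pct_viability"]].mean()
        viab_frac = (grp["pct_viability"] / 100.0).clip(lower=0.05)
        mean_ri = (grp["pct_ri"] / viab_frac).to_dict()
        fold_map = sham.set_index("conc_h295r")["conc_calux"].to_dict()
        obs = []
        if d_calls:
            fold = (d_calls[0].conc / fold_map[d_calls[0].conc]
                    if fold_map.get(d_calls[0].conc) else 1.0)
            obs = direct_observations(d_calls, mean_ri, fold, calux_cyto[family])
        direct_acts[family] = direct_receptor_calls(obs)

    classification = classify_chemical(
        chemical, steroid_calls, direct_acts, h295r_cyto, calux_cyto)

    return AnalysisBundle(
        chemical_id=chemical,
        qc=qc_report,
        stat_calls=calls_frame(all_calls),
        classification=classification,
        cytotox=cytotox,
        excluded_bio_reps=excluded,
        selected_er_plates=selected,
    )
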