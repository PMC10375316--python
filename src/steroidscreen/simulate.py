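"""Synthetic five-plate experiments with known ground truth.

Simulates raw RLU tables for the coupled design: hormone production by
treated cells (Hill-shaped fold changes on basal output, scaled by viable
cell fraction), supernatant dilution onto reporter plates, direct receptor
activity of the carried chemical (additive agonist-equivalents for ER,
competitive AC50-shift antagonism for AR) appearing identically in treated
and sham wells, per-cell-type cytotoxicity, standard curves, and
multiplicative log-normal measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .plates import (Assay, DilutionScheme, LayoutWell, Mode, PlateSet, Role,
                     WellMeasurement, default_layout)

__all__ = [
    "HillTerm",
    "Cytotoxicity",
    "ChemicalModel",
    "CurveModel",
    "SimulationConfig",
    "four_pl",
    "hill_fraction",
    "simulate_hormones",
    "calux_signal",
    "simulate_plate_set",
    "assemble_experiment",
    "ground_truth",
    "preset",
    "PRESETS",
]


def hill_fraction(conc: float, ec50: float, hill: float = 1.0) -> float:
    """Occupancy-style Hill fraction in [0, 1); 0 at conc = 0."""
    if conc < 0:
        raise ValueError("negative concentration")
    if conc == 0:
        return 0.0
    return 1.0 / (1.0 + (ec50 / conc) ** hill)


def four_pl(conc: float, bottom: float, top: float, ac50: float,
            hill: float = 1.0) -> float:
    """4-parameter logistic response; equals (top+bottom)/2 at conc = ac50."""
    return bottom + (top - bottom) * hill_fraction(conc, ac50, hill)


@dataclass(frozen=True)
class HillTerm:
    """One Hill-shaped fold-change term on basal hormone production.

    ``max_fold`` > 1 is induction, < 1 inhibition; terms multiply, so a
    biphasic (down-then-up) response is a low-potency induction term on top
    of a high-potency inhibition term.
    """

    ec50: float
    max_fold: float
    hill: float = 1.0

    def fold(self, conc: float) -> float:
        return 1.0 + (self.max_fold - 1.0) * hill_fraction(conc, self.ec50, self.hill)


@dataclass(frozen=True)
class Cytotoxicity:
    lc50: float
    hill: float = 2.0

    def viability(self, conc: float) -> float:
        return 1.0 - hill_fraction(conc, self.lc50, self.hill)


@dataclass(frozen=True)
class ChemicalModel:
    """Ground-truth behaviour of one test chemical."""

    chemical_id: str
    concentration_grid: tuple[float, ...]  # 8 nominal mol/L concentrations
    estrogen_terms: tuple[HillTerm, ...] = ()
    androgen_terms: tuple[HillTerm, ...] = ()
    #: mol E2-equivalent per mol chemical (additive agonist-equivalents)
    er_agonism_eef: float | None = None
    #: competitive AR antagonism IC50 (mol/L)
    ar_antagonism_ic50: float | None = None
    cytotox_h295r: Cytotoxicity | None = None
    cytotox_calux: Cytotoxicity | None = None

    def __post_init__(self):
        if any(c <= 0 for c in self.concentration_grid):
            raise ValueError("concentrations must be positive")
        if self.er_agonism_eef is not None and self.er_agonism_eef <= 0:
            raise ValueError("EEF must be positive")
        if self.ar_antagonism_ic50 is not None and self.ar_antagonism_ic50 <= 0:
            raise ValueError("IC50 must be positive")

    def fold(self, family: str, conc: float) -> float:
        terms = self.estrogen_terms if family == "estrogens" else self.androgen_terms
        out = 1.0
        for t in terms:
            out *= t.fold(conc)
        return out

    def h295r_viability(self, conc: float) -> float:
        return self.cytotox_h295r.viability(conc) if self.cytotox_h295r else 1.0

    def calux_viability(self, conc_in_well: float) -> float:
        return self.cytotox_calux.viability(conc_in_well) if self.cytotox_calux else 1.0


@dataclass(frozen=True)
class CurveModel:
    """Reporter curve of one standard compound on its CALUX line."""

    ac50: float
    hill: float
    background_rlu: float
    span_rlu: float


# Curve midpoints sit at the centres of the plate-acceptance AC50 windows.
DEFAULT_CURVES: dict[str, CurveModel] = {
    "E2": CurveModel(ac50=1.825e-11, hill=1.0, background_rlu=200.0, span_rlu=4000.0),
    "DHT": CurveModel(ac50=2.75e-10, hill=1.0, background_rlu=150.0, span_rlu=6000.0),
}
# Competitive FLT IC50: the fitted curve midpoint lands near 2*IC50 when the
# co-agonist sits at its EC50, i.e. ~8.2e-7 M, centred in the window.
FLT_IC50 = 4.1e-7
AR_CO_AGONIST = 0.3e-9  # mol/L DHT in antagonist-mode wells


def _log_grid(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(float(10 ** x) for x in np.linspace(math.log10(lo), math.log10(hi), n))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    noise_cv: float = 0.10
    #: basal hormone-equivalents in the undiluted cell supernatant; defaults
    #: put the diluted basal at ~40% (ER) and ~50% (AR) curve response.
    basal_e2_equiv: float = 0.4 * 1.825e-11 * (200 / 30 + 200 / 28 + 8.0) / 3
    basal_dht_equiv: float = 3.0 * 2.75e-10
    dilution: DilutionScheme = field(default_factory=DilutionScheme)
    curves: Mapping[str, CurveModel] = field(default_factory=lambda: dict(DEFAULT_CURVES))
    viability_base_rlu: float = 5000.0
    ar_mode: str = "antagonist"  # sham-well AR mode; "agonist" uses a DHT curve
    e2_curve_grid: tuple[float, ...] = _log_grid(0.5e-12, 500e-12, 9)
    dht_curve_grid: tuple[float, ...] = _log_grid(5e-12, 0.5e-6, 9)
    flt_curve_grid: tuple[float, ...] = _log_grid(0.005e-6, 50e-6, 8)


def _noise(rng: np.random.Generator | None, cv: float) -> float:
    if rng is None or cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def simulate_hormones(model: ChemicalModel, conc: float,
                      cfg: SimulationConfig) -> tuple[float, float, float]:
    """Hormone-equivalents in the supernatant of one treated well.

    Returns (E2-equivalent, DHT-equivalent, viable-cell fraction); hormone
    output scales with both the Hill fold-change and the viable fraction.
    """
    viab = model.h295r_viability(conc)
    e2 = cfg.basal_e2_equiv * model.fold("estrogens", conc) * viab
    dht = cfg.basal_dht_equiv * model.fold("androgens", conc) * viab
    return e2, dht, viab


def calux_signal(assay: Assay, mode: Mode, hormone_equiv: float,
                 chem_conc_in_well: float, model: ChemicalModel | None,
                 cfg: SimulationConfig,
                 rng: np.random.Generator | None,
                 co_agonist: float = 0.0) -> tuple[float, float]:
    """Reporter and viability RLUs of one detection well.

    ER wells respond to E2-equivalents plus the chemical's additive
    agonist-equivalents; AR wells respond to DHT-equivalents (plus any
    antagonist-mode co-agonist) with the chemical shifting the curve AC50
    competitively (factor 1 + [antagonist]/IC50).  Both signals scale with
    the detection cells' viability and carry multiplicative log-normal
    noise with CV ``cfg.noise_cv``.
    """
    curve = cfg.curves["E2"] if assay is Assay.ER_CALUX else cfg.curves["DHT"]
    if assay is Assay.ER_CALUX:
        eef = (model.er_agonism_eef if model else None) or 0.0
        effective = hormone_equiv + eef * chem_conc_in_well
        ac50 = curve.ac50
    else:
        ic50 = model.ar_antagonism_ic50 if model else None
        effective = hormone_equiv + co_agonist
        shift = 1.0 + (chem_conc_in_well / ic50 if ic50 else 0.0)
        ac50 = curve.ac50 * shift
    frac = hill_fraction(effective, ac50, curve.hill)
    viab = model.calux_viability(chem_conc_in_well) if model else 1.0
    reporter = (curve.background_rlu + curve.span_rlu * frac) * viab * _noise(rng, cfg.noise_cv)
    viability = cfg.viability_base_rlu * viab * _noise(rng, cfg.noise_cv)
    return reporter, viability


# ---------------------------------------------------------------------------
# Built-in control substances (always present on every plate)
# ---------------------------------------------------------------------------

CONTROL_MODELS: dict[str, tuple["ChemicalModel", float]] = {
    "forskolin": (ChemicalModel(
        "forskolin", (1e-6,),
        estrogen_terms=(HillTerm(1e-7, 3.0),)), 1e-6),
    "pfos": (ChemicalModel(
        "pfos", (1e-4,),
        estrogen_terms=(HillTerm(3e-5, 1.8, 1.5),),
        androgen_terms=(HillTerm(3e-5, 1.8, 1.5),)), 1e-4),
    "prochloraz": (ChemicalModel(
        "prochloraz", (1e-6,),
        estrogen_terms=(HillTerm(1e-7, 0.05),),
        androgen_terms=(HillTerm(1e-7, 0.05),)), 1e-6),
    "menadione": (ChemicalModel(
        "menadione", (1e-5,),
        cytotox_h295r=Cytotoxicity(3e-6, 3.0)), 1e-5),
}


# ---------------------------------------------------------------------------
# Experiment assembly
# ---------------------------------------------------------------------------

def _source_model(lw: LayoutWell, model: ChemicalModel) -> ChemicalModel | None:
    if lw.role is Role.POSITIVE_CONTROL:
        return CONTROL_MODELS[lw.control_name][0]
    if lw.role in (Role.H295R_TREATED, Role.SHAM):
        return model
    return None


def _source_contents(lw: LayoutWell, model: ChemicalModel, cfg: SimulationConfig,
                     ) -> tuple[str | None, float | None, float, float, float]:
    """(chemical_id, nominal conc, e2, dht, chemical conc) in a source well."""
    if lw.role in (Role.H295R_TREATED, Role.SHAM):
        conc = model.concentration_grid[lw.conc_index]
        if lw.has_cells:
            e2, dht, _ = simulate_hormones(model, conc, cfg)
            return model.chemical_id, conc, e2, dht, conc
        return model.chemical_id, conc, 0.0, 0.0, conc
    if lw.role is Role.POSITIVE_CONTROL:
        ctrl_model, conc = CONTROL_MODELS[lw.control_name]
        if lw.has_cells:
            e2, dht, _ = simulate_hormones(ctrl_model, conc, cfg)
            return lw.control_name, conc, e2, dht, conc
        return lw.control_name, conc, 0.0, 0.0, conc
    # vehicle / medium-only controls
    if lw.has_cells:
        e2, dht, _ = simulate_hormones(model, 0.0, cfg)
        return None, None, e2, dht, 0.0
    return None, None, 0.0, 0.0, 0.0


def _h295r_plate(model: ChemicalModel, cfg: SimulationConfig, bio_rep: int,
                 layout: Sequence[LayoutWell], rng: np.random.Generator | None,
                 ) -> list[WellMeasurement]:
    plate_id = f"{model.chemical_id}-b{bio_rep}-H295R"
    wells = []
    for lw in layout:
        if lw.role is Role.STANDARD_CURVE:
            continue  # cell-free reserve for the detection-plate curves
        chem, conc, _, _, chem_conc = _source_contents(lw, model, cfg)
        src = _source_model(lw, model)
        if lw.has_cells:
            viab = src.h295r_viability(chem_conc) if src else 1.0
            rlu_v = cfg.viability_base_rlu * viab * _noise(rng, cfg.noise_cv)
        else:
            rlu_v = 0.02 * cfg.viability_base_rlu * _noise(rng, cfg.noise_cv)
        wells.append(WellMeasurement(
            plate_id=plate_id, assay=Assay.H295R, mode=Mode.NONE,
            row=lw.row, col=lw.col, role=lw.role,
            chemical_id=chem, conc_h295r=conc, conc_standard=None,
            bio_rep=bio_rep, tech_rep=lw.tech_rep or 1,
            rlu_reporter=0.0, rlu_viability=rlu_v,
            supernatant_vol_ul=0.0, total_vol_ul=100.0,
            has_cells=lw.has_cells))
    return wells


def _curve_treatment(assay: Assay, cfg: SimulationConfig, curve_index: int,
                     ) -> tuple[float, float, Mode]:
    """(standard conc, co-agonist conc, mode) of one curve position."""
    if assay is Assay.ER_CALUX:
        grid = cfg.e2_curve_grid
        conc = 0.0 if curve_index == 0 else grid[curve_index - 1]
        return conc, 0.0, Mode.AGONIST
    if cfg.ar_mode == "agonist":
        grid = cfg.dht_curve_grid
        conc = 0.0 if curve_index == 0 else grid[curve_index - 1]
        return conc, 0.0, Mode.AGONIST
    # Antagonist standard curve: vehicle, agonist-only, then 8 points with
    # the co-agonist held at its EC50.
    if curve_index == 0:
        return 0.0, 0.0, Mode.ANTAGONIST
    if curve_index == 1:
        return 0.0, AR_CO_AGONIST, Mode.ANTAGONIST
    return cfg.flt_curve_grid[curve_index - 2], AR_CO_AGONIST, Mode.ANTAGONIST


def _curve_rlu(assay: Assay, conc_standard: float, co_agonist: float,
               cfg: SimulationConfig, rng: np.random.Generator | None,
               ) -> tuple[float, float]:
    if assay is Assay.ER_CALUX or cfg.ar_mode == "agonist":
        curve = cfg.curves["E2" if assay is Assay.ER_CALUX else "DHT"]
        frac = hill_fraction(conc_standard, curve.ac50, curve.hill)
    else:
        curve = cfg.curves["DHT"]
        shift = 1.0 + conc_standard / FLT_IC50
        frac = hill_fraction(co_agonist, curve.ac50 * shift, curve.hill)
    reporter = (curve.background_rlu + curve.span_rlu * frac) * _noise(rng, cfg.noise_cv)
    viability = cfg.viability_base_rlu * _noise(rng, cfg.noise_cv)
    return reporter, viability


def _calux_plate(model: ChemicalModel, cfg: SimulationConfig, bio_rep: int,
                 assay: Assay, plate_tag: str, volumes: tuple[float, float],
                 layout: Sequence[LayoutWell], rng: np.random.Generator | None,
                 ) -> list[WellMeasurement]:
    plate_id = f"{model.chemical_id}-b{bio_rep}-{plate_tag}"
    sup_ul, tot_ul = volumes
    fold = tot_ul / sup_ul
    wells = []
    for lw in layout:
        if lw.role is Role.STANDARD_CURVE:
            conc_std, co_ag, mode = _curve_treatment(assay, cfg, lw.curve_index)
            rlu_r, rlu_v = _curve_rlu(assay, conc_std, co_ag, cfg, rng)
            wells.append(WellMeasurement(
                plate_id=plate_id, assay=assay, mode=mode,
                row=lw.row, col=lw.col, role=lw.role, chemical_id=None,
                conc_h295r=None, conc_standard=conc_std,
                bio_rep=bio_rep, tech_rep=lw.curve_rep or 1,
                rlu_reporter=rlu_r, rlu_viability=rlu_v,
                supernatant_vol_ul=sup_ul, total_vol_ul=tot_ul,
                has_cells=False, co_agonist_conc=co_ag))
            continue
        chem, conc, e2, dht, chem_conc = _source_contents(lw, model, cfg)
        src = _source_model(lw, model)
        if assay is Assay.ER_CALUX:
            mode = Mode.AGONIST
            hormone, co_ag = e2 / fold, 0.0
        elif lw.has_cells or cfg.ar_mode == "agonist":
            mode = Mode.AGONIST
            hormone, co_ag = dht / fold, 0.0
        else:
            mode = Mode.ANTAGONIST
            hormone, co_ag = dht / fold, AR_CO_AGONIST
        rlu_r, rlu_v = calux_signal(assay, mode, hormone, chem_conc / fold,
                                    src, cfg, rng, co_agonist=co_ag)
        wells.append(WellMeasurement(
            plate_id=plate_id, assay=assay, mode=mode,
            row=lw.row, col=lw.col, role=lw.role, chemical_id=chem,
            conc_h295r=conc, conc_standard=None,
            bio_rep=bio_rep, tech_rep=lw.tech_rep or 1,
            rlu_reporter=rlu_r, rlu_viability=rlu_v,
            supernatant_vol_ul=sup_ul, total_vol_ul=tot_ul,
            has_cells=lw.has_cells, co_agonist_conc=co_ag))
    return wells


def simulate_plate_set(model: ChemicalModel, cfg: SimulationConfig, bio_rep: int,
                       rng: np.random.Generator | None) -> PlateSet:
    layout = default_layout()
    er_plates = [
        _calux_plate(model, cfg, bio_rep, Assay.ER_CALUX, f"ER{i + 1}", vols,
                     layout, rng)
        for i, vols in enumerate(cfg.dilution.er_volumes_ul)
    ]
    ar_plate = _calux_plate(model, cfg, bio_rep, Assay.AR_CALUX, "AR",
                            cfg.dilution.ar_volumes_ul, layout, rng)
    return PlateSet(
        experiment_id=f"{model.chemical_id}-b{bio_rep}",
        h295r_plate=_h295r_plate(model, cfg, bio_rep, layout, rng),
        er_plates=er_plates, ar_plate=ar_plate,
        dilution_scheme=cfg.dilution)


def assemble_experiment(model: ChemicalModel, cfg: SimulationConfig,
                        n_bio_reps: int = 3) -> tuple[list[PlateSet], dict]:
    """Simulate the biological replicates of one chemical's experiment.

    Reproducible from ``cfg.seed``; returns the plate sets and a
    ground-truth ledger with the model's true effects and the noise-free
    detectability bracket for each endpoint.
    """
    rng = np.random.default_rng(cfg.seed)
    plate_sets = [simulate_plate_set(model, cfg, b, rng)
                  for b in range(1, n_bio_reps + 1)]
    return plate_sets, ground_truth(model, cfg)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _expected_pct_of_basal(model: ChemicalModel, conc: float, family: str,
                           cfg: SimulationConfig) -> float:
    """Noise-free % of basal signal at one nominal concentration."""
    e2, dht, _ = simulate_hormones(model, conc, cfg)
    if family == "estrogens":
        assay, fold = Assay.ER_CALUX, cfg.dilution.er_mean_fold
        hormone, basal = e2, cfg.basal_e2_equiv
        curve = cfg.curves["E2"]
    else:
        assay, fold = Assay.AR_CALUX, cfg.dilution.ar_fold
        hormone, basal = dht, cfg.basal_dht_equiv
        curve = cfg.curves["DHT"]
    treated, _ = calux_signal(assay, Mode.AGONIST, hormone / fold, conc / fold,
                              model, cfg, rng=None)
    basal_rlu, _ = calux_signal(assay, Mode.AGONIST, basal / fold, 0.0, None,
                                cfg, rng=None)
    bg = curve.background_rlu
    return 100.0 * (treated - bg) / (basal_rlu - bg)


def _expected_direct_deviation(model: ChemicalModel, conc: float, family: str,
                               cfg: SimulationConfig) -> float:
    """Noise-free deviation (%RI points) of the sham well from no-activity."""
    if family == "estrogens":
        fold = cfg.dilution.er_mean_fold
        rlu, _ = calux_signal(Assay.ER_CALUX, Mode.AGONIST, 0.0, conc / fold,
                              model, cfg, rng=None)
        curve = cfg.curves["E2"]
        top, _ = _curve_rlu(Assay.ER_CALUX, cfg.e2_curve_grid[-1], 0.0, cfg, None)
        return abs(100.0 * (rlu - curve.background_rlu) / (top - curve.background_rlu))
    fold = cfg.dilution.ar_fold
    rlu, _ = calux_signal(Assay.AR_CALUX, Mode.ANTAGONIST, 0.0, conc / fold,
                          model, cfg, rng=None, co_agonist=AR_CO_AGONIST)
    ref, _ = _curve_rlu(Assay.AR_CALUX, 0.0, AR_CO_AGONIST, cfg, None)
    curve = cfg.curves["DHT"]
    ri = 100.0 * (rlu - curve.background_rlu) / (ref - curve.background_rlu)
    return abs(ri - 100.0)


def ground_truth(model: ChemicalModel, cfg: SimulationConfig,
                 detect_pct: float = 20.0,
                 direct_detect_pct: float = 10.0) -> dict:
    """Noise-free expectations: directions, detectable LOECs, confounders."""
    truth: dict = {"chemical_id": model.chemical_id, "families": {}, "direct": {}}
    for family in ("estrogens", "androgens"):
        loec = None
        direction = None
        for conc in model.concentration_grid:
            pct = _expected_pct_of_basal(model, conc, family, cfg)
            if abs(pct - 100.0) >= detect_pct:
                loec = conc
                direction = "up" if pct > 100 else "down"
                break
        truth["families"][family] = {"loec": loec, "direction": direction}
    for family in ("estrogens", "androgens"):
        loec = None
        for conc in model.concentration_grid:
            if _expected_direct_deviation(model, conc, family, cfg) >= direct_detect_pct:
                loec = conc
                break
        truth["direct"][family] = {"loec_nominal": loec}
    truth["cytotoxic_concs_h295r"] = [
        c for c in model.concentration_grid if model.h295r_viability(c) < 0.8]
    return truth


# ---------------------------------------------------------------------------
# Preset library
# ---------------------------------------------------------------------------

_GRID_LOW = _log_grid(3e-8, 1e-4, 8)     # 0.03-100 uM in ~3.2x steps
_GRID_TINY = _log_grid(3e-12, 1e-8, 8)   # pM-range inhibitors

PRESETS: dict[str, ChemicalModel] = {
    # steroidogenesis inhibitor of both hormone families
    "prochloraz_like": ChemicalModel(
        "prochloraz_like", _GRID_LOW,
        estrogen_terms=(HillTerm(3e-7, 0.05),),
        androgen_terms=(HillTerm(3e-7, 0.05),)),
    # estrogen-synthesis inducer only
    "forskolin_like": ChemicalModel(
        "forskolin_like", _GRID_LOW,
        estrogen_terms=(HillTerm(1e-7, 3.0),)),
    # potent estrogen-synthesis inhibitor
    "letrozole_like": ChemicalModel(
        "letrozole_like", _GRID_TINY,
        estrogen_terms=(HillTerm(3e-11, 0.1),)),
    # direct ER agonist + AR antagonist without steroidogenic terms
    "bpa_like": ChemicalModel(
        "bpa_like", _GRID_LOW,
        er_agonism_eef=2e-5,
        ar_antagonism_ic50=3e-7),
    # cytotoxic to the hormone-producing cells only + direct AR antagonism
    "benomyl_like": ChemicalModel(
        "benomyl_like", _GRID_LOW,
        ar_antagonism_ic50=1e-6,
        cytotox_h295r=Cytotoxicity(2e-5, 4.0)),
    # cytotoxic to every cell line
    "cadmium_like": ChemicalModel(
        "cadmium_like", _GRID_LOW,
        cytotox_h295r=Cytotoxicity(1e-5, 4.0),
        cytotox_calux=Cytotoxicity(1e-5, 4.0)),
    # no activity whatsoever
    "inactive": ChemicalModel("inactive", _GRID_LOW),
    # steep inhibitor whose true threshold falls between grid points
    "threshold_inhibitor": ChemicalModel(
        "threshold_inhibitor", _GRID_LOW,
        estrogen_terms=(HillTerm(1.7e-7, 0.1, 3.0),),
        androgen_terms=(HillTerm(1.7e-7, 0.1, 3.0),)),
}


def preset(name: str, **overrides) -> ChemicalModel:
    """A copy of a preset model, optionally with field overrides."""
    try:
        model = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(model, **overrides) if overrides else model
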