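"""Data model and I/O for the coupled five-plate experiment.

One experiment couples a hormone-producing plate (H295R cells, left half
treated, right half cell-free "sham" wells) with reporter-gene detection
plates: three ER CALUX plates at slightly different supernatant dilutions
and one AR CALUX plate.  This module holds the well-level data model, the
default 96-well layout, long-format CSV I/O and treated/sham pairing.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Assay",
    "Mode",
    "Role",
    "WellMeasurement",
    "DilutionScheme",
    "StandardCurveSpec",
    "PlateSet",
    "ParseError",
    "PairingError",
    "default_layout",
    "LayoutWell",
    "read_measurements",
    "write_measurements",
    "pair_sham",
    "HCG_M_PER_IU_ML",
]

# Conversion factor for human chorionic gonadotropin doses given in IU/ml.
HCG_M_PER_IU_ML = 3.9e-6

ROWS = "ABCDEFGH"
N_COLS = 12
N_TEST_CONCENTRATIONS = 8
TECH_REPLICATES = 3


class Assay(str, Enum):
    H295R = "H295R"
    ER_CALUX = "ER_CALUX"
    AR_CALUX = "AR_CALUX"


class Mode(str, Enum):
    AGONIST = "agonist"
    ANTAGONIST = "antagonist"
    NONE = "none"


class Role(str, Enum):
    H295R_TREATED = "h295r_treated"
    SHAM = "sham"
    STANDARD_CURVE = "standard_curve"
    VEHICLE_CONTROL = "vehicle_control"
    MEDIUM_CONTROL = "medium_control"
    POSITIVE_CONTROL = "positive_control"


class ParseError(ValueError):
    """Structured input error naming plate / row / col where known."""

    def __init__(self, message: str, plate_id: str | None = None,
                 row: str | None = None, col: int | None = None):
        self.plate_id, self.row, self.col = plate_id, row, col
        where = ""
        if plate_id is not None:
            where = f" [plate={plate_id}"
            if row is not None and col is not None:
                where += f", well={row}{col}"
            where += "]"
        super().__init__(message + where)


class PairingError(KeyError):
    pass


@dataclass
class WellMeasurement:
    """One well's raw reporter and viability signals plus its coordinates.

    Concentrations are stored in mol/L.  ``conc_h295r`` is the nominal
    concentration in the hormone-producing plate (it travels with the
    supernatant onto the CALUX plates); ``conc_standard`` is the standard
    compound concentration for standard-curve wells.  ``co_agonist_conc``
    is the reference-agonist concentration in antagonist-mode wells (mol/L;
    0 where absent).  ``has_cells`` distinguishes supernatant that came from
    hormone-producing wells from cell-free sham supernatant.
    """

    plate_id: str
    assay: Assay
    mode: Mode
    row: str
    col: int
    role: Role
    chemical_id: str | None
    conc_h295r: float | None
    conc_standard: float | None
    bio_rep: int
    tech_rep: int
    rlu_reporter: float
    rlu_viability: float
    supernatant_vol_ul: float
    total_vol_ul: float
    has_cells: bool = True
    co_agonist_conc: float = 0.0

    def __post_init__(self):
        if self.row not in ROWS:
            raise ParseError(f"bad row {self.row!r}", self.plate_id, self.row, self.col)
        if not 1 <= int(self.col) <= N_COLS:
            raise ParseError(f"bad column {self.col!r}", self.plate_id, self.row, self.col)
        if self.rlu_reporter < 0 or self.rlu_viability < 0:
            raise ParseError("negative RLU", self.plate_id, self.row, self.col)
        if self.supernatant_vol_ul > self.total_vol_ul:
            raise ParseError("supernatant volume exceeds total volume",
                             self.plate_id, self.row, self.col)
        if self.role in (Role.H295R_TREATED, Role.SHAM):
            if (self.conc_h295r is None) == (self.conc_standard is None):
                raise ParseError(
                    "exactly one of conc_h295r/conc_standard must be set for "
                    f"role {self.role.value}", self.plate_id, self.row, self.col)

    @property
    def well(self) -> str:
        return f"{self.row}{self.col}"


@dataclass(frozen=True)
class DilutionScheme:
    """Supernatant transfer volumes (μl into final well volume) per plate.

    Defaults follow the published procedure: three ER dilutions between
    6.25- and 10-fold (30/200, 28/200, 25/200 μl ≈ 6.7-, 7.1- and 8-fold)
    and a single ~3-fold AR dilution (67/200 μl).
    """

    er_volumes_ul: tuple[tuple[float, float], ...] = ((30.0, 200.0), (28.0, 200.0), (25.0, 200.0))
    ar_volumes_ul: tuple[float, float] = (67.0, 200.0)

    def __post_init__(self):
        for sup, tot in (*self.er_volumes_ul, self.ar_volumes_ul):
            if not 0 < sup <= tot:
                raise ValueError("invalid dilution volumes")
        for f in self.er_folds:
            if not 6.25 <= f <= 10.0:
                raise ValueError(f"ER fold dilution {f:.2f} outside [6.25, 10]")
        if not 2.5 <= self.ar_fold <= 3.5:
            raise ValueError(f"AR fold dilution {self.ar_fold:.2f} not ~3-fold")

    @property
    def er_folds(self) -> tuple[float, ...]:
        return tuple(tot / sup for sup, tot in self.er_volumes_ul)

    @property
    def ar_fold(self) -> float:
        sup, tot = self.ar_volumes_ul
        return tot / sup

    @property
    def er_mean_fold(self) -> float:
        folds = self.er_folds
        return sum(folds) / len(folds)


# Allowed standard-curve concentration windows (mol/L).
_CURVE_RANGES = {
    "E2": (0.5e-12, 500e-12),
    "FLT": (0.005e-6, 50e-6),
    "DHT": (5e-12, 0.5e-6),
}


@dataclass(frozen=True)
class StandardCurveSpec:
    """Standard compound, its concentration grid and optional co-agonist."""

    compound: str  # E2 | DHT | FLT
    concentration_grid: tuple[float, ...]
    co_agonist: tuple[str, float] | None = None  # e.g. ("DHT", 0.3e-9)

    def __post_init__(self):
        if self.compound not in _CURVE_RANGES:
            raise ValueError(f"unknown standard compound {self.compound!r}")
        lo, hi = _CURVE_RANGES[self.compound]
        grid = self.concentration_grid
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("concentration grid must be strictly increasing")
        if grid and (grid[0] < lo * (1 - 1e-9) or grid[-1] > hi * (1 + 1e-9)):
            raise ValueError(f"{self.compound} grid outside allowed range {lo:g}-{hi:g} M")


def _log_grid(lo: float, hi: float, n: int) -> tuple[float, ...]:
    step = (math.log10(hi) - math.log10(lo)) / (n - 1)
    return tuple(10 ** (math.log10(lo) + i * step) for i in range(n))


def default_curve_specs() -> dict[str, StandardCurveSpec]:
    """Default 8-point standard curve grids within the published ranges."""
    return {
        "E2": StandardCurveSpec("E2", _log_grid(0.5e-12, 500e-12, 8)),
        "DHT": StandardCurveSpec("DHT", _log_grid(5e-12, 0.5e-6, 8)),
        "FLT": StandardCurveSpec("FLT", _log_grid(0.005e-6, 50e-6, 8),
                                 co_agonist=("DHT", 0.3e-9)),
    }


@dataclass
class PlateSet:
    """One biological replicate: 1 H295R plate, 3 ER plates, 1 AR plate."""

    experiment_id: str
    h295r_plate: list[WellMeasurement]
    er_plates: list[list[WellMeasurement]]
    ar_plate: list[WellMeasurement]
    dilution_scheme: DilutionScheme = field(default_factory=DilutionScheme)

    def __post_init__(self):
        if len(self.er_plates) != 3:
            raise ValueError("a plate set requires exactly 3 ER CALUX plates")
        for plate in self.plates():
            seen = set()
            for w in plate:
                key = (w.plate_id, w.row, w.col)
                if key in seen:
                    raise ParseError("duplicate well", w.plate_id, w.row, w.col)
                seen.add(key)
        treated = {(w.chemical_id, w.conc_h295r) for w in self.h295r_plate
                   if w.role is Role.H295R_TREATED}
        sham = {(w.chemical_id, w.conc_h295r) for w in self.h295r_plate
                if w.role is Role.SHAM}
        missing = treated - sham
        if missing:
            raise PairingError(f"treated keys without sham counterpart: {sorted(missing)}")

    def plates(self) -> Iterable[list[WellMeasurement]]:
        yield self.h295r_plate
        yield from self.er_plates
        yield self.ar_plate


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutWell:
    row: str
    col: int
    role: Role
    has_cells: bool
    conc_index: int | None = None   # 0-based index into the chemical's grid
    tech_rep: int | None = None
    curve_index: int | None = None  # 0-based index along the standard curve
    curve_rep: int | None = None
    control_name: str | None = None  # forskolin / pfos / prochloraz / menadione

    @property
    def well(self) -> str:
        return f"{self.row}{self.col}"


_POSITIVE_CONTROLS = ("forskolin", "pfos", "prochloraz", "menadione")


def default_layout() -> list[LayoutWell]:
    """The default 96-well role map.

    Standard-curve wells occupy rows A-B, columns 1-5 and 7-11 (10 curve
    points in duplicate).  Columns 1-5, rows C-H carry the 8 test
    concentrations in technical triplicate plus triplicate vehicle and
    medium-only controls with cells; columns 7-11, rows C-H mirror them as
    cell-free sham wells.  Column 6 and column 12 + A12/B12 hold the
    duplicate positive controls (with and without cells respectively); the
    exact placement of those duplicates within their columns is a
    convention.
    """
    wells: list[LayoutWell] = []

    # Standard curve: 10 points x 2 replicates across both half-plates.
    curve_positions = [(r, c) for r in "AB" for c in range(1, 6)] + \
                      [(r, c) for r in "AB" for c in range(7, 12)]
    for i, (row, col) in enumerate(curve_positions):
        wells.append(LayoutWell(row, col, Role.STANDARD_CURVE, has_cells=False,
                                curve_index=i % 10, curve_rep=i // 10 + 1))

    # Treated half (with cells) and sham half (no cells), rows C-H.
    for sham, cols in ((False, range(1, 6)), (True, range(7, 12))):
        slots = [(r, c) for c in cols for r in "CDEFGH"]  # 30 slots
        k = 0
        for conc_index in range(N_TEST_CONCENTRATIONS):
            for rep in range(1, TECH_REPLICATES + 1):
                row, col = slots[k]; k += 1
                wells.append(LayoutWell(
                    row, col, Role.SHAM if sham else Role.H295R_TREATED,
                    has_cells=not sham, conc_index=conc_index, tech_rep=rep))
        for rep in range(1, TECH_REPLICATES + 1):
            row, col = slots[k]; k += 1
            wells.append(LayoutWell(row, col, Role.VEHICLE_CONTROL,
                                    has_cells=not sham, tech_rep=rep))
        for rep in range(1, TECH_REPLICATES + 1):
            row, col = slots[k]; k += 1
            wells.append(LayoutWell(row, col, Role.MEDIUM_CONTROL,
                                    has_cells=not sham, tech_rep=rep))

    # Duplicate positive controls: column 6 (with cells), col 12 + A12/B12 (sham).
    cell_slots = [("A", 6), ("B", 6), ("C", 6), ("D", 6),
                  ("E", 6), ("F", 6), ("G", 6), ("H", 6)]
    sham_slots = [("A", 12), ("B", 12), ("C", 12), ("D", 12),
                  ("E", 12), ("F", 12), ("G", 12), ("H", 12)]
    for slots, has_cells in ((cell_slots, True), (sham_slots, False)):
        k = 0
        for name in _POSITIVE_CONTROLS:
            for rep in (1, 2):
                row, col = slots[k]; k += 1
                wells.append(LayoutWell(row, col, Role.POSITIVE_CONTROL,
                                        has_cells=has_cells, tech_rep=rep,
                                        control_name=name))

    assert len(wells) == 96 and len({w.well for w in wells}) == 96
    return wells


def layout_by_well(layout: Sequence[LayoutWell]) -> dict[str, LayoutWell]:
    return {w.well: w for w in layout}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "plate_id", "assay", "mode", "row", "col", "role", "has_cells",
    "chemical_id", "conc_h295r", "conc_standard", "conc_unit",
    "co_agonist_conc", "bio_rep", "tech_rep", "rlu_reporter",
    "rlu_viability", "supernatant_vol_ul", "total_vol_ul",
]

_UNIT_FACTORS = {"M": 1.0, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12,
                 "IU_per_ml": HCG_M_PER_IU_ML}


def _opt_float(value: str, what: str, plate: str, row: str, col: int) -> float | None:
    if value is None or value == "" or value.lower() in ("na", "nan", "null", "none"):
        return None
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {value!r}", plate, row, col) from None


def read_measurements(path: str | Path,
                      layout: Sequence[LayoutWell] | None = None) -> list[WellMeasurement]:
    """Read a long-format measurements CSV into validated records.

    Concentrations are normalized to mol/L on read (``conc_unit`` column:
    M, uM, nM, pM or IU_per_ml).  If ``layout`` is given, each well's role
    is checked against the layout role map.
    """
    path = Path(path)
    records: list[WellMeasurement] = []
    seen: set[tuple[str, str, int]] = set()
    role_map = layout_by_well(layout) if layout is not None else None
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CSV_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"missing column(s): {', '.join(missing)}")
        for raw in reader:
            plate, row = raw["plate_id"], raw["row"].strip()
            try:
                col = int(raw["col"])
            except ValueError:
                raise ParseError(f"bad column {raw['col']!r}", plate, row, None) from None
            if (plate, row, col) in seen:
                raise ParseError("duplicate well", plate, row, col)
            seen.add((plate, row, col))
            try:
                role = Role(raw["role"])
                assay = Assay(raw["assay"])
                mode = Mode(raw["mode"])
            except ValueError as exc:
                raise ParseError(str(exc), plate, row, col) from None
            unit = raw.get("conc_unit") or "M"
            if unit not in _UNIT_FACTORS:
                raise ParseError(f"unknown concentration unit {unit!r}", plate, row, col)
            factor = _UNIT_FACTORS[unit]
            conc_h = _opt_float(raw["conc_h295r"], "conc_h295r", plate, row, col)
            conc_s = _opt_float(raw["conc_standard"], "conc_standard", plate, row, col)
            rlu_r = _opt_float(raw["rlu_reporter"], "RLU", plate, row, col)
            rlu_v = _opt_float(raw["rlu_viability"], "RLU", plate, row, col)
            if rlu_r is None or rlu_v is None:
                raise ParseError("missing RLU value", plate, row, col)
            rec = WellMeasurement(
                plate_id=plate, assay=assay, mode=mode, row=row, col=col,
                role=role,
                chemical_id=raw["chemical_id"] or None,
                conc_h295r=None if conc_h is None else conc_h * factor,
                conc_standard=None if conc_s is None else conc_s * factor,
                bio_rep=int(raw["bio_rep"]), tech_rep=int(raw["tech_rep"]),
                rlu_reporter=rlu_r, rlu_viability=rlu_v,
                supernatant_vol_ul=float(raw["supernatant_vol_ul"]),
                total_vol_ul=float(raw["total_vol_ul"]),
                has_cells=raw["has_cells"].strip().lower() in ("1", "true", "yes"),
                co_agonist_conc=float(raw["co_agonist_conc"] or 0.0),
            )
            if role_map is not None:
                expected = role_map.get(rec.well)
                if expected is not None and expected.role is not rec.role:
                    raise ParseError(
                        f"role {rec.role.value!r} does not match layout "
                        f"({expected.role.value!r})", plate, row, col)
            records.append(rec)
    return records


def write_measurements(records: Iterable[WellMeasurement], path: str | Path) -> None:
    """Write records to long-format CSV (concentrations stay in mol/L)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            d = asdict(rec)
            d["assay"] = rec.assay.value
            d["mode"] = rec.mode.value
            d["role"] = rec.role.value
            d["conc_unit"] = "M"
            d["has_cells"] = str(rec.has_cells).lower()
            d["conc_h295r"] = "" if rec.conc_h295r is None else repr(rec.conc_h295r)
            d["conc_standard"] = "" if rec.conc_standard is None else repr(rec.conc_standard)
            writer.writerow({k: d[k] for k in CSV_COLUMNS})


class UnitsError(ValueError):
    pass


def normalize_units(rows: list[dict]) -> list[dict]:
    """Convert raw CSV row dicts' concentrations to mol/L, once.

    Rows that already went through this conversion carry a marker; a second
    pass is refused rather than silently re-scaled.
    """
    out = []
    for raw in rows:
        if raw.get("_units_normalized"):
            raise UnitsError("concentrations already normalized to mol/L")
        unit = raw.get("conc_unit") or "M"
        if unit not in _UNIT_FACTORS:
            raise UnitsError(f"unknown concentration unit {unit!r}")
        factor = _UNIT_FACTORS[unit]
        row = dict(raw)
        for key in ("conc_h295r", "conc_standard"):
            v = row.get(key)
            if v not in (None, ""):
                row[key] = float(v) * factor
        row["conc_unit"] = "M"
        row["_units_normalized"] = True
        out.append(row)
    return out


def read_matrix_block(reporter: Sequence[Sequence[float]],
                      viability: Sequence[Sequence[float]],
                      layout: Sequence[LayoutWell],
                      *,
                      plate_id: str,
                      assay: Assay,
                      mode: Mode,
                      chemical_id: str,
                      concentration_grid: Sequence[float],
                      bio_rep: int = 1,
                      supernatant_vol_ul: float = 200.0,
                      total_vol_ul: float = 200.0) -> list[WellMeasurement]:
    """Convenience converter: two 8x12 RLU matrices -> long-format records.

    Test-substance concentrations are taken from ``concentration_grid``
    (mol/L) via each layout well's ``conc_index``; standard-curve wells get
    no concentration (fill them downstream if needed).
    """
    if len(reporter) != 8 or any(len(r) != 12 for r in reporter):
        raise ParseError("reporter matrix must be 8x12", plate_id)
    if len(viability) != 8 or any(len(r) != 12 for r in viability):
        raise ParseError("viability matrix must be 8x12", plate_id)
    records = []
    for lw in layout:
        i, j = ROWS.index(lw.row), lw.col - 1
        conc = None
        if lw.conc_index is not None:
            conc = float(concentration_grid[lw.conc_index])
        records.append(WellMeasurement(
            plate_id=plate_id, assay=assay, mode=mode, row=lw.row, col=lw.col,
            role=lw.role,
            chemical_id=chemical_id if lw.conc_index is not None else lw.control_name,
            conc_h295r=conc, conc_standard=None,
            bio_rep=bio_rep, tech_rep=lw.tech_rep or 1,
            rlu_reporter=float(reporter[i][j]), rlu_viability=float(viability[i][j]),
            supernatant_vol_ul=supernatant_vol_ul, total_vol_ul=total_vol_ul,
            has_cells=lw.has_cells))
    return records


# ---------------------------------------------------------------------------
# Treated / sham pairing
# ---------------------------------------------------------------------------

def pair_sham(treated: Iterable[WellMeasurement],
              sham: Iterable[WellMeasurement],
              ) -> dict[tuple[str, float], tuple[list[WellMeasurement], list[WellMeasurement]]]:
    """Pair treated wells with their sham counterparts by (chemical, conc).

    Every treated key must have at least one sham well at the same nominal
    concentration; a missing counterpart raises :class:`PairingError`
    naming the key.
    """
    t_groups: dict[tuple[str, float], list[WellMeasurement]] = {}
    s_groups: dict[tuple[str, float], list[WellMeasurement]] = {}
    for w in treated:
        t_groups.setdefault((w.chemical_id, w.conc_h295r), []).append(w)
    for w in sham:
        s_groups.setdefault((w.chemical_id, w.conc_h295r), []).append(w)
    missing = sorted(k for k in t_groups if k not in s_groups)
    if missing:
        raise PairingError(f"no sham counterpart for {missing}")
    return {k: (t_groups[k], s_groups[k]) for k in t_groups}
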