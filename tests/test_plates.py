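import pytest

from steroidscreen.plates import (Assay, DilutionScheme, Mode, PairingError,
                                  ParseError, PlateSet, Role,
                                  StandardCurveSpec, UnitsError,
                                  WellMeasurement, default_layout,
                                  normalize_units, pair_sham,
                                  read_matrix_block, read_measurements,
                                  write_measurements, HCG_M_PER_IU_ML)


def make_well(**kw) -> WellMeasurement:
    base = dict(plate_id="P1", assay=Assay.H295R, mode=Mode.NONE, row="C",
                col=1, role=Role.H295R_TREATED, chemical_id="x",
                conc_h295r=3e-8, conc_standard=None, bio_rep=1, tech_rep=1,
                rlu_reporter=100.0, rlu_viability=100.0,
                supernatant_vol_ul=67.0, total_vol_ul=200.0)
    base.update(kw)
    return WellMeasurement(**base)


class TestLayout:
    def test_covers_96_wells_once(self):
        layout = default_layout()
        assert len(layout) == 96
        assert len({(w.row, w.col) for w in layout}) == 96

    def test_corner_roles(self):
        by_well = {(w.row, w.col): w for w in default_layout()}
        assert by_well[("A", 1)].role is Role.STANDARD_CURVE
        assert by_well[("C", 8)].role is Role.SHAM

    def test_left_half_cell_wells(self):
        # everything on columns 1-6 except the curve wells carries cells
        layout = default_layout()
        left = [w for w in layout if w.col <= 6]
        curve = [w for w in left if w.role is Role.STANDARD_CURVE]
        assert len(left) == 48
        assert len(left) - len(curve) == 38
        assert all(w.has_cells for w in left if w.role is not Role.STANDARD_CURVE)

    def test_counts_per_role(self):
        layout = default_layout()
        count = lambda role: sum(w.role is role for w in layout)
        assert count(Role.STANDARD_CURVE) == 20
        assert count(Role.H295R_TREATED) == 24
        assert count(Role.SHAM) == 24
        assert count(Role.VEHICLE_CONTROL) == 6
        assert count(Role.MEDIUM_CONTROL) == 6
        assert count(Role.POSITIVE_CONTROL) == 16


class TestWellValidation:
    def test_negative_rlu(self):
        with pytest.raises(ParseError):
            make_well(rlu_reporter=-1.0)

    def test_conc_exclusivity(self):
        with pytest.raises(ParseError):
            make_well(conc_h295r=1e-6, conc_standard=1e-9)
        with pytest.raises(ParseError):
            make_well(conc_h295r=None)

    def test_volumes(self):
        with pytest.raises(ParseError):
            make_well(supernatant_vol_ul=300.0)

    def test_bad_row(self):
        with pytest.raises(ParseError):
            make_well(row="Z")


class TestCSV:
    def test_round_trip(self, tmp_path):
        wells = [make_well(col=c, conc_h295r=3e-8 * c) for c in range(1, 6)]
        path = tmp_path / "m.csv"
        write_measurements(wells, path)
        back = read_measurements(path)
        assert back == wells

    def test_hcg_unit_conversion(self, tmp_path):
        w = make_well(chemical_id="hcg")
        path = tmp_path / "m.csv"
        write_measurements([w], path)
        text = path.read_text().replace(repr(3e-8), "1").replace(",M,", ",IU_per_ml,")
        path.write_text(text)
        (rec,) = read_measurements(path)
        assert rec.conc_h295r == pytest.approx(3.9e-6)
        assert HCG_M_PER_IU_ML == 3.9e-6

    def test_micromolar_conversion(self, tmp_path):
        w = make_well()
        path = tmp_path / "m.csv"
        write_measurements([w], path)
        text = path.read_text().replace(repr(3e-8), "0.03").replace(",M,", ",uM,")
        path.write_text(text)
        (rec,) = read_measurements(path)
        assert rec.conc_h295r == pytest.approx(3e-8)

    def test_duplicate_well_error(self, tmp_path):
        w = make_well()
        path = tmp_path / "m.csv"
        write_measurements([w, make_well(col=2)], path)
        text = path.read_text().replace(",2,", ",1,")
        path.write_text(text)
        with pytest.raises(ParseError, match="duplicate"):
            read_measurements(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("plate_id,row\nP1,C\n")
        with pytest.raises(ParseError, match="missing column"):
            read_measurements(path)

    def test_unknown_role(self, tmp_path):
        w = make_well()
        path = tmp_path / "m.csv"
        write_measurements([w], path)
        path.write_text(path.read_text().replace("h295r_treated", "mystery"))
        with pytest.raises(ParseError):
            read_measurements(path)

    def test_non_numeric_rlu(self, tmp_path):
        w = make_well()
        path = tmp_path / "m.csv"
        write_measurements([w], path)
        path.write_text(path.read_text().replace("100.0,100.0", "oops,100.0"))
        with pytest.raises(ParseError, match="non-numeric"):
            read_measurements(path)


class TestUnits:
    def test_double_conversion_refused(self):
        rows = [{"conc_h295r": "1", "conc_standard": "", "conc_unit": "uM"}]
        once = normalize_units(rows)
        assert once[0]["conc_h295r"] == pytest.approx(1e-6)
        with pytest.raises(UnitsError):
            normalize_units(once)


class TestDilutionScheme:
    def test_default_folds(self):
        scheme = DilutionScheme()
        assert scheme.ar_fold == pytest.approx(200 / 67)
        assert all(6.25 <= f <= 10 for f in scheme.er_folds)

    def test_out_of_range_er(self):
        with pytest.raises(ValueError):
            DilutionScheme(er_volumes_ul=((10.0, 200.0),) * 3)

    def test_ar_not_threefold(self):
        with pytest.raises(ValueError):
            DilutionScheme(ar_volumes_ul=(20.0, 200.0))


class TestStandardCurveSpec:
    def test_valid(self):
        StandardCurveSpec("E2", (1e-12, 1e-11, 1e-10))

    def test_not_increasing(self):
        with pytest.raises(ValueError):
            StandardCurveSpec("E2", (1e-11, 1e-12))

    def test_outside_range(self):
        with pytest.raises(ValueError):
            StandardCurveSpec("E2", (1e-13, 1e-9))

    def test_unknown_compound(self):
        with pytest.raises(ValueError):
            StandardCurveSpec("T", (1e-12,))


class TestPairSham:
    def _wells(self, role, concs, reps=3):
        return [make_well(role=role, col=(1 if role is Role.H295R_TREATED else 7),
                          row="CDEFGH"[i % 6], conc_h295r=c, tech_rep=r,
                          plate_id=f"{role.value}-{i}-{r}")
                for i, c in enumerate(concs) for r in range(1, reps + 1)]

    def test_eight_pairs(self):
        concs = [10 ** -i for i in range(8)]
        pairs = pair_sham(self._wells(Role.H295R_TREATED, concs),
                          self._wells(Role.SHAM, concs))
        assert len(pairs) == 8
        treated, sham = pairs[("x", 1.0)]
        assert len(treated) == 3 and len(sham) == 3

    def test_missing_counterpart(self):
        concs = [1e-6, 1e-5]
        with pytest.raises(PairingError, match="1e-05"):
            pair_sham(self._wells(Role.H295R_TREATED, concs),
                      self._wells(Role.SHAM, concs[:1]))


class TestPlateSetInvariants:
    def test_requires_three_er_plates(self, noisefree_run):
        ps = noisefree_run[0][0]
        with pytest.raises(ValueError):
            PlateSet(experiment_id="x", h295r_plate=ps.h295r_plate,
                     er_plates=ps.er_plates[:2], ar_plate=ps.ar_plate,
                     dilution_scheme=ps.dilution_scheme)

    def test_duplicate_well_rejected(self, noisefree_run):
        ps = noisefree_run[0][0]
        with pytest.raises(ParseError, match="duplicate"):
            PlateSet(experiment_id="x",
                     h295r_plate=ps.h295r_plate + [ps.h295r_plate[0]],
                     er_plates=ps.er_plates, ar_plate=ps.ar_plate,
                     dilution_scheme=ps.dilution_scheme)


class TestMatrixBlock:
    def test_shape_error(self):
        with pytest.raises(ParseError, match="8x12"):
            read_matrix_block([[0.0] * 12] * 7, [[0.0] * 12] * 8,
                              default_layout(), plate_id="P", assay=Assay.H295R,
                              mode=Mode.NONE, chemical_id="x",
                              concentration_grid=[1e-8] * 8)

    def test_converts_treated_wells(self):
        grid = [float(i + 1) * 1e-8 for i in range(8)]
        reporter = [[float(10 * r + c) for c in range(12)] for r in range(8)]
        viability = [[1.0] * 12 for _ in range(8)]
        records = read_matrix_block(reporter, viability, default_layout(),
                                    plate_id="P", assay=Assay.H295R,
                                    mode=Mode.NONE, chemical_id="x",
                                    concentration_grid=grid)
        assert len(records) == 96
        treated = [r for r in records if r.role is Role.H295R_TREATED]
        assert {r.conc_h295r for r in treated} == set(grid)
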