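"""Closed-form parameter math: quenching analysis, RLC, MDA, percent change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chillclass.chlf import (
    ChlFRecord, MDASample, RLCRecord,
    compute_mda, derive_parameters, derive_rlc, percent_change_vs_reference,
    read_chlf_csv, records_to_frame, FEATURE_NAMES,
)
from chillclass.errors import DomainError, SchemaError


def rec(Fo=400.0, Fm=2000.0, F=700.0, Fmp=900.0, Fop=380.0, **meta):
    return ChlFRecord(plant_id=meta.get("plant_id", "p1"),
                      temperature_C=meta.get("temperature_C", 12.0),
                      day=meta.get("day", 1),
                      Fo=Fo, Fm=Fm, F=F, Fm_prime=Fmp, Fo_prime=Fop)


class TestDeriveParameters:
    def test_hand_evaluated_quenching_parameters(self):
        d = derive_parameters(rec())
        assert d.Fv == 1600.0
        assert d.Fv_Fm == pytest.approx(0.8)
        assert d.Fv_Fo == pytest.approx(4.0)
        assert d.Y_II == pytest.approx(200 / 900)
        assert d.Y_NO == pytest.approx(0.35)
        assert d.Y_NPQ == pytest.approx(1 - 200 / 900 - 0.35)
        assert d.NPQ == pytest.approx(1100 / 900)
        assert d.qP == pytest.approx(200 / 520)
        assert d.qL == pytest.approx((200 / 520) * 380 / 700)
        assert d.qN == pytest.approx(0.675)

    def test_group_mean_fv_identity(self):
        # Fv = Fm − Fo is linear, so it holds for group means too
        d = derive_parameters(rec(Fo=345.3, Fm=1115.9, F=668.7, Fmp=739.8, Fop=349.1))
        assert d.Fv == pytest.approx(770.6, abs=0.05)

    def test_no_variable_quenching_in_light(self):
        # F at the light-adapted maximum: no photochemical quenching left
        d = derive_parameters(rec(Fo=300, Fm=300 + 1e-6 + 500, F=800, Fmp=800, Fop=290))
        assert d.Y_II == 0.0
        assert d.qP == 0.0

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            (dict(Fmp=380.0, Fop=380.0), "Fm_prime - Fo_prime"),
            (dict(Fo=2000.0, Fm=2000.0), "Fm"),
        ],
    )
    def test_zero_denominators_rejected(self, kwargs, fragment):
        with pytest.raises(DomainError):
            derive_parameters(rec(**kwargs))

    def test_invalid_records_rejected(self):
        with pytest.raises(DomainError, match="Fm must exceed Fo"):
            rec(Fo=2100.0)
        with pytest.raises(DomainError, match="positive"):
            rec(F=-1.0)
        with pytest.raises(DomainError, match="Fo_prime"):
            rec(Fmp=300.0, Fop=380.0)

    @given(
        Fo=st.floats(100, 1000),
        dFv=st.floats(1, 3000),
        F=st.floats(50, 3000),
        dq=st.floats(1, 2000),
        Fop=st.floats(50, 900),
    )
    @settings(max_examples=200, derandomize=True)
    def test_yield_partition_and_ratio_identities(self, Fo, dFv, F, dq, Fop):
        """Y(II)+Y(NPQ)+Y(NO)=1 and Fv/Fm=(Fv/Fo)/(1+Fv/Fo) for any valid record."""
        r = rec(Fo=Fo, Fm=Fo + dFv, F=F, Fmp=Fop + dq, Fop=Fop)
        d = derive_parameters(r)
        assert d.Y_II + d.Y_NPQ + d.Y_NO == pytest.approx(1.0, abs=1e-12)
        assert d.Fv_Fm == pytest.approx(d.Fv_Fo / (1 + d.Fv_Fo), rel=1e-12)


class TestDeriveRLC:
    def test_etr_from_yield(self):
        r = derive_rlc(RLCRecord(plant_id="a", PAR=100, Y_II=0.5, Y_I=0.5))
        assert r.ETR_II == pytest.approx(21.0)
        assert r.Y_CEF == pytest.approx(0.0)

    def test_cyclic_flow_from_yield_gap(self):
        r = derive_rlc(RLCRecord(plant_id="a", PAR=270, Y_II=0.2, Y_I=0.6))
        assert r.Y_CEF == pytest.approx((0.6 - 0.2) * 270 * 0.42)
        assert r.Y_CEF == pytest.approx(45.36)

    def test_raw_p700_signals(self):
        r = derive_rlc(RLCRecord(plant_id="a", PAR=100, Y_II=0.1,
                                 P=20.0, Pm=100.0, Pm_prime=80.0))
        assert r.Y_I == pytest.approx(0.6)
        assert r.Y_ND == pytest.approx(0.2)

    def test_nonpositive_pm_rejected(self):
        with pytest.raises(DomainError, match="Pm"):
            derive_rlc(RLCRecord(plant_id="a", PAR=100, Y_II=0.1,
                                 P=1.0, Pm=0.0, Pm_prime=2.0))

    @given(y_i=st.floats(0, 1), y_ii=st.floats(0, 1), par=st.floats(0, 2256))
    @settings(max_examples=100, derandomize=True)
    def test_cyclic_flow_sign(self, y_i, y_ii, par):
        r = derive_rlc(RLCRecord(plant_id="a", PAR=par, Y_II=y_ii, Y_I=y_i))
        if y_i >= y_ii:
            assert r.Y_CEF >= -1e-12


class TestMDA:
    def test_hand_evaluated_content(self):
        s = MDASample(D450=0.1, D510=0.2, D532=0.5, D560=0.15, N=5, W=0.5)
        assert compute_mda(s) == pytest.approx(30.0775)

    def test_zero_absorbances(self):
        assert compute_mda(MDASample(0, 0, 0, 0, N=5, W=0.5)) == 0.0

    @given(n=st.floats(0.5, 20), w=st.floats(0.1, 5),
           d532=st.floats(0, 2), d450=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_linearity_and_scale_invariance(self, n, w, d532, d450):
        s1 = MDASample(d450, 0.3, d532, 0.1, N=n, W=w)
        s2 = MDASample(d450, 0.3, d532, 0.1, N=2 * n, W=w)
        s3 = MDASample(d450, 0.3, d532, 0.1, N=2 * n, W=2 * w)
        assert compute_mda(s2) == pytest.approx(2 * compute_mda(s1), rel=1e-12)
        assert compute_mda(s3) == pytest.approx(compute_mda(s1), rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DomainError):
            MDASample(0.1, 0.2, 0.5, 0.15, N=5, W=0.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "by_class, expected",
        [
            ({0: [10, 10], 1: [12, 12]}, {0: 0.0, 1: 20.0}),
            ({0: [8, 12], 1: [15, 15]}, {0: 0.0, 1: 50.0}),
        ],
    )
    def test_signed_percent_change(self, by_class, expected):
        out = percent_change_vs_reference(by_class, 0)
        for k, v in expected.items():
            assert out[k] == pytest.approx(v)

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(DomainError):
            percent_change_vs_reference({0: [0.0, 0.0], 1: [1.0]}, 0)

    def test_empty_reference_rejected(self):
        with pytest.raises(DomainError):
            percent_change_vs_reference({0: [], 1: [1.0]}, 0)


class TestCSV:
    def test_roundtrip_and_derived_table(self, tmp_path):
        path = tmp_path / "chlf.csv"
        records_to_frame([rec(plant_id="a"), rec(plant_id="b", Fo=350)],
                         derive=False).to_csv(path, index=False)
        back = read_chlf_csv(str(path))
        assert [r.plant_id for r in back] == ["a", "b"]
        table = records_to_frame(back)
        assert list(table.columns)[3:] == list(FEATURE_NAMES)

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plant_id,Fo\np1,100\n")
        with pytest.raises(SchemaError, match="missing required columns"):
            read_chlf_csv(str(path))

    def test_bad_row_reported_with_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "plant_id,temperature_C,day,Fo,Fm,F,Fm_prime,Fo_prime\n"
            "p1,8,1,400,2000,700,900,380\n"
            "p2,8,1,2100,2000,700,900,380\n"
        )
        with pytest.raises(SchemaError, match="row 3"):
            read_chlf_csv(str(path))
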