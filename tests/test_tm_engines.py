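"""Tm formulas, F-factor logic, method selection and the full pipeline."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from nnmelt.corrections import Environment
from nnmelt.energetics import EnergyBreakdown
from nnmelt.errors import (NotApplicableError, UnknownMethodError,
                           ValidationError)
from nnmelt.fixtures import FixtureSpec, make_duplex, make_fixture_set
from nnmelt.paramstore import ThermoResult, write_parameter_set
from nnmelt.sequences import build_duplex
from nnmelt.tm_engines import (Options, compute, f_factor, select_method,
                               tm_cng, tm_nn, tm_wetmur_dna, tm_wetmur_rna)

R = 1.9872


def _breakdown(dh, ds):
    return EnergyBreakdown(per_segment=[], initiation=ThermoResult(dh, ds),
                           symmetry=ThermoResult(0, 0), ds_salt_independent=0.0)


def _env(**kw):
    kw.setdefault("hybridization", "dnadna")
    kw.setdefault("Na", 1.0)
    return Environment(**kw)


class TestFFactor:
    def test_self_complementary_is_one(self):
        assert f_factor(_env(self_complementary=True)) == 1

    def test_equimolar_non_self_is_four(self):
        assert f_factor(_env()) == 4

    def test_large_excess_is_one(self):
        assert f_factor(_env(Cmax=1e-3, Cmin=1e-6)) == 1

    def test_explicit_excess_flag(self):
        assert f_factor(_env(strand_excess=True)) == 1

    def test_moderate_ratio_stays_four(self):
        assert f_factor(_env(Cmax=2e-6, Cmin=1e-6)) == 4


class TestTmNN:
    def test_log_term_vanishes_when_ct_equals_f(self):
        # dH=-84000, dS=-230, CT=F: Tm = 84000/230 - 273.15
        tm = tm_nn(_breakdown(-84000, -230), _env(CT=4.0))
        assert tm == pytest.approx(84000 / 230 - 273.15, abs=1e-9)
        assert tm == pytest.approx(92.07, abs=0.01)

    def test_hand_value_with_concentration_term(self):
        tm = tm_nn(_breakdown(-50000, -135), _env(CT=1e-4))
        expected = -50000 / (-135 + R * math.log(2.5e-5)) - 273.15
        assert tm == pytest.approx(expected, abs=1e-9)
        assert tm == pytest.approx(47.24, abs=0.01)

    def test_self_complementary_uses_f1(self):
        tm1 = tm_nn(_breakdown(-84000, -230),
                    _env(CT=1e-4, self_complementary=True))
        tm4 = tm_nn(_breakdown(-84000, -230), _env(CT=1e-4))
        assert tm1 > tm4  # ln(CT/1) > ln(CT/4) makes the denominator larger

    def test_cmax_cmin_replaces_ct_over_f(self):
        env = _env(CT=3e-4, Cmax=2e-4, Cmin=1e-4)
        tm = tm_nn(_breakdown(-84000, -230), env)
        expected = -84000 / (-230 + R * math.log(2e-4 - 1e-4 / 2)) - 273.15
        assert tm == pytest.approx(expected, abs=1e-12)

    def test_cmax_cmin_limits(self):
        # large excess ~ ln(CT); equimolar ~ ln(CT/4)
        big = _env(CT=1e-3, Cmax=1e-3, Cmin=1e-9)
        assert tm_nn(_breakdown(-84000, -230), big) == pytest.approx(
            -84000 / (-230 + R * math.log(1e-3)) - 273.15, abs=1e-3)
        eq = _env(CT=2e-4, Cmax=1e-4, Cmin=1e-4)
        assert tm_nn(_breakdown(-84000, -230), eq) == pytest.approx(
            -84000 / (-230 + R * math.log(2e-4 / 4)) - 273.15, abs=1e-6)

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValidationError):
            tm_nn(_breakdown(-84000, -230), _env(CT=0.0))

    @given(dh=st.floats(min_value=-200_000, max_value=-10_000),
           ds=st.floats(min_value=-500, max_value=-30))
    @settings(max_examples=200, derandomize=True)
    def test_tm_increases_with_ct(self, dh, ds):
        tms = [tm_nn(_breakdown(dh, ds), _env(CT=ct))
               for ct in (1e-7, 1e-6, 1e-5, 1e-4)]
        assert tms == sorted(tms)

    def test_kelvin_consistency(self):
        env = _env(CT=2e-4)
        tm_c = tm_nn(_breakdown(-84000, -230), env)
        tm_k = -84000 / (-230 + R * math.log(env.CT / 4))
        assert tm_c == pytest.approx(tm_k - 273.15, abs=1e-9)


class TestTmCng:
    def test_hairpin_form_is_concentration_free(self):
        bd = _breakdown(-40000, -120)
        tm5 = tm_cng(bd, 5, _env(CT=1e-4))
        assert tm5 == pytest.approx(-40000 / -120 - 273.15, abs=1e-9)
        assert tm5 == pytest.approx(60.18, abs=0.01)
        assert tm_cng(bd, 6, _env(CT=1e-8)) == tm5

    def test_few_repeats_use_duplex_formula_with_f1(self):
        bd = _breakdown(-40000, -120)
        env = _env(CT=1e-4, self_complementary=True)
        assert tm_cng(bd, 3, env) == pytest.approx(tm_nn(bd, env), abs=1e-12)

    def test_zero_entropy_rejected(self):
        with pytest.raises(ValidationError):
            tm_cng(_breakdown(-40000, 0), 5)


class TestWetmur:
    def test_hand_value(self):
        tm = tm_wetmur_dna(50.0, 20, 1.0, 0.0)
        expected = 81.5 + 16.6 * math.log10(1 / 1.7) + 0.41 * 50 - 500 / 20
        assert tm == pytest.approx(expected, abs=1e-12)
        assert tm == pytest.approx(73.17, abs=0.01)

    def test_linear_responses_exact(self):
        base = tm_wetmur_dna(50.0, 20, 0.1, 0.0)
        assert tm_wetmur_dna(51.0, 20, 0.1, 0.0) - base == pytest.approx(0.41)
        assert tm_wetmur_dna(50.0, 20, 0.1, 5.0) - base == pytest.approx(-5.0)

    def test_monotone_in_size_and_salt(self):
        tms = [tm_wetmur_dna(50.0, n, 0.1) for n in (10, 20, 50, 200)]
        assert tms == sorted(tms)
        tms = [tm_wetmur_dna(50.0, 20, na) for na in (0.01, 0.1, 0.5, 1.0)]
        assert tms == sorted(tms)

    def test_rna_variant_differs(self):
        assert tm_wetmur_rna(50.0, 20, 1.0) != tm_wetmur_dna(50.0, 20, 1.0)

    def test_invalid_salt_rejected(self):
        with pytest.raises(ValidationError):
            tm_wetmur_dna(50.0, 20, 0.0)


class TestSelectMethod:
    def test_threshold(self):
        short = build_duplex("A" * 20, None, "dnadna")
        long = build_duplex("A" * 100, None, "dnadna")
        env = _env(CT=1e-4)
        assert select_method(short, env, threshold=60) == "nn"
        assert select_method(long, env, threshold=60) == "approx"

    def test_forced_method_wins(self):
        long = build_duplex("A" * 100, None, "dnadna")
        assert select_method(long, _env(CT=1e-4), threshold=60,
                             forced="nn") == "nn"

    def test_unknown_forced_method(self):
        with pytest.raises(UnknownMethodError):
            select_method(build_duplex("ACGT", None, "dnadna"),
                          _env(CT=1e-4), forced="magic")


class TestComputePipeline:
    def test_reference_state_run(self):
        duplex = build_duplex("AGCGTCATGCAT", None, "dnadna")
        r = compute(duplex, _env(CT=2e-4))
        assert r.method == "nn"
        assert r.dh is not None and r.ds is not None
        # at 1 M Na the ion correction is a fixed point
        assert r.tm == pytest.approx(
            r.dh / (r.ds + R * math.log(2e-4 / 4)) - 273.15, abs=1e-9)

    def test_seq1_only_equals_explicit_complement(self):
        top = "AGCGTCATGCAT"
        auto = compute(build_duplex(top, None, "dnadna"), _env(CT=2e-4))
        explicit = compute(build_duplex(top, "TCGCAGTACGTA", "dnadna"),
                           _env(CT=2e-4))
        assert auto.tm == explicit.tm

    def test_approx_path_has_no_energies_and_no_ion_step(self):
        duplex = build_duplex("ACGT" * 30, None, "dnadna")
        r = compute(duplex, _env(CT=2e-4, K=0.05, Mg=0.002))
        assert r.method == "approx"
        assert r.dh is None and r.ds is None
        assert r.corrections_applied == []
        assert r.diagnostics["na_eq"] > 1.0  # NaEq computed from the buffer

    def test_lower_salt_lowers_tm(self):
        duplex = build_duplex("AGCGTCATGCAT", None, "dnadna")
        high = compute(duplex, _env(CT=2e-4))
        low = compute(duplex, _env(Na=0.05, CT=2e-4))
        assert low.tm < high.tm

    def test_entropy_type_correction_spares_salt_independent_part(self, tmp_path):
        spec = FixtureSpec(defects=("internal_loop",), loop_sizes=(3, 4),
                           seed=9)
        duplex, _ = make_duplex(spec)
        pset = make_fixture_set(spec)
        write_parameter_set(pset, tmp_path / f"{pset.id}.xml")
        opts = Options(parameter_set=pset.id, data_dir=str(tmp_path),
                       ion_id="san04")
        r1 = compute(duplex, _env(CT=2e-4), opts)
        r05 = compute(duplex, _env(Na=0.5, CT=2e-4), opts)
        n_bp = len(duplex.paired_columns())
        shift = 0.368 * (n_bp - 1) * math.log(0.5)
        assert r05.ds - r1.ds == pytest.approx(shift)
        assert r05.diagnostics["ds_salt_independent"] == \
            r1.diagnostics["ds_salt_independent"]

    def test_cng_pipeline(self, tmp_path):
        duplex = build_duplex("CAG" * 5, None, "dnadna", self_flag=True)
        spec = FixtureSpec()
        pset = make_fixture_set(spec)
        write_parameter_set(pset, tmp_path / f"{pset.id}.xml")
        opts = Options(parameter_set=pset.id, data_dir=str(tmp_path))
        r = compute(duplex, _env(CT=2e-4), opts)
        # one uniform CNG entry (-8000, -22), zero initiation, symmetry
        # entropy -1.4; 5 repeats use the hairpin form dh/ds - 273.15
        assert r.tm == pytest.approx(-8000.0 / (-22.0 - 1.4) - 273.15,
                                     abs=1e-9)

    def test_missing_default_set_for_hybrid_duplex(self):
        duplex = build_duplex("AGCT", None, "dnarna")
        with pytest.raises(Exception, match="no default parameter set"):
            compute(duplex, Environment(hybridization="dnarna", Na=1.0,
                                        CT=1e-4))

    def test_deterministic(self):
        duplex = build_duplex("AGCGTCATGCAT", None, "dnadna")
        r1 = compute(duplex, _env(CT=2e-4))
        r2 = compute(duplex, _env(CT=2e-4))
        assert (r1.tm, r1.dh, r1.ds) == (r2.tm, r2.dh, r2.ds)
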