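"""Donor decomposition, NO autooxidation, and steady-state summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notet import (
    DEA_NO,
    DETA_NO,
    SPER_NO,
    DonorSpec,
    KineticParams,
    decay_constant,
    donor_ic50_to_no_ic50,
    quasi_steady_state_no,
    simulate_no,
    summarize_steady_state,
)
from notet.errors import IntegrationError, InvalidParameterError
from notet.kinetics import NOTimeCourse


@pytest.mark.parametrize(
    "donor,expected",
    [(DEA_NO, 7.22e-4), (SPER_NO, 5.02e-5), (DETA_NO, 3.38e-6)],
)
def test_decay_constant_matches_ln2_over_half_life(donor, expected):
    k = decay_constant(donor)
    assert k == pytest.approx(math.log(2) / donor.half_life, rel=1e-12)
    assert k == pytest.approx(expected, rel=1e-2)


def test_invalid_donor_parameters_rejected():
    with pytest.raises(InvalidParameterError):
        DonorSpec("bad", half_life=-1.0, no_equivalents=2.0)
    with pytest.raises(InvalidParameterError):
        DonorSpec("bad", half_life=100.0, no_equivalents=0.0)
    with pytest.raises(InvalidParameterError):
        KineticParams(no_per_o2=3)


def test_zero_dose_gives_zero_no_and_constant_o2():
    tc = simulate_no(SPER_NO, 0.0, duration=3600.0)
    assert np.all(tc.no == 0)
    assert np.allclose(tc.o2, 220.0)
    assert np.all(tc.no_consumed == 0)


def test_donor_half_life_exact_within_1e4_relative():
    tc = simulate_no(DEA_NO, 25.0, duration=3 * 3600.0, output_step=1.0)
    d_half = np.interp(DEA_NO.half_life, tc.times, tc.donor)
    assert d_half == pytest.approx(25.0 / 2, rel=1e-4)


def test_dea_burst_shape():
    """25 uM DEA/NO: donor exhausted by 3 h, NO peaks at several uM then
    falls through the sub-uM range between 1 and 2 h."""
    tc = simulate_no(DEA_NO, 25.0, duration=3 * 3600.0)
    assert np.interp(3 * 3600.0, tc.times, tc.donor) < 25.0 * 1e-3
    peak = tc.no.max()
    assert 2.0 < peak < 5.0
    assert tc.times[np.argmax(tc.no)] < 15 * 60.0 * 2  # early peak
    no_1h = np.interp(3600.0, tc.times, tc.no)
    no_2h = np.interp(7200.0, tc.times, tc.no)
    assert 0.6 < no_1h < 1.65
    assert no_2h < 0.6


@pytest.mark.parametrize("donor,dose,expected", [
    (SPER_NO, 165.0, 3.07),
    (DETA_NO, 100.0, 0.62),
])
def test_quasi_steady_state_closed_form(donor, dose, expected):
    assert quasi_steady_state_no(donor, dose) == pytest.approx(expected, rel=5e-3)


def test_quasi_steady_state_edge_cases():
    assert quasi_steady_state_no(SPER_NO, 0.0) == 0.0
    with pytest.raises(IntegrationError):
        quasi_steady_state_no(SPER_NO, 10.0, KineticParams(o2_initial=0.0))


@pytest.mark.parametrize("donor,dose", [(SPER_NO, 165.0), (DETA_NO, 100.0)])
def test_ode_matches_qss_oracle_for_slow_donors(donor, dose):
    """After the NO relaxation transient the numerical [NO](t) tracks the
    analytic quasi-steady-state evaluated at the instantaneous [D], [O2]."""
    tc = simulate_no(donor, dose, duration=3 * 3600.0)
    params = tc.params
    for frac in (0.25, 0.5, 0.75, 1.0):
        t = frac * 3 * 3600.0
        i = np.searchsorted(tc.times, t)
        i = min(i, len(tc.times) - 1)
        d, o2, no = tc.donor[i], tc.o2[i], tc.no[i]
        qss = quasi_steady_state_no(donor, d, KineticParams(
            k_aut=params.k_aut, no_per_o2=params.no_per_o2, o2_initial=o2))
        assert no == pytest.approx(qss, rel=0.10)


@settings(max_examples=20, deadline=None)
@given(
    dose=st.floats(min_value=1.0, max_value=500.0),
    half_life=st.floats(min_value=300.0, max_value=3e5),
    e=st.floats(min_value=1.0, max_value=2.0),
)
def test_mass_balance_and_nonnegativity(dose, half_life, e):
    """e_NO (dose - [D]) = [NO] + consumed at every output time; all states >= 0."""
    donor = DonorSpec("x", half_life, e)
    tc = simulate_no(donor, dose, duration=2 * 3600.0, output_step=60.0)
    assert np.all(tc.donor >= 0) and np.all(tc.no >= 0)
    assert np.all(tc.o2 >= 0) and np.all(tc.no_consumed >= 0)
    released = e * (tc.dose - tc.donor)
    resid = np.abs(released - (tc.no + tc.no_consumed))
    assert resid.max() <= 1e-3 * max(e * dose, 1.0)


def test_released_no_conserved_after_many_half_lives():
    tc = simulate_no(DEA_NO, 10.0, duration=20 * DEA_NO.half_life, output_step=120.0)
    total = tc.no[-1] + tc.no_consumed[-1]
    assert total == pytest.approx(DEA_NO.no_equivalents * 10.0, rel=1e-3)


def test_mean_no_monotone_in_dose_equivalents_stoich_o2():
    window = (0.0, 3600.0)

    def mean_no(dose=100.0, e=2.0, s=4, o2=220.0):
        donor = DonorSpec("x", SPER_NO.half_life, e)
        tc = simulate_no(donor, dose, KineticParams(no_per_o2=s, o2_initial=o2),
                         duration=3600.0)
        return summarize_steady_state(tc, window).mean_no

    assert mean_no(dose=50.0) < mean_no(dose=100.0) < mean_no(dose=200.0)
    assert mean_no(e=1.0) < mean_no(e=2.0)
    assert mean_no(s=4) < mean_no(s=2) < mean_no(s=1)
    assert mean_no(o2=440.0) < mean_no(o2=220.0) < mean_no(o2=110.0)


def test_summarize_constant_series():
    tc = NOTimeCourse(
        times=np.linspace(0, 100, 11),
        donor=np.full(11, 5.0),
        no=np.full(11, 2.5),
        o2=np.full(11, 220.0),
        no_consumed=np.zeros(11),
        dose=5.0,
    )
    ss = summarize_steady_state(tc, (0.0, 100.0))
    assert ss.mean_no == pytest.approx(2.5)
    assert ss.peak_no == pytest.approx(2.5)


def test_summarize_rejects_bad_windows():
    tc = simulate_no(SPER_NO, 10.0, duration=600.0)
    with pytest.raises(InvalidParameterError):
        summarize_steady_state(tc, (100.0, 100.0))
    with pytest.raises(InvalidParameterError):
        summarize_steady_state(tc, (0.0, 1e6))


def test_sper_no_ic50_converts_to_about_3_uM():
    ss = donor_ic50_to_no_ic50(SPER_NO, 165.0, assay_duration=3 * 3600.0)
    assert ss.mean_no == pytest.approx(3.0, rel=0.30)


def test_deta_no_plateau_about_600_nM():
    ss = donor_ic50_to_no_ic50(DETA_NO, 100.0, assay_duration=12 * 3600.0,
                               output_step=60.0)
    assert ss.mean_no == pytest.approx(0.6, rel=0.30)


def test_zero_donor_ic50_maps_to_zero_no():
    ss = donor_ic50_to_no_ic50(SPER_NO, 0.0, assay_duration=3600.0)
    assert ss.mean_no == 0.0 and ss.peak_no == 0.0
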