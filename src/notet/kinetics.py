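"""NONOate donor decomposition and NO autooxidation kinetics.

Diazeniumdiolate ("NONOate") donors release nitric oxide by first-order
decomposition with a characteristic half-life and stoichiometry (moles of NO
per mole of donor, ``e_NO``).  In an aerobic aqueous assay, free NO is removed
predominantly by autooxidation::

    4 NO + O2 -> 4 NO2-      rate = k [NO]^2 [O2],  k = 2e6 M^-2 s^-1

so the steady-state NO concentration is set by the balance between donor
release and autooxidation.  This module integrates the coupled system

    d[D]/dt   = -k1 [D]                      k1 = ln(2) / t_half
    d[NO]/dt  =  k1 [D] e_NO - s k [O2] [NO]^2
    d[O2]/dt  = -k [O2] [NO]^2
    dC/dt     =  s k [O2] [NO]^2             (C = cumulative NO oxidized)

where ``s`` is the NO:O2 consumption stoichiometry (4 for the textbook
autooxidation reaction; configurable).  Internal units are micromolar and
seconds throughout, hence the default ``k_aut = 2e-6 uM^-2 s^-1``.

The closed-form quasi-steady-state concentration

    [NO]_qss = sqrt( k1 [D] e_NO / (s k [O2]) )

serves as an independent analytic check on the numerical solution for donors
whose release is slow compared with the NO relaxation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidParameterError

__all__ = [
    "DonorSpec",
    "KineticParams",
    "NOTimeCourse",
    "SteadyStateSummary",
    "DEA_NO",
    "SPER_NO",
    "DETA_NO",
    "DONORS",
    "decay_constant",
    "simulate_no",
    "quasi_steady_state_no",
    "summarize_steady_state",
    "donor_ic50_to_no_ic50",
]

_LN2 = math.log(2.0)

# Solver tolerances (uM, s).  Negative excursions beyond _NEG_CLIP abort the
# run instead of being silently clipped.
_RTOL = 1e-8
_ATOL = 1e-9
_NEG_CLIP = 1e-6


@dataclass(frozen=True)
class DonorSpec:
    """A NONOate NO donor: release half-life (s) and NO stoichiometry.

    Parameters
    ----------
    name : str
        Donor identifier, e.g. ``"Sper/NO"``.
    half_life : float
        First-order decomposition half-life in seconds.
    no_equivalents : float
        Moles of NO released per mole of donor (``e_NO``).
    note : str
        Free text, typically the temperature the half-life applies to.
    """

    name: str
    half_life: float
    no_equivalents: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise InvalidParameterError(
                f"half_life must be positive, got {self.half_life!r}"
            )
        if not self.no_equivalents > 0:
            raise InvalidParameterError(
                f"no_equivalents must be positive, got {self.no_equivalents!r}"
            )


#: Short-acting donor, t1/2 = 16 min at 25 C, 1.5 NO equivalents.
DEA_NO = DonorSpec("DEA/NO", half_life=16 * 60.0, no_equivalents=1.5, note="25 C")
#: Intermediate donor, t1/2 = 230 min at 25 C, 2 NO equivalents.
SPER_NO = DonorSpec("Sper/NO", half_life=230 * 60.0, no_equivalents=2.0, note="25 C")
#: Slow donor, t1/2 = 57 h (simulation value; ~22 h is also quoted at 37 C).
DETA_NO = DonorSpec("DETA/NO", half_life=57 * 3600.0, no_equivalents=2.0, note="57 h simulation value")

DONORS = {"dea": DEA_NO, "sper": SPER_NO, "deta": DETA_NO}


@dataclass(frozen=True)
class KineticParams:
    """Autooxidation parameters.

    ``k_aut`` is the third-order autooxidation rate constant in uM^-2 s^-1
    (2e-6 uM^-2 s^-1 == 2e6 M^-2 s^-1).  ``no_per_o2`` is the NO:O2
    consumption stoichiometry ``s``; 4 corresponds to 4NO + O2 -> 4NO2-.
    ``o2_initial`` is the dissolved O2 concentration in uM (room-air ~220 uM).
    """

    k_aut: float = 2e-6
    no_per_o2: int = 4
    o2_initial: float = 220.0
    temperature_note: str = ""

    def __post_init__(self) -> None:
        if not self.k_aut > 0:
            raise InvalidParameterError(f"k_aut must be positive, got {self.k_aut!r}")
        if self.no_per_o2 not in (1, 2, 4):
            raise InvalidParameterError(
                f"no_per_o2 must be one of 1, 2, 4; got {self.no_per_o2!r}"
            )
        if self.o2_initial < 0:
            raise InvalidParameterError(
                f"o2_initial must be non-negative, got {self.o2_initial!r}"
            )


@dataclass
class NOTimeCourse:
    """Gridded trajectories of donor, NO, O2 and cumulative oxidized NO (uM, s)."""

    times: np.ndarray
    donor: np.ndarray
    no: np.ndarray
    o2: np.ndarray
    no_consumed: np.ndarray
    dose: float
    donor_spec: DonorSpec | None = None
    params: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("donor", "no", "o2", "no_consumed"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"series {name!r} length != time grid")


@dataclass(frozen=True)
class SteadyStateSummary:
    """Operational summary of [NO]_ss over a stated window (uM, s)."""

    mean_no: float
    peak_no: float
    time_of_peak: float
    window: tuple[float, float]


def decay_constant(donor: DonorSpec) -> float:
    """First-order donor decay constant, ln(2)/half_life (s^-1)."""
    return _LN2 / donor.half_life


def simulate_no(
    donor: DonorSpec,
    dose: float,
    params: KineticParams | None = None,
    duration: float = 3 * 3600.0,
    output_step: float = 10.0,
) -> NOTimeCourse:
    """Integrate donor decomposition + NO autooxidation over ``duration`` seconds.

    Parameters
    ----------
    donor : DonorSpec
    dose : float
        Initial donor concentration [D]0 in uM.
    params : KineticParams, optional
        Autooxidation parameters; defaults are the standard aerobic assay
        conditions (k = 2e-6 uM^-2 s^-1, s = 4, [O2]0 = 220 uM).
    duration : float
        Simulated span in seconds.
    output_step : float
        Output grid spacing in seconds.

    Returns
    -------
    NOTimeCourse
        Trajectories sampled on the requested grid.  Mass balance
        ``e_NO (dose - [D]) = [NO] + no_consumed`` holds to solver tolerance.
    """
    if params is None:
        params = KineticParams()
    if dose < 0:
        raise InvalidParameterError(f"dose must be non-negative, got {dose!r}")
    if not duration > 0:
        raise InvalidParameterError(f"duration must be positive, got {duration!r}")
    if not output_step > 0:
        raise InvalidParameterError(f"output_step must be positive, got {output_step!r}")

    k1 = decay_constant(donor)
    e = donor.no_equivalents
    s = params.no_per_o2
    k = params.k_aut

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        d, no, o2 = y[0], max(y[1], 0.0), max(y[2], 0.0)
        r = k * o2 * no * no  # elementary autooxidation rate (uM/s of O2)
        return [-k1 * d, k1 * d * e - s * r, -r, s * r]

    t_eval = np.arange(0.0, duration + output_step / 2, output_step)
    t_eval[-1] = min(t_eval[-1], duration)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        [dose, 0.0, params.o2_initial, 0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    y = sol.y
    if np.any(y < -_NEG_CLIP):
        worst = float(y.min())
        raise IntegrationError(
            f"negative state excursion beyond tolerance (min value {worst:g} uM)"
        )
    y = np.clip(y, 0.0, None)
    return NOTimeCourse(
        times=sol.t,
        donor=y[0],
        no=y[1],
        o2=y[2],
        no_consumed=y[3],
        dose=dose,
        donor_spec=donor,
        params=params,
    )


def quasi_steady_state_no(
    donor: DonorSpec, dose_at_t: float, params: KineticParams | None = None
) -> float:
    """Closed-form quasi-steady-state [NO] at a given instantaneous donor level.

    Balances production ``k1 [D] e_NO`` against consumption
    ``s k [O2] [NO]^2`` and solves for [NO].  Serves as an analytic oracle for
    :func:`simulate_no` when donor release is slow.
    """
    if params is None:
        params = KineticParams()
    if dose_at_t < 0:
        raise InvalidParameterError(f"dose_at_t must be non-negative, got {dose_at_t!r}")
    if dose_at_t == 0:
        return 0.0
    if params.o2_initial == 0:
        raise IntegrationError("zero O2: quasi-steady-state NO is unbounded")
    k1 = decay_constant(donor)
    return math.sqrt(
        k1 * dose_at_t * donor.no_equivalents
        / (params.no_per_o2 * params.k_aut * params.o2_initial)
    )


def summarize_steady_state(
    tc: NOTimeCourse, window: tuple[float, float] | None = None
) -> SteadyStateSummary:
    """Time-averaged (trapezoidal) and peak [NO] over ``window`` seconds.

    ``window`` defaults to the full simulated span.
    """
    t0 = float(tc.times[0])
    t1 = float(tc.times[-1])
    if window is None:
        window = (t0, t1)
    w0, w1 = float(window[0]), float(window[1])
    if not w0 < w1:
        raise InvalidParameterError(f"empty window {window!r}")
    if w0 < t0 - 1e-9 or w1 > t1 + 1e-9:
        raise InvalidParameterError(
            f"window {window!r} outside simulated span ({t0:g}, {t1:g})"
        )
    mask = (tc.times >= w0 - 1e-9) & (tc.times <= w1 + 1e-9)
    t = tc.times[mask]
    no = tc.no[mask]
    if len(t) < 2:
        raise InvalidParameterError("window contains fewer than 2 grid points")
    mean = float(np.trapezoid(no, t) / (t[-1] - t[0]))
    i = int(np.argmax(no))
    return SteadyStateSummary(
        mean_no=mean,
        peak_no=float(no[i]),
        time_of_peak=float(t[i]),
        window=(w0, w1),
    )


def donor_ic50_to_no_ic50(
    donor: DonorSpec,
    donor_ic50: float,
    params: KineticParams | None = None,
    assay_duration: float = 3 * 3600.0,
    output_step: float = 10.0,
) -> SteadyStateSummary:
    """Convert a donor-denominated IC50 into an NO-denominated one.

    Simulates the donor at its IC50 dose for the assay duration and summarizes
    the resulting free-NO trajectory over the full assay window; the
    time-averaged [NO] is the NO-based IC50.
    """
    if donor_ic50 < 0:
        raise InvalidParameterError(f"donor_ic50 must be non-negative, got {donor_ic50!r}")
    tc = simulate_no(donor, donor_ic50, params=params, duration=assay_duration,
                     output_step=output_step)
    return summarize_steady_state(tc)
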