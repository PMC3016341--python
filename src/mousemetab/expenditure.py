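"""Energy expenditure: the activity coefficient lambda(t), the EE model, and
the closed-form resolution of the coupled balance/expenditure system.

Total energy expenditure is modeled as

    EE = K + gamma_FFM*FFM + gamma_FM*FM + lambda*BW + beta*DeltaEI
         + eta_FFM*dFFM/dt + eta_FM*dFM/dt,

i.e. basal thermogenesis, tissue-mass-dependent metabolic rate, physical
activity proportional to body weight, diet-induced thermogenesis driven by
the intake change relative to chow, and the biochemical cost of tissue
deposition.  Because the tissue rates themselves depend on EE through the
energy-balance equation EI - EE = rho_FM*dFM/dt + rho_FFM*dFFM/dt, the two
relations form an implicit system; :func:`resolve_energy_balance` solves it
exactly in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import BodyState, ModelParameters
from .partition import alpha
from .schedules import ActivitySchedule

#: Minutes per day; used when converting kcal/g/d coefficients to cal/g/min.
_MIN_PER_DAY = 1440.0


@dataclass(frozen=True)
class EnergyRates:
    """Resolved instantaneous rates at one state/forcing combination.

    ``components`` breaks EE (kcal/d) into basal (K), FFM metabolism,
    FM metabolism, activity (lambda*BW), DIT (beta*DeltaEI), and the
    deposition cost; the six entries sum to ``EE``.
    """

    EE: float
    dFM_dt: float
    dFFM_dt: float
    components: dict

    def component_sum(self) -> float:
        return sum(self.components.values())


def lambda_at(t: float, s: ActivitySchedule) -> float:
    """Physical-activity coefficient (kcal/g/d) at time ``t``.

    Right-continuous piecewise evaluation of the diet-switch dynamics:
    the baseline chow value ``lambda_C0`` before any switch; ``lambda_H``
    while on a high-energy diet; and after a switch back to chow at time
    ``ts``, ``lambda_C2 + (lambda_C1 - lambda_C2)*exp(-(t - ts)/tau)``.
    The instantaneous jumps are evaluated exactly as a piecewise function
    rather than through a stiff ODE with impulse forcing.
    """
    last = None
    for ts, kind in s.switches:
        if ts <= t:
            last = (ts, kind)
        else:
            break
    if last is None:
        return s.lambda_C0
    ts, kind = last
    if kind == "high_fat":
        return s.lambda_H
    return s.lambda_C2 + (s.lambda_C1 - s.lambda_C2) * math.exp(-(t - ts) / s.tau)


def resolve_energy_balance(
    state: BodyState,
    EI: float,
    dEI: float,
    lam: float,
    p: ModelParameters,
) -> EnergyRates:
    """Solve the implicit EE/tissue-rate system at one instant.

    With A = alpha(FM) and the mass/forcing part of expenditure
    M = K + gamma_FFM*FFM + gamma_FM*FM + lam*BW + beta*dEI, substituting
    dFFM/dt = A*dFM/dt into both the energy-balance identity and the EE
    model and eliminating EE gives the unique simultaneous solution

        dFM/dt  = (EI - M) / (rho_FM + A*rho_FFM + eta_FM + A*eta_FFM)
        dFFM/dt = A * dFM/dt
        EE      = EI - (rho_FM + A*rho_FFM) * dFM/dt.

    This closed form satisfies the balance identity algebraically; the
    deposition costs eta enter with the sign of the tissue rates, so
    mobilization (negative rates) lowers EE.  DeltaEI may be negative
    (intake below the chow baseline), in which case DIT is negative.
    """
    if not (math.isfinite(EI) and math.isfinite(dEI) and math.isfinite(lam)):
        raise ValueError("EI, dEI, and lam must be finite")
    A = alpha(state.FM, p)
    M = (
        p.K
        + p.gamma_FFM * state.FFM
        + p.gamma_FM * state.FM
        + lam * state.BW
        + p.beta * dEI
    )
    denom = p.rho_FM + A * p.rho_FFM + p.eta_FM + A * p.eta_FFM
    assert denom > 0, "impossible: non-positive denominator with valid parameters"
    dFM_dt = (EI - M) / denom
    dFFM_dt = A * dFM_dt
    EE = EI - (p.rho_FM + A * p.rho_FFM) * dFM_dt
    components = {
        "basal": p.K,
        "ffm_metab": p.gamma_FFM * state.FFM,
        "fm_metab": p.gamma_FM * state.FM,
        "activity": lam * state.BW,
        "dit": p.beta * dEI,
        "deposition": p.eta_FM * dFM_dt + p.eta_FFM * dFFM_dt,
    }
    return EnergyRates(EE=EE, dFM_dt=dFM_dt, dFFM_dt=dFFM_dt, components=components)


def rescale_gamma(gamma_ref: float, m_ref_kg: float, m_target_kg: float) -> float:
    """Quarter-power (Kleiber) rescaling of a specific metabolic rate.

    Basal metabolic rate scales across species as body mass to the 3/4
    power, so the mass-*specific* rate scales as mass to the -1/4.  Given
    a reference rate in kcal/kg/d at reference mass ``m_ref_kg``, returns
    the rate for ``m_target_kg`` converted to kcal/g/d:

        gamma_target = gamma_ref * (m_ref / m_target)**(1/4) / 1000.

    The conventional reference masses for rescaling human coefficients to
    the mouse are 70 kg and 30 g (0.030 kg).
    """
    if not (m_ref_kg > 0 and m_target_kg > 0):
        raise ValueError("masses must be strictly positive")
    return gamma_ref * (m_ref_kg / m_target_kg) ** 0.25 / 1000.0


def ee_mass_coefficients(
    p: ModelParameters,
    lam_values: tuple[float, ...],
) -> tuple[float, float]:
    """Effective EE-vs-mass regression coefficients in cal/g/min.

    In the EE model the coefficient multiplying FFM is gamma_FFM + lambda
    and the one multiplying FM is gamma_FM + lambda (the activity term
    lambda*BW distributes over both compartments).  Averaging lambda over
    the supplied diet-specific values and converting kcal/g/d to cal/g/min
    gives coefficients directly comparable to indirect-calorimetry
    regressions of total EE against FFM and FM.
    """
    lam_bar = sum(lam_values) / len(lam_values)
    to_cal_min = 1000.0 / _MIN_PER_DAY
    return (
        (p.gamma_FFM + lam_bar) * to_cal_min,
        (p.gamma_FM + lam_bar) * to_cal_min,
    )
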