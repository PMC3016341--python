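"""Metabolic fuel selection: net oxidation rates, RQ, and FQ.

Macronutrient balance reasoning reduces to three net oxidation rates once
glycogen is assumed to be in average balance over the day-to-week time
scale (glycogen stores are tiny next to daily carbohydrate intake) and the
de novo lipogenesis / gluconeogenesis inter-conversion fluxes are absorbed
into the "net" definitions:

    NetCarbOx = I_C
    NetProtOx = I_P - rho_FFM * dFFM/dt
    NetFatOx  = EE - NetCarbOx - NetProtOx  (= I_F - rho_FM * dFM/dt)

The protein term uses the proportionality of FFM change to body-protein
change: the energy content of an FFM change is rho_FFM per gram because the
change is protein plus its (energy-free) intracellular water.  The three
net rates close exactly to EE through the energy-balance identity.

The respiratory quotient is the CO2-production to O2-consumption ratio of
the oxidized fuel mix.  Each kcal of a macronutrient consumes a known
volume of O2 and burns at a known stoichiometric RQ, so both RQ and the
food quotient FQ (the RQ the diet would give if combusted directly) are
O2-flux-weighted means of the per-macronutrient quotients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DietSpec, ModelParameters, split_intake
from .simulate import Trajectory

#: Stoichiometric respiratory quotients of the pure macronutrients.
RQ_CARB = 1.00
RQ_FAT = 0.71
RQ_PROT = 0.835

#: Energy equivalents of oxygen, kcal per liter O2 consumed.
KCAL_PER_L_O2_CARB = 5.05
KCAL_PER_L_O2_FAT = 4.69
KCAL_PER_L_O2_PROT = 4.66

#: Window (d) after a diet change in which computed RQ is flagged approximate:
#: the carbohydrate-balance assumption needs a few days to re-establish.
RQ_TRANSITION_WINDOW = 2.0


@dataclass(frozen=True)
class FuelState:
    """Net oxidation rates (kcal/d) and the resulting respiratory quotient."""

    net_fat_ox: float
    net_prot_ox: float
    net_carb_ox: float
    RQ: float


def compute_RQ(net_carb_ox, net_fat_ox, net_prot_ox):
    """Respiratory quotient of an oxidation mix given in kcal/d.

    RQ = sum_i RQ_i * VO2_i / sum_i VO2_i with VO2_i the oxygen volume
    implied by each energy flux.  Net rates may be negative (net synthesis);
    a net lipogenic mix can push RQ above 1.  Raises if the implied total
    oxygen consumption is not positive.
    """
    vo2_c = np.asarray(net_carb_ox, dtype=float) / KCAL_PER_L_O2_CARB
    vo2_f = np.asarray(net_fat_ox, dtype=float) / KCAL_PER_L_O2_FAT
    vo2_p = np.asarray(net_prot_ox, dtype=float) / KCAL_PER_L_O2_PROT
    total = vo2_c + vo2_f + vo2_p
    if np.any(total <= 0):
        raise ValueError("total oxygen consumption must be positive; RQ undefined")
    rq = (RQ_CARB * vo2_c + RQ_FAT * vo2_f + RQ_PROT * vo2_p) / total
    return float(rq) if rq.ndim == 0 else rq


def compute_FQ(diet: DietSpec) -> float:
    """Food quotient of a diet: the RQ of directly combusting the food.

    Identical weighting to :func:`compute_RQ` with the diet's energy
    fractions standing in for the oxidation fluxes.  In energy and
    macronutrient balance RQ equals FQ; deviations signal that the fuel
    mix differs from the diet and that body composition is changing.
    """
    return compute_RQ(diet.frac_carb, diet.frac_fat, diet.frac_protein)


def net_oxidation(
    dFM_dt: float,
    dFFM_dt: float,
    EE: float,
    intakes: tuple[float, float, float],
    p: ModelParameters,
) -> FuelState:
    """Net macronutrient oxidation rates at one trajectory sample.

    ``intakes`` is the (I_P, I_F, I_C) split of current intake in kcal/d.
    Carbohydrate is oxidized at its intake rate (average glycogen balance);
    protein oxidation is intake minus the protein-equivalent energy of the
    FFM change; fat takes up the remainder so the three rates sum to EE.
    """
    I_P, I_F, I_C = intakes
    net_carb = I_C
    net_prot = I_P - p.rho_FFM * dFFM_dt
    net_fat = EE - net_carb - net_prot
    return FuelState(
        net_fat_ox=net_fat,
        net_prot_ox=net_prot,
        net_carb_ox=net_carb,
        RQ=compute_RQ(net_carb, net_fat, net_prot),
    )


def annotate_fuel(traj: Trajectory, intake, p: ModelParameters | None = None) -> Trajectory:
    """Append fuel-selection columns to a simulated trajectory.

    Adds the macronutrient intake streams, the three net oxidation rates,
    RQ, the FQ of the diet currently fed, and ``rq_approx`` — True within
    the first two days after a diet change, where the carbohydrate-balance
    approximation (and hence RQ) is least reliable.
    """
    if p is None:
        p = ModelParameters()
    df = traj.data.copy()
    t = df["t_d"].to_numpy()
    n = len(df)
    cols = {
        name: np.empty(n)
        for name in (
            "I_P_kcal_d", "I_F_kcal_d", "I_C_kcal_d", "net_fat_ox_kcal_d",
            "net_prot_ox_kcal_d", "net_carb_ox_kcal_d", "RQ", "FQ",
        )
    }
    for i in range(n):
        EI = float(intake.EI_at(t[i]))
        diet = intake.diet_at(t[i])
        intakes = split_intake(EI, diet)
        fs = net_oxidation(
            df["dFM_dt_g_d"].iat[i],
            df["dFFM_dt_g_d"].iat[i],
            df["EE_kcal_d"].iat[i],
            intakes,
            p,
        )
        cols["I_P_kcal_d"][i], cols["I_F_kcal_d"][i], cols["I_C_kcal_d"][i] = intakes
        cols["net_fat_ox_kcal_d"][i] = fs.net_fat_ox
        cols["net_prot_ox_kcal_d"][i] = fs.net_prot_ox
        cols["net_carb_ox_kcal_d"][i] = fs.net_carb_ox
        cols["RQ"][i] = fs.RQ
        cols["FQ"][i] = compute_FQ(diet)
    for name, arr in cols.items():
        df[name] = arr
    changes = intake.diet_change_times()
    approx = np.zeros(n, dtype=bool)
    for tc in changes:
        approx |= (t >= tc) & (t < tc + RQ_TRANSITION_WINDOW)
    df["rq_approx"] = approx
    return Trajectory(df)
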