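"""Forward integration of the body-composition ODE pair.

The state is (FM, FFM); its rates come from :func:`resolve_energy_balance`
evaluated with the time-dependent forcings (intake, diet, activity).  The
forcings are piecewise with known breakpoints, so integration proceeds
segment by segment with an adaptive Runge-Kutta solver restarted at every
discontinuity; no event root-finding is needed.

A third auxiliary state accumulates the integral of EI - EE along the
solution.  Comparing it with rho_FM*dFM + rho_FFM*dFFM at the output times
gives a per-sample cumulative energy-conservation residual that measures
solver self-consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import BodyState, ModelParameters
from .expenditure import lambda_at, resolve_energy_balance
from .partition import FM_MAX, FM_MIN
from .schedules import ActivitySchedule, IntakeSchedule

#: Canonical trajectory CSV columns (in order), before fuel annotation.
TRAJECTORY_COLUMNS = [
    "t_d", "FM_g", "FFM_g", "BW_g", "EI_kcal_d", "dEI_kcal_d",
    "lambda_kcal_g_d", "EE_kcal_d", "dFM_dt_g_d", "dFFM_dt_g_d",
    "ee_basal", "ee_ffm_metab", "ee_fm_metab", "ee_activity", "ee_dit",
    "ee_deposition", "energy_residual_kcal",
]


class SimulationError(RuntimeError):
    """Integration failed or the state left the supported domain."""


@dataclass
class Trajectory:
    """A simulated time course stored as a tidy table (one row per output time).

    Columns are named with explicit units (see :data:`TRAJECTORY_COLUMNS`);
    fuel-selection columns are appended by :func:`mousemetab.fuel.annotate_fuel`.
    """

    data: pd.DataFrame

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy()

    @property
    def t(self) -> np.ndarray:
        return self["t_d"]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls(pd.read_csv(path))


def _segment_edges(
    intake: IntakeSchedule, activity: ActivitySchedule, horizon: float
) -> np.ndarray:
    inner = np.concatenate([intake.times, activity.switch_times()])
    inner = inner[(inner > 0) & (inner < horizon)]
    return np.unique(np.concatenate([[0.0, horizon], inner]))


def simulate(
    init: BodyState,
    intake: IntakeSchedule,
    activity: ActivitySchedule,
    p: ModelParameters | None = None,
    horizon: float = 140.0,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the FM/FFM dynamics over ``[0, horizon]`` days.

    Parameters
    ----------
    init
        Initial body composition; conventionally measured BW and FM at t=0
        with FFM = BW - FM.
    intake, activity
        Forcing schedules; they must cover the whole horizon.
    p
        Model constants (defaults to the published C57BL/6 set).
    horizon, dt_out
        Simulation length and output sampling step, both in days.
    rtol, atol
        Adaptive RK45 tolerances.

    Returns a :class:`Trajectory` sampled on the ``dt_out`` grid, annotated
    at every sample with EE, the activity coefficient, the tissue rates,
    the six EE components, and the cumulative energy-conservation residual.
    Raises :class:`SimulationError`, naming the failure time, if the fat
    mass leaves the empirical partition-function domain.
    """
    if p is None:
        p = ModelParameters()
    if not horizon > 0:
        raise ValueError("horizon must be positive")

    def rhs(t, y):
        # inline, domain-unchecked evaluation: RK trial stages may probe
        # slightly outside the trusted FM range; the terminal events below
        # stop the integration at the boundary crossing itself
        FM, FFM = y[0], y[1]
        EI = float(intake.EI_at(t))
        dEI = EI - intake.baseline_EI
        lam = lambda_at(t, activity)
        A = p.alpha_c + p.alpha_d * np.exp(p.alpha_k * FM)
        M = (p.K + p.gamma_FFM * FFM + p.gamma_FM * FM
             + lam * (FM + FFM) + p.beta * dEI)
        dFM = (EI - M) / (p.rho_FM + A * p.rho_FFM + p.eta_FM + A * p.eta_FFM)
        EE = EI - (p.rho_FM + A * p.rho_FFM) * dFM
        return (dFM, A * dFM, EI - EE)

    def low(t, y):
        return y[0] - FM_MIN

    def high(t, y):
        return FM_MAX - y[0]

    def ffm_pos(t, y):
        return y[1]

    for ev in (low, high, ffm_pos):
        ev.terminal = True

    edges = _segment_edges(intake, activity, horizon)
    t_out = np.unique(np.concatenate([np.arange(0.0, horizon, dt_out), [horizon]]))
    y0 = np.array([init.FM, init.FFM, 0.0])
    FM = np.empty_like(t_out)
    FFM = np.empty_like(t_out)
    cum = np.empty_like(t_out)

    for a, b in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(
            rhs, (a, b), y0, method="RK45", rtol=rtol, atol=atol,
            dense_output=True, events=[low, high, ffm_pos],
        )
        if sol.status == 1:
            t_fail = min(te[0] for te in sol.t_events if len(te))
            raise SimulationError(
                f"body composition left the supported domain at t={t_fail:.3f} d "
                f"(FM must stay in [{FM_MIN}, {FM_MAX}] g and FFM positive)"
            )
        if not sol.success:
            raise SimulationError(f"integration failed on [{a}, {b}]: {sol.message}")
        # sample output times inside [a, b); the final edge owns b itself
        mask = (t_out >= a) & ((t_out < b) | (b == edges[-1]) & (t_out <= b))
        if mask.any():
            vals = sol.sol(t_out[mask])
            FM[mask], FFM[mask], cum[mask] = vals[0], vals[1], vals[2]
        y0 = sol.y[:, -1]

    rows = {c: np.empty_like(t_out) for c in TRAJECTORY_COLUMNS}
    for i, t in enumerate(t_out):
        state = BodyState(FM[i], FFM[i])
        EI = float(intake.EI_at(t))
        dEI = EI - intake.baseline_EI
        lam = lambda_at(t, activity)
        r = resolve_energy_balance(state, EI, dEI, lam, p)
        c = r.components
        residual = (
            p.rho_FM * (FM[i] - init.FM) + p.rho_FFM * (FFM[i] - init.FFM) - cum[i]
        )
        for col, v in zip(
            TRAJECTORY_COLUMNS,
            (
                t, FM[i], FFM[i], state.BW, EI, dEI, lam, r.EE,
                r.dFM_dt, r.dFFM_dt, c["basal"], c["ffm_metab"], c["fm_metab"],
                c["activity"], c["dit"], c["deposition"], residual,
            ),
        ):
            rows[col][i] = v
    return Trajectory(pd.DataFrame(rows))


def maintenance_EI(state: BodyState, lam: float, p: ModelParameters | None = None) -> float:
    """Intake rate (kcal/d) that holds ``state`` exactly steady at dEI = 0.

    At maintenance the tissue rates vanish, so EI equals the mass/forcing
    part of expenditure: K + gamma_FFM*FFM + gamma_FM*FM + lam*BW.
    """
    if p is None:
        p = ModelParameters()
    return (
        p.K + p.gamma_FFM * state.FFM + p.gamma_FM * state.FM + lam * state.BW
    )
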