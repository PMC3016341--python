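"""Time-dependent forcings: intake schedules and activity (diet-switch) schedules.

Both schedules are right-continuous piecewise descriptions of the protocol a
group of mice experienced.  The intake schedule carries the measured (or
synthetic) metabolizable energy intake per interval together with the diet
fed on that interval; the activity schedule carries the diet-switch event
times that drive the physical-activity coefficient lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CHOW, HIGH_FAT, DietSpec, split_intake

#: Default diet lookup for intake CSVs.
DEFAULT_DIETS = {"chow": CHOW, "high_fat": HIGH_FAT}

#: Event kinds understood by :class:`ActivitySchedule`.
SWITCH_KINDS = ("high_fat", "chow")


class ScheduleError(ValueError):
    """A schedule's breakpoints or events are inconsistent."""


@dataclass
class IntakeSchedule:
    """Piecewise metabolizable energy-intake series with diet per interval.

    ``times[i]`` is the start (d) of interval *i*; the interval extends to
    ``times[i+1]`` (the last interval is open-ended).  ``EI[i]`` is the
    intake rate (kcal/d) on interval *i* and ``diets[i]`` the diet fed.
    By default the intake is piecewise constant; with ``smooth=True`` a
    monotone cubic (PCHIP) interpolant through ``(times, EI)`` is used
    instead, held constant beyond the last breakpoint.

    ``baseline_EI`` is the reference chow intake used to form the intake
    change Delta-EI that drives diet-induced thermogenesis.  If omitted it
    defaults to the mean intake over the leading run of intervals sharing
    the first interval's diet; groups whose records start on a non-chow
    diet should supply it explicitly.
    """

    times: np.ndarray
    EI: np.ndarray
    diets: tuple[DietSpec, ...]
    baseline_EI: float | None = None
    smooth: bool = False
    _interp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.EI = np.asarray(self.EI, dtype=float)
        self.diets = tuple(self.diets)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ScheduleError("times must be a non-empty 1-d array")
        if np.any(np.diff(self.times) <= 0):
            raise ScheduleError("breakpoint times must be strictly increasing")
        if len(self.EI) != len(self.times) or len(self.diets) != len(self.times):
            raise ScheduleError("times, EI, and diets must have equal length")
        if np.any(self.EI < 0):
            raise ScheduleError("EI must be non-negative everywhere")
        if self.baseline_EI is None:
            first = self.diets[0].name
            lead = [e for e, d in zip(self.EI, self.diets) if d.name == first]
            n = next(
                (i for i, d in enumerate(self.diets) if d.name != first),
                len(self.diets),
            )
            self.baseline_EI = float(np.mean(self.EI[:n]))
        if self.smooth:
            from scipy.interpolate import PchipInterpolator

            if len(self.times) >= 2:
                self._interp = PchipInterpolator(self.times, self.EI)

    # -- lookups ---------------------------------------------------------

    def index_at(self, t: float) -> int:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return max(i, 0)

    def EI_at(self, t):
        """Intake rate (kcal/d) at time ``t`` (right-continuous)."""
        if self._interp is not None:
            t_clip = np.clip(t, self.times[0], self.times[-1])
            return np.maximum(self._interp(t_clip), 0.0)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.EI) - 1)
        return self.EI[idx]

    def diet_at(self, t: float) -> DietSpec:
        return self.diets[self.index_at(t)]

    def intakes_at(self, t: float) -> tuple[float, float, float]:
        """Macronutrient streams (I_P, I_F, I_C) in kcal/d at time ``t``."""
        return split_intake(float(self.EI_at(t)), self.diet_at(t))

    def delta_EI_at(self, t):
        """Intake change relative to the chow baseline (kcal/d); may be < 0."""
        return self.EI_at(t) - self.baseline_EI

    def diet_change_times(self) -> np.ndarray:
        """Times at which the fed diet changes between consecutive intervals."""
        out = [
            self.times[i]
            for i in range(1, len(self.diets))
            if self.diets[i].name != self.diets[i - 1].name
        ]
        return np.asarray(out, dtype=float)

    # -- i/o -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "EI_kcal_d": self.EI,
                "diet_name": [d.name for d in self.diets],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        diets: dict[str, DietSpec] | None = None,
        baseline_EI: float | None = None,
        smooth: bool = False,
    ) -> "IntakeSchedule":
        """Read an intake series from a CSV with columns
        ``time_d, EI_kcal_d, diet_name``; diet definitions come from
        ``diets`` (defaults provide ``chow`` and ``high_fat``)."""
        if diets is None:
            diets = DEFAULT_DIETS
        df = pd.read_csv(path)
        missing = {"time_d", "EI_kcal_d", "diet_name"} - set(df.columns)
        if missing:
            raise ScheduleError(f"intake CSV missing columns {sorted(missing)}")
        try:
            diet_seq = tuple(diets[name] for name in df["diet_name"])
        except KeyError as e:
            raise ScheduleError(f"unknown diet name {e.args[0]!r}") from None
        return cls(
            df["time_d"].to_numpy(),
            df["EI_kcal_d"].to_numpy(),
            diet_seq,
            baseline_EI=baseline_EI,
            smooth=smooth,
        )


@dataclass(frozen=True)
class ActivitySchedule:
    """Diet-switch events and the physical-activity coefficients they select.

    The mouse starts on chow with activity coefficient ``lambda_C0``
    (kcal per g body weight per day).  Each switch to a high-fat (or other
    high-energy) diet drops the coefficient instantly to ``lambda_H``;
    each switch back to chow raises it instantly to ``lambda_C1``, after
    which it relaxes exponentially to ``lambda_C2`` with time constant
    ``tau``.  ``switches`` is an ordered tuple of ``(time_d, kind)`` events
    with ``kind`` in ``{"high_fat", "chow"}``; the two-switch protocol of a
    single high-fat episode is built with :meth:`two_switch`.
    """

    lambda_C0: float = 0.22
    lambda_C1: float = 0.27
    lambda_C2: float = 0.19
    lambda_H: float = 0.13
    tau: float = 14.0
    switches: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        for lam in (self.lambda_C0, self.lambda_C1, self.lambda_C2, self.lambda_H):
            if lam < 0:
                raise ScheduleError(f"activity coefficients must be >= 0, got {lam!r}")
        if not (self.tau > 0):
            raise ScheduleError(f"tau must be strictly positive, got {self.tau!r}")
        sw = tuple((float(t), str(kind)) for t, kind in self.switches)
        object.__setattr__(self, "switches", sw)
        prev_t, prev_kind = -np.inf, "chow"
        for t, kind in sw:
            if kind not in SWITCH_KINDS:
                raise ScheduleError(f"unknown switch kind {kind!r}")
            if t <= prev_t:
                raise ScheduleError("switch times must be strictly increasing")
            if kind == prev_kind:
                raise ScheduleError(
                    f"switch to {kind!r} at t={t} while already on that diet"
                )
            prev_t, prev_kind = t, kind

    @classmethod
    def two_switch(cls, t_switch1: float, t_switch2: float, **kw) -> "ActivitySchedule":
        """Chow -> high-fat at ``t_switch1``, back to chow at ``t_switch2``."""
        if t_switch2 <= t_switch1:
            raise ScheduleError(
                f"t_switch2 ({t_switch2!r}) must exceed t_switch1 ({t_switch1!r})"
            )
        return cls(switches=((t_switch1, "high_fat"), (t_switch2, "chow")), **kw)

    def switch_times(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.switches], dtype=float)
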