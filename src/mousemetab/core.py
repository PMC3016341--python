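"""Core types of the mouse energy-balance model.

The model tracks a mouse's body as two compartments, fat mass (FM) and
fat-free mass (FFM), whose changes are driven by the gap between
metabolizable energy intake (EI) and total energy expenditure (EE).  All
quantities are kept in a fixed internal unit system: grams, days, and
kilocalories.  Inputs in other units are rejected rather than converted.

:class:`ModelParameters` collects every fixed model constant; the defaults
are the published parameter set for adult male C57BL/6 mice housed
individually at 22 degC.  :class:`DietSpec` describes a diet by its
macronutrient energy fractions and is the source of both the food quotient
and the splitting of total intake into protein/fat/carbohydrate streams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace


class UnitError(ValueError):
    """A parameter value is outside its physically meaningful range."""


class DietError(ValueError):
    """A diet composition is not a valid set of energy fractions."""


@dataclass(frozen=True)
class DietSpec:
    """Macronutrient energy fractions of a diet.

    Fractions are dimensionless shares of metabolizable energy and must be
    non-negative and sum to 1 (tolerance 1e-6).
    """

    name: str
    frac_protein: float
    frac_fat: float
    frac_carb: float

    def __post_init__(self) -> None:
        fracs = (self.frac_protein, self.frac_fat, self.frac_carb)
        if any(f < 0 for f in fracs):
            raise DietError(f"diet {self.name!r}: negative energy fraction {fracs}")
        total = sum(fracs)
        if abs(total - 1.0) > 1e-6:
            raise DietError(
                f"diet {self.name!r}: energy fractions sum to {total!r}, not 1"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DietSpec":
        return cls(**d)


#: Standard chow: 24% protein, 12% fat, 64% carbohydrate by energy.
CHOW = DietSpec("chow", 0.24, 0.12, 0.64)
#: High-fat diet: 14% protein, 59% fat, 27% carbohydrate by energy.
HIGH_FAT = DietSpec("high_fat", 0.14, 0.59, 0.27)


@dataclass(frozen=True)
class ModelParameters:
    """Fixed constants of the energy-balance model (g / d / kcal units).

    Attributes
    ----------
    rho_FM, rho_FFM
        Energy densities of fat-mass and fat-free-mass *changes* (kcal/g).
        rho_FFM is much smaller than the energy density of pure protein
        because FFM change is mostly protein plus its associated
        intracellular water.
    gamma_FM, gamma_FFM
        Mass-specific metabolic rates of the two compartments (kcal/g/d),
        obtained by quarter-power (Kleiber) rescaling of human values.
    eta_FM, eta_FFM
        Biochemical deposition costs of fat and protein synthesis (kcal/g),
        applied with the sign of the tissue rate.
    beta
        Diet-induced thermogenesis fraction: the DIT component of EE is
        beta times the intake change relative to the chow baseline.
    K
        Basal (diet- and mass-independent) thermogenesis rate (kcal/d) for
        a fixed 22 degC environment.
    alpha_c, alpha_d, alpha_k
        Shape constants of the empirical FM/FFM partition function
        alpha(FM) = alpha_c + alpha_d * exp(alpha_k * FM); alpha_k in 1/g.
    tau
        Relaxation time constant (d) of the physical-activity coefficient
        after a switch back to chow.
    """

    rho_FM: float = 9.4
    rho_FFM: float = 1.8
    gamma_FM: float = 0.03
    gamma_FFM: float = 0.15
    eta_FM: float = 0.18
    eta_FFM: float = 0.23
    beta: float = 0.4
    K: float = 2.1
    alpha_c: float = 0.1
    alpha_d: float = 1.89e-4
    alpha_k: float = 0.45
    tau: float = 14.0

    def __post_init__(self) -> None:
        validate_parameters(self)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelParameters":
        return cls.from_dict(json.loads(s))

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


def validate_parameters(p: ModelParameters) -> ModelParameters:
    """Check all parameter invariants; return ``p`` or raise :class:`UnitError`.

    Energy densities, specific metabolic rates, deposition costs, basal
    thermogenesis, and the relaxation time must be strictly positive;
    the DIT fraction must satisfy 0 <= beta < 1; the partition-function
    constants must be non-negative (alpha must be non-negative on its
    whole domain).
    """
    strictly_positive = (
        "rho_FM", "rho_FFM", "gamma_FM", "gamma_FFM",
        "eta_FM", "eta_FFM", "K", "tau",
    )
    for name in strictly_positive:
        v = getattr(p, name)
        if not (v > 0):
            raise UnitError(f"{name} must be strictly positive, got {v!r}")
    if not (0 <= p.beta < 1):
        raise UnitError(f"beta must lie in [0, 1), got {p.beta!r}")
    for name in ("alpha_c", "alpha_d", "alpha_k"):
        v = getattr(p, name)
        if v < 0:
            raise UnitError(f"{name} must be non-negative, got {v!r}")
    return p


def split_intake(EI: float, diet: DietSpec) -> tuple[float, float, float]:
    """Split total metabolizable intake into (I_P, I_F, I_C) in kcal/d.

    Each macronutrient stream is the total intake times that nutrient's
    energy fraction, so the three components sum exactly to ``EI``.
    """
    if EI < 0:
        raise ValueError(f"energy intake must be non-negative, got {EI!r}")
    return EI * diet.frac_protein, EI * diet.frac_fat, EI * diet.frac_carb


@dataclass
class BodyState:
    """Body composition state: fat mass and fat-free mass in grams."""

    FM: float
    FFM: float

    def __post_init__(self) -> None:
        if not (self.FM > 0 and self.FFM > 0):
            raise ValueError(
                f"FM and FFM must be strictly positive, got FM={self.FM!r}, "
                f"FFM={self.FFM!r}"
            )

    @property
    def BW(self) -> float:
        """Body weight, the sum of the two compartments (g)."""
        return self.FM + self.FFM
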