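"""Temperature-dependent constants and Hougen-Watson rate laws for the
selective hydrogenation of C18 fatty acids.

The reacting mixture is lumped into four classes by number of double bonds:
C18:3 (A, linolenic), C18:2 (B, linoleic), C18:1 (C, oleic) and C18:0
(D, stearic).  Hydrogenation proceeds as the irreversible cascade

    A --(+H2)--> B --(+H2)--> C --(+H2)--> D

over a Lindlar (supported-Pd) catalyst.  Six alternative surface mechanisms
are implemented, each yielding a closed-form Hougen-Watson rate law for the
four lumped species.  The mechanisms differ in whether H2 adsorbs on the
catalyst at all (Langmuir-Hinshelwood vs Eley-Rideal), whether its
adsorption is molecular or dissociative, whether it competes with the fatty
acids for sites, and whether semihydrogenated surface intermediates form:

======== =============================================================
scheme   hypotheses
======== =============================================================
``a``    dissociative H2 on dedicated sites (non-competitive),
         semihydrogenated intermediates (Horiuti-Polanyi type)
``b``    dissociative H2, competitive adsorption, intermediates
``c``    Eley-Rideal: H2 reacts from solution with adsorbed fatty acids
``d``    molecular H2 on dedicated sites (non-competitive),
         no intermediates (pairwise H addition)
``e``    molecular H2, competitive adsorption, no intermediates
``f``    molecular H2, both competitive and non-competitive channels
======== =============================================================

Surface reaction steps carry Arrhenius rate constants ``k_n``;
adsorption/desorption quasi-equilibria carry van't Hoff equilibrium
constants ``K_m``.  Both are centred at a reference temperature ``Tmean``
(the average temperature of the experimental campaign) so that the
pre-exponential equals the constant's value at ``Tmean``:

    k_n = A_n  exp(-Ea_n /R (1/T - 1/Tmean))
    K_m = B_m  exp(-dH_m /R (1/T - 1/Tmean))
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "T_MEAN_DEFAULT",
    "COMPONENTS",
    "ConstantKind",
    "TemperatureDependentConstant",
    "OperatingConditions",
    "Composition",
    "RateVector",
    "MechanismSpec",
    "ParameterVector",
    "MECHANISMS",
    "evaluate_rate_constant",
    "evaluate_equilibrium_constant",
    "evaluate_constants",
    "evaluate_rates",
    "parameter_dimension",
]

#: ideal-gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: default reference temperature [K]: arithmetic mean of the nominal test
#: temperatures of the batch campaign (120, 180, 180 degC -> 160 degC).
T_MEAN_DEFAULT = 433.15

#: component order used everywhere: C18:3, C18:2, C18:1, C18:0
COMPONENTS = ("A", "B", "C", "D")

#: negative mole fractions above this magnitude are a contract violation;
#: smaller ones (ODE round-off) are clamped to zero.
NEGATIVE_TOL = 1e-9

_SUM_TOL = 1e-6


class ConstantKind(str, enum.Enum):
    RATE = "rate"
    EQUILIBRIUM = "equilibrium"


@dataclass(frozen=True)
class TemperatureDependentConstant:
    """One Arrhenius (``A``, ``Ea``) or van't Hoff (``B``, ``dH``) pair.

    ``preexponential`` is the value of the constant at the reference
    temperature; ``energy`` is the activation energy (rate) or the
    adsorption/desorption enthalpy (equilibrium), in kJ/mol.
    """

    label: str
    kind: ConstantKind
    preexponential: float
    energy: float

    def __post_init__(self) -> None:
        if not self.preexponential > 0:
            raise ValueError(
                f"{self.label}: preexponential must be > 0, got "
                f"{self.preexponential!r}"
            )
        if self.kind is ConstantKind.RATE and self.energy < 0:
            raise ValueError(
                f"{self.label}: activation energy must be >= 0, got "
                f"{self.energy!r}"
            )

    def value_at(self, temperature: float, t_mean: float = T_MEAN_DEFAULT) -> float:
        """Evaluate the constant at ``temperature`` [K]."""
        return self.preexponential * math.exp(
            -self.energy * 1e3 / R_GAS * (1.0 / temperature - 1.0 / t_mean)
        )


@dataclass(frozen=True)
class OperatingConditions:
    """Isothermal, isobaric conditions of one batch test.

    ``p_h2`` is the hydrogen partial pressure in bar, held constant by
    continuous insufflation at regulated pressure.
    """

    temperature: float  # K
    p_h2: float  # bar
    t_mean: float = T_MEAN_DEFAULT  # K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        if not self.t_mean > 0:
            raise ValueError("t_mean must be > 0 K")
        if self.p_h2 < 0:
            raise ValueError("p_h2 must be >= 0 bar")


def evaluate_rate_constant(
    c: TemperatureDependentConstant, cond: OperatingConditions
) -> float:
    """Arrhenius rate constant at the test temperature, centred at Tmean."""
    if c.kind is not ConstantKind.RATE:
        raise ValueError(f"{c.label} is not a rate constant")
    return c.value_at(cond.temperature, cond.t_mean)


def evaluate_equilibrium_constant(
    c: TemperatureDependentConstant, cond: OperatingConditions
) -> float:
    """van't Hoff adsorption/desorption equilibrium constant at T."""
    if c.kind is not ConstantKind.EQUILIBRIUM:
        raise ValueError(f"{c.label} is not an equilibrium constant")
    return c.value_at(cond.temperature, cond.t_mean)


@dataclass(frozen=True)
class Composition:
    """Relative molar fractions of the four C18 lumps (must sum to 1)."""

    x_a: float
    x_b: float
    x_c: float
    x_d: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -NEGATIVE_TOL) or np.any(arr > 1 + NEGATIVE_TOL):
            raise ValueError(f"molar fractions out of [0, 1]: {arr}")
        if abs(float(arr.sum()) - 1.0) > _SUM_TOL:
            raise ValueError(f"molar fractions must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_a, self.x_b, self.x_c, self.x_d], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "Composition":
        a = np.asarray(arr, dtype=float)
        if a.shape != (4,):
            raise ValueError("composition array must have shape (4,)")
        return cls(*a.tolist())


@dataclass(frozen=True)
class RateVector:
    """Net formation rates of A..D in mole-fraction per minute."""

    r_a: float
    r_b: float
    r_c: float
    r_d: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r_a, self.r_b, self.r_c, self.r_d], dtype=float)


# ---------------------------------------------------------------------------
# Rate-law dispatch
#
# Each factory takes the evaluated constants (a plain dict label -> value at
# the test temperature) and the H2 pressure [bar] and returns a fast closure
# x(4,) -> r(4,).  All laws share the cascade structure r = (-t1, t1-t2,
# t2-t3, t3), which conserves the total mole count to machine precision.
# ---------------------------------------------------------------------------


def _cascade(t1: float, t2: float, t3: float) -> np.ndarray:
    return np.array([-t1, t1 - t2, t2 - t3, t3])


def _rates_a(c: Mapping[str, float], ph2: float) -> Callable[[np.ndarray], np.ndarray]:
    # dissociative H2 on dedicated sites; semihydrogenated intermediates.
    k4, k5, k6, k7, k8, k9 = (c[k] for k in ("k4", "k5", "k6", "k7", "k8", "k9"))
    K1, K2, K3, K10 = (c[k] for k in ("K1", "K2", "K3", "K10"))
    sa = K2 * (k5 + k4) / k5
    sb = K3 * (k7 + k6) / k7
    sc = (k9 + k8) / (K10 * k9)
    h2 = K1 * ph2

    def rates(x: np.ndarray) -> np.ndarray:
        den = (1.0 + sa * x[0] + sb * x[1] + sc * x[2]) * (1.0 + h2)
        f = h2 / den
        return _cascade(
            k4 * K2 * x[0] * f, k6 * K3 * x[1] * f, k8 / K10 * x[2] * f
        )

    return rates


def _rates_b(c: Mapping[str, float], ph2: float) -> Callable[[np.ndarray], np.ndarray]:
    # dissociative H2 competing with the fatty acids for the same sites.
    k4, k5, k6, k7, k8, k9 = (c[k] for k in ("k4", "k5", "k6", "k7", "k8", "k9"))
    K1, K2, K3, K10 = (c[k] for k in ("K1", "K2", "K3", "K10"))
    sa = K2 * (k5 + k4) / k5
    sb = K3 * (k7 + k6) / k7
    sc = (k9 + k8) / (K10 * k9)
    h2 = K1 * ph2

    def rates(x: np.ndarray) -> np.ndarray:
        den = (1.0 + sa * x[0] + sb * x[1] + sc * x[2] + h2) ** 2
        f = h2 / den
        return _cascade(
            k4 * K2 * x[0] * f, k6 * K3 * x[1] * f, k8 / K10 * x[2] * f
        )

    return rates


def _rates_c(c: Mapping[str, float], ph2: float) -> Callable[[np.ndarray], np.ndarray]:
    # Eley-Rideal: molecular H2 reacts from the liquid with adsorbed species;
    # hydrogenated surface intermediates relax by first-order surface steps.
    k3, k4, k5, k6, k7, k8 = (c[k] for k in ("k3", "k4", "k5", "k6", "k7", "k8"))
    K1, K2, K9 = c["K1"], c["K2"], c["K9"]
    sa = K1 * (k3 * ph2 + k4) / k4
    sb = K2 * (k5 * ph2 + k6) / k6
    sc = (k7 * ph2 + k8) / (K9 * k8)

    def rates(x: np.ndarray) -> np.ndarray:
        den = 1.0 + sa * x[0] + sb * x[1] + sc * x[2]
        f = ph2 / den
        return _cascade(
            k3 * K1 * x[0] * f, k5 * K2 * x[1] * f, k7 / K9 * x[2] * f
        )

    return rates


def _rates_d(c: Mapping[str, float], ph2: float) -> Callable[[np.ndarray], np.ndarray]:
    # molecular H2 on dedicated sites (pairwise addition), no intermediates.
    k4, k5, k6 = c["k4"], c["k5"], c["k6"]
    K1, K2, K3, K7 = c["K1"], c["K2"], c["K3"], c["K7"]
    h2 = K1 * ph2

    def rates(x: np.ndarray) -> np.ndarray:
        den = (1.0 + K2 * x[0] + K3 * x[1] + x[2] / K7) * (1.0 + h2)
        f = h2 / den
        return _cascade(
            k4 * K2 * x[0] * f, k5 * K3 * x[1] * f, k6 / K7 * x[2] * f
        )

    return rates


def _rates_e(c: Mapping[str, float], ph2: float) -> Callable[[np.ndarray], np.ndarray]:
    # molecular H2 competing with the fatty acids for the same sites.
    k4, k5, k6 = c["k4"], c["k5"], c["k6"]
    K1, K2, K3, K7 = c["K1"], c["K2"], c["K3"], c["K7"]
    h2 = K1 * ph2

    def rates(x: np.ndarray) -> np.ndarray:
        den = (1.0 + K2 * x[0] + K3 * x[1] + x[2] / K7 + h2) ** 2
        f = h2 / den
        return _cascade(
            k4 * K2 * x[0] * f, k5 * K3 * x[1] * f, k6 / K7 * x[2] * f
        )

    return rates


def _rates_f(c: Mapping[str, float], ph2: float) -> Callable[[np.ndarray], np.ndarray]:
    # molecular H2 through two parallel channels: a non-competitive one
    # (sites Z', constant K1) and a competitive one (sites Z, constant K2).
    k5, k6, k7, k8, k9, k10 = (
        c[k] for k in ("k5", "k6", "k7", "k8", "k9", "k10")
    )
    K1, K2, K3, K4, K11 = c["K1"], c["K2"], c["K3"], c["K4"], c["K11"]
    h2nc = K1 * ph2
    h2c = K2 * ph2

    def rates(x: np.ndarray) -> np.ndarray:
        s = 1.0 + K3 * x[0] + K4 * x[1] + x[2] / K11 + h2c
        f1 = h2nc / (s * (1.0 + h2nc))
        f2 = h2c / (s * s)
        r1 = _cascade(
            k5 * K3 * x[0] * f1, k7 * K4 * x[1] * f1, k9 / K11 * x[2] * f1
        )
        r2 = _cascade(
            k6 * K3 * x[0] * f2, k8 * K4 * x[1] * f2, k10 / K11 * x[2] * f2
        )
        return r1 + r2

    return rates


@dataclass(frozen=True)
class MechanismSpec:
    """Identity of one surface mechanism and its rate-law dispatch."""

    mechanism_id: str
    constant_labels: tuple[str, ...]
    description: str
    rate_factory: Callable[
        [Mapping[str, float], float], Callable[[np.ndarray], np.ndarray]
    ] = field(repr=False, compare=False)

    @property
    def n_constants(self) -> int:
        return len(self.constant_labels)


MECHANISMS: dict[str, MechanismSpec] = {
    "a": MechanismSpec(
        "a",
        ("k4", "k5", "k6", "k7", "k8", "k9", "K1", "K2", "K3", "K10"),
        "dissociative H2 on dedicated sites (non-competitive), "
        "semihydrogenated intermediates",
        _rates_a,
    ),
    "b": MechanismSpec(
        "b",
        ("k4", "k5", "k6", "k7", "k8", "k9", "K1", "K2", "K3", "K10"),
        "dissociative H2, competitive adsorption, semihydrogenated "
        "intermediates",
        _rates_b,
    ),
    "c": MechanismSpec(
        "c",
        ("k3", "k4", "k5", "k6", "k7", "k8", "K1", "K2", "K9"),
        "Eley-Rideal H2 (not adsorbed), surface intermediates",
        _rates_c,
    ),
    "d": MechanismSpec(
        "d",
        ("k4", "k5", "k6", "K1", "K2", "K3", "K7"),
        "molecular H2 on dedicated sites (non-competitive), no intermediates",
        _rates_d,
    ),
    "e": MechanismSpec(
        "e",
        ("k4", "k5", "k6", "K1", "K2", "K3", "K7"),
        "molecular H2, competitive adsorption, no intermediates",
        _rates_e,
    ),
    "f": MechanismSpec(
        "f",
        ("k5", "k6", "k7", "k8", "k9", "k10", "K1", "K2", "K3", "K4", "K11"),
        "molecular H2, competitive and non-competitive channels, "
        "no intermediates",
        _rates_f,
    ),
}


def get_mechanism(mechanism_id: str | MechanismSpec) -> MechanismSpec:
    if isinstance(mechanism_id, MechanismSpec):
        return mechanism_id
    try:
        return MECHANISMS[mechanism_id]
    except KeyError:
        raise KeyError(
            f"unknown mechanism {mechanism_id!r}; expected one of "
            f"{sorted(MECHANISMS)}"
        ) from None


def parameter_dimension(mech: str | MechanismSpec) -> int:
    """Number of regressed parameters: one (pre-exponential, energy) pair per
    constant in the printed rate law.

    Structural counts: a -> 20, b -> 20, c -> 18, d -> 14, e -> 14, f -> 22.
    (Counts for c and e follow the printed rate-law structures; see
    docs/methods.md for a note on a transposed literature tabulation.)
    """
    return 2 * get_mechanism(mech).n_constants


def _constant_kind(label: str) -> ConstantKind:
    return ConstantKind.RATE if label.startswith("k") else ConstantKind.EQUILIBRIUM


@dataclass(frozen=True)
class ParameterVector:
    """Ordered (pre-exponential, energy) pairs matching a mechanism's
    constant labels.  Energies in kJ/mol; pre-exponentials in the natural
    units of each constant."""

    mechanism_id: str
    values: np.ndarray  # shape (2 n,), pairs (preexponential, energy)

    def __post_init__(self) -> None:
        mech = get_mechanism(self.mechanism_id)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (2 * mech.n_constants,):
            raise ValueError(
                f"mechanism {mech.mechanism_id!r} needs "
                f"{2 * mech.n_constants} parameters, got {vals.shape}"
            )
        # delegate per-constant validation (positivity, Ea >= 0)
        self.constants()

    @classmethod
    def from_dict(
        cls, mechanism_id: str, entries: Mapping[str, tuple[float, float]]
    ) -> "ParameterVector":
        """Build from ``{label: (preexponential, energy)}``."""
        mech = get_mechanism(mechanism_id)
        missing = set(mech.constant_labels) - set(entries)
        extra = set(entries) - set(mech.constant_labels)
        if missing or extra:
            raise ValueError(
                f"parameter labels do not match mechanism "
                f"{mechanism_id!r}: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        vals = np.array(
            [v for lab in mech.constant_labels for v in entries[lab]], dtype=float
        )
        return cls(mechanism_id, vals)

    def to_dict(self) -> dict[str, tuple[float, float]]:
        mech = get_mechanism(self.mechanism_id)
        return {
            lab: (float(self.values[2 * i]), float(self.values[2 * i + 1]))
            for i, lab in enumerate(mech.constant_labels)
        }

    def constants(self) -> list[TemperatureDependentConstant]:
        mech = get_mechanism(self.mechanism_id)
        return [
            TemperatureDependentConstant(
                lab,
                _constant_kind(lab),
                float(self.values[2 * i]),
                float(self.values[2 * i + 1]),
            )
            for i, lab in enumerate(mech.constant_labels)
        ]


def evaluate_constants(
    params: ParameterVector, cond: OperatingConditions
) -> dict[str, float]:
    """All constants of the mechanism evaluated at the test temperature."""
    return {
        c.label: c.value_at(cond.temperature, cond.t_mean)
        for c in params.constants()
    }


def _clamp_fractions(x: np.ndarray) -> np.ndarray:
    """Clamp round-off-negative fractions to zero; reject real violations."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -NEGATIVE_TOL):
        raise ValueError(f"negative molar fraction beyond tolerance: {x}")
    return np.where(x < 0.0, 0.0, x)


def evaluate_rates(
    mech: str | MechanismSpec,
    params: ParameterVector,
    x: Composition | Sequence[float],
    cond: OperatingConditions,
) -> RateVector:
    """Net formation rates for one state under one mechanism.

    All denominators are >= 1 for non-negative fractions and positive
    constants, so the rates are always finite; the cascade structure makes
    r_a + r_b + r_c + r_d vanish to machine precision.
    """
    mech = get_mechanism(mech)
    if params.mechanism_id != mech.mechanism_id:
        raise ValueError(
            f"parameter vector is for mechanism {params.mechanism_id!r}, "
            f"not {mech.mechanism_id!r}"
        )
    arr = x.as_array() if isinstance(x, Composition) else np.asarray(x, dtype=float)
    arr = _clamp_fractions(arr)
    if abs(float(arr.sum()) - 1.0) > _SUM_TOL:
        raise ValueError(f"molar fractions must sum to 1, got {arr.sum()!r}")
    c = evaluate_constants(params, cond)
    r = mech.rate_factory(c, cond.p_h2)(arr)
    return RateVector(*r.tolist())
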