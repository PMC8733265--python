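"""Mass-action equilibrium solvers for 1:1 and competitive protein binding.

All concentrations are in μmol/l internally (see :mod:`mstbind.units` for
boundary conversions).  Two reaction schemes are covered:

* a single labeled receptor R binding one titrant L (``R + L <-> RL``),
  solved exactly with the ligand-depletion quadratic, and
* two mutually exclusive ligands A and B competing for one site on R
  (``R + A <-> RA``, ``R + B <-> RB``), solved by monotone root bracketing
  on the free-receptor concentration.

The quadratic's "−" branch is always the physical root; it is asserted to
lie in ``[0, min(R_t, L_t)]`` rather than selected by inspection.  The
competition system is deliberately *not* solved through its closed-form
cubic — bracketing on free R is numerically robust for the extreme
concentration ratios that arise in titration ladders; the cubic serves as
an independent oracle in the test suite only.

Interactions for which no complex forms (the affinity table's "cnd" cells
and the tail-vs-tail negative control) are represented by the explicit
:data:`NON_BINDER` sentinel, never by an infinite Kd encoded as a float.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NON_BINDER",
    "NonBinder",
    "Kd",
    "BindingDomainError",
    "SolverError",
    "UnknownSpeciesError",
    "BinaryReaction",
    "CompetitionSystem",
    "EquilibriumState",
    "check_concentration",
    "complex_concentration",
    "solve_binary",
    "solve_competition",
    "fraction_bound",
]


class NonBinder(enum.Enum):
    """Sentinel for pairs where no complex forms at any concentration."""

    NON_BINDER = "non-binder"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NON_BINDER"


NON_BINDER = NonBinder.NON_BINDER

#: A dissociation constant: a positive concentration in μmol/l, or the
#: explicit non-binder sentinel.
Kd = Union[float, NonBinder]


class BindingDomainError(ValueError):
    """Raised for physically invalid inputs (negative or NaN concentrations)."""


class SolverError(RuntimeError):
    """Raised when an equilibrium solve fails; carries the residual."""

    def __init__(self, message: str, residual: float = math.nan) -> None:
        super().__init__(message)
        self.residual = residual


class UnknownSpeciesError(KeyError):
    """Raised when a species name is not present in an equilibrium state."""


def check_concentration(value: float, name: str = "concentration") -> float:
    """Validate a concentration (μmol/l): finite and non-negative."""
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise BindingDomainError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def _check_kd(kd: Kd, name: str = "kd") -> Kd:
    if kd is NON_BINDER:
        return kd
    kd = float(kd)
    if not math.isfinite(kd) or kd <= 0.0:
        raise BindingDomainError(
            f"{name} must be a finite positive concentration or NON_BINDER, got {kd!r}"
        )
    return kd


@dataclass(frozen=True)
class BinaryReaction:
    """One labeled receptor (total ``receptor_total``) titrated with one ligand.

    Parameters
    ----------
    receptor_total :
        Total concentration of the labeled species R_t (μmol/l).
    ligand_total :
        Total titrant concentration L_t (μmol/l).
    kd :
        Equilibrium dissociation constant (μmol/l), or :data:`NON_BINDER`.
    """

    receptor_total: float
    ligand_total: float
    kd: Kd

    def __post_init__(self) -> None:
        check_concentration(self.receptor_total, "receptor_total")
        check_concentration(self.ligand_total, "ligand_total")
        _check_kd(self.kd)


@dataclass(frozen=True)
class CompetitionSystem:
    """Two ligands A and B mutually exclusive for a single site on R."""

    receptor_total: float
    competitor_a_total: float
    titrant_b_total: float
    kd_a: float
    kd_b: float

    def __post_init__(self) -> None:
        check_concentration(self.receptor_total, "receptor_total")
        check_concentration(self.competitor_a_total, "competitor_a_total")
        check_concentration(self.titrant_b_total, "titrant_b_total")
        for name in ("kd_a", "kd_b"):
            kd = getattr(self, name)
            if kd is NON_BINDER or not math.isfinite(float(kd)) or float(kd) <= 0:
                raise BindingDomainError(f"{name} must be finite and > 0, got {kd!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Free and complexed concentrations satisfying mass conservation.

    ``complexes`` is keyed by a pair of species names, e.g. ``("R", "L")``.
    """

    free: Mapping[str, float]
    complexes: Mapping[tuple[str, str], float]
    totals: Mapping[str, float]

    def bound(self, species: str) -> float:
        """Total concentration of ``species`` held in complexes."""
        if species not in self.totals:
            raise UnknownSpeciesError(species)
        return float(
            sum(c for pair, c in self.complexes.items() if species in pair)
        )

    def mass_balance_residual(self, species: str) -> float:
        """Relative mass-conservation residual for ``species``."""
        total = self.totals[species]
        recon = self.free[species] + self.bound(species)
        scale = max(abs(total), 1.0e-300)
        return abs(recon - total) / scale


def complex_concentration(receptor_total, ligand_total, kd):
    """Exact 1:1 complex concentration by the ligand-depletion quadratic.

    Vectorized over any of the three arguments.  Implements the physical
    ("−") root of ``[RL]^2 − (R_t + L_t + Kd)[RL] + R_t·L_t = 0``::

        [RL] = ((R_t + L_t + Kd) − sqrt((R_t + L_t + Kd)^2 − 4 R_t L_t)) / 2

    and clips the few-ulp excursions outside ``[0, min(R_t, L_t)]`` that
    floating point can produce near the stoichiometric limit.
    """
    rt = np.asarray(receptor_total, dtype=float)
    lt = np.asarray(ligand_total, dtype=float)
    kd = np.asarray(kd, dtype=float)
    s = rt + lt + kd
    disc = s * s - 4.0 * rt * lt
    # disc >= kd^2 + 2 kd (rt+lt) + (rt-lt)^2 > 0 for kd > 0; guard anyway
    disc = np.maximum(disc, 0.0)
    # conjugate form of the "-" branch: immune to the catastrophic
    # cancellation of (s - sqrt(disc)) when [RL] << s
    denom = s + np.sqrt(disc)
    rl = 2.0 * rt * lt / np.maximum(denom, 1.0e-300)
    upper = np.minimum(rt, lt)
    if np.any(rl < -1.0e-9 * np.maximum(upper, 1.0)) or np.any(
        rl > upper * (1.0 + 1.0e-9) + 1.0e-300
    ):
        raise SolverError("quadratic root escaped [0, min(R_t, L_t)]")
    return np.clip(rl, 0.0, upper)


def solve_binary(rx: BinaryReaction) -> EquilibriumState:
    """Solve ``R + L <-> RL`` exactly, accounting for ligand depletion.

    Returns an :class:`EquilibriumState` with species ``"R"`` and ``"L"``
    and complex ``("R", "L")``.  A :data:`NON_BINDER` Kd yields exactly
    zero complex.
    """
    rt, lt = rx.receptor_total, rx.ligand_total
    if rx.kd is NON_BINDER:
        return EquilibriumState(
            free={"R": rt, "L": lt},
            complexes={("R", "L"): 0.0},
            totals={"R": rt, "L": lt},
        )
    kd = float(rx.kd)
    rl = float(complex_concentration(rt, lt, kd))
    # Free species by difference cancels badly when one partner is in large
    # excess; use the algebraically equivalent stable forms instead
    # (from d^2 - c^2 = 4 lt kd with d = sqrt(disc), c = rt + kd - lt):
    d = math.sqrt(max((rt + lt + kd) ** 2 - 4.0 * rt * lt, 0.0))
    c_l = rt + kd - lt
    free_l = 2.0 * lt * kd / (d + c_l) if c_l >= 0.0 else 0.5 * (d - c_l)
    c_r = lt + kd - rt
    free_r = 2.0 * rt * kd / (d + c_r) if c_r >= 0.0 else 0.5 * (d - c_r)
    return EquilibriumState(
        free={"R": free_r, "L": free_l},
        complexes={("R", "L"): rl},
        totals={"R": rt, "L": lt},
    )


def _competition_residual(r_free: float, sys: CompetitionSystem) -> float:
    # Free-competitor concentrations follow from free R:
    #   A = A_t / (1 + R/Kd_a),  B = B_t / (1 + R/Kd_b)
    # so receptor mass balance is a monotone increasing function of R.
    a = sys.competitor_a_total * sys.kd_a / (sys.kd_a + r_free)
    b = sys.titrant_b_total * sys.kd_b / (sys.kd_b + r_free)
    return r_free * (1.0 + a / sys.kd_a + b / sys.kd_b) - sys.receptor_total


def solve_competition(
    sys: CompetitionSystem,
    rtol: float = 1.0e-14,
    maxiter: int = 200,
) -> EquilibriumState:
    """Solve the exact ternary equilibrium of two ligands sharing one site.

    The coupled conservation laws

    .. math::

        R_t &= R\\,(1 + A/K_{d,a} + B/K_{d,b}) \\\\
        A_t &= A\\,(1 + R/K_{d,a}) \\\\
        B_t &= B\\,(1 + R/K_{d,b})

    are reduced to a single monotone equation in free receptor R, bracketed
    on ``[0, R_t]`` and solved with Brent's method.  No approximation is
    made for titrant depletion by either complex.

    Raises
    ------
    SolverError
        If the bracketing solve does not converge within ``maxiter``, or
        the solution violates mass conservation beyond 1e−10 relative.
    """
    rt = sys.receptor_total
    if rt == 0.0:
        r = 0.0
    elif sys.competitor_a_total == 0.0 and sys.titrant_b_total == 0.0:
        r = rt
    else:
        try:
            r = brentq(
                _competition_residual,
                0.0,
                rt,
                args=(sys,),
                rtol=rtol,
                xtol=1.0e-300,
                maxiter=maxiter,
            )
        except (RuntimeError, ValueError) as exc:
            raise SolverError(
                f"competition solve failed: {exc}",
                residual=_competition_residual(rt / 2.0, sys),
            ) from exc
    a = sys.competitor_a_total * sys.kd_a / (sys.kd_a + r)
    b = sys.titrant_b_total * sys.kd_b / (sys.kd_b + r)
    ra = r * a / sys.kd_a
    rb = r * b / sys.kd_b
    state = EquilibriumState(
        free={"R": r, "A": a, "B": b},
        complexes={("R", "A"): ra, ("R", "B"): rb},
        totals={
            "R": rt,
            "A": sys.competitor_a_total,
            "B": sys.titrant_b_total,
        },
    )
    for species in ("R", "A", "B"):
        if state.totals[species] > 0 and state.mass_balance_residual(species) > 1.0e-10:
            raise SolverError(
                f"mass conservation violated for {species}",
                residual=state.mass_balance_residual(species),
            )
    return state


def fraction_bound(state: EquilibriumState, species: str) -> float:
    """Fraction of ``species``' total held in complexes, in [0, 1].

    This is the quantity the normalized MST signal reports for the labeled
    species.  Zero total maps to zero occupancy.
    """
    if species not in state.totals:
        raise UnknownSpeciesError(species)
    total = state.totals[species]
    if total == 0.0:
        return 0.0
    theta = state.bound(species) / total
    return float(min(max(theta, 0.0), 1.0))
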