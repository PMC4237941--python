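"""Mass-action equilibrium of a two-species couplet and its binary complex.

Two soluble messengers (species ``a`` and species ``i``) reversibly form a
1:1 complex with association constant ``ka`` (L/mol)::

    a + i  <=>  a:i          ka = [a:i] / ([a][i])

An optional low-affinity analog competes for one of the two species with its
own constant ``ka_analog``.  Binding is treated as instantaneous relative to
a simulation step: only the equilibrium point matters, never the on/off
rates.

All concentrations are mol/L.  Amount <-> concentration conversion via a
compartment volume is the caller's business.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "EquilibriumResult",
    "equilibrate_pair",
    "equilibrate_with_analog",
    "discretize_level",
    "LEVELS",
]

#: Ordered discrete signal levels used by the decision layer.
LEVELS = ("Lo", "Mid", "Hi")


@dataclass(frozen=True)
class BindingSystem:
    """Couplet binding chemistry: constants and species labels.

    Parameters
    ----------
    ka:
        Association constant of the couplet complex, L/mol.  Must be > 0.
    ka_analog:
        Association constant of the analog for its target species, L/mol.
        0 means the analog does not bind at all (or there is no analog).
    analog_target:
        Which couplet species the analog competes to bind, ``"i"`` or
        ``"a"``.  A des(1-3)IGF-I-style analog mimics species ``a`` at the
        receptor but binds species ``i`` only weakly, hence the default.
    """

    ka: float
    ka_analog: float = 0.0
    label_a: str = "aT"
    label_i: str = "iT"
    label_analog: str = "analog"
    analog_target: str = "i"

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise ValueError(f"ka must be > 0, got {self.ka}")
        if self.ka_analog < 0:
            raise ValueError(f"ka_analog must be >= 0, got {self.ka_analog}")
        if self.analog_target not in ("a", "i"):
            raise ValueError(
                f"analog_target must be 'a' or 'i', got {self.analog_target!r}"
            )

    @property
    def analog_mimics(self) -> str:
        """Species whose receptor the analog activates (the non-target)."""
        return "a" if self.analog_target == "i" else "i"


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium partition of the three totals into free and bound pools.

    ``complex_ai`` is the couplet complex; ``complex_di`` is the
    analog:target complex (named for the default ``i`` target but used for
    either orientation).  All fields are concentrations in mol/L.
    """

    free_a: float
    free_i: float
    free_analog: float
    complex_ai: float
    complex_di: float

    @property
    def total_a(self) -> float:
        return self.free_a + self.complex_ai

    @property
    def total_i(self) -> float:
        # the couplet species that the analog targets also sits in complex_di;
        # orientation is resolved by the caller (see equilibrate_with_analog)
        return self.free_i + self.complex_ai + self.complex_di


def _require_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")


def equilibrate_pair(total_a: float, total_i: float, ka: float) -> EquilibriumResult:
    """Equilibrate a single reversible 1:1 association.

    Solves ``ka * (total_a - C) * (total_i - C) = C`` for the complex
    concentration ``C`` and returns the unique physical root
    (``0 <= C <= min(total_a, total_i)``).

    The quadratic ``ka*C**2 - (ka*(Ta+Ti)+1)*C + ka*Ta*Ti = 0`` is solved in
    the cancellation-free form ``C = 2*ka*Ta*Ti / (b + sqrt(b^2 - 4*ka^2*Ta*Ti))``
    with ``b = ka*(Ta+Ti)+1``, which stays accurate for very large ``ka``
    where the naive smaller root suffers catastrophic cancellation.
    """
    _require_nonneg(total_a=total_a, total_i=total_i, ka=ka)
    if ka == 0 or total_a == 0 or total_i == 0:
        return EquilibriumResult(
            free_a=total_a, free_i=total_i, free_analog=0.0,
            complex_ai=0.0, complex_di=0.0,
        )
    b = ka * (total_a + total_i) + 1.0
    disc = b * b - 4.0 * ka * ka * total_a * total_i
    # disc >= 1 analytically; guard against rounding
    root = math.sqrt(max(disc, 0.0))
    complex_ai = 2.0 * ka * total_a * total_i / (b + root)
    complex_ai = min(complex_ai, total_a, total_i)
    return EquilibriumResult(
        free_a=total_a - complex_ai,
        free_i=total_i - complex_ai,
        free_analog=0.0,
        complex_ai=complex_ai,
        complex_di=0.0,
    )


def _equilibrate_shared(
    total_a: float,
    total_i: float,
    total_d: float,
    ka: float,
    kd: float,
    max_iter: int,
) -> tuple[float, float, float, float, float]:
    """Simultaneous equilibrium of a:i and d:i sharing free i.

    Root-finds on the free concentration of the shared species ``i``:
    ``g(fi) = fi + ka*fa(fi)*fi + kd*fd(fi)*fi - total_i`` with
    ``fa = total_a/(1+ka*fi)`` and ``fd = total_d/(1+kd*fi)``.  ``g`` is
    strictly increasing, ``g(0) = -total_i <= 0`` and ``g(total_i) >= 0``,
    so a bracketed root always exists.
    """
    if total_i == 0:
        return total_a, 0.0, total_d, 0.0, 0.0

    def g(fi: float) -> float:
        fa = total_a / (1.0 + ka * fi)
        fd = total_d / (1.0 + kd * fi)
        return fi + ka * fa * fi + kd * fd * fi - total_i

    if g(total_i) <= 0.0:  # nothing binds
        return total_a, total_i, total_d, 0.0, 0.0
    try:
        fi = brentq(g, 0.0, total_i, xtol=1e-300, rtol=8.9e-16, maxiter=max_iter)
    except RuntimeError as exc:  # pragma: no cover - brentq converges in practice
        raise RuntimeError(
            f"shared-species equilibrium did not converge in {max_iter} "
            f"iterations (residual at midpoint: {g(total_i / 2):.3e})"
        ) from exc
    fa = total_a / (1.0 + ka * fi)
    fd = total_d / (1.0 + kd * fi)
    c_ai = ka * fa * fi
    c_di = kd * fd * fi
    # enforce exact conservation for the shared species; mass action then
    # holds to well within 1e-7 relative
    fi = max(total_i - c_ai - c_di, 0.0)
    return fa, fi, fd, c_ai, c_di


def equilibrate_with_analog(
    total_a: float,
    total_i: float,
    total_analog: float,
    system: BindingSystem,
    max_iter: int = 200,
) -> EquilibriumResult:
    """Equilibrate the couplet complex plus a competing analog complex.

    The analog competes for ``system.analog_target`` with constant
    ``system.ka_analog``.  With a zero analog total (or a non-binding
    analog) this reduces exactly to :func:`equilibrate_pair`.
    """
    _require_nonneg(total_a=total_a, total_i=total_i, total_analog=total_analog)
    if total_analog == 0 or system.ka_analog == 0:
        base = equilibrate_pair(total_a, total_i, system.ka)
        return EquilibriumResult(
            free_a=base.free_a, free_i=base.free_i,
            free_analog=total_analog, complex_ai=base.complex_ai,
            complex_di=0.0,
        )
    if system.analog_target == "i":
        fa, fi, fd, c_ai, c_di = _equilibrate_shared(
            total_a, total_i, total_analog, system.ka, system.ka_analog, max_iter
        )
        return EquilibriumResult(
            free_a=fa, free_i=fi, free_analog=fd,
            complex_ai=c_ai, complex_di=c_di,
        )
    # analog targets species a: same problem with the couplet roles swapped
    fi, fa, fd, c_ai, c_di = _equilibrate_shared(
        total_i, total_a, total_analog, system.ka, system.ka_analog, max_iter
    )
    return EquilibriumResult(
        free_a=fa, free_i=fi, free_analog=fd,
        complex_ai=c_ai, complex_di=c_di,
    )


def discretize_level(conc: float, theta_lo: float, theta_hi: float) -> str:
    """Map a concentration onto {Lo, Mid, Hi} with half-open bins.

    ``Lo`` if ``conc < theta_lo``; ``Hi`` if ``conc >= theta_hi``; else
    ``Mid``.  A value exactly at a threshold lands in the upper bin.
    """
    if conc < 0:
        raise ValueError(f"conc must be >= 0, got {conc}")
    if not 0 <= theta_lo < theta_hi:
        raise ValueError(
            f"thresholds must satisfy 0 <= theta_lo < theta_hi, "
            f"got ({theta_lo}, {theta_hi})"
        )
    if conc < theta_lo:
        return "Lo"
    if conc >= theta_hi:
        return "Hi"
    return "Mid"
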