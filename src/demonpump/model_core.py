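"""Closed-form theory of the two-state information-engine ion pump.

The pump is a membrane transporter with two conformations, ``e`` (empty)
and ``f`` (filled with an ion).  It exchanges ions with a high-concentration
outer reservoir (concentration ``C_h``, affinity constant ``k_h``) through
*intrinsic* transitions, and with a low-concentration inner reservoir
(``C_l``, ``k_l``) through *cooperative* transitions that simultaneously
convert a bound ATP to ADP (or back).  The inner pool supplies nucleotides
with ATP excess ``delta = p_t - p_d``; the stream acts as a writable tape,
so the pump operates as an autonomous Maxwell demon: it can move ions
uphill by randomizing the tape, or erase the tape by letting ions flow
downhill.

This module evaluates every closed-form quantity of the model:

* ``epsilon`` -- the tanh-compressed concentration-gradient bias,
* ``shannon_entropy`` -- tape information content per nucleotide,
* ``eta_factor`` / ``phi_analytic`` -- the steady-state per-interaction
  ADP production fraction ``Phi = (delta - epsilon)/2 * eta``,
* ``net_efflux`` -- ion efflux per interaction (equal to ``Phi``),
* ``outgoing_excess`` / ``delta_S`` -- outgoing-tape composition and the
  entropy written to the pool,
* ``second_law_lhs`` -- the per-interaction entropy production
  ``delta_S - Q * 2*artanh(epsilon)`` (nonnegative for all valid
  parameters),
* ``classify_regime`` -- pump / eraser / stalled classification.

Concentration--affinity products ``k*C`` are treated as dimensionless
throughout; all entropies default to natural-log units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PumpParameters",
    "RegimeLabel",
    "DomainError",
    "epsilon",
    "shannon_entropy",
    "eta_factor",
    "phi_analytic",
    "net_efflux",
    "outgoing_excess",
    "delta_S",
    "second_law_lhs",
    "classify_regime",
    "REGIME_TIE_TOL",
]

#: |delta - epsilon| below this is classified as stalled.
REGIME_TIE_TOL = 1e-9

EntropyBase = Literal["nat", "bit"]


class DomainError(ValueError):
    """A parameter lies outside the model's physical domain."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise DomainError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PumpParameters:
    """Full parameter vector of the pump plus nucleotide-pool composition.

    Parameters
    ----------
    delta
        Proportional excess of ATP in the incoming nucleotide stream,
        ``p_t - p_d``, in [-1, 1].
    k_h, k_l
        Affinity constants of the outer (intrinsic) and inner (cooperative)
        reservoir couplings, reciprocal-concentration units; positive.
    C_h, C_l
        Outer and inner reservoir ion concentrations, ``C_h >= C_l >= 0``
        and ``C_h > 0``.  ``C_l = 0`` is accepted and handled by analytic
        limits (``epsilon = 1``).

    The ATP/ADP proportions ``p_t = (1+delta)/2`` and ``p_d = (1-delta)/2``
    are derived on construction.
    """

    delta: float
    k_h: float
    k_l: float
    C_h: float
    C_l: float
    p_t: float = field(init=False)
    p_d: float = field(init=False)

    def __post_init__(self) -> None:
        _require(-1.0 <= self.delta <= 1.0, "delta", "must lie in [-1, 1]")
        _require(self.k_h > 0, "k_h", "must be positive")
        _require(self.k_l > 0, "k_l", "must be positive")
        _require(self.C_h > 0, "C_h", "must be positive")
        _require(self.C_l >= 0, "C_l", "must be nonnegative")
        _require(self.C_h >= self.C_l, "C_l", "must not exceed C_h")
        object.__setattr__(self, "p_t", (1.0 + self.delta) / 2.0)
        object.__setattr__(self, "p_d", (1.0 - self.delta) / 2.0)


@dataclass(frozen=True)
class RegimeLabel:
    """Operating regime of the pump.

    ``pump``: ions move uphill, information is written to the tape.
    ``eraser``: ions flow downhill, tape entropy is consumed.
    ``stalled``: delta = epsilon, no net flux.
    """

    label: Literal["pump", "eraser", "stalled"]
    q_sign: int
    ds_sign: int

    def __post_init__(self) -> None:
        expected = {1: "pump", -1: "eraser", 0: "stalled"}[self.q_sign]
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with q_sign {self.q_sign}"
            )


def epsilon(params: PumpParameters) -> float:
    """Concentration-gradient bias ``tanh((C_h - C_l)/(2 k_h k_l C_h C_l))``.

    Lies in [0, 1]: 0 iff the gradient vanishes (``C_h = C_l``), 1 in the
    empty-inner-reservoir limit ``C_l = 0``.
    """
    if params.C_l == 0.0:
        return 1.0
    arg = (params.C_h - params.C_l) / (
        2.0 * params.k_h * params.k_l * params.C_h * params.C_l
    )
    return math.tanh(arg)


def shannon_entropy(excess: float, base: EntropyBase = "nat") -> float:
    """Information content per nucleotide of a stream with ATP excess ``excess``.

    ``S = -p_t log p_t - p_d log p_d`` with ``p = (1 +/- excess)/2`` and the
    convention ``0 log 0 = 0``.  Symmetric in the sign of the excess and
    maximal (log 2) at a balanced stream.
    """
    if not -1.0 <= excess <= 1.0:
        raise DomainError(f"excess: {excess} outside [-1, 1]")
    s = 0.0
    for p in ((1.0 + excess) / 2.0, (1.0 - excess) / 2.0):
        if p > 0.0:
            s -= p * math.log(p)
    if base == "bit":
        return s / math.log(2.0)
    if base != "nat":
        raise ValueError(f"unknown entropy base {base!r}")
    return s


def _log_cosh(t: float) -> float:
    t = abs(t)
    return t + math.log1p(math.exp(-2.0 * t)) - math.log(2.0)


def eta_factor(params: PumpParameters) -> float:
    """Efficiency-like factor of the steady-state flux law.

    ``eta = 1 - exp(-(1 - tanh(a) * tanh(b)))`` with ``a = 1/(2 k_h C_h)``
    and ``b = 1/(2 k_l C_l)``; strictly inside (0, 1 - 1/e].  For
    ``C_l = 0`` the second tanh saturates at 1 (analytic limit).

    The naive product form cancels catastrophically when both tanh terms
    saturate, so the exponent is evaluated through the identity
    ``1 - tanh(a) tanh(b) = 2 cosh(a-b) / (cosh(a+b) + cosh(a-b))`` in log
    space, which stays positive down to ``min(a, b) ~ 370`` (beyond that
    the true value underflows double precision).
    """
    a = 1.0 / (2.0 * params.k_h * params.C_h)
    if params.C_l == 0.0:
        # b -> inf: exponent is 1 - tanh(a) = 2/(1 + exp(2a))
        x = 2.0 / (1.0 + math.exp(min(2.0 * a, 700.0)))
    else:
        b = 1.0 / (2.0 * params.k_l * params.C_l)
        log_num = math.log(2.0) + _log_cosh(a - b)
        log_den = np.logaddexp(_log_cosh(a + b), _log_cosh(a - b))
        x = math.exp(log_num - log_den)
    return -math.expm1(-x)


def phi_analytic(params: PumpParameters) -> float:
    """Per-interaction ADP production fraction ``Phi = (delta - eps)/2 * eta``.

    Positive when the tape bias exceeds the gradient bias (``delta > eps``:
    the pump writes information and moves ions uphill), negative in the
    eraser regime, zero exactly at the stall point ``delta = eps``.
    """
    return (params.delta - epsilon(params)) / 2.0 * eta_factor(params)


def net_efflux(params: PumpParameters) -> float:
    """Net ion efflux per interaction, ``Q_{l->h} = Phi``.

    Each ATP->ADP conversion moves exactly one ion from the inner to the
    outer reservoir, so the ion current and the tape current coincide.
    """
    return phi_analytic(params)


def outgoing_excess(params: PumpParameters, *, tol: float = 1e-9) -> float:
    """ATP excess ``delta' = delta - 2 Phi`` of the released nucleotide stream."""
    d_out = params.delta - 2.0 * phi_analytic(params)
    if abs(d_out) > 1.0 + tol:
        raise RuntimeError(
            f"outgoing excess {d_out} outside [-1, 1]: Phi implementation broken"
        )
    return max(-1.0, min(1.0, d_out))


def delta_S(params: PumpParameters, base: EntropyBase = "nat") -> float:
    """Entropy written to the nucleotide pool per interaction.

    ``delta_S = S(delta - 2 Phi) - S(delta)``; positive means information is
    recorded on the tape, negative means erasure.
    """
    return shannon_entropy(outgoing_excess(params), base) - shannon_entropy(
        params.delta, base
    )


def second_law_lhs(params: PumpParameters) -> float:
    """Per-interaction entropy production (natural-log units); >= 0 always.

    Moving one ion uphill withdraws ``(C_h - C_l)/(k_h k_l C_h C_l)
    = 2 artanh(eps)`` of entropy from the reservoirs, so total entropy
    production per interaction is::

        delta_S - Q_{l->h} * 2 artanh(eps)

    which the model guarantees nonnegative, with equality at the stall
    point.  Requires ``C_l > 0`` (the multiplier diverges at ``C_l = 0``).
    """
    _require(params.C_l > 0, "C_l", "must be positive for the entropy balance")
    mult = (params.C_h - params.C_l) / (
        params.k_h * params.k_l * params.C_h * params.C_l
    )
    return delta_S(params, base="nat") - net_efflux(params) * mult


def classify_regime(params: PumpParameters, *, tol: float = REGIME_TIE_TOL) -> RegimeLabel:
    """Classify the operating point by the sign of ``delta - epsilon``."""
    gap = params.delta - epsilon(params)
    if abs(gap) <= tol:
        return RegimeLabel("stalled", 0, 0)
    q = 1 if gap > 0 else -1
    ds = delta_S(params)
    ds_sign = 0 if ds == 0.0 else (1 if ds > 0 else -1)
    return RegimeLabel("pump" if q > 0 else "eraser", q, ds_sign)
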