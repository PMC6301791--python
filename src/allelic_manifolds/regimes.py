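"""Asymptotic regimes of an allelic manifold.

Plotting paired measurements (t-, t+) for an allelic series of RNAP
binding sites traces a one-dimensional manifold as the RNAP binding
factor P sweeps from 0 to infinity.  When the scale separations hold
(F >> 1 and tbg << tsat for occlusion; tsat/tbg >> alpha' >> 1 for
activation) the manifold breaks into five regimes, each with simple
power-law approximations for t- and t+:

occlusion (repression)                 activation (stabilization / acceleration)
1: background/background               1: background/background
2: t- ~ tsat*P,  t+ ~ tbg              2: t- ~ tbg,  t+ ~ b'*a'*tsat*P
3: t- ~ tsat*P,  t+ ~ tsat*P/(1+F)     3: t- ~ tsat*P,  t+ ~ b'*a'*tsat*P
4: t- ~ tsat,    t+ ~ tsat*P/(1+F)     4: t- ~ tsat*P,  t+ ~ b'*tsat
5: t- ~ tsat,    t+ ~ tsat             5: t- ~ tsat,    t+ ~ b'*tsat

Regime 3 is the workhorse: there the manifold runs parallel to the
diagonal on log-log axes, offset by 1/(1+F) (occlusion) or by a'
(stabilization) — the offset is what a fit measures.

Regime boundaries are taken at the crossover points where adjacent
approximate expressions intersect (dominant-term analysis of the exact
rate laws); each boundary formula is stated next to its code below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thermo import ThermoParams

__all__ = ["RegimeLabel", "RegimesUndefinedError", "regime_bounds", "classify_regime", "regime_ratio"]


class RegimesUndefinedError(ValueError):
    """The parameter scales do not separate enough for the five-regime picture."""


class AmbiguousRegimeError(ValueError):
    """P falls inside a crossover zone excluded by the strictness factor."""


@dataclass(frozen=True)
class RegimeLabel:
    """One point classified onto the manifold."""

    index: int  # 1..5
    mechanism: str
    p_range: tuple  # (low, high) validity range for P
    approx_t_minus: float  # regime approximation evaluated at the query P
    approx_t_plus: float
    description: str

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3, 4, 5):
            raise ValueError("regime index must be in 1..5")


_DESCRIPTIONS = {
    ("repression", 1): "background-dominated in both channels",
    ("repression", 2): "t- proportional to P, t+ still background",
    ("repression", 3): "parallel offset: t+ ~ t-/(1+F)",
    ("repression", 4): "t- saturated, t+ still proportional to P",
    ("repression", 5): "both channels saturated",
    ("activation", 1): "background-dominated in both channels",
    ("activation", 2): "t+ proportional to P, t- still background",
    ("activation", 3): "parallel offset: t+ ~ b'a' t-",
    ("activation", 4): "t+ saturated, t- still proportional to P",
    ("activation", 5): "both channels saturated",
}


def _require_scale_separation(params: ThermoParams) -> None:
    ratio = params.tsat / params.tbg if params.tbg > 0 else np.inf
    if params.mechanism == "repression":
        if params.F < 10 or ratio < 100:
            raise RegimesUndefinedError(
                f"five-regime structure needs F >> 1 and tbg << tsat; got F={params.F}, tsat/tbg={ratio:.3g}"
            )
    else:
        ap = params.alpha_prime * params.beta_prime
        if ap < 10 or ratio < 10 * ap:
            raise RegimesUndefinedError(
                "five-regime structure needs tsat/tbg >> alpha' >> 1; "
                f"got alpha'*beta'={ap:.3g}, tsat/tbg={ratio:.3g}"
            )


def regime_bounds(params: ThermoParams) -> np.ndarray:
    """The six edges (0, b1..b4, inf) of the five contiguous P-ranges.

    Crossovers (repression):  tbg = tsat*P  ->  b1 = tbg/tsat;
    tbg = tsat*P/(1+F)  ->  b2 = (1+F)*tbg/tsat;  t- saturates at P = 1;
    t+ saturates at P = 1+F.
    Crossovers (activation):  tbg = b'a'tsat*P  ->  b1 = tbg/(b'a'tsat);
    t- leaves background at b2 = tbg/tsat;  t+ saturates at b3 = 1/a';
    t- saturates at b4 = 1.
    """
    _require_scale_separation(params)
    tsat, tbg = params.tsat, params.tbg
    if params.mechanism == "repression":
        F = params.F
        edges = [0.0, tbg / tsat, (1.0 + F) * tbg / tsat, 1.0, 1.0 + F, np.inf]
    else:
        ap = params.alpha_prime
        bp = params.beta_prime
        edges = [0.0, tbg / (bp * ap * tsat), tbg / tsat, 1.0 / ap, 1.0, np.inf]
    edges = np.asarray(edges)
    if np.any(np.diff(edges) <= 0):  # cannot happen once separation holds
        raise RegimesUndefinedError(f"regime edges are not increasing: {edges}")
    return edges


def _approximations(params: ThermoParams, index: int, P: float) -> tuple:
    tsat, tbg = params.tsat, params.tbg
    if params.mechanism == "repression":
        F = params.F
        table = {
            1: (tbg, tbg),
            2: (tsat * P, tbg),
            3: (tsat * P, tsat * P / (1.0 + F)),
            4: (tsat, tsat * P / (1.0 + F)),
            5: (tsat, tsat),
        }
    else:
        ap = params.alpha_prime
        bp = params.beta_prime
        table = {
            1: (tbg, tbg),
            2: (tbg, bp * ap * tsat * P),
            3: (tsat * P, bp * ap * tsat * P),
            4: (tsat * P, bp * tsat),
            5: (tsat, bp * tsat),
        }
    return table[index]


def classify_regime(P: float, params: ThermoParams, strictness: float = 1.0) -> RegimeLabel:
    """Locate P among the five regimes of the manifold for ``params``.

    ``strictness`` >= 1 shrinks every range symmetrically (in log space)
    about its crossover edges by that multiplier; a P falling in an
    excluded crossover zone raises :class:`AmbiguousRegimeError`.  At the
    default 1 the ranges tile (0, inf) exactly.
    """
    if not np.isfinite(P) or P < 0:
        raise ValueError(f"P must be a nonnegative real, got {P!r}")
    if strictness < 1:
        raise ValueError("strictness must be >= 1")
    edges = regime_bounds(params)
    index = int(np.searchsorted(edges, P, side="right"))
    index = min(max(index, 1), 5)
    lo, hi = edges[index - 1], edges[index]
    if strictness > 1.0:
        lo_s = lo * strictness if lo > 0 else 0.0
        hi_s = hi / strictness if np.isfinite(hi) else np.inf
        if not (lo_s <= P < hi_s):
            raise AmbiguousRegimeError(
                f"P={P:.3g} lies within a factor {strictness} of a regime boundary"
            )
    mech_kind = "repression" if params.mechanism == "repression" else "activation"
    tm, tp = _approximations(params, index, P)
    return RegimeLabel(
        index=index,
        mechanism=params.mechanism,
        p_range=(float(lo), float(hi)),
        approx_t_minus=float(tm),
        approx_t_plus=float(tp),
        description=_DESCRIPTIONS[(mech_kind, index)],
    )


def regime_ratio(regime: int, params: ThermoParams) -> float:
    """The t+/t- offset of the parallel regime (regime 3).

    Occlusion: 1/(1+F).  Stabilization: alpha'.  Acceleration:
    alpha'*beta' (the manifold offset absorbs both couplings; for pure
    stabilization beta' = 1 and the two coincide).
    """
    if regime != 3:
        raise ValueError(f"the parallel offset is defined only in regime 3, got regime {regime}")
    if params.mechanism == "repression":
        return 1.0 / (1.0 + params.F)
    return params.alpha_prime * params.beta_prime
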