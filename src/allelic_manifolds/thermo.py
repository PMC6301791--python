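"""Equilibrium thermodynamic models of bacterial transcriptional regulation.

This module provides closed-form transcription-rate laws for three
regulatory mechanisms at a promoter carrying one transcription-factor (TF)
binding site and one RNA-polymerase (RNAP) binding site:

* **repression** — the DNA-bound TF sterically occludes RNAP (three
  promoter states: unbound, TF-bound, RNAP-bound);
* **stabilization** — the DNA-bound TF stabilizes the RNAP–DNA closed
  complex via a cooperativity factor ``alpha`` (four states, the doubly
  bound state carrying Boltzmann weight ``alpha*F*P``);
* **acceleration** — as stabilization, but the TF–RNAP–DNA ternary complex
  additionally initiates transcripts ``beta``-fold faster than RNAP alone.

States are populated in thermal equilibrium with probabilities
proportional to their Boltzmann weights ``(1, F, P, alpha*F*P)``, where the
dimensionless *binding factors* ``F = [TF]*K_F`` and ``P = [RNAP]*K_P``
are equivalently ``exp(-dG/kBT)`` for the corresponding Gibbs free energy
of binding.  The observable transcription rate is the rate-weighted state
average plus a background term ``tbg``; a promoter saturated by RNAP
initiates at rate ``tsat``.  Rates carry the arbitrary units (a.u.) of the
reporter assay; free energies are reported in kcal/mol using the
convention 1 kcal/mol = 1.62 kBT at 37 °C.

All rate functions broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import constants as _const

__all__ = [
    "MECHANISMS",
    "KBT_KCAL_PER_MOL",
    "ThermoConstants",
    "BindingFactor",
    "ThermoParams",
    "t_minus",
    "t_plus_repression",
    "alpha_prime",
    "beta_prime",
    "t_plus_activation",
    "t_plus_acceleration",
    "state_probabilities",
    "dg_from_factor",
    "factor_from_dg",
]

MECHANISMS = ("repression", "stabilization", "acceleration")

#: kBT in kcal/mol at 37 °C under the reporting convention
#: 1 kcal/mol = 1.62 kBT.  Used for all free-energy conversions so that
#: printed dG values round reproducibly at two decimals.
KBT_KCAL_PER_MOL = 1.0 / 1.62


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants for factor <-> free-energy conversion.

    ``kbt`` is recomputed from the molar gas constant at ``temperature``
    (kelvin); the module-level default :data:`KBT_KCAL_PER_MOL` instead
    fixes the rounded 37 °C convention used for reported energies.
    """

    temperature: float = 310.15  # kelvin

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def kbt(self) -> float:
        """kBT in kcal/mol computed from physical constants."""
        joule_per_mol = _const.R * self.temperature
        return joule_per_mol / (_const.calorie * 1000.0)

    @property
    def kbt_per_kcal(self) -> float:
        """How many kBT one kcal/mol is worth at this temperature."""
        return 1.0 / self.kbt


@dataclass(frozen=True)
class BindingFactor:
    """Dimensionless Boltzmann weight of a bound state (F for a TF, P for RNAP).

    Equals concentration x affinity constant when that decomposition is
    known, and always ``exp(-dG/kBT)`` for the paired binding free energy.
    """

    value: float
    concentration: Optional[float] = None  # molar
    affinity: Optional[float] = None  # per molar

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError(f"binding factor must be a positive real, got {self.value}")
        if self.concentration is not None and self.affinity is not None:
            prod = self.concentration * self.affinity
            if not np.isclose(prod, self.value, rtol=1e-9):
                raise ValueError(
                    f"concentration*affinity = {prod} inconsistent with value {self.value}"
                )

    @property
    def dg(self) -> float:
        """Gibbs free energy of binding, kcal/mol."""
        return dg_from_factor(self.value)

    @classmethod
    def from_dg(cls, dg: float, kbt: float = KBT_KCAL_PER_MOL) -> "BindingFactor":
        return cls(value=factor_from_dg(dg, kbt=kbt))


@dataclass(frozen=True)
class ThermoParams:
    """Parameters of one regulatory architecture.

    tsat, tbg : transcription rates, a.u. (tsat > tbg >= 0)
    F         : TF binding factor (None allowed for stabilization /
                acceleration when only the renormalized couplings matter,
                i.e. the F >> 1 limit)
    alpha     : TF-RNAP cooperativity (ignored under repression)
    beta      : initiation acceleration of the ternary complex
                (must be 1 under repression / stabilization)
    """

    mechanism: str
    tsat: float
    tbg: float = 0.0
    F: Optional[float] = None
    alpha: Optional[float] = None
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if not (self.tsat > self.tbg >= 0):
            raise ValueError(f"require tsat > tbg >= 0, got tsat={self.tsat}, tbg={self.tbg}")
        if self.F is not None and self.F < 0:
            raise ValueError("F must be >= 0")
        if self.mechanism == "repression":
            if self.F is None:
                raise ValueError("repression requires a TF binding factor F")
            if self.beta != 1.0:
                raise ValueError("beta is meaningless under repression; leave it at 1")
        else:
            if self.alpha is None:
                raise ValueError(f"{self.mechanism} requires a cooperativity alpha")
            if self.alpha < 0:
                raise ValueError("alpha must be >= 0")
            if self.mechanism == "stabilization" and self.beta != 1.0:
                raise ValueError("stabilization fixes beta = 1; use mechanism='acceleration'")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    # -- derived couplings -------------------------------------------------
    @property
    def alpha_prime(self) -> float:
        """Renormalized cooperativity (1 + alpha F)/(1 + F); alpha itself if F is None."""
        if self.mechanism == "repression":
            raise ValueError("alpha_prime is undefined under repression")
        if self.F is None:
            return float(self.alpha)
        return float(alpha_prime(self.alpha, self.F))

    @property
    def beta_prime(self) -> float:
        if self.mechanism != "acceleration":
            return 1.0
        if self.F is None:
            return float(self.beta)
        return float(beta_prime(self.alpha, self.beta, self.F))

    # -- rate laws ---------------------------------------------------------
    def t_minus(self, P):
        return t_minus(P, self.tsat, self.tbg)

    def t_plus(self, P):
        if self.mechanism == "repression":
            return t_plus_repression(P, self.F, self.tsat, self.tbg)
        F = np.inf if self.F is None else self.F
        if self.mechanism == "stabilization":
            return t_plus_activation(P, F, self.alpha, self.tsat, self.tbg)
        return t_plus_acceleration(P, F, self.alpha, self.beta, self.tsat, self.tbg)

    # -- energy views ------------------------------------------------------
    @property
    def dg_F(self) -> float:
        if self.F is None:
            raise ValueError("F is not set")
        return dg_from_factor(self.F)

    @property
    def dg_alpha(self) -> float:
        if self.mechanism == "repression":
            raise ValueError("dg_alpha is undefined under repression")
        return dg_from_factor(self.alpha)


# ---------------------------------------------------------------------------
# rate laws


def _check_nonneg(name: str, x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if np.any(np.isnan(a)) or np.any(a < 0):
        raise ValueError(f"{name} must be >= 0, got {x!r}")
    return a


def _check_rates(tsat: float, tbg: float) -> None:
    if tsat < 0 or tbg < 0:
        raise ValueError(f"rates must be >= 0, got tsat={tsat}, tbg={tbg}")


def t_minus(P, tsat: float, tbg: float = 0.0):
    """Transcription rate without the TF: ``tsat * P/(1+P) + tbg``.

    Strictly increasing in P, bounded in [tbg, tsat + tbg).
    """
    P = _check_nonneg("P", P)
    _check_rates(tsat, tbg)
    out = tsat * P / (1.0 + P) + tbg
    return out if out.shape else float(out)


def t_plus_repression(P, F, tsat: float, tbg: float = 0.0):
    """Rate with an occluding TF bound with factor F: ``tsat * P/(1+F+P) + tbg``."""
    P = _check_nonneg("P", P)
    F = _check_nonneg("F", F)
    _check_rates(tsat, tbg)
    out = tsat * P / (1.0 + F + P) + tbg
    return out if out.shape else float(out)


def alpha_prime(alpha, F):
    """Renormalized cooperativity ``(1 + alpha*F) / (1 + F)``.

    Absorbs the TF binding factor into an effective RNAP-recruitment
    strength: the activated rate law depends on (alpha, F) only through
    this combination.  Tends to alpha as F -> inf.
    """
    alpha = _check_nonneg("alpha", alpha)
    F = _check_nonneg("F", F)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(F), alpha, (1.0 + alpha * F) / (1.0 + F))
    return out if out.shape else float(out)


def beta_prime(alpha, beta, F):
    """Renormalized acceleration ``(1 + alpha*beta*F) / (1 + alpha*F)``.

    Equals 1 for pure stabilization (beta = 1) and tends to beta as
    alpha*F -> inf.
    """
    alpha = _check_nonneg("alpha", alpha)
    beta = _check_nonneg("beta", beta)
    F = _check_nonneg("F", F)
    aF = alpha * F
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(aF), beta, (1.0 + beta * aF) / (1.0 + aF))
    return out if out.shape else float(out)


def t_plus_activation(P, F, alpha, tsat: float, tbg: float = 0.0):
    """Activated rate under stabilization.

    Computed as the explicit four-state Boltzmann average
    ``tsat * (P + alpha*F*P) / (1 + F + P + alpha*F*P) + tbg``;
    algebraically identical to the renormalized form
    ``tsat * a'*P / (1 + a'*P) + tbg`` with a' = alpha_prime(alpha, F).
    F = inf selects the renormalized form with a' = alpha.
    """
    P = _check_nonneg("P", P)
    F = _check_nonneg("F", F)
    alpha = _check_nonneg("alpha", alpha)
    _check_rates(tsat, tbg)
    if np.any(np.isinf(F)):
        ap = alpha_prime(alpha, F)
        out = tsat * ap * P / (1.0 + ap * P) + tbg
    else:
        num = P + alpha * F * P
        out = tsat * num / (1.0 + F + num) + tbg
    out = np.asarray(out)
    return out if out.shape else float(out)


def t_plus_acceleration(P, F, alpha, beta, tsat: float, tbg: float = 0.0):
    """Activated rate when the ternary complex also initiates beta-fold faster.

    Explicit state sum: the RNAP-only state initiates at tsat, the
    TF-RNAP-DNA ternary complex at beta*tsat:
    ``tsat*P/(Z) + beta*tsat*alpha*F*P/(Z) + tbg`` with
    ``Z = 1 + F + P + alpha*F*P``.  Identical to
    ``b'*tsat*a'*P / (1 + a'*P) + tbg``; saturates at b'*tsat + tbg.
    """
    P = _check_nonneg("P", P)
    F = _check_nonneg("F", F)
    alpha = _check_nonneg("alpha", alpha)
    beta = _check_nonneg("beta", beta)
    _check_rates(tsat, tbg)
    if np.any(np.isinf(F)):
        ap = alpha_prime(alpha, F)
        bp = beta_prime(alpha, beta, F)
        out = bp * tsat * ap * P / (1.0 + ap * P) + tbg
    else:
        Z = 1.0 + F + P + alpha * F * P
        out = tsat * P / Z + beta * tsat * alpha * F * P / Z + tbg
    out = np.asarray(out)
    return out if out.shape else float(out)


def state_probabilities(P, F, alpha: Optional[float] = None) -> np.ndarray:
    """Equilibrium occupancies of {unbound, TF-bound, RNAP-bound, doubly bound}.

    Boltzmann weights (1, F, P, alpha*F*P), normalized to sum to one.
    ``alpha=None`` selects the three-state occlusion model (the doubly
    bound state is sterically forbidden and gets probability zero).
    """
    P = _check_nonneg("P", P)
    F = _check_nonneg("F", F)
    if alpha is None:
        w_double = np.zeros(np.broadcast(P, F).shape)
    else:
        alpha = _check_nonneg("alpha", alpha)
        w_double = alpha * F * P
    w = np.stack(np.broadcast_arrays(np.ones_like(P * F), F * np.ones_like(P), P * np.ones_like(F), w_double), axis=-1)
    return w / w.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# free-energy conversions


def dg_from_factor(x, kbt: float = KBT_KCAL_PER_MOL):
    """Gibbs free energy (kcal/mol) of a binding or cooperativity factor.

    dG = -kBT * ln(x).  A factor above 1 is a favorable (negative dG)
    interaction.  Natural log; kBT defaults to the 37 °C convention.
    """
    a = np.asarray(x, dtype=float)
    if np.any(~(a > 0)):
        raise ValueError(f"factor must be > 0 to have a free energy, got {x!r}")
    out = -kbt * np.log(a)
    return out if out.shape else float(out)


def factor_from_dg(dg, kbt: float = KBT_KCAL_PER_MOL):
    """Inverse of :func:`dg_from_factor`: ``exp(-dG/kBT)``."""
    a = np.asarray(dg, dtype=float)
    out = np.exp(-a / kbt)
    return out if out.shape else float(out)
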