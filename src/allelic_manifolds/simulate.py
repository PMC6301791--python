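"""Synthetic allelic-series generator.

Emulates the measurement design the fitting pipeline expects: an allelic
series of RNAP binding sites whose binding factors P span several
decades, each variant assayed with and without the active TF, with
multiplicative (lognormal) replicate noise and an optional sprinkling of
outlier promoters whose regulated channel is corrupted (as happens when
a random mutation creates a new TF site or shifts the RNAP site).

Default parameters are the characteristic values of the CRP / sigma-70
RNAP system this package targets: tsat = 15.1 a.u., tbg = 2.3e-3 a.u.,
TF binding factor F = 23.9 (the near-consensus CRP site), class I
cooperativity alpha = 712, noise CV 10%, and P drawn log-uniformly over
[1e-4, 3] — populating regimes 1–4 of the manifold.  Regime-5 coverage
(needed to pin down beta) requires explicitly widening the P range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .fit import _model_rates
from .io import MeasurementTable, dump_json_summary
from .thermo import MECHANISMS

__all__ = ["SyntheticTruth", "simulate_allelic_series", "simulate_titration"]

_DEFAULT_ARCHITECTURE = {
    "repression": "+0.5",
    "stabilization": "-61.5",
    "acceleration": "-60.5",
}


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated allelic series.

    noise_cv is the fractional replicate scatter: observed rates are the
    model rates times exp(eps) with eps ~ Normal(0, ln(1 + CV)),
    independent per row and per channel.  Outlier promoters additionally
    have t+ multiplied by a log-uniform factor of up to one decade, at
    least two-fold, in either direction.
    """

    mechanism: str = "repression"
    tsat: float = 15.1  # a.u.
    tbg: float = 0.0023  # a.u.
    F: float = 23.9
    alpha: float = 712.0
    beta: float = 1.0
    p_range: tuple = (1e-4, 3.0)
    p_mode: str = "log-uniform"  # or "log-spaced"
    noise_cv: float = 0.1
    outlier_fraction: float = 0.0
    outlier_max_decades: float = 1.0
    seed: int = 0
    architecture: str = ""
    condition: str = ""
    # filled in by the generator:
    P_by_promoter: Dict[str, float] = field(default_factory=dict)
    outlier_ids: list = field(default_factory=list)
    F_by_concentration: Dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (self.tsat > self.tbg >= 0):
            raise ValueError("require tsat > tbg >= 0")
        if self.F <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("F, alpha, beta must be positive")
        if self.mechanism == "stabilization" and self.beta != 1.0:
            raise ValueError("stabilization fixes beta = 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        lo, hi = self.p_range
        if not (0 < lo < hi):
            raise ValueError(f"p_range must satisfy 0 < low < high, got {self.p_range}")
        if self.p_mode not in ("log-uniform", "log-spaced"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")
        if not self.architecture:
            self.architecture = _DEFAULT_ARCHITECTURE[self.mechanism]

    @property
    def scalars(self) -> dict:
        s = {"tsat": self.tsat, "tbg": self.tbg, "F": self.F}
        if self.mechanism != "repression":
            s["alpha"] = self.alpha
        if self.mechanism == "acceleration":
            s["beta"] = self.beta
        return s

    def to_json(self, path) -> None:
        dump_json_summary({"truth": dataclasses.asdict(self)}, path)


def _draw_P(truth: SyntheticTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = np.log(truth.p_range[0]), np.log(truth.p_range[1])
    if truth.p_mode == "log-spaced":
        return np.exp(np.linspace(lo, hi, n))
    return np.exp(np.sort(rng.uniform(lo, hi, size=n)))


def _outlier_multipliers(n: int, max_decades: float, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform over [2, 10**d]-fold, up or down with equal probability."""
    mag = rng.uniform(np.log10(2.0), max_decades, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return 10.0 ** (sign * mag)


def simulate_allelic_series(truth: SyntheticTruth, n_promoters: int):
    """Generate one measurement table; returns (table, truth-with-bookkeeping).

    The returned truth is a copy whose ``P_by_promoter`` and
    ``outlier_ids`` record exactly what was injected; the table itself
    carries no outlier flags (detection is the analysis's job).
    """
    if n_promoters < 1:
        raise ValueError("n_promoters must be >= 1")
    truth = dataclasses.replace(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5EED]))
    P = _draw_P(truth, n_promoters, rng)
    ids = [f"p{i:03d}" for i in range(n_promoters)]
    tm, tp = _model_rates(truth.mechanism, P, truth.scalars)
    sigma = np.log1p(truth.noise_cv)
    tm_obs = tm * np.exp(rng.normal(0.0, sigma, size=n_promoters))
    tp_obs = tp * np.exp(rng.normal(0.0, sigma, size=n_promoters))
    is_out = rng.random(n_promoters) < truth.outlier_fraction
    if is_out.any():
        mult = _outlier_multipliers(int(is_out.sum()), truth.outlier_max_decades, rng)
        tp_obs[is_out] *= mult
    truth.P_by_promoter = dict(zip(ids, map(float, P)))
    truth.outlier_ids = [pid for pid, o in zip(ids, is_out) if o]
    table = MeasurementTable(
        pd.DataFrame(
            {
                "promoter_id": ids,
                "architecture": truth.architecture,
                "condition": truth.condition,
                "t_minus": tm_obs,
                "t_plus": tp_obs,
            }
        )
    )
    return table, truth


def simulate_titration(
    truth: SyntheticTruth,
    concentrations: Sequence[float],
    exponent: float,
    n_promoters: int,
    c_ref: Optional[float] = None,
):
    """Simulate one promoter library assayed across inducer concentrations.

    The TF binding factor follows a power law of the inducer
    concentration, ``F(c) = F_ref * (c / c_ref)**exponent`` with
    ``F_ref = truth.F`` at ``c_ref`` (default: the largest
    concentration).  The unregulated channel does not involve the
    inducer, so its model value is identical across conditions; noise is
    drawn independently per condition, as for independently repeated
    assays.  The P values (the promoter library) are shared.

    Returns (dict concentration -> MeasurementTable, truth) where the
    truth records ``F_by_concentration``.
    """
    concs = [float(c) for c in concentrations]
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive")
    if len(set(concs)) != len(concs):
        raise ValueError("concentrations must be distinct")
    if truth.mechanism != "repression":
        raise ValueError("titration emulates the occlusion (repression) design")
    c_ref = float(c_ref) if c_ref is not None else max(concs)
    truth = dataclasses.replace(truth)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x717]))
    P = _draw_P(truth, n_promoters, rng)
    ids = [f"p{i:03d}" for i in range(n_promoters)]
    sigma = np.log1p(truth.noise_cv)
    tables = {}
    truth.P_by_promoter = dict(zip(ids, map(float, P)))
    for c in sorted(concs):
        F_c = truth.F * (c / c_ref) ** exponent
        scalars = {**truth.scalars, "F": F_c}
        tm, tp = _model_rates("repression", P, scalars)
        tm_obs = tm * np.exp(rng.normal(0.0, sigma, size=n_promoters))
        tp_obs = tp * np.exp(rng.normal(0.0, sigma, size=n_promoters))
        truth.F_by_concentration[c] = float(F_c)
        tables[c] = MeasurementTable(
            pd.DataFrame(
                {
                    "promoter_id": ids,
                    "architecture": truth.architecture,
                    "condition": f"cAMP={c:g}uM",
                    "cAMP_uM": c,
                    "t_minus": tm_obs,
                    "t_plus": tp_obs,
                }
            )
        )
    return tables, truth
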