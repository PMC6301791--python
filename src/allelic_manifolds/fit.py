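"""Nonlinear least-squares inference on allelic manifolds.

A dataset is n promoter variants, each measured with (t+) and without
(t-) the active transcription factor.  Under the thermodynamic models in
:mod:`.thermo`, varying the RNAP binding site changes only the RNAP
binding factor P of each variant, so the 2n measurements are explained
by n + k parameters: one P per promoter plus k architecture-level
parameters (tsat, tbg, and the regulatory coupling F, alpha, or
alpha/beta).  Because 2n > n + k for n > k, the model is testable and
the couplings are identifiable.

Fitting minimizes squared residuals of log10 rates (measurements span
several decades and replicate noise is multiplicative).  All positive
parameters are optimized as logarithms, so positivity holds by
construction and no bounds are needed; Levenberg-Marquardt is used for
plain fits and a soft-L1 trust-region pass for outlier detection.
Uncertainties come from refitting bootstrap-resampled promoters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import thermo
from .io import MeasurementTable

__all__ = [
    "FitResult",
    "BootstrapEnsemble",
    "TitrationResult",
    "IdentifiabilityError",
    "FitFailureError",
    "CollapseError",
    "fit_manifold",
    "joint_fit",
    "fit_beta",
    "bootstrap",
    "detect_outliers",
    "titration_fit",
]

#: architecture-level parameters per mechanism, in packing order.
SCALAR_PARAMS = {
    "repression": ("tsat", "tbg", "F"),
    "stabilization": ("tsat", "tbg", "alpha"),
    "acceleration": ("tsat", "tbg", "alpha", "beta"),
}

_LN10 = np.log(10.0)
_CLIP = 300.0  # |ln parameter| ceiling inside the optimizer


class IdentifiabilityError(ValueError):
    """Too few promoters: 2n measurements cannot pin down n + k parameters."""


class FitFailureError(RuntimeError):
    """No optimization start converged; carries the best loss seen."""

    def __init__(self, message: str, best_loss: float = np.inf):
        super().__init__(message)
        self.best_loss = best_loss


class CollapseError(RuntimeError):
    """The data do not collapse to a one-dimensional manifold."""


# ---------------------------------------------------------------------------
# model evaluation (fast path used inside the optimizer; formulas identical
# to the documented ones in .thermo)


def _model_rates(mechanism: str, P: np.ndarray, s: Mapping[str, float]):
    tsat, tbg = s["tsat"], s["tbg"]
    tm = tsat * P / (1.0 + P) + tbg
    if mechanism == "repression":
        tp = tsat * P / (1.0 + s["F"] + P) + tbg
        return tm, tp
    F = s.get("F", np.inf)
    a = s["alpha"]
    ap = a if np.isinf(F) else (1.0 + a * F) / (1.0 + F)
    if mechanism == "stabilization":
        tp = tsat * ap * P / (1.0 + ap * P) + tbg
    else:
        b = s["beta"]
        bp = b if np.isinf(F) else (1.0 + a * b * F) / (1.0 + a * F)
        tp = bp * tsat * ap * P / (1.0 + ap * P) + tbg
    return tm, tp


def _invert_t_minus(tm_obs: np.ndarray, tsat: float, tbg: float) -> np.ndarray:
    """Initial per-promoter P from the unregulated channel, clipped into
    the identifiable window between background- and saturation-limited."""
    y = np.clip(tm_obs - tbg, 1e-4 * tsat, 0.999 * tsat)
    return y / (tsat - y)


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Point estimate of one manifold fit."""

    mechanism: str
    params: Dict[str, float]  # fitted architecture-level parameters
    fixed: Dict[str, float]  # parameters held fixed (includes known F)
    P_by_promoter: Dict[str, float]
    residuals: np.ndarray  # log10 residuals, t- block then t+ block (2n)
    loss: float  # sum of squared log10 residuals
    n_used: int
    outliers_excluded: list
    seed: int
    n_starts: int
    success: bool
    message: str = ""
    architecture: str = ""

    def __post_init__(self) -> None:
        for name, v in self.params.items():
            if v <= 0 and name != "beta":
                raise ValueError(f"fitted {name} must be positive, got {v}")

    # -- convenience views -------------------------------------------------
    def param(self, name: str) -> float:
        if name in self.params:
            return self.params[name]
        if name in self.fixed:
            return self.fixed[name]
        raise KeyError(name)

    @property
    def all_params(self) -> Dict[str, float]:
        return {**self.fixed, **self.params}

    @property
    def dg_F(self) -> float:
        """TF-DNA binding free energy, kcal/mol."""
        return thermo.dg_from_factor(self.param("F"))

    @property
    def dg_alpha(self) -> float:
        """TF-RNAP interaction free energy, kcal/mol."""
        return thermo.dg_from_factor(self.param("alpha"))

    @property
    def dg_P_by_promoter(self) -> Dict[str, float]:
        """RNAP-DNA binding free energy per promoter, kcal/mol."""
        return {k: thermo.dg_from_factor(v) for k, v in self.P_by_promoter.items()}

    def predict(self, P):
        """(t-, t+) on the fitted manifold at RNAP binding factor(s) P."""
        P = np.asarray(P, dtype=float)
        return _model_rates(self.mechanism, P, self.all_params)

    def to_dict(self) -> dict:
        d = {
            "mechanism": self.mechanism,
            "architecture": self.architecture,
            "params": dict(self.params),
            "fixed": {k: v for k, v in self.fixed.items() if np.isfinite(v)},
            "loss": float(self.loss),
            "n_used": self.n_used,
            "outliers_excluded": list(self.outliers_excluded),
            "seed": self.seed,
            "n_starts": self.n_starts,
            "success": self.success,
        }
        if "F" in self.params or np.isfinite(self.fixed.get("F", np.nan)):
            d["dg_F_kcal_mol"] = self.dg_F
        if self.mechanism != "repression":
            d["dg_alpha_kcal_mol"] = self.dg_alpha
        d["P_by_promoter"] = dict(self.P_by_promoter)
        return d


@dataclass
class BootstrapEnsemble:
    """Parameter draws from refitting bootstrap-resampled promoters."""

    point: FitResult
    draws: pd.DataFrame  # one row per successful replicate
    n_boot: int
    n_failed: int
    seed: int

    def ci(self, name: str, level: float = 0.68) -> tuple:
        """Percentile interval for a draw column (e.g. 'F', 'dg_F')."""
        lo = 50.0 * (1.0 - level)
        vals = self.draws[name].to_numpy()
        return tuple(np.percentile(vals, [lo, 100.0 - lo]))

    @property
    def ci68(self) -> Dict[str, tuple]:
        return {c: self.ci(c, 0.68) for c in self.draws.columns}

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "ci68": {k: list(v) for k, v in self.ci68.items()},
            "point": self.point.to_dict(),
        }


@dataclass
class TitrationResult:
    """Per-condition TF binding factors and their power-law exponent."""

    F_by_concentration: Dict[float, float]
    exponent: float
    exponent_ci95: tuple
    selected_concentrations: list
    fits: Dict[float, FitResult]
    ci68_F: Optional[Dict[float, tuple]] = None

    def to_dict(self) -> dict:
        d = {
            "F_by_concentration": {str(k): v for k, v in self.F_by_concentration.items()},
            "exponent": self.exponent,
            "exponent_ci95": list(self.exponent_ci95),
            "selected_concentrations": list(self.selected_concentrations),
        }
        if self.ci68_F is not None:
            d["ci68_F"] = {str(k): list(v) for k, v in self.ci68_F.items()}
        return d


# ---------------------------------------------------------------------------
# single-architecture fit


def _prepare(data: MeasurementTable, mechanism: str, fixed: Optional[Mapping[str, float]]):
    if mechanism not in SCALAR_PARAMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    fixed = {k: float(v) for k, v in (fixed or {}).items()}
    names = SCALAR_PARAMS[mechanism]
    for k in fixed:
        if k not in names and k != "F":
            raise ValueError(f"cannot fix unknown parameter {k!r} for {mechanism}")
        if fixed[k] <= 0 and k != "beta":
            raise ValueError(f"fixed {k} must be positive, got {fixed[k]}")
    if mechanism != "repression":
        fixed.setdefault("F", np.inf)  # unknown TF factor: fit the renormalized coupling
    if mechanism == "acceleration" and "tsat" not in fixed and "beta" not in fixed:
        # the manifold constrains only beta'*alpha' and (alpha'-1)/tsat:
        # with both tsat and beta free a zero-loss degeneracy family exists
        raise IdentifiabilityError(
            "acceleration fits need tsat (or beta) pinned: t+ as a function of t- "
            "determines only the products beta'*alpha'*tsat and (alpha'-1)/tsat, "
            "so tsat, alpha and beta cannot all be free"
        )
    free = [n for n in names if n not in fixed]
    used = data.non_outliers()
    excluded = [p for p in data.promoter_ids if p not in used.promoter_ids]
    n = used.n
    if n < max(4, len(free) + 1):
        raise IdentifiabilityError(
            f"{n} promoters cannot identify {n} binding factors plus "
            f"{len(free)} architecture parameters (need n >= {max(4, len(free) + 1)})"
        )
    return fixed, free, used, excluded


def _default_scalar_init(mechanism, tm, tp, fixed):
    init = {}
    tsat0 = fixed.get("tsat", 1.5 * float(np.max(tm)))
    tbg0 = fixed.get("tbg", 0.5 * float(min(np.min(tm), np.min(tp))))
    init["tsat"], init["tbg"] = tsat0, tbg0
    ratio = np.median(tp / tm)
    if mechanism == "repression":
        init["F"] = fixed.get("F", max(1.0 / max(ratio, 1e-6) - 1.0, 1e-2))
    else:
        ap0 = max(ratio, 1e-2)
        F = fixed.get("F", np.inf)
        if np.isinf(F):
            a0 = ap0
        else:
            a0 = max((ap0 * (1.0 + F) - 1.0) / F, 1e-3)
        init["alpha"] = fixed.get("alpha", a0)
        if mechanism == "acceleration":
            init["beta"] = fixed.get("beta", 1.0)
    return init


def _random_scalar_init(mechanism, tm, tp, fixed, rng):
    lo_all = min(float(np.min(tm)), float(np.min(tp)))
    hi_tm = float(np.max(tm))

    def draw(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    init = {
        "tsat": fixed.get("tsat", draw(0.8 * hi_tm, 30.0 * hi_tm)),
        "tbg": fixed.get("tbg", draw(0.05 * lo_all, 2.0 * lo_all)),
    }
    if mechanism == "repression":
        init["F"] = fixed.get("F", draw(3e-2, 3e4))
    else:
        init["alpha"] = fixed.get("alpha", draw(3e-2, 3e4))
        if mechanism == "acceleration":
            init["beta"] = fixed.get("beta", draw(0.2, 5.0))
    return init


def _solve(mechanism, free, fixed, tm_obs, tp_obs, theta0, robust=False, f_scale=0.1, tol=1e-14):
    k = len(free)
    log_tm = np.log10(tm_obs)
    log_tp = np.log10(tp_obs)

    def residuals(theta):
        theta = np.clip(theta, -_CLIP, _CLIP)
        s = dict(fixed)
        for i, name in enumerate(free):
            s[name] = np.exp(theta[i])
        P = np.exp(theta[k:])
        tm, tp = _model_rates(mechanism, P, s)
        return np.concatenate([np.log10(tm) - log_tm, np.log10(tp) - log_tp])

    if robust:
        res = least_squares(residuals, theta0, method="trf", loss="soft_l1", f_scale=f_scale,
                            xtol=tol, ftol=tol, gtol=tol)
    else:
        res = least_squares(residuals, theta0, method="lm", xtol=tol, ftol=tol, gtol=tol)
    return res


def _run_starts(mechanism, free, fixed, tm_obs, tp_obs, *, n_starts, seed, init, robust,
                f_scale, tol):
    k = len(free)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=max(n_starts, 1))
    best = None
    for s_idx in range(max(n_starts, 1)):
        if s_idx == 0 and init is not None:
            scal = dict(init["scalars"])
            P0 = np.asarray(init["P"], dtype=float)
        elif s_idx == 0:
            scal = _default_scalar_init(mechanism, tm_obs, tp_obs, fixed)
            P0 = _invert_t_minus(tm_obs, scal["tsat"], scal["tbg"])
        else:
            sub = np.random.default_rng(sub_seeds[s_idx])
            scal = _random_scalar_init(mechanism, tm_obs, tp_obs, fixed, sub)
            P0 = _invert_t_minus(tm_obs, scal["tsat"], scal["tbg"])
        theta0 = np.concatenate([[np.log(scal[name]) for name in free], np.log(P0)])
        try:
            res = _solve(mechanism, free, fixed, tm_obs, tp_obs, theta0,
                         robust=robust, f_scale=f_scale, tol=tol)
        except Exception:  # a pathological start must not kill the fit
            continue
        if best is None or res.cost < best.cost - 0.0:  # strict: ties keep first
            best = res
    if best is None:
        raise FitFailureError("all optimization starts failed")
    return best


def fit_manifold(
    data: MeasurementTable,
    mechanism: str,
    fixed: Optional[Mapping[str, float]] = None,
    *,
    n_starts: int = 10,
    seed: int = 0,
    init: Optional[dict] = None,
    robust: bool = False,
    f_scale: float = 0.1,
    tol: float = 1e-14,
    architecture: str = "",
) -> FitResult:
    """Fit one allelic manifold: n binding factors P plus the architecture
    parameters not held in ``fixed``.

    ``fixed`` may pin any of the mechanism's scalar parameters; for the
    activation mechanisms it may also carry the TF binding factor ``F``
    measured separately by occlusion (omitted, the renormalized coupling
    is fitted, i.e. the F -> inf limit).  ``init`` (used by bootstrap)
    supplies a single warm start as ``{"scalars": {...}, "P": array}``.

    Refitting noiseless model-generated data recovers the generating
    parameters; with data, the log-space residuals quantify manifold
    collapse quality.
    """
    fixed, free, used, excluded = _prepare(data, mechanism, fixed)
    df = used.df
    tm_obs = df["t_minus"].to_numpy()
    tp_obs = df["t_plus"].to_numpy()
    best = _run_starts(mechanism, free, fixed, tm_obs, tp_obs, n_starts=n_starts, seed=seed,
                       init=init, robust=robust, f_scale=f_scale, tol=tol)
    k = len(free)
    theta = np.clip(best.x, -_CLIP, _CLIP)
    params = {name: float(np.exp(theta[i])) for i, name in enumerate(free)}
    P = np.exp(theta[k:])
    s = {**fixed, **params}
    tm_fit, tp_fit = _model_rates(mechanism, P, s)
    residuals = np.concatenate([np.log10(tm_fit) - np.log10(tm_obs),
                                np.log10(tp_fit) - np.log10(tp_obs)])
    if not architecture:
        archs = used.architectures
        architecture = archs[0] if len(archs) == 1 else "+".join(archs)
    return FitResult(
        mechanism=mechanism,
        params=params,
        fixed=fixed,
        P_by_promoter={pid: float(p) for pid, p in zip(df["promoter_id"], P)},
        residuals=residuals,
        loss=float(np.sum(residuals**2)),
        n_used=used.n,
        outliers_excluded=excluded,
        seed=seed,
        n_starts=n_starts,
        success=bool(best.success) if best.success is not None else True,
        message=str(best.message),
        architecture=architecture,
    )


# ---------------------------------------------------------------------------
# joint fit with shared saturation rate


def joint_fit(
    datasets: Mapping[str, MeasurementTable],
    mechanism: str,
    fixed: Optional[Mapping[str, float]] = None,
    *,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-14,
) -> Dict[str, FitResult]:
    """Fit several architectures at once with a single shared tsat.

    Each architecture keeps its own regulatory coupling, tbg, and
    per-promoter binding factors; tsat — a property of RNAP, not of the
    TF placement — is common.  Architectures whose data never approach
    saturation borrow tsat from those that do.
    """
    if len(datasets) < 2:
        raise ValueError("joint_fit needs at least two architectures")
    archs = sorted(datasets)
    prepared = {}
    for arch in archs:
        fx, free, used, excluded = _prepare(datasets[arch], mechanism, fixed)
        prepared[arch] = dict(fixed=fx, free=[n for n in free if n != "tsat"],
                              used=used, excluded=excluded)
    share_tsat = "tsat" not in (fixed or {})
    tm_all = {a: prepared[a]["used"].df["t_minus"].to_numpy() for a in archs}
    tp_all = {a: prepared[a]["used"].df["t_plus"].to_numpy() for a in archs}
    log_tm = np.concatenate([np.log10(tm_all[a]) for a in archs])
    log_tp = np.concatenate([np.log10(tp_all[a]) for a in archs])
    sizes = [len(tm_all[a]) for a in archs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def unpack(theta):
        theta = np.clip(theta, -_CLIP, _CLIP)
        pos = 0
        tsat = None
        if share_tsat:
            tsat = np.exp(theta[0])
            pos = 1
        scalars, Ps = {}, {}
        for a in archs:
            pr = prepared[a]
            s = dict(pr["fixed"])
            if share_tsat:
                s["tsat"] = tsat
            for name in pr["free"]:
                s[name] = np.exp(theta[pos])
                pos += 1
            scalars[a] = s
        for i, a in enumerate(archs):
            n = sizes[i]
            Ps[a] = np.exp(theta[pos:pos + n])
            pos += n
        return scalars, Ps

    def residuals(theta):
        scalars, Ps = unpack(theta)
        tm_parts, tp_parts = [], []
        for a in archs:
            tm, tp = _model_rates(mechanism, Ps[a], scalars[a])
            tm_parts.append(np.log10(tm))
            tp_parts.append(np.log10(tp))
        return np.concatenate([np.concatenate(tm_parts) - log_tm,
                               np.concatenate(tp_parts) - log_tp])

    # multistart over the shared tsat and per-architecture couplings
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=max(n_starts, 1))
    hi_tm = max(float(np.max(tm_all[a])) for a in archs)
    best = None
    for s_idx in range(max(n_starts, 1)):
        parts = []
        if s_idx == 0:
            tsat0 = (fixed or {}).get("tsat", 1.5 * hi_tm)
            if share_tsat:
                parts.append([np.log(tsat0)])
            for a in archs:
                pr = prepared[a]
                scal = _default_scalar_init(mechanism, tm_all[a], tp_all[a],
                                            {**pr["fixed"], "tsat": tsat0})
                parts.append([np.log(scal[name]) for name in pr["free"]])
            for a in archs:
                parts.append(np.log(_invert_t_minus(tm_all[a], tsat0, 0.5 * float(np.min(tm_all[a])))))
        else:
            sub = np.random.default_rng(sub_seeds[s_idx])
            tsat0 = (fixed or {}).get("tsat",
                                      float(np.exp(sub.uniform(np.log(0.8 * hi_tm), np.log(30 * hi_tm)))))
            if share_tsat:
                parts.append([np.log(tsat0)])
            for a in archs:
                pr = prepared[a]
                scal = _random_scalar_init(mechanism, tm_all[a], tp_all[a],
                                           {**pr["fixed"], "tsat": tsat0}, sub)
                parts.append([np.log(scal[name]) for name in pr["free"]])
            for a in archs:
                parts.append(np.log(_invert_t_minus(tm_all[a], tsat0, 0.5 * float(np.min(tm_all[a])))))
        theta0 = np.concatenate([np.asarray(p, dtype=float) for p in parts])
        try:
            res = least_squares(residuals, theta0, method="lm", xtol=tol, ftol=tol, gtol=tol)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("all optimization starts failed")

    scalars, Ps = unpack(best.x)
    results = {}
    for i, a in enumerate(archs):
        pr = prepared[a]
        df = pr["used"].df
        s = {k: float(v) for k, v in scalars[a].items()}
        free_names = (["tsat"] if share_tsat else []) + pr["free"]
        params = {name: s[name] for name in free_names}
        fixed_out = {k: v for k, v in s.items() if k not in params}
        tm, tp = _model_rates(mechanism, Ps[a], s)
        resid = np.concatenate([np.log10(tm) - np.log10(tm_all[a]),
                                np.log10(tp) - np.log10(tp_all[a])])
        results[a] = FitResult(
            mechanism=mechanism,
            params=params,
            fixed=fixed_out,
            P_by_promoter={pid: float(p) for pid, p in zip(df["promoter_id"], Ps[a])},
            residuals=resid,
            loss=float(np.sum(resid**2)),
            n_used=len(df),
            outliers_excluded=pr["excluded"],
            seed=seed,
            n_starts=n_starts,
            success=bool(best.success),
            message=str(best.message),
            architecture=a,
        )
    return results


# ---------------------------------------------------------------------------
# acceleration fit at fixed saturation rate


def fit_beta(
    data: MeasurementTable,
    tsat: float,
    F: float = np.inf,
    fixed: Optional[Mapping[str, float]] = None,
    **kwargs,
) -> FitResult:
    """Fit the acceleration model at a known saturation rate.

    beta is read off the strong-promoter plateau (t+ saturates at
    beta'*tsat while t- saturates at tsat), so tsat must come from an
    architecture whose data reach saturation.  A dataset with no fitted
    P above ~0.1 leaves beta essentially unconstrained and triggers a
    warning.
    """
    merged = {"tsat": float(tsat), "F": float(F), **(fixed or {})}
    result = fit_manifold(data, "acceleration", merged, **kwargs)
    if max(result.P_by_promoter.values()) < 0.1:
        warnings.warn(
            "no promoter reaches P ~ 0.1: beta is weakly identified by these data",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# bootstrap


_DG_VIEWS = {"F": "dg_F", "alpha": "dg_alpha"}


def bootstrap(
    data: MeasurementTable,
    mechanism: str,
    fixed: Optional[Mapping[str, float]] = None,
    *,
    n_boot: int = 100,
    seed: int = 0,
    n_starts: int = 10,
    max_failure_fraction: float = 0.2,
    tol: float = 1e-12,
) -> BootstrapEnsemble:
    """Resample promoters with replacement, refit, and collect the draws.

    The resampling unit is the promoter, i.e. its (t-, t+) pair.  Each
    replicate is warm-started at the full-data point estimate.  Draw
    columns include the fitted scalars and their free-energy views
    (dg_F, dg_alpha) where defined.  Seeded runs are reproducible.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = fit_manifold(data, mechanism, fixed, n_starts=n_starts, seed=seed, tol=tol)
    used = data.non_outliers()
    df = used.df
    n = len(df)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    rows = []
    n_failed = 0
    P_point = np.array([point.P_by_promoter[p] for p in df["promoter_id"]])
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = df.iloc[idx].reset_index(drop=True)
        # duplicated promoters are distinct resampled observations
        sub["promoter_id"] = [f"{p}#{i}" for i, p in enumerate(sub["promoter_id"])]
        table = MeasurementTable(sub)
        warm = {"scalars": {**point.fixed, **point.params}, "P": P_point[idx]}
        try:
            res = fit_manifold(table, mechanism, fixed, n_starts=1, seed=seed,
                               init=warm, tol=tol)
        except (FitFailureError, IdentifiabilityError):
            n_failed += 1
            continue
        row = dict(res.params)
        for pname, view in _DG_VIEWS.items():
            if pname in res.params:
                row[view] = thermo.dg_from_factor(res.params[pname])
        row["loss"] = res.loss
        rows.append(row)
    if n_failed > max_failure_fraction * n_boot:
        raise FitFailureError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to converge"
        )
    return BootstrapEnsemble(
        point=point,
        draws=pd.DataFrame(rows),
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# outlier detection


def detect_outliers(
    data: MeasurementTable,
    mechanism: str,
    fixed: Optional[Mapping[str, float]] = None,
    *,
    threshold: float = 0.5,
    max_flag_fraction: float = 0.25,
    seed: int = 0,
    n_starts: int = 10,
    f_scale: float = 0.1,
) -> MeasurementTable:
    """Flag promoters that deviate grossly from a robust preliminary fit.

    A soft-L1 fit downweights gross deviants, then any promoter whose
    larger |log10 residual| (over the two channels) exceeds ``threshold``
    (default 0.5, about 3.2-fold) is flagged.  Flags are recorded on the
    returned table, never silently dropped.  If more than
    ``max_flag_fraction`` of promoters would be flagged the data are
    deemed not to collapse to a manifold at all and :class:`CollapseError`
    is raised.
    """
    pre = fit_manifold(data, mechanism, fixed, n_starts=n_starts, seed=seed,
                       robust=True, f_scale=f_scale)
    used = data.non_outliers()
    n = used.n
    per_channel = pre.residuals.reshape(2, n)
    worst = np.abs(per_channel).max(axis=0)
    flagged = [pid for pid, w in zip(used.promoter_ids, worst) if w > threshold]
    if len(flagged) > max_flag_fraction * n:
        raise CollapseError(
            f"{len(flagged)}/{n} promoters deviate more than {threshold} decades from "
            "the robust fit: the data do not collapse to a 1D allelic manifold"
        )
    return data.with_outliers(flagged)


# ---------------------------------------------------------------------------
# titration across inducer concentrations


def titration_fit(
    datasets: Mapping[float, MeasurementTable],
    tsat: float,
    tbg: float,
    *,
    select: int = 4,
    n_boot: int = 0,
    seed: int = 0,
    n_starts: int = 10,
    tol: float = 1e-14,
) -> TitrationResult:
    """Per-concentration TF binding factors and their power-law exponent.

    Each concentration's manifold is fitted with tsat and tbg pinned
    (they do not depend on the inducer), leaving F and the per-promoter
    binding factors free.  The exponent is the ordinary least-squares
    slope of ln F against ln concentration over the ``select`` largest
    concentrations (weak-induction conditions give large, asymmetric F
    uncertainties), with a 95% confidence interval from the regression.
    """
    import statsmodels.api as sm

    if len(datasets) < 2:
        raise ValueError("titration_fit needs at least two concentrations")
    if select < 3:
        raise IdentifiabilityError(
            "slope confidence interval is undefined with fewer than 3 selected concentrations"
        )
    concs = sorted(float(c) for c in datasets)
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive")
    fits, F_hat, ci68 = {}, {}, {}
    for i, c in enumerate(concs):
        fx = {"tsat": float(tsat), "tbg": float(tbg)}
        if n_boot > 0:
            ens = bootstrap(datasets[c], "repression", fx, n_boot=n_boot,
                            seed=seed + i + 1, n_starts=n_starts)
            fits[c] = ens.point
            ci68[c] = ens.ci("F", 0.68)
        else:
            fits[c] = fit_manifold(datasets[c], "repression", fx,
                                   n_starts=n_starts, seed=seed, tol=tol)
        F_hat[c] = fits[c].params["F"]
    selected = concs[-select:]
    if len(selected) < 3:
        raise IdentifiabilityError(
            "slope confidence interval is undefined with fewer than 3 selected concentrations"
        )
    x = np.log([c for c in selected])
    y = np.log([F_hat[c] for c in selected])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    lo, hi = model.conf_int(alpha=0.05)[1]
    return TitrationResult(
        F_by_concentration=F_hat,
        exponent=slope,
        exponent_ci95=(float(lo), float(hi)),
        selected_concentrations=selected,
        fits=fits,
        ci68_F=ci68 if n_boot > 0 else None,
    )
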