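"""Nonlinear least-squares estimation of intrinsic pKa and solubility.

Two routes to the intrinsic parameters:

* :func:`fit_titration` — fit raw potentiometric curves directly against the
  full linked-equilibrium simulator (curves at several concentrations share
  one (pKa, S) pair);
* :func:`fit_shift_curve` — fit an observed-pKa-versus-concentration table
  against the model's predicted apparent pKa.

Both optimize in ``(pKa, log10 S)`` space (positivity and conditioning) with
bounded trust-region least squares and a small fixed set of restarts.
Uncertainty comes from a case-resampling percentile bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .equilibria import CompoundParams, Polarity, solve_ph_many
from .titration import (
    FittingError,
    ObservedPka,
    TitrationCurve,
    _composition_grid,
    observed_pka_vs_concentration,
)

__all__ = [
    "FitResult",
    "fit_titration",
    "fit_shift_curve",
    "bootstrap_ci",
    "bootstrap_titration_ci",
    "bootstrap_shift_ci",
]

logger = logging.getLogger(__name__)

_LOG10S_LO, _LOG10S_HI = -9.0, 3.0
# fixed restart offsets in (pka, log10 S); deterministic given init
_RESTART_OFFSETS = [(0.0, 0.0), (0.5, 1.0), (-0.5, -1.0), (1.0, 0.0), (0.0, -2.0)]


@dataclass
class FitResult:
    """Point estimates, optional bootstrap CIs and fit diagnostics."""

    pka_intrinsic_hat: float
    s_intrinsic_hat: float
    rmse: float
    n_points: int
    converged: bool
    s_identifiable: bool = True
    pka_ci: Optional[Tuple[float, float]] = None
    s_ci: Optional[Tuple[float, float]] = None
    ph_offset_hat: Optional[float] = None
    polarity: Polarity = Polarity.ACID
    pkw: float = 13.997
    message: str = ""

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        for ci, est in ((self.pka_ci, self.pka_intrinsic_hat),
                        (self.s_ci, self.s_intrinsic_hat)):
            if ci is not None and not (ci[0] <= est <= ci[1]):
                raise ValueError(f"CI {ci} does not contain estimate {est}")

    @property
    def params(self) -> CompoundParams:
        return CompoundParams(self.pka_intrinsic_hat, self.s_intrinsic_hat,
                              self.polarity, self.pkw)

    def to_dict(self) -> Dict:
        return {
            "pka_intrinsic_hat": self.pka_intrinsic_hat,
            "s_intrinsic_hat": self.s_intrinsic_hat,
            "pka_ci": list(self.pka_ci) if self.pka_ci else None,
            "s_ci": list(self.s_ci) if self.s_ci else None,
            "ph_offset_hat": self.ph_offset_hat,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "converged": self.converged,
            "s_identifiable": self.s_identifiable,
            "polarity": self.polarity.value,
            "pkw": self.pkw,
            "message": self.message,
        }


def _theta_to_params(theta, polarity: Polarity, pkw: float) -> CompoundParams:
    pka, log10_s = float(theta[0]), float(theta[1])
    s = math.inf if log10_s >= _LOG10S_HI else 10.0 ** log10_s
    return CompoundParams(pka, s, polarity, pkw)


def _run_restarts(resid, x0, bounds, n_restarts=len(_RESTART_OFFSETS)):
    """Bounded trust-region least squares from a fixed set of starts."""
    best = None
    for dpka, dls in _RESTART_OFFSETS[:max(1, n_restarts)]:
        x0_k = np.array(x0, dtype=float)
        x0_k[0] += dpka
        x0_k[1] += dls
        x0_k = np.clip(x0_k, bounds[0], bounds[1])
        try:
            sol = least_squares(resid, x0_k, bounds=bounds, method="trf")
        except (ValueError, FittingError) as err:  # pathological start
            logger.debug("restart at %s failed: %s", x0_k, err)
            continue
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol
    if best is None:
        raise FittingError("all restarts failed to produce a fit")
    return best


def _default_titration_init(curves, polarity: Polarity, pkw: float):
    # midpoint pH of the lowest-concentration curve approximates pKa;
    # start S at that concentration (shift onset heuristic)
    low = min(curves, key=lambda c: c.setup.c_total_initial)
    pka0 = float(np.clip(np.median(low.ph), 1.0, pkw - 1.0))
    log10_s0 = float(np.clip(math.log10(low.setup.c_total_initial),
                             _LOG10S_LO + 1, _LOG10S_HI - 1))
    return np.array([pka0, log10_s0])


def fit_titration(
    curves: Union[TitrationCurve, Sequence[TitrationCurve]],
    init: Optional[CompoundParams] = None,
    *,
    polarity: Union[str, Polarity] = Polarity.ACID,
    pkw: float = 13.997,
    fit_ph_offset: bool = False,
    weights: Optional[Sequence[np.ndarray]] = None,
    n_restarts: int = 5,
) -> FitResult:
    """Joint fit of (pKa, S) to one or more titration curves.

    Minimizes the summed squared pH residual between measured curves and the
    full-model simulation over ``(pKa, log10 S)``; curves at different
    concentrations share the thermodynamic parameters, which is what makes S
    identifiable.  An optional per-fit pH electrode offset can be enabled.

    A single curve well below the solubility never aggregates appreciably,
    so S is then unidentifiable: the estimate runs to the upper bound and the
    result is flagged (``s_identifiable=False``) rather than silently
    reported.
    """
    if isinstance(curves, TitrationCurve):
        curves = [curves]
    if not curves:
        raise ValueError("need at least one curve")
    if init is not None:
        polarity, pkw = init.polarity, init.pkw
    polarity = Polarity(polarity)
    grids = [_composition_grid(c.setup, polarity) for c in curves]
    obs = [np.asarray(c.ph, dtype=float) for c in curves]
    if weights is None:
        w_sqrt = [np.ones_like(o) for o in obs]
    else:
        w_sqrt = [np.sqrt(np.asarray(w, dtype=float)) for w in weights]
    n_points = int(sum(o.size for o in obs))

    def resid(theta):
        params = _theta_to_params(theta, polarity, pkw)
        offset = theta[2] if fit_ph_offset else 0.0
        parts = []
        for (c_tot, c_na, c_cl, _), ph_obs, ws in zip(grids, obs, w_sqrt):
            model = solve_ph_many(params, c_tot, c_na, c_cl) + offset
            parts.append((model - ph_obs) * ws)
        return np.concatenate(parts)

    if init is not None:
        s0 = (math.log10(init.s_intrinsic) if math.isfinite(init.s_intrinsic)
              else _LOG10S_HI)
        x0 = [init.pka_intrinsic, np.clip(s0, _LOG10S_LO, _LOG10S_HI)]
    else:
        x0 = _default_titration_init(curves, polarity, pkw)
    lo = [0.05, _LOG10S_LO]
    hi = [pkw - 0.05, _LOG10S_HI]
    if fit_ph_offset:
        x0 = list(x0) + [0.0]
        lo, hi = lo + [-1.0], hi + [1.0]
    sol = _run_restarts(resid, x0, (lo, hi), n_restarts)

    pka_hat, log10_s_hat = float(sol.x[0]), float(sol.x[1])
    # profile check: if switching aggregation off entirely and refitting pKa
    # costs essentially nothing, the data carry no information on S
    theta_a0 = np.array(sol.x, dtype=float)
    theta_a0[1] = _LOG10S_HI

    def a0_cost(pka):
        t = theta_a0.copy()
        t[0] = pka
        return float(np.sum(resid(t) ** 2))

    cost_a0 = minimize_scalar(a0_cost, bounds=(lo[0], hi[0]),
                              method="bounded").fun
    cost_best = float(2.0 * sol.cost)
    at_bound = log10_s_hat >= _LOG10S_HI - 0.1
    flat_profile = (cost_a0 - cost_best) <= max(0.02 * cost_a0, 1e-20)
    s_identifiable = not (at_bound or flat_profile)
    if not s_identifiable:
        logger.warning(
            "no usable aggregation signal (log10 S = %.2f, cost with A=0 "
            "within 2%% of the best fit); S is unidentifiable and any CI on "
            "it should be treated as unbounded", log10_s_hat)
    eff_n = float(sum(np.sum(w ** 2) for w in w_sqrt))
    rmse = float(np.sqrt(2.0 * sol.cost / eff_n))
    return FitResult(
        pka_intrinsic_hat=pka_hat,
        s_intrinsic_hat=math.inf if not s_identifiable and sol.x[1] >= _LOG10S_HI
        else 10.0 ** log10_s_hat,
        rmse=rmse,
        n_points=n_points,
        converged=bool(sol.success),
        s_identifiable=s_identifiable,
        ph_offset_hat=float(sol.x[2]) if fit_ph_offset else None,
        polarity=polarity,
        pkw=pkw,
        message=sol.message,
    )


def fit_shift_curve(
    observations: Sequence[ObservedPka],
    init: Optional[CompoundParams] = None,
    *,
    polarity: Union[str, Polarity] = Polarity.ACID,
    pkw: float = 13.997,
    rmse_flag_threshold: float = 0.1,
    n_restarts: int = 5,
) -> FitResult:
    """Fit (pKa, S) to an observed-pKa-versus-concentration table.

    The model prediction for each tabulated concentration is produced by the
    same pipeline used on data: simulate the standard titration, fit the
    no-aggregation model.  A poor fit (RMSE above ``rmse_flag_threshold`` pH
    units, e.g. from a wrong polarity) is flagged via ``converged=False``.
    """
    if len(observations) < 3:
        raise ValueError("need at least 3 concentrations")
    c = np.array([o.c_total for o in observations], dtype=float)
    y = np.array([o.value for o in observations], dtype=float)
    if np.log10(c.max() / c.min()) < 1.0 - 1e-9:
        raise ValueError("concentrations must span at least one decade")
    if init is not None:
        polarity, pkw = init.polarity, init.pkw
    polarity = Polarity(polarity)

    def resid(theta):
        params = _theta_to_params(theta, polarity, pkw)
        pred = observed_pka_vs_concentration(params, c)
        return np.array([p.value for p in pred]) - y

    if init is not None:
        s0 = (math.log10(init.s_intrinsic) if math.isfinite(init.s_intrinsic)
              else _LOG10S_HI)
        x0 = [init.pka_intrinsic, np.clip(s0, _LOG10S_LO, _LOG10S_HI)]
    else:
        # lowest concentration is closest to the intrinsic pKa; S from the
        # concentration where the shift first exceeds 0.1 pH
        order = np.argsort(c)
        pka0 = y[order[0]]
        shifted = np.abs(y[order] - pka0) > 0.1
        c_onset = c[order][np.argmax(shifted)] if shifted.any() else c.max()
        x0 = [np.clip(pka0, 1.0, pkw - 1.0),
              np.clip(math.log10(c_onset), _LOG10S_LO + 1, _LOG10S_HI - 1)]
    bounds = ([0.05, _LOG10S_LO], [pkw - 0.05, _LOG10S_HI])
    sol = _run_restarts(resid, x0, bounds, n_restarts)

    pka_hat, log10_s_hat = float(sol.x[0]), float(sol.x[1])
    rmse = float(np.sqrt(2.0 * sol.cost / c.size))
    s_identifiable = log10_s_hat < _LOG10S_HI - 0.1
    # all observations below the aggregation onset: shift range ~0
    if np.ptp(y) < 0.02 or log10_s_hat >= math.log10(c.max()) + 2:
        s_identifiable = False
    converged = bool(sol.success) and rmse <= rmse_flag_threshold
    message = sol.message
    if rmse > rmse_flag_threshold:
        message += (f"; RMSE {rmse:.3f} pH exceeds {rmse_flag_threshold}: "
                    "model/polarity may be misspecified")
    return FitResult(
        pka_intrinsic_hat=pka_hat,
        s_intrinsic_hat=10.0 ** log10_s_hat,
        rmse=rmse,
        n_points=int(c.size),
        converged=converged,
        s_identifiable=s_identifiable,
        polarity=polarity,
        pkw=pkw,
        message=message,
    )


def bootstrap_ci(
    fit: Callable[[Sequence], FitResult],
    data: Sequence,
    n_resamples: int = 200,
    seed: int = 0,
    min_cases: int = 3,
    level: float = 0.95,
) -> Dict[str, Tuple[float, float]]:
    """Case-resampling percentile bootstrap CIs for (pKa, S).

    ``fit`` maps a resampled list of cases to a :class:`FitResult`.
    Degenerate resamples (fewer than ``min_cases`` unique cases, or a failed
    fit) are redrawn, with a log record.  Reproducible under a fixed seed.
    """
    if n_resamples < 50:
        raise ValueError("n_resamples must be >= 50")
    rng = np.random.default_rng(seed)
    n = len(data)
    pkas, ss = [], []
    draws = 0
    while len(pkas) < n_resamples:
        draws += 1
        if draws > 20 * n_resamples:
            raise FittingError("bootstrap could not obtain enough valid resamples")
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size < min(min_cases, n):
            logger.info("degenerate resample redrawn (%d unique cases)",
                        np.unique(idx).size)
            continue
        try:
            res = fit([data[i] for i in idx])
        except (FittingError, ValueError) as err:
            logger.info("bootstrap resample failed and was redrawn: %s", err)
            continue
        pkas.append(res.pka_intrinsic_hat)
        ss.append(res.s_intrinsic_hat)
    alpha = (1.0 - level) / 2.0
    qs = [100 * alpha, 100 * (1 - alpha)]
    pka_ci = tuple(np.percentile(pkas, qs))
    s_ci = tuple(np.percentile(ss, qs))
    return {"pka_intrinsic": pka_ci, "s_intrinsic": s_ci}


def bootstrap_titration_ci(
    curves: Sequence[TitrationCurve],
    init: Optional[CompoundParams] = None,
    n_resamples: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> Dict[str, Tuple[float, float]]:
    """Bootstrap over titration points (multiplicity-weighted within curves)."""
    if n_resamples < 50:
        raise ValueError("n_resamples must be >= 50")
    rng = np.random.default_rng(seed)
    pkas, ss = [], []
    while len(pkas) < n_resamples:
        weights = []
        ok = True
        for c in curves:
            n = len(c)
            counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
            if np.count_nonzero(counts) < 5:
                ok = False
                break
            weights.append(counts.astype(float))
        if not ok:
            logger.info("degenerate titration resample redrawn")
            continue
        try:
            res = fit_titration(list(curves), init, weights=weights,
                                n_restarts=1, **fit_kwargs)
        except (FittingError, ValueError) as err:
            logger.info("bootstrap titration fit redrawn: %s", err)
            continue
        pkas.append(res.pka_intrinsic_hat)
        ss.append(res.s_intrinsic_hat)
    pka_ci = tuple(np.percentile(pkas, [2.5, 97.5]))
    s_ci = tuple(np.percentile(ss, [2.5, 97.5]))
    return {"pka_intrinsic": pka_ci, "s_intrinsic": s_ci}


def bootstrap_shift_ci(
    observations: Sequence[ObservedPka],
    init: Optional[CompoundParams] = None,
    n_resamples: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> Dict[str, Tuple[float, float]]:
    """Bootstrap over the concentrations of a shift table."""
    def fit(cases):
        c = [o.c_total for o in cases]
        if np.log10(max(c) / min(c)) < 1.0 - 1e-9:
            raise FittingError("resample spans less than a decade")
        return fit_shift_curve(cases, init, n_restarts=1, **fit_kwargs)

    return bootstrap_ci(fit, list(observations), n_resamples, seed)
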