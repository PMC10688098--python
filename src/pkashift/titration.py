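"""Potentiometric titration simulation, observed-pKa extraction, Bjerrum plots.

The experimental design emulated here: the compound is first driven fully
into its soluble charged form with an excess of strong base (acids; strong
acid for bases), then titrated back with aliquots of concentrated strong
titrant while pH is recorded after each injection.  All concentrations are
dilution-corrected exactly — moles of Na, Cl and compound are conserved and
rescaled by the growing volume.

"Observed pKa" is operationally defined throughout the package as the
least-squares best-fit pKa of the *no-aggregation* (A = 0) model to a curve,
with pKa the only free parameter — the construction used to read an apparent
pKa off a titration regardless of whether aggregation shifted it.  A Bjerrum
midpoint reading is provided as an independent secondary method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .equilibria import (
    CompoundParams,
    EquilibriumError,
    Polarity,
    SolutionComposition,
    solve_ph_many,
)

__all__ = [
    "TitrantKind",
    "PkaMethod",
    "TitrationSetup",
    "TitrationCurve",
    "ObservedPka",
    "BjerrumPoint",
    "FittingError",
    "standard_setup",
    "simulate_titration",
    "observed_pka_from_curve",
    "observed_pka_vs_concentration",
    "bjerrum_from_curve",
    "titrant_from_bjerrum",
]


class TitrantKind(str, Enum):
    STRONG_ACID = "strong_acid"
    STRONG_BASE = "strong_base"


class PkaMethod(str, Enum):
    TITRATION_FIT = "titration_fit"
    SPECTRO_FIT = "spectro_fit"
    BJERRUM_MIDPOINT = "bjerrum_midpoint"


class FittingError(RuntimeError):
    """Raised when a curve cannot support the requested fit."""


@dataclass(frozen=True)
class TitrationSetup:
    """Geometry and reagent schedule of one potentiometric titration.

    Defaults mirror the standard design: 2.5 mL of analyte pre-charged with
    1.5 equivalents of strong base (0.5 equiv excess past full
    deprotonation), titrated with 25 aliquots of 10 uL of strong acid.
    """

    c_total_initial: float
    titrant_concentration: float
    titrant_kind: TitrantKind = TitrantKind.STRONG_ACID
    pre_added_equivalents: float = 1.5
    v_initial: float = 2.5e-3
    injection_volume: float = 10e-6
    n_injections: int = 25

    def __post_init__(self) -> None:
        object.__setattr__(self, "titrant_kind", TitrantKind(self.titrant_kind))
        for name in ("c_total_initial", "titrant_concentration", "v_initial",
                     "injection_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.pre_added_equivalents < 0:
            raise ValueError("pre_added_equivalents must be >= 0")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")

    @property
    def total_equivalents(self) -> float:
        """Total titrant delivered, in mol per mol of compound."""
        return (self.n_injections * self.injection_volume
                * self.titrant_concentration
                / (self.c_total_initial * self.v_initial))


def standard_setup(
    c_total: float,
    *,
    total_equivalents: float = 2.5,
    pre_added_equivalents: float = 1.5,
    titrant_kind: TitrantKind = TitrantKind.STRONG_ACID,
    v_initial: float = 2.5e-3,
    injection_volume: float = 10e-6,
    n_injections: int = 25,
) -> TitrationSetup:
    """The standard design at a given compound concentration.

    The titrant concentration is chosen so the full schedule delivers
    ``total_equivalents`` (default 2.5, comfortably spanning the transition
    that runs from 0.5 to 1.5 equivalents after the 1.5-equiv pre-charge).
    """
    titrant_conc = (total_equivalents * c_total * v_initial
                    / (n_injections * injection_volume))
    return TitrationSetup(
        c_total_initial=c_total,
        titrant_concentration=titrant_conc,
        titrant_kind=TitrantKind(titrant_kind),
        pre_added_equivalents=pre_added_equivalents,
        v_initial=v_initial,
        injection_volume=injection_volume,
        n_injections=n_injections,
    )


@dataclass(frozen=True)
class TitrationCurve:
    """Ordered (titrant added in equivalents, pH) observations plus setup."""

    titrant_added: np.ndarray  # mol titrant per mol compound, cumulative
    ph: np.ndarray
    setup: TitrationSetup

    def __post_init__(self) -> None:
        object.__setattr__(self, "titrant_added",
                           np.asarray(self.titrant_added, dtype=float))
        object.__setattr__(self, "ph", np.asarray(self.ph, dtype=float))
        if self.titrant_added.shape != self.ph.shape:
            raise ValueError("titrant_added and ph must have equal length")
        if np.any(np.diff(self.titrant_added) <= 0):
            raise ValueError("titrant_added must be strictly increasing")

    def __len__(self) -> int:
        return self.titrant_added.size

    @property
    def points(self) -> List[Tuple[float, float]]:
        return list(zip(self.titrant_added.tolist(), self.ph.tolist()))


@dataclass(frozen=True)
class ObservedPka:
    """An apparent pKa bound to the total concentration it was measured at."""

    value: float
    c_total: float
    method: PkaMethod

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", PkaMethod(self.method))


@dataclass(frozen=True)
class BjerrumPoint:
    """Bound hydrogen ions per compound molecule at one pH."""

    ph: float
    n_bound: float


def _composition_grid(
    setup: TitrationSetup, polarity: Polarity
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(c_total, c_na, c_cl, equivalents) after each injection, 0..n.

    Bookkeeping by conserved moles, rescaled by the running volume.  For an
    acid the pre-charge is NaOH and the titrant HCl; for a base the
    pre-charge is HCl and the titrant NaOH.  The pre-charge is dissolved in
    the initial volume (no extra volume attributed to it).
    """
    k = np.arange(setup.n_injections + 1)
    v = setup.v_initial + k * setup.injection_volume
    n_compound = setup.c_total_initial * setup.v_initial
    n_pre = setup.pre_added_equivalents * n_compound
    n_titrant = k * setup.injection_volume * setup.titrant_concentration
    if polarity is Polarity.ACID:
        if setup.titrant_kind is not TitrantKind.STRONG_ACID:
            raise ValueError("acid compounds are titrated with strong acid "
                             "after pre-deprotonation with strong base")
        n_na, n_cl = n_pre, n_titrant
    else:
        if setup.titrant_kind is not TitrantKind.STRONG_BASE:
            raise ValueError("base compounds are titrated with strong base "
                             "after pre-protonation with strong acid")
        n_na, n_cl = n_titrant, n_pre
    equivalents = n_titrant / n_compound
    return n_compound / v, n_na / v, n_cl / v, equivalents


def simulate_titration(
    params: CompoundParams, setup: TitrationSetup
) -> TitrationCurve:
    """Model titration curve: one pH point before and after each injection.

    Each point updates the strong-electrolyte totals and compound
    concentration with exact dilution, then solves the charge balance for
    pH.  A tiny strictly increasing epsilon is used for the pre-injection
    abscissa offsetting nothing (equivalents start at 0).
    """
    c_total, c_na, c_cl, equiv = _composition_grid(setup, params.polarity)
    try:
        ph = solve_ph_many(params, c_total, c_na, c_cl)
    except EquilibriumError as err:
        raise EquilibriumError(f"titration solve failed: {err}") from err
    return TitrationCurve(titrant_added=equiv, ph=ph, setup=setup)


def observed_pka_from_curve(
    curve: TitrationCurve,
    params_hint: CompoundParams,
) -> ObservedPka:
    """Apparent pKa by least-squares fit of the no-aggregation model.

    Re-simulates the curve's own schedule with A = 0 and a trial pKa, and
    minimizes the summed squared pH residual over pKa alone (pH is the
    measured quantity; titrant volume is controlled).  This is the package's
    operational definition of "observed pKa".
    """
    if len(curve) < 5:
        raise FittingError("need at least 5 points spanning the transition")
    setup = curve.setup
    polarity = params_hint.polarity
    c_total, c_na, c_cl, _ = _composition_grid(setup, polarity)
    ideal = params_hint.without_aggregation()
    pkw = params_hint.pkw

    def loss(pka: float) -> float:
        model_ph = solve_ph_many(ideal.with_pka(pka), c_total, c_na, c_cl)
        return float(np.sum((model_ph - curve.ph) ** 2))

    res = minimize_scalar(loss, bounds=(0.05, pkw - 0.05), method="bounded",
                          options={"xatol": 1e-7})
    pka_obs = float(res.x)
    rmse = math.sqrt(res.fun / len(curve))
    span = float(np.ptp(curve.ph))
    if span <= 0 or rmse > 0.25 * span:
        raise FittingError(
            f"no-aggregation model cannot follow the curve (fit RMSE "
            f"{rmse:.3f} pH over a {span:.3f} pH span); the curve does not "
            "trace a protonation transition"
        )
    return ObservedPka(pka_obs, setup.c_total_initial, PkaMethod.TITRATION_FIT)


def observed_pka_vs_concentration(
    params: CompoundParams,
    c_list: Sequence[float],
    *,
    total_equivalents: float = 2.5,
) -> List[ObservedPka]:
    """Apparent pKa across total concentrations via the standard titration.

    For each concentration, simulates the standard design and extracts the
    A = 0 fit pKa.  For acids the result is non-decreasing in concentration,
    for bases non-increasing, converging to the intrinsic pKa at infinite
    dilution.
    """
    out = []
    kind = (TitrantKind.STRONG_ACID if params.polarity is Polarity.ACID
            else TitrantKind.STRONG_BASE)
    for c in c_list:
        if not (c > 0 and math.isfinite(c)):
            raise ValueError(f"concentrations must be positive and finite, got {c}")
        setup = standard_setup(c, total_equivalents=total_equivalents,
                               titrant_kind=kind)
        curve = simulate_titration(params, setup)
        out.append(observed_pka_from_curve(curve, params))
    return out


def _reference_level(polarity: Polarity) -> float:
    # chosen so the fully deprotonated state maps to 0 bound protons:
    # acids start deprotonated (r = 1 cancels the full anion charge),
    # bases end deprotonated (r = 0).
    return 1.0 if polarity is Polarity.ACID else 0.0


def bjerrum_from_curve(
    curve: TitrationCurve,
    pkw: float = 13.997,
) -> List[BjerrumPoint]:
    """Bound protons per compound molecule from titrant bookkeeping.

    ``n_bound = (strong acid − strong base − [H+] + [OH−]) / C + r`` with
    free H+/OH− from the measured pH, all dilution-corrected, and the
    reference level ``r`` pinning the fully deprotonated state at 0.  The
    compound polarity is inferred from the titrant direction (acids are
    titrated with strong acid, bases with strong base).
    """
    setup = curve.setup
    if setup.c_total_initial <= 0:
        raise ValueError("n_bound is undefined for c_total = 0")
    polarity = (Polarity.ACID if setup.titrant_kind is TitrantKind.STRONG_ACID
                else Polarity.BASE)
    c_total, c_na, c_cl, _ = _composition_grid(setup, polarity)
    h = 10.0 ** (-curve.ph)
    oh = 10.0 ** (curve.ph - pkw)
    n_bound = (c_cl - c_na - h + oh) / c_total + _reference_level(polarity)
    return [BjerrumPoint(float(p), float(n)) for p, n in zip(curve.ph, n_bound)]


def bjerrum_midpoint_pka(points: Sequence[BjerrumPoint]) -> float:
    """pH at half-protonation (n_bound = 0.5), by monotone interpolation."""
    ph = np.array([p.ph for p in points])
    nb = np.array([p.n_bound for p in points])
    order = np.argsort(nb)
    nb_s, ph_s = nb[order], ph[order]
    if not (nb_s[0] <= 0.5 <= nb_s[-1]):
        raise FittingError("Bjerrum points do not bracket n_bound = 0.5")
    return float(np.interp(0.5, nb_s, ph_s))


def titrant_from_bjerrum(
    points: Sequence[BjerrumPoint],
    setup: TitrationSetup,
    pkw: float = 13.997,
) -> List[Tuple[float, float]]:
    """Reconstruct cumulative titrant equivalents from a Bjerrum plot.

    Exact closed-form inverse of :func:`bjerrum_from_curve` including the
    dilution correction (the running volume depends linearly on the titrant
    delivered, so the inversion reduces to a linear equation per point).
    Useful for reverse-engineering titrant schedules from published Bjerrum
    plots.  Returns (titrant_added in equivalents, pH) pairs.
    """
    polarity = (Polarity.ACID if setup.titrant_kind is TitrantKind.STRONG_ACID
                else Polarity.BASE)
    c0 = setup.c_total_initial
    ct = setup.titrant_concentration
    pre = setup.pre_added_equivalents
    r = _reference_level(polarity)
    out: List[Tuple[float, float]] = []
    for p in points:
        if not math.isfinite(p.n_bound):
            raise ValueError(f"non-physical n_bound {p.n_bound}")
        h = 10.0 ** (-p.ph)
        oh = 10.0 ** (p.ph - pkw)
        w = h - oh
        # n_bound - r = ±(e - pre) - w·V(e)/(V0·C0), V(e)/V0 = 1 + e·C0/Ct
        if polarity is Polarity.ACID:
            e = ((p.n_bound - r) + pre + w / c0) / (1.0 - w / ct)
        else:
            e = (pre - (p.n_bound - r) - w / c0) / (1.0 + w / ct)
        out.append((float(e), p.ph))
    return out
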