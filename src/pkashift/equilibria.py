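"""Core speciation and charge-balance machinery.

An ionizable compound is modeled in three forms that coexist at equilibrium:
the dissolved charged form, the dissolved neutral form, and the aggregated
(undissolved) neutral form, the latter entering the equilibria through its
*active concentration* — amount of aggregate divided by solution volume.

Two linked equilibria govern the system:

* proton dissociation of the single ionizable site,
  ``Ka = [charged][H+] / [neutral]`` for acids (mirrored for bases), and
* dissolution–aggregation of the neutral form, with mass-action law
  ``[aggregate] = A * C * [neutral]`` where ``C`` is the total added compound
  and ``A = 1/S`` is the aggregation constant, inversely proportional to the
  intrinsic solubility ``S``.

The second law makes the dissolved neutral concentration saturate at ``S`` as
``C → ∞`` (which is what "intrinsic solubility" means) while letting all three
forms coexist at any pH and any total concentration.  Its immediate
consequence is the concentration-dependent apparent pKa,
``pKa_app = pKa ± log10(1 + C/S)`` (``+`` for acids, ``−`` for bases).

pH during a titration follows from electroneutrality over Na+, H+, Cl−, OH−
and the compound's charged form; the residual of that balance is strictly
monotone in pH, so the root is unique and is found by bracketed bisection.
Activity coefficients are taken as 1 throughout (ideal solution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "Polarity",
    "CompoundParams",
    "SpeciesState",
    "SolutionComposition",
    "EquilibriumError",
    "aggregate_link",
    "aggregate_link_inverse",
    "species_at_ph",
    "charge_balance_residual",
    "solve_ph",
    "solve_ph_many",
]

PKW_25C = 13.997  # ionic product of water at 25 degC, mol^2/L^2 scale


class EquilibriumError(ValueError):
    """Raised when an equilibrium problem has no physical solution."""


class Polarity(str, Enum):
    """Which protonation state the aggregation-prone neutral form is.

    ``acid``: the neutral form is protonated (phenols, carboxylic acids);
    deprotonation yields the soluble anion and the apparent pKa shifts
    alkaline with concentration.  ``base``: the neutral form is deprotonated
    (amines); protonation yields the soluble cation and the shift is acidic.
    """

    ACID = "acid"
    BASE = "base"


def _as_polarity(polarity: Union[str, Polarity]) -> Polarity:
    return Polarity(polarity)


@dataclass(frozen=True)
class CompoundParams:
    """Intrinsic thermodynamic description of one monoprotic compound.

    Parameters
    ----------
    pka_intrinsic:
        −log10 of the acid-dissociation constant of the dissolved species
        (mol/L scale); concentration-independent by construction.
    s_intrinsic:
        Intrinsic solubility of the neutral form, mol/L.  ``math.inf`` means
        the neutral form never aggregates.
    polarity:
        Whether the neutral form is the protonated (``acid``) or the
        deprotonated (``base``) species.
    pkw:
        −log10 of the ionic product of water; default 13.997 (25 degC).
    """

    pka_intrinsic: float
    s_intrinsic: float = math.inf
    polarity: Polarity = Polarity.ACID
    pkw: float = PKW_25C

    def __post_init__(self) -> None:
        object.__setattr__(self, "polarity", _as_polarity(self.polarity))
        if not self.pkw > 0:
            raise ValueError(f"pkw must be positive, got {self.pkw}")
        if not 0 < self.pka_intrinsic < self.pkw:
            raise ValueError(
                f"pka_intrinsic must lie in (0, pkw={self.pkw}), "
                f"got {self.pka_intrinsic}"
            )
        if not self.s_intrinsic > 0:
            raise ValueError(f"s_intrinsic must be positive, got {self.s_intrinsic}")

    @property
    def a_aggregation(self) -> float:
        """Aggregation constant ``A = 1/S`` in L/mol; 0 when S is infinite."""
        return aggregate_link(self.s_intrinsic)

    @property
    def ka(self) -> float:
        return 10.0 ** (-self.pka_intrinsic)

    @property
    def kw(self) -> float:
        return 10.0 ** (-self.pkw)

    @classmethod
    def from_aggregation(
        cls,
        pka_intrinsic: float,
        a_aggregation: float,
        polarity: Union[str, Polarity] = Polarity.ACID,
        pkw: float = PKW_25C,
    ) -> "CompoundParams":
        """Build params from the aggregation constant instead of solubility."""
        if a_aggregation < 0:
            raise ValueError(f"a_aggregation must be >= 0, got {a_aggregation}")
        s = math.inf if a_aggregation == 0 else aggregate_link_inverse(a_aggregation)
        return cls(pka_intrinsic, s, polarity, pkw)

    def without_aggregation(self) -> "CompoundParams":
        """The same compound with aggregation switched off (A = 0)."""
        return replace(self, s_intrinsic=math.inf)

    def with_pka(self, pka: float) -> "CompoundParams":
        return replace(self, pka_intrinsic=pka)


def aggregate_link(s_intrinsic: float) -> float:
    """Aggregation constant from intrinsic solubility: ``A = 1/S`` (L/mol).

    ``A`` is inversely proportional to the intrinsic solubility; with the
    mass-action law ``[agg] = A·C·[neutral]`` this makes ``S`` the saturating
    value of the dissolved neutral concentration.  ``S = ∞`` maps to ``A = 0``
    (no aggregation).  The relation is bijective on (0, ∞].
    """
    if not s_intrinsic > 0:
        raise ValueError(f"s_intrinsic must be positive, got {s_intrinsic}")
    if math.isinf(s_intrinsic):
        return 0.0
    return 1.0 / s_intrinsic


def aggregate_link_inverse(a_aggregation: float) -> float:
    """Intrinsic solubility from the aggregation constant: ``S = 1/A``."""
    if a_aggregation < 0:
        raise ValueError(f"a_aggregation must be >= 0, got {a_aggregation}")
    if a_aggregation == 0:
        return math.inf
    return 1.0 / a_aggregation


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (mol/L) of all species at one condition."""

    c_neutral_dissolved: float
    c_charged: float
    c_aggregate: float
    c_h: float
    c_oh: float
    ph: float


@dataclass(frozen=True)
class SolutionComposition:
    """Strong-electrolyte bookkeeping for one solution state.

    All fields are analytical (total added) concentrations in mol/L at the
    current volume.  When strong acid is HCl, increments of ``c_cl`` equal
    increments of ``c_h_added`` because the ions are added together.
    """

    c_total: float = 0.0
    c_na: float = 0.0
    c_cl: float = 0.0
    c_h_added: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_total", "c_na", "c_cl", "c_h_added"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def species_at_ph(
    params: CompoundParams, c_total: float, ph: Union[float, np.ndarray]
):
    """Equilibrium speciation at a fixed (buffered) pH.

    Solves mass balance ``C = [neutral] + [charged] + [aggregate]`` jointly
    with the two mass-action laws at the given pH, the regime of the
    spectrophotometric experiments where a buffer pins the pH.  Closed form:
    for an acid, ``[neutral] = C / (1 + Ka/[H+] + A·C)``, the charged form
    carries the ``Ka/[H+]`` share and the aggregate the ``A·C`` share (bases
    mirrored with ``[H+]/Ka``).

    Accepts a scalar or an array of pH values; returns a ``SpeciesState``
    (with array fields for array input).
    """
    if np.any(np.asarray(c_total) < 0):
        raise ValueError(f"c_total must be >= 0, got {c_total}")
    ph_arr = np.asarray(ph, dtype=float)
    if np.any(ph_arr <= 0) or np.any(ph_arr >= params.pkw):
        raise ValueError(f"ph must lie in (0, pkw={params.pkw})")
    h = 10.0 ** (-ph_arr)
    oh = 10.0 ** (ph_arr - params.pkw)
    a = params.a_aggregation
    if params.polarity is Polarity.ACID:
        ratio = params.ka / h  # [charged]/[neutral]
    else:
        ratio = h / params.ka
    denom = 1.0 + ratio + a * c_total
    neutral = c_total / denom
    charged = ratio * neutral
    aggregate = a * c_total * neutral
    if np.ndim(ph) == 0 and np.ndim(c_total) == 0:
        return SpeciesState(
            float(neutral), float(charged), float(aggregate),
            float(h), float(oh), float(ph_arr),
        )
    return SpeciesState(neutral, charged, aggregate, h, oh, ph_arr)


def charge_balance_residual(
    state: SpeciesState,
    comp: SolutionComposition,
    polarity: Union[str, Polarity],
) -> float:
    """Cations minus anions, mol/L; zero at true equilibrium.

    Counts Na+, H+, Cl−, OH− and the compound's charged form (anion for
    acids, cation for bases).  ``c_h_added`` does not appear directly: added
    protons are already distributed among H+, the neutral form and water.
    """
    res = comp.c_na + state.c_h - comp.c_cl - state.c_oh
    if _as_polarity(polarity) is Polarity.ACID:
        res -= state.c_charged
    else:
        res += state.c_charged
    return res


def _residual_at_ph(params: CompoundParams, comp, ph):
    """Charge-balance residual as a function of pH (vectorized).

    Strictly decreasing in pH for both polarities: H+ falls, OH− rises, the
    anionic form rises (acid) / the cationic form falls (base).
    """
    h = 10.0 ** (-np.asarray(ph, dtype=float))
    oh = 10.0 ** (np.asarray(ph, dtype=float) - params.pkw)
    a = params.a_aggregation
    c_total = comp.c_total
    if params.polarity is Polarity.ACID:
        ratio = params.ka / h
    else:
        ratio = h / params.ka
    charged = ratio * c_total / (1.0 + ratio + a * c_total)
    res = comp.c_na + h - comp.c_cl - oh
    return res - charged if params.polarity is Polarity.ACID else res + charged


_PH_MARGIN = 1e-9
_BISECT_ITER = 80  # pH interval 14 / 2^80 — converges to float precision


def solve_ph_many(
    params: CompoundParams,
    c_total: np.ndarray,
    c_na: np.ndarray,
    c_cl: np.ndarray,
) -> np.ndarray:
    """Vectorized pH solve for arrays of solution compositions.

    Bracketed bisection on pH over (0, pkw) exploiting the strict
    monotonicity of the charge-balance residual; all points iterate in
    lockstep, so a whole titration curve solves in one call.
    """
    c_total = np.asarray(c_total, dtype=float)
    c_na = np.asarray(c_na, dtype=float)
    c_cl = np.asarray(c_cl, dtype=float)
    comp = _ArrayComp(c_total, c_na, c_cl)
    lo = np.full(np.broadcast(c_total, c_na, c_cl).shape, _PH_MARGIN)
    hi = np.full_like(lo, params.pkw - _PH_MARGIN)
    f_lo = _residual_at_ph(params, comp, lo)
    f_hi = _residual_at_ph(params, comp, hi)
    bad = (f_lo < 0) | (f_hi > 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise EquilibriumError(
            "charge-balance residual does not change sign on (0, pkw): "
            f"c_total={c_total.flat[i] if c_total.ndim else float(c_total):.4g}, "
            f"c_na={c_na.flat[i] if c_na.ndim else float(c_na):.4g}, "
            f"c_cl={c_cl.flat[i] if c_cl.ndim else float(c_cl):.4g} "
            "is not a physically realizable composition"
        )
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        f_mid = _residual_at_ph(params, comp, mid)
        take_hi = f_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi)


class _ArrayComp:
    """Duck-typed SolutionComposition over arrays for the vectorized solver."""

    __slots__ = ("c_total", "c_na", "c_cl")

    def __init__(self, c_total, c_na, c_cl):
        self.c_total = c_total
        self.c_na = c_na
        self.c_cl = c_cl


def solve_ph(params: CompoundParams, comp: SolutionComposition) -> SpeciesState:
    """pH and full speciation of an unbuffered solution.

    Finds the unique pH at which the charge balance closes, then evaluates
    the speciation there.  Converges to float precision in pH, so the
    residual of the returned state is at rounding level (≪ 1e−12 mol/L).
    """
    ph = solve_ph_many(
        params,
        np.asarray(comp.c_total),
        np.asarray(comp.c_na),
        np.asarray(comp.c_cl),
    )
    return species_at_ph(params, comp.c_total, float(ph))
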