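"""Spectrophotometric observed-pKa workflow.

Absorbance spectra are recorded over a pH series in a universal buffer at a
set of total compound concentrations.  Samples are centrifuged before the
measurement, so only the two *dissolved* species contribute to the
absorbance; the aggregate is spun out.  At a wavelength where the two
dissolved species differ in extinction, the absorbance traces out a
single-site protonation sigmoid in pH whose midpoint is the observed pKa —
shifted from the intrinsic value when aggregation withdraws neutral form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .equilibria import Polarity
from .titration import FittingError, ObservedPka, PkaMethod

__all__ = [
    "SpectraSet",
    "select_wavelength",
    "normalized_transition",
    "fit_observed_pka_spectro",
]

COLUMNS = ["c_total_M", "pH", "wavelength_nm", "absorbance"]


@dataclass(frozen=True)
class SpectraSet:
    """Tidy absorbance records: (c_total, pH, wavelength, absorbance)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"spectra table is missing columns {missing}")
        if not np.all(np.isfinite(self.data["absorbance"])):
            raise ValueError("absorbance values must be finite")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.sort(self.data["wavelength_nm"].unique())

    @property
    def ph_values(self) -> np.ndarray:
        return np.sort(self.data["pH"].unique())

    @property
    def c_totals(self) -> np.ndarray:
        return np.sort(self.data["c_total_M"].unique())


def select_wavelength(
    spectra: SpectraSet,
    c_total: Optional[float] = None,
    min_contrast: float = 0.01,
) -> float:
    """Wavelength with maximal absorbance contrast between the pH extremes.

    Picks the wavelength maximizing |A(pH_max) − A(pH_min)| (averaged over
    concentrations unless one is given), the standard choice for a two-state
    transition — by construction never an isosbestic wavelength.
    """
    df = spectra.data
    if c_total is not None:
        df = df[np.isclose(df["c_total_M"], c_total)]
        if df.empty:
            raise ValueError(f"no spectra at c_total = {c_total}")
    ph = np.sort(df["pH"].unique())
    if ph.size < 2:
        raise ValueError("need spectra at two or more pH values")
    lo = df[df["pH"] == ph[0]].groupby("wavelength_nm")["absorbance"].mean()
    hi = df[df["pH"] == ph[-1]].groupby("wavelength_nm")["absorbance"].mean()
    contrast = (hi - lo).abs().dropna()
    if contrast.empty:
        raise ValueError("pH extremes share no wavelengths")
    best = float(contrast.idxmax())
    if contrast.max() < min_contrast:
        warnings.warn(
            f"maximum pH contrast {contrast.max():.4g} AU is below "
            f"{min_contrast}; spectra are nearly pH-insensitive",
            stacklevel=2,
        )
        raise ValueError("flat spectra: no pH-sensitive wavelength")
    return best


def normalized_transition(
    spectra: SpectraSet,
    wavelength: float,
    c_total: float,
) -> List[Tuple[float, float]]:
    """Min–max normalized absorbance across the pH series.

    At a fixed concentration and wavelength, maps the absorbance series onto
    [0, 1]; gain and offset of the instrument cancel.  Returns (pH,
    normalized absorbance) sorted by pH.
    """
    df = spectra.data
    sel = df[np.isclose(df["wavelength_nm"], wavelength)
             & np.isclose(df["c_total_M"], c_total)]
    if sel.empty:
        raise ValueError(
            f"no records at wavelength {wavelength} nm, c_total {c_total} M")
    sel = sel.sort_values("pH")
    a = sel["absorbance"].to_numpy(dtype=float)
    span = a.max() - a.min()
    if span <= 0:
        raise ValueError("zero dynamic range: absorbance is constant over pH")
    norm = (a - a.min()) / span
    return list(zip(sel["pH"].tolist(), norm.tolist()))


def fit_observed_pka_spectro(
    transition: Sequence[Tuple[float, float]],
    polarity: Union[str, Polarity] = Polarity.ACID,
    c_total: float = float("nan"),
) -> ObservedPka:
    """Observed pKa as the midpoint of the single-site sigmoid.

    Fits ``y = 1 / (1 + 10^(±(pKa_obs − pH)))`` by least squares with the
    midpoint as the only free parameter; the branch (rising or falling with
    pH) is chosen from the data so either assignment of the normalized
    endpoints works.
    """
    pts = np.asarray(transition, dtype=float)
    if pts.shape[0] < 5:
        raise FittingError("need at least 5 (pH, normalized) points")
    ph, y = pts[:, 0], pts[:, 1]
    if y.max() - y.min() < 0.6:
        raise FittingError(
            "transition spans less than 0.6 of the normalized range; "
            "data do not bracket the midpoint")
    # orient so y increases with pH (fraction of the high-pH species)
    rising = np.corrcoef(ph, y)[0, 1] >= 0
    y_fit = y if rising else 1.0 - y

    def resid(theta):
        return 1.0 / (1.0 + 10.0 ** (theta[0] - ph)) - y_fit

    res = least_squares(resid, x0=[float(np.interp(0.5, np.sort(y_fit),
                                                   ph[np.argsort(y_fit)]))],
                        bounds=([ph.min() - 2.0], [ph.max() + 2.0]))
    pka = float(res.x[0])
    if not (ph.min() - 1.0 <= pka <= ph.max() + 1.0):
        raise FittingError(
            f"fitted midpoint {pka:.3f} outside measured pH range; "
            "transition is not bracketed")
    return ObservedPka(pka, c_total, PkaMethod.SPECTRO_FIT)
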