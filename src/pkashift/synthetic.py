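"""Synthetic data with known ground truth.

Emulates the three experimental designs the package analyzes — replicate
potentiometric titrations, a universal-buffer UV–vis pH series, and
observed-pKa-versus-concentration tables — so that every fitting routine can
be exercised against a known truth.  Measurement error is i.i.d. Gaussian:
on pH for titrations (electrode read noise), on absorbance for spectra, on
the tabulated pKa for shift tables.  Instrument drift, electrode hysteresis
and carbonate contamination are deliberately not modeled.

A single master seed deterministically derives an independent stream per
dataset, so regenerating any one artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .equilibria import CompoundParams, Polarity, species_at_ph
from .spectro import COLUMNS, SpectraSet
from .titration import (
    ObservedPka,
    PkaMethod,
    TitrationCurve,
    TitrationSetup,
    TitrantKind,
    observed_pka_vs_concentration,
    simulate_titration,
    standard_setup,
)

__all__ = [
    "ExtinctionModel",
    "GeneratorConfig",
    "generate_titration",
    "generate_spectra",
    "generate_shift_table",
]

# universal-buffer pH series: 4.5 to 10.5 at every 0.5 unit
DEFAULT_PH_GRID = tuple(np.arange(4.5, 10.5 + 1e-9, 0.5).round(2))
# total added concentrations, mol/L: 0.025 to 2 mM
DEFAULT_SPECTRO_C = (25e-6, 50e-6, 100e-6, 200e-6, 500e-6, 1e-3, 2e-3)


def _gaussian_band(wl, center, width, eps_max):
    return eps_max * np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass(frozen=True)
class ExtinctionModel:
    """Molar extinction profiles (L mol−1 cm−1) of the two dissolved species.

    Defaults mimic a phenol/phenolate pair: deprotonation red-shifts the
    absorption band, so the two Gaussians cross at an isosbestic wavelength.
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(240.0, 421.0, 10.0))
    eps_neutral: Optional[np.ndarray] = None
    eps_charged: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if self.eps_neutral is None:
            object.__setattr__(self, "eps_neutral",
                               _gaussian_band(wl, 280.0, 28.0, 9000.0))
        if self.eps_charged is None:
            object.__setattr__(self, "eps_charged",
                               _gaussian_band(wl, 330.0, 32.0, 12000.0))
        for name in ("eps_neutral", "eps_charged"):
            eps = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, eps)
            if eps.shape != wl.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(eps < 0):
                raise ValueError(f"{name} has negative extinction coefficients")

    @property
    def contrast_max_wavelength(self) -> float:
        """Wavelength of maximal |eps_charged − eps_neutral| (ground truth)."""
        return float(self.wavelengths[
            np.argmax(np.abs(self.eps_charged - self.eps_neutral))])


@dataclass(frozen=True)
class GeneratorConfig:
    """Truth parameters, experimental designs and noise model.

    ``seed`` is mandatory; every generated dataset derives its own stream
    from it.  Noise standard deviations default to 0.01 pH (electrode
    stability criterion) and 0.005 AU.
    """

    truth: CompoundParams
    seed: int
    setup: Optional[TitrationSetup] = None  # None: standard design
    ph_grid: Tuple[float, ...] = DEFAULT_PH_GRID
    c_list_spectro: Tuple[float, ...] = DEFAULT_SPECTRO_C
    extinction: ExtinctionModel = field(default_factory=ExtinctionModel)
    ph_noise_sd: float = 0.01
    absorbance_noise_sd: float = 0.005
    pka_noise_sd: float = 0.01
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ph_noise_sd", "absorbance_noise_sd", "pka_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def resolved_setup(self, c_total: Optional[float] = None) -> TitrationSetup:
        if self.setup is not None and c_total is None:
            return self.setup
        kind = (TitrantKind.STRONG_ACID
                if self.truth.polarity is Polarity.ACID
                else TitrantKind.STRONG_BASE)
        c = c_total if c_total is not None else 1e-3
        return standard_setup(c, titrant_kind=kind)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _truth_record(config: GeneratorConfig, **extra) -> Dict:
    t = config.truth
    rec = {
        "pka_intrinsic": t.pka_intrinsic,
        "s_intrinsic": None if math.isinf(t.s_intrinsic) else t.s_intrinsic,
        "a_aggregation": t.a_aggregation,
        "polarity": t.polarity.value,
        "pkw": t.pkw,
        "seed": config.seed,
    }
    rec.update(extra)
    return rec


def generate_titration(
    config: GeneratorConfig,
    c_total: Optional[float] = None,
    stream: int = 0,
) -> Tuple[TitrationCurve, Dict]:
    """One noisy titration curve plus its truth record.

    The noise-free curve is the exact model simulation; Gaussian pH noise of
    ``ph_noise_sd`` is added to every point.  ``stream`` distinguishes
    replicates under one master seed.
    """
    setup = config.resolved_setup(c_total)
    clean = simulate_titration(config.truth, setup)
    rng = config._rng(stream)
    noisy_ph = clean.ph + rng.normal(0.0, config.ph_noise_sd, size=len(clean))
    curve = TitrationCurve(clean.titrant_added, noisy_ph, setup)
    truth = _truth_record(
        config,
        kind="titration",
        c_total=setup.c_total_initial,
        ph_noise_sd=config.ph_noise_sd,
        stream=stream,
        setup={
            "c_total_initial": setup.c_total_initial,
            "titrant_concentration": setup.titrant_concentration,
            "titrant_kind": setup.titrant_kind.value,
            "pre_added_equivalents": setup.pre_added_equivalents,
            "v_initial": setup.v_initial,
            "injection_volume": setup.injection_volume,
            "n_injections": setup.n_injections,
        },
    )
    return curve, truth


def generate_spectra(config: GeneratorConfig, stream: int = 1) -> Tuple[SpectraSet, Dict]:
    """Universal-buffer absorbance records plus truth.

    Samples are centrifuged before measurement, so only the dissolved
    charged and neutral species absorb (Beer–Lambert, 1 cm path); the
    aggregate is excluded.  Gaussian absorbance noise is added per record.
    """
    ext = config.extinction
    rng = config._rng(stream)
    rows = []
    for c in config.c_list_spectro:
        state = species_at_ph(config.truth, c, np.asarray(config.ph_grid))
        # dissolved species only: aggregate is centrifuged out
        absorb = config.path_length_cm * (
            np.outer(state.c_neutral_dissolved, ext.eps_neutral)
            + np.outer(state.c_charged, ext.eps_charged))
        absorb = absorb + rng.normal(0.0, config.absorbance_noise_sd,
                                     size=absorb.shape)
        for i, ph in enumerate(config.ph_grid):
            for j, wl in enumerate(ext.wavelengths):
                rows.append((c, ph, wl, absorb[i, j]))
    df = pd.DataFrame(rows, columns=COLUMNS)
    truth = _truth_record(
        config,
        kind="spectra",
        ph_grid=list(config.ph_grid),
        c_list=list(config.c_list_spectro),
        absorbance_noise_sd=config.absorbance_noise_sd,
        contrast_max_wavelength=ext.contrast_max_wavelength,
        stream=stream,
    )
    return SpectraSet(df), truth


def generate_shift_table(
    config: GeneratorConfig,
    c_list: Sequence[float],
    stream: int = 2,
) -> Tuple[List[ObservedPka], Dict]:
    """Observed-pKa-versus-concentration table plus truth.

    The noise-free values come from the full pipeline (standard titration at
    each concentration, no-aggregation fit); Gaussian noise of
    ``pka_noise_sd`` is added to each tabulated pKa.
    """
    clean = observed_pka_vs_concentration(config.truth, list(c_list))
    rng = config._rng(stream)
    noise = rng.normal(0.0, config.pka_noise_sd, size=len(clean))
    noisy = [ObservedPka(o.value + float(e), o.c_total, o.method)
             for o, e in zip(clean, noise)]
    truth = _truth_record(
        config,
        kind="shift_table",
        c_list=[float(c) for c in c_list],
        pka_noise_sd=config.pka_noise_sd,
        clean_values=[o.value for o in clean],
        stream=stream,
    )
    return noisy, truth
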