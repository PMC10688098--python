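"""CSV/JSON readers and writers for the package's interchange formats.

Dialect: plain CSV with ``#``-prefixed key=value metadata lines before the
header for formats that need setup information; JSON for configurations,
truth records and fit results.  Floats are written with ``repr`` precision
so write→read round-trips are exact.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .equilibria import CompoundParams
from .spectro import COLUMNS as SPECTRA_COLUMNS
from .spectro import SpectraSet
from .titration import (
    ObservedPka,
    PkaMethod,
    TitrationCurve,
    TitrationSetup,
    TitrantKind,
)

__all__ = [
    "write_titration_csv", "read_titration_csv",
    "write_spectra_csv", "read_spectra_csv",
    "write_shift_csv", "read_shift_csv",
    "write_json", "read_json",
]

PathLike = Union[str, Path]

_SETUP_KEYS = {
    "c_total_M": ("c_total_initial", 1.0),
    "v_initial_L": ("v_initial", 1.0),
    "titrant_M": ("titrant_concentration", 1.0),
    "pre_equiv": ("pre_added_equivalents", 1.0),
    "injection_uL": ("injection_volume", 1e-6),
}


def write_titration_csv(curve: TitrationCurve, path: PathLike) -> None:
    """Titration curve with its setup as ``#`` metadata lines."""
    s = curve.setup
    lines = [
        f"# c_total_M={s.c_total_initial!r}",
        f"# v_initial_L={s.v_initial!r}",
        f"# titrant_M={s.titrant_concentration!r}",
        f"# titrant_kind={s.titrant_kind.value}",
        f"# pre_equiv={s.pre_added_equivalents!r}",
        f"# injection_uL={s.injection_volume / 1e-6!r}",
        "titrant_added_equiv,pH",
    ]
    for t, p in zip(curve.titrant_added, curve.ph):
        lines.append(f"{float(t)!r},{float(p)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_titration_csv(path: PathLike) -> TitrationCurve:
    meta: Dict[str, str] = {}
    rows: List[List[float]] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        elif not header_seen:
            if line.lower().replace(" ", "") != "titrant_added_equiv,ph":
                raise ValueError(f"unexpected header line: {line!r}")
            header_seen = True
        else:
            t, p = line.split(",")
            rows.append([float(t), float(p)])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    kwargs = {}
    for key, (attr, scale) in _SETUP_KEYS.items():
        if key not in meta:
            raise ValueError(f"titration CSV is missing metadata key {key}")
        kwargs[attr] = float(meta[key]) * scale
    kwargs["titrant_kind"] = TitrantKind(meta.get("titrant_kind", "strong_acid"))
    kwargs["n_injections"] = max(len(rows) - 1, 1)
    setup = TitrationSetup(**kwargs)
    arr = np.asarray(rows)
    return TitrationCurve(arr[:, 0], arr[:, 1], setup)


def write_spectra_csv(spectra: SpectraSet, path: PathLike) -> None:
    df = spectra.data[SPECTRA_COLUMNS].copy()
    with open(path, "w") as fh:
        fh.write(",".join(SPECTRA_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_spectra_csv(path: PathLike) -> SpectraSet:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return SpectraSet(df)


def write_shift_csv(observations: Sequence[ObservedPka], path: PathLike) -> None:
    lines = ["c_total_M,pka_observed,method"]
    for o in observations:
        lines.append(f"{float(o.c_total)!r},{float(o.value)!r},{o.method.value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shift_csv(path: PathLike) -> List[ObservedPka]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"c_total_M", "pka_observed"}
    if not required <= set(df.columns):
        raise ValueError(f"shift CSV must have columns {sorted(required)}")
    methods = (df["method"] if "method" in df.columns
               else ["titration_fit"] * len(df))
    return [
        ObservedPka(float(v), float(c), PkaMethod(m))
        for c, v, m in zip(df["c_total_M"], df["pka_observed"], methods)
    ]


def write_json(obj: Dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike) -> Dict:
    return json.loads(Path(path).read_text())
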