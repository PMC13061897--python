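"""Monoisotopic adduct m/z computation and known-ion matching."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaktable import PeakTable

#: monoisotopic masses of the elements handled (CODATA/IUPAC 2021 values)
MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.968852682,
    "Fe": 55.9349375,
}

PROTON = 1.0072765

#: adduct -> (mass shift, charge, polarity)
ADDUCTS = {
    "[M+H]+": (PROTON, 1, "+"),
    "[M+2H]2+": (2 * PROTON, 2, "+"),
    "[M+Na]+": (MONOISOTOPIC["Na"] - 0.0005485799, 1, "+"),
    "[M-H]-": (-PROTON, 1, "-"),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C25H48N6O8`` into element counts."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in MONOISOTOPIC:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    return sum(MONOISOTOPIC[el] * n for el, n in parse_formula(formula).items())


def adduct_mz(formula: str, adduct: str) -> float:
    """m/z of an adduct ion, rounded half-even to 3 decimals."""
    if adduct not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    shift, charge, _pol = ADDUCTS[adduct]
    M = monoisotopic_mass(formula)
    mz = (M + shift) / charge
    return float(np.round(mz, 3))  # numpy rounds half-even


@dataclass
class IonTarget:
    name: str
    formula: str
    adducts: tuple[str, ...] = ("[M+H]+",)


def match_known_ions(
    table: PeakTable, targets: list[IonTarget], tol_ppm: float = 10.0
) -> pd.DataFrame:
    """Annotate features matching target adduct masses within ``tol_ppm``.

    A feature matches iff its m/z is within tolerance of the target adduct
    m/z (computed at full precision) and its polarity agrees with the
    adduct's. Returns one row per (feature, target, adduct) match with the
    signed ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    rows = []
    mz = table.feature_meta["mz"].astype(float)
    pol = table.feature_meta["polarity"]
    for t in targets:
        M = monoisotopic_mass(t.formula)
        for ad in t.adducts:
            shift, charge, ad_pol = ADDUCTS[ad]
            target_mz = (M + shift) / charge
            ppm = (mz - target_mz) / target_mz * 1e6
            hit = (ppm.abs() <= tol_ppm) & (pol == ad_pol)
            for f in mz.index[hit]:
                rows.append(
                    {
                        "feature_id": f,
                        "name": t.name,
                        "adduct": ad,
                        "target_mz": round(target_mz, 4),
                        "feature_mz": mz[f],
                        "ppm_error": float(ppm[f]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["feature_id", "name", "adduct", "target_mz",
                       "feature_mz", "ppm_error"],
    )


#: the hydroxamate siderophore targets used in the worked examples
DFO_B = IonTarget("DFO-B", "C25H48N6O8", ("[M+H]+", "[M+2H]2+"))
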