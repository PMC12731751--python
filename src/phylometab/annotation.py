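"""Putative metabolite annotation by accurate-mass matching.

Feature m/z values are matched against a user-supplied local compound table
(name, formula, monoisotopic mass) under a ppm tolerance, considering singly
charged adducts (protonation, sodium, potassium, deprotonation).  Matches are
*putative* identifications: a feature may match several compounds and a
compound several features; candidates are ranked by ppm error.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .feature_io import FeatureTable

#: Mass of a proton in Da (charge carrier for singly charged ions).
PROTON = 1.007276
#: Replacement shifts relative to [M+H]+ (Da).
NA_MINUS_H = 21.981944
K_MINUS_H = 37.955881


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged adduct: observed m/z = monoisotopic mass + mass_shift."""

    label: str
    mass_shift: float  # Da
    polarity: str      # "positive" | "negative"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        sign = "+" if self.polarity == "positive" else "-"
        if not self.label.rstrip().endswith(sign):
            raise ValueError(f"adduct label {self.label!r} inconsistent with {self.polarity} polarity")


POSITIVE_ADDUCTS = [
    AdductSpec("[M+H]+", PROTON, "positive"),
    AdductSpec("[M+Na]+", PROTON + NA_MINUS_H, "positive"),
    AdductSpec("[M+K]+", PROTON + K_MINUS_H, "positive"),
]
NEGATIVE_ADDUCTS = [AdductSpec("[M-H]-", -PROTON, "negative")]
DEFAULT_ADDUCTS = POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    monoisotopic_mass: float  # Da, neutral molecule
    formula: str | None = None

    def __post_init__(self):
        if not self.monoisotopic_mass > 0:
            raise ValueError(f"compound {self.name}: mass must be > 0")


def adduct_mz(monoisotopic_mass: float, adduct: AdductSpec) -> float:
    """Theoretical m/z of a singly charged adduct ion."""
    if not monoisotopic_mass > 0:
        raise ValueError("monoisotopic mass must be > 0")
    return monoisotopic_mass + adduct.mass_shift


def read_compound_table(path) -> list[CompoundRecord]:
    """Compound table CSV: columns name, monoisotopic_mass[, formula]."""
    df = pd.read_csv(path)
    formula = df["formula"] if "formula" in df.columns else [None] * len(df)
    return [
        CompoundRecord(name=str(n), monoisotopic_mass=float(m), formula=f)
        for n, m, f in zip(df["name"], df["monoisotopic_mass"], formula)
    ]


def match_features(
    table: FeatureTable,
    compounds: list[CompoundRecord],
    adducts: list[AdductSpec] | None = None,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """All (feature, compound, adduct) candidates within ``tol_ppm``.

    The ppm error is computed on the adduct m/z:
    |observed - theoretical| / theoretical * 1e6.  When the table declares an
    ion mode, adducts of the other polarity are skipped.  Result is sorted by
    ppm error (ties broken by feature, compound, adduct labels).
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be > 0")
    if adducts is None:
        adducts = DEFAULT_ADDUCTS
    if table.ion_mode is not None:
        adducts = [a for a in adducts if a.polarity == table.ion_mode]
    if not compounds:
        warnings.warn("empty compound table; no annotation candidates")
        return pd.DataFrame(
            columns=["feature_id", "mz", "compound", "adduct", "theoretical_mz", "ppm_error"]
        )
    obs = table.meta["mz"].to_numpy(float)
    rows = []
    for comp in compounds:
        for add in adducts:
            theo = adduct_mz(comp.monoisotopic_mass, add)
            ppm = np.abs(obs - theo) / theo * 1e6
            for idx in np.flatnonzero(ppm <= tol_ppm):
                rows.append(
                    {
                        "feature_id": table.meta.index[idx],
                        "mz": obs[idx],
                        "compound": comp.name,
                        "adduct": add.label,
                        "theoretical_mz": theo,
                        "ppm_error": ppm[idx],
                    }
                )
    out = pd.DataFrame(rows, columns=["feature_id", "mz", "compound", "adduct", "theoretical_mz", "ppm_error"])
    return out.sort_values(
        ["ppm_error", "feature_id", "compound", "adduct"], kind="mergesort"
    ).reset_index(drop=True)
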