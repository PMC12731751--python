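"""Reading, validation and filtering of aligned LC-MS feature tables.

The expected input is the aligned, normalized feature matrix exported by an
XCMS-style pre-processing pipeline, written as CSV with one row per feature:

    feature_id, mz, rt, <specimen_1>, <specimen_2>, ...

``mz`` is the mass-to-charge ratio in Da, ``rt`` the retention time in
minutes, and each specimen column holds a non-negative intensity.  An empty
cell means "peak not detected in this specimen" and is read as missing (NaN);
downstream polarization maps missing to intensity 0.

A companion sample manifest (CSV: specimen_id, patient_id, role[, note])
assigns each specimen a role: ``outgroup`` (healthy reference), ``pre_RT`` or
``post_RT``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLES = ("outgroup", "pre_RT", "post_RT")
RESERVED_COLS = ("feature_id", "mz", "rt")

#: Internal standards spiked into every run (positive / negative ion mode).
DEBRISOQUINE = ("debrisoquine", 176.117, 1.705, "positive")
NITROBENZOIC_ACID = ("4-nitrobenzoic acid", 166.014, 4.063, "negative")


class ValidationError(ValueError):
    """Input violates a structural invariant of the expected format."""


class ParseError(ValueError):
    """A cell could not be parsed; message names row and column."""


@dataclass(frozen=True)
class InternalStandard:
    name: str
    expected_mz: float  # Da
    expected_rt: float  # minutes
    ion_mode: str = "positive"

    def __post_init__(self):
        if not self.expected_mz > 0:
            raise ValidationError(f"standard {self.name}: expected_mz must be > 0")


DEFAULT_STANDARDS = [InternalStandard(*DEBRISOQUINE), InternalStandard(*NITROBENZOIC_ACID)]


@dataclass
class FeatureTable:
    """Features (m/z, RT) x specimens intensity matrix.

    ``meta`` is indexed by feature_id with columns ``mz`` and ``rt``;
    ``intensities`` shares the index and has one column per specimen.
    Missing intensities are NaN.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    ion_mode: str | None = None

    def __post_init__(self):
        if not self.meta.index.equals(self.intensities.index):
            raise ValidationError("meta and intensity feature indexes differ")
        if self.meta.index.has_duplicates:
            raise ValidationError("duplicate feature_id values")
        if self.intensities.columns.has_duplicates:
            dup = self.intensities.columns[self.intensities.columns.duplicated()]
            raise ValidationError(f"duplicate specimen columns: {sorted(set(dup))}")
        mz = self.meta["mz"].to_numpy(float)
        rt = self.meta["rt"].to_numpy(float)
        if not np.all(np.isfinite(mz) & (mz > 0)):
            bad = self.meta.index[~(np.isfinite(mz) & (mz > 0))][0]
            raise ValidationError(f"feature {bad!r}: mz must be finite and > 0")
        if not np.all(np.isfinite(rt) & (rt >= 0)):
            bad = self.meta.index[~(np.isfinite(rt) & (rt >= 0))][0]
            raise ValidationError(f"feature {bad!r}: rt must be finite and >= 0")
        vals = self.intensities.to_numpy(float)
        neg = np.nan_to_num(vals, nan=0.0) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative intensity at feature {self.intensities.index[i]!r}, "
                f"specimen {self.intensities.columns[j]!r}"
            )

    @property
    def specimens(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.meta)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.meta.equals(other.meta)
            and self.intensities.equals(other.intensities)
            and self.ion_mode == other.ion_mode
        )


@dataclass
class SampleManifest:
    """Specimen-to-patient/role assignment.

    One row per specimen; roles are ``outgroup``, ``pre_RT``, ``post_RT``.
    A patient may contribute both a pre_RT and a post_RT specimen; outgroup
    specimens carry no pre/post pairing.
    """

    table: pd.DataFrame  # columns: specimen_id, patient_id, role, note

    def __post_init__(self):
        t = self.table
        for col in ("specimen_id", "patient_id", "role"):
            if col not in t.columns:
                raise ValidationError(f"manifest missing column {col!r}")
        if "note" not in t.columns:
            t = t.assign(note="")
        if t["specimen_id"].duplicated().any():
            dup = t.loc[t["specimen_id"].duplicated(), "specimen_id"].iloc[0]
            raise ValidationError(f"duplicate specimen_id {dup!r} in manifest")
        bad = set(t["role"]) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown roles in manifest: {sorted(bad)}")
        dup_role = t[t["role"] != "outgroup"].duplicated(subset=["patient_id", "role"])
        if dup_role.any():
            raise ValidationError("a patient has two specimens with the same role")
        self.table = t.reset_index(drop=True)

    def specimens(self, role: str | None = None) -> list[str]:
        t = self.table
        if role is not None:
            t = t[t["role"] == role]
        return list(t["specimen_id"])

    @property
    def outgroup(self) -> list[str]:
        return self.specimens("outgroup")

    @property
    def ingroup(self) -> list[str]:
        return [s for s in self.specimens() if s not in set(self.outgroup)]

    def patient_of(self) -> dict[str, str]:
        return dict(zip(self.table["specimen_id"], self.table["patient_id"]))

    def role_of(self) -> dict[str, str]:
        return dict(zip(self.table["specimen_id"], self.table["role"]))


# ---------------------------------------------------------------------------
# readers / writers


def _parse_numeric(df: pd.DataFrame, col: str, allow_missing: bool) -> pd.Series:
    # cell-by-cell float(): exact round trip (pandas' fast parser is lossy in
    # the last ulp) and precise error locations
    raw = df[col]
    vals = np.empty(len(raw))
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, str) and v.strip() == ""):
            if not allow_missing:
                raise ParseError(f"missing required value at row {i + 2}, column {col!r}")
            vals[i] = np.nan
            continue
        try:
            vals[i] = float(v)
        except (TypeError, ValueError):
            raise ParseError(
                f"malformed numeric value {v!r} at row {i + 2} (feature "
                f"{df['feature_id'].iloc[i]!r}), column {col!r}"
            ) from None
    return pd.Series(vals, index=raw.index)


def read_feature_table(path, ion_mode: str | None = None) -> FeatureTable:
    """Read a feature table CSV in the declared dialect.

    Raises :class:`ParseError` for malformed cells (naming row and column) and
    :class:`ValidationError` for duplicate specimen columns or negative
    intensities.  Row and column order are preserved.
    """
    header = pd.read_csv(path, nrows=0)
    cols = list(header.columns)
    if cols[:3] != list(RESERVED_COLS):
        raise ValidationError(
            f"feature table must start with columns {RESERVED_COLS}, got {cols[:3]}"
        )
    seen, dups = set(), []
    for c in cols[3:]:
        base = c.split(".")[0] if c.split(".")[-1].isdigit() else c
        if base in seen:
            dups.append(base)
        seen.add(base)
    if dups:
        raise ValidationError(f"duplicate specimen columns: {sorted(set(dups))}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    meta = pd.DataFrame(
        {
            "mz": _parse_numeric(df, "mz", allow_missing=False),
            "rt": _parse_numeric(df, "rt", allow_missing=False),
        }
    )
    meta.index = pd.Index(df["feature_id"], name="feature_id")
    inten = {}
    for spec in cols[3:]:
        inten[spec] = _parse_numeric(df, spec, allow_missing=True).to_numpy(float)
    intensities = pd.DataFrame(inten, index=meta.index)
    return FeatureTable(meta=meta, intensities=intensities, ion_mode=ion_mode)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.meta.join(table.intensities).reset_index()
    # %.17g keeps the round trip bitwise exact
    out.to_csv(path, index=False, float_format="%.17g")


def read_manifest(path) -> SampleManifest:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations


def filter_mass_range(table: FeatureTable, lo: float = 50.0, hi: float = 850.0) -> FeatureTable:
    """Keep features with lo <= mz <= hi (closed interval); order preserved."""
    if not lo < hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
    keep = (table.meta["mz"] >= lo) & (table.meta["mz"] <= hi)
    return FeatureTable(
        meta=table.meta[keep].copy(),
        intensities=table.intensities[keep].copy(),
        ion_mode=table.ion_mode,
    )


def ppm_deviation(observed: float, expected: float) -> float:
    """|observed - expected| / expected * 1e6."""
    return abs(observed - expected) / expected * 1e6


def check_internal_standards(
    table: FeatureTable,
    standards: list[InternalStandard] | None = None,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.1,
) -> pd.DataFrame:
    """Locate each internal standard in the table.

    For every standard the closest in-tolerance feature (by ppm deviation,
    then RT deviation) is reported, or status "missing" when none falls within
    both tolerances.  The table is never mutated; missing standards are a
    report outcome, not an error.
    """
    if standards is None:
        standards = DEFAULT_STANDARDS
    if not (mz_tol_ppm > 0 and rt_tol_min > 0):
        raise ValueError("tolerances must be > 0")
    mz = table.meta["mz"].to_numpy(float)
    rt = table.meta["rt"].to_numpy(float)
    rows = []
    for std in standards:
        ppm = np.abs(mz - std.expected_mz) / std.expected_mz * 1e6
        drt = np.abs(rt - std.expected_rt)
        ok = (ppm <= mz_tol_ppm) & (drt <= rt_tol_min)
        if ok.any():
            order = np.lexsort((drt[ok], ppm[ok]))
            idx = np.flatnonzero(ok)[order[0]]
            rows.append(
                {
                    "standard": std.name,
                    "status": "found",
                    "feature_id": table.meta.index[idx],
                    "observed_mz": mz[idx],
                    "ppm_deviation": ppm[idx],
                    "observed_rt": rt[idx],
                    "rt_deviation": drt[idx],
                }
            )
        else:
            rows.append(
                {
                    "standard": std.name,
                    "status": "missing",
                    "feature_id": None,
                    "observed_mz": np.nan,
                    "ppm_deviation": np.nan,
                    "observed_rt": np.nan,
                    "rt_deviation": np.nan,
                }
            )
    return pd.DataFrame(rows)
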