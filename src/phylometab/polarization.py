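"""Character polarization against a healthy outgroup.

Each LC-MS feature becomes a binary phylogenetic character: the outgroup
specimens define a per-feature *normal range* of intensities, and every
patient specimen is coded **ancestral (0)** when its intensity falls inside
that range or **derived (1)** when it falls outside.  The direction of the
departure is kept as metadata:

* ``up``       — intensity above the normal range (feature detected in outgroup)
* ``down``     — positive intensity below the normal range
* ``novel``    — peak absent from every outgroup specimen but present here
* ``vanished`` — peak present in the outgroup but undetected here

The character matrix itself is strictly 0/1 — up/down/novel/vanished are not
distinct states, because downstream Wagner parsimony consumes binary
characters.  Missing intensities are treated as "peak not detected" and
mapped to 0 before coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_io import FeatureTable, SampleManifest, ValidationError

DIRECTIONS = ("none", "up", "down", "novel", "vanished")


@dataclass
class NormalRanges:
    """Per-feature outgroup normal ranges.

    ``table`` is indexed by feature_id with columns ``lo``, ``hi`` (intensity
    bounds, lo <= hi, both >= 0) and ``outgroup_detected`` (feature seen in at
    least one outgroup specimen).  ``method`` records how the range was set.
    """

    table: pd.DataFrame
    method: str

    def __post_init__(self):
        t = self.table
        if not ((t["lo"] <= t["hi"]).all() and (t["lo"] >= 0).all()):
            raise ValidationError("normal ranges require 0 <= lo <= hi")


@dataclass
class PolarizedMatrix:
    """Specimens x characters binary matrix with a parallel direction channel.

    ``states`` holds 0/1 (int8), rows = patient specimens, columns = feature
    (character) IDs.  ``directions`` is the same shape with values from
    :data:`DIRECTIONS`; state 0 cells carry ``none``, state 1 cells carry the
    kind of departure from the outgroup normal range.
    """

    states: pd.DataFrame
    directions: pd.DataFrame
    ranges: NormalRanges | None = None
    ancestor_label: str | None = None

    def __post_init__(self):
        s = self.states.to_numpy()
        if not np.isin(s, (0, 1)).all():
            raise ValidationError("polarized matrix may contain only 0s and 1s")
        d = self.directions.to_numpy(dtype=object)
        if ((s == 0) != (d == "none")).any():
            raise ValidationError("state 0 <=> direction 'none' violated")

    @property
    def specimens(self) -> list[str]:
        return list(self.states.index)

    @property
    def characters(self) -> list[str]:
        return list(self.states.columns)


def compute_normal_ranges(
    table: FeatureTable,
    manifest: SampleManifest,
    method: str = "minmax",
    k: float = 2.0,
) -> NormalRanges:
    """Estimate per-feature normal ranges from the outgroup specimens.

    ``minmax`` (default) uses [min, max] of outgroup intensities; ``mean_k_sd``
    uses [mean - k*sd, mean + k*sd] with the sample standard deviation,
    clipped at 0.  Missing outgroup intensities count as 0.
    """
    og = manifest.outgroup
    if len(og) == 0:
        raise ValidationError("manifest declares no outgroup specimens")
    if len(og) < 2:
        raise ValidationError("need >= 2 outgroup specimens to define a range")
    if len(og) < 3:
        import warnings

        warnings.warn("fewer than 3 outgroup specimens; normal ranges will be crude")
    missing = [s for s in og if s not in table.intensities.columns]
    if missing:
        raise ValidationError(f"outgroup specimens absent from table: {missing}")
    vals = table.intensities[og].to_numpy(float)
    vals = np.nan_to_num(vals, nan=0.0)
    if method == "minmax":
        lo, hi = vals.min(axis=1), vals.max(axis=1)
    elif method == "mean_k_sd":
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        lo = np.clip(mean - k * sd, 0.0, None)
        hi = mean + k * sd
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(
        {"lo": lo, "hi": hi, "outgroup_detected": (vals > 0).any(axis=1)},
        index=table.meta.index,
    )
    return NormalRanges(out, method=method)


def polarize(
    table: FeatureTable,
    ranges: NormalRanges,
    manifest: SampleManifest,
    min_intensity: float = 0.0,
) -> PolarizedMatrix:
    """Code every patient specimen x feature cell as ancestral (0) or derived (1).

    Coding, per cell with effective intensity x (missing or <= ``min_intensity``
    maps to 0), against the feature's normal range [lo, hi]:

    * lo <= x <= hi              -> (0, none)
    * x > hi                     -> (1, up); reported as (1, novel) when the
      feature was never detected in the outgroup
    * 0 < x < lo                 -> (1, down)
    * x = 0 and lo > 0           -> (1, vanished)
    * x = 0 and lo = 0           -> (0, none)   (inside the range)

    Outgroup specimens are excluded from the output rows — they define the
    ancestral state rather than being classified against it.
    """
    not_covered = table.meta.index.difference(ranges.table.index)
    if len(not_covered):
        raise ValidationError(f"features without a normal range: {list(not_covered)[:5]}")
    rt = ranges.table.loc[table.meta.index]
    lo = rt["lo"].to_numpy(float)
    hi = rt["hi"].to_numpy(float)
    og_det = rt["outgroup_detected"].to_numpy(bool)

    specimens = [s for s in manifest.ingroup if s in table.intensities.columns]
    missing = [s for s in manifest.ingroup if s not in table.intensities.columns]
    if missing:
        raise ValidationError(f"ingroup specimens absent from table: {missing}")
    X = table.intensities[specimens].to_numpy(float).T  # specimens x features
    X = np.nan_to_num(X, nan=0.0)
    X = np.where(X <= min_intensity, 0.0, X)

    within = (X >= lo) & (X <= hi)
    up = X > hi
    down = (X > 0) & (X < lo)
    vanished = (X == 0) & (lo > 0)
    direction = np.select(
        [within, up & og_det, up & ~og_det, down, vanished],
        ["none", "up", "novel", "down", "vanished"],
        default="none",
    )
    states = (direction != "none").astype(np.int8)
    cols = table.meta.index
    return PolarizedMatrix(
        states=pd.DataFrame(states, index=pd.Index(specimens, name="specimen"), columns=cols),
        directions=pd.DataFrame(direction, index=pd.Index(specimens, name="specimen"), columns=cols),
        ranges=ranges,
    )


def append_hypothetical_ancestor(matrix: PolarizedMatrix, label: str = "HYP_ANCESTOR") -> PolarizedMatrix:
    """Add an all-ancestral (all-zero) taxon used downstream to root the tree."""
    if label in matrix.states.index:
        raise ValidationError(f"label {label!r} already present in matrix")
    zero = pd.DataFrame(
        np.zeros((1, len(matrix.characters)), dtype=np.int8),
        index=pd.Index([label], name="specimen"),
        columns=matrix.states.columns,
    )
    none = zero.astype(object).replace(0, "none")
    return PolarizedMatrix(
        states=pd.concat([matrix.states, zero]),
        directions=pd.concat([matrix.directions, none]),
        ranges=matrix.ranges,
        ancestor_label=label,
    )


def drop_uninformative_characters(
    matrix: PolarizedMatrix, mode: str = "constant_only"
) -> tuple[PolarizedMatrix, pd.DataFrame]:
    """Remove characters that cannot influence the parsimony tree.

    ``constant_only`` drops all-0 and all-1 columns; ``parsimony_uninformative``
    additionally drops singletons (derived in exactly one specimen).  The
    removed characters are returned with their reason so synapomorphy
    accounting can re-attach autapomorphies.  The default pipeline keeps all
    characters (no a priori selection); this is an opt-in speed switch.
    """
    if mode not in ("constant_only", "parsimony_uninformative"):
        raise ValueError(f"unknown mode {mode!r}")
    s = matrix.states.to_numpy()
    n = s.shape[0]
    colsum = s.sum(axis=0)
    reason = np.full(s.shape[1], "", dtype=object)
    reason[colsum == 0] = "constant_0"
    reason[colsum == n] = "constant_1"
    if mode == "parsimony_uninformative":
        reason[(colsum == 1) & (reason == "")] = "singleton"
    drop = reason != ""
    removed = pd.DataFrame(
        {
            "character": matrix.states.columns[drop],
            "reason": reason[drop],
            "derived_count": colsum[drop],
        }
    )
    keep_cols = matrix.states.columns[~drop]
    kept = PolarizedMatrix(
        states=matrix.states[keep_cols].copy(),
        directions=matrix.directions[keep_cols].copy(),
        ranges=matrix.ranges,
        ancestor_label=matrix.ancestor_label,
    )
    return kept, removed


# ---------------------------------------------------------------------------
# writers


def write_matrix_csv(matrix: PolarizedMatrix, path) -> None:
    matrix.states.to_csv(path)


def write_directions_csv(matrix: PolarizedMatrix, path) -> None:
    matrix.directions.to_csv(path)


def write_phylip(matrix: PolarizedMatrix, path) -> None:
    """Relaxed sequential PHYLIP: taxon name, whitespace, 0/1 string."""
    s = matrix.states
    width = max(len(str(i)) for i in s.index) + 2
    with open(path, "w") as fh:
        fh.write(f" {s.shape[0]} {s.shape[1]}\n")
        for name, row in zip(s.index, s.to_numpy()):
            fh.write(str(name).ljust(width) + "".join(map(str, row)) + "\n")
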