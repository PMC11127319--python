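"""Data model and I/O for DMS count tables and score tables.

A screen is a variant-by-timepoint-by-replicate tensor of raw sequencing
counts ``c[v, t, r]`` together with per-variant annotations.  Time index
``t`` runs from 0 (pre-selection) to ``T`` (the number of selection rounds);
``r`` indexes replicates.  Missing counts are carried as NaN and are never
silently converted to zero.

Count tables are plain delimited text with one row per variant: annotation
columns plus one count column per ``(t, r)`` pair named by a configurable
pattern (default ``c_<t>_<r>``, ``t`` from 0 and ``r`` from 1).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MUTATION_TYPES = ("synonymous", "missense", "nonsense", "insertion", "deletion")

#: Fixed column order of a serialized score table.
SCORE_COLUMNS = (
    "variant_id",
    "position",
    "mutant",
    "mutation_type",
    "estimate",
    "se",
    "stat",
    "raw",
    "adjusted",
    "method",
)

ANNOTATION_COLUMNS = ("variant_id", "position", "mutant", "mutation_type", "is_wildtype_reference")


class ScreenFormatError(ValueError):
    """Malformed count table: bad counts, bad annotations, or inconsistent shape."""


class DuplicateVariantError(ScreenFormatError):
    """Two rows share the same (position, mutant) identity."""


class ConfigError(ValueError):
    """Invalid or unresolvable configuration (e.g. no wild-type series)."""


@dataclass
class CountTableFormat:
    """Column-mapping configuration for reading/writing count tables."""

    n_rounds: int = 1
    n_reps: int = 1
    sep: str = "\t"
    count_pattern: str = "c_{t}_{r}"
    variant_id: str = "variant_id"
    position: str = "position"
    mutant: str = "mutant"
    mutation_type: str = "mutation_type"
    is_wildtype_reference: str | None = "is_wildtype_reference"

    def count_column(self, t: int, r: int) -> str:
        """Name of the count column for time point ``t`` and replicate ``r`` (1-based)."""
        return self.count_pattern.format(t=t, r=r)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CountTableFormat":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ScreenCounts:
    """Raw counts ``c[v, t, r]`` plus variant annotations.

    ``counts`` is a float array of shape ``(V, T+1, R)``; NaN marks missing
    cells.  ``annotations`` is a DataFrame with columns ``variant_id``,
    ``position`` (1-based residue; an indel is annotated by its leftmost
    residue), ``mutant``, ``mutation_type`` and ``is_wildtype_reference``.
    """

    annotations: pd.DataFrame
    counts: np.ndarray
    n_rounds: int
    n_reps: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return self.counts.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.counts)

    def copy(self) -> "ScreenCounts":
        return ScreenCounts(
            annotations=self.annotations.copy(),
            counts=self.counts.copy(),
            n_rounds=self.n_rounds,
            n_reps=self.n_reps,
            provenance=dict(self.provenance),
        )

    def validate(self, require_integer: bool = False) -> None:
        """Check the structural invariants; raise :class:`ScreenFormatError` on violation."""
        V, Tp1, R = self.counts.shape
        if Tp1 != self.n_rounds + 1 or R != self.n_reps:
            raise ScreenFormatError(
                f"count tensor shape {self.counts.shape} does not match "
                f"T={self.n_rounds}, R={self.n_reps}"
            )
        if self.n_rounds < 1 or self.n_reps < 1 or V < 2:
            raise ScreenFormatError("need T >= 1, R >= 1 and V >= 2")
        if len(self.annotations) != V:
            raise ScreenFormatError("annotation rows do not match count rows")
        present = self.counts[~np.isnan(self.counts)]
        if (present < 0).any():
            raise ScreenFormatError("negative counts present")
        if require_integer and not np.allclose(present, np.round(present)):
            raise ScreenFormatError("non-integer counts present")
        ann = self.annotations
        dup = ann.duplicated(subset=["position", "mutant"])
        if dup.any():
            row = ann.index[dup][0]
            raise DuplicateVariantError(
                f"duplicate (position, mutant) at row {row}: "
                f"({ann.loc[row, 'position']}, {ann.loc[row, 'mutant']})"
            )
        bad_type = ~ann["mutation_type"].isin(MUTATION_TYPES)
        if bad_type.any():
            raise ScreenFormatError(
                f"unknown mutation_type {ann.loc[bad_type.idxmax(), 'mutation_type']!r}"
            )
        if (ann["position"] < 1).any():
            raise ScreenFormatError("positions must be 1-based positive integers")
        has_reference = bool(ann["is_wildtype_reference"].any()) or bool(
            (ann["mutation_type"] == "synonymous").any()
        )
        if not has_reference:
            raise ScreenFormatError(
                "screen has neither a wild-type reference row nor synonymous "
                "variants; wild-type normalization is impossible"
            )


def wildtype_series(sc: ScreenCounts) -> np.ndarray:
    """Resolve the wild-type count series, shape ``(T+1, R)``.

    Uses designated wild-type rows when present, otherwise the sum of
    synonymous counts (missing cells excluded from the sum).
    """
    ann = sc.annotations
    wt_rows = ann["is_wildtype_reference"].to_numpy(dtype=bool)
    if wt_rows.any():
        series = np.nansum(sc.counts[wt_rows], axis=0)
    else:
        syn_rows = (ann["mutation_type"] == "synonymous").to_numpy()
        if not syn_rows.any():
            raise ConfigError("no wild-type reference row and no synonymous variants")
        series = np.nansum(sc.counts[syn_rows], axis=0)
    if (series <= 0).all():
        raise ConfigError("wild-type count series is all zero")
    return series


def read_counts(path: str | os.PathLike, fmt: CountTableFormat) -> ScreenCounts:
    """Read a delimited count table into a validated :class:`ScreenCounts`.

    Blank count cells are preserved as missing (NaN), never coerced to 0.
    Malformed counts raise :class:`ScreenFormatError` naming row and column.
    """
    df = pd.read_csv(path, sep=fmt.sep, dtype={fmt.mutant: str})
    for col in (fmt.variant_id, fmt.position, fmt.mutant, fmt.mutation_type):
        if col not in df.columns:
            raise ScreenFormatError(f"missing annotation column {col!r}")
    count_cols = [
        (t, r, fmt.count_column(t, r))
        for t in range(fmt.n_rounds + 1)
        for r in range(1, fmt.n_reps + 1)
    ]
    for _, _, c in count_cols:
        if c not in df.columns:
            raise ScreenFormatError(f"missing count column {c!r}")

    V = len(df)
    counts = np.full((V, fmt.n_rounds + 1, fmt.n_reps), np.nan)
    for t, r, col in count_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ScreenFormatError(f"malformed count at row {row}, column {col!r}")
        arr = vals.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if (arr[present] < 0).any():
            row = int(np.flatnonzero(present & (arr < 0))[0])
            raise ScreenFormatError(f"negative count at row {row}, column {col!r}")
        if not np.allclose(arr[present], np.round(arr[present])):
            row = int(np.flatnonzero(present & (arr != np.round(arr)))[0])
            raise ScreenFormatError(f"non-integer count at row {row}, column {col!r}")
        counts[:, t, r - 1] = arr

    ann = pd.DataFrame(
        {
            "variant_id": df[fmt.variant_id].astype(str),
            "position": df[fmt.position].astype(int),
            "mutant": df[fmt.mutant].astype(str),
            "mutation_type": df[fmt.mutation_type].astype(str),
            "is_wildtype_reference": (
                df[fmt.is_wildtype_reference].astype(bool)
                if fmt.is_wildtype_reference and fmt.is_wildtype_reference in df.columns
                else False
            ),
        }
    )
    sc = ScreenCounts(annotations=ann, counts=counts, n_rounds=fmt.n_rounds, n_reps=fmt.n_reps)
    sc.validate(require_integer=True)
    return sc


def write_counts(sc: ScreenCounts, path: str | os.PathLike, fmt: CountTableFormat | None = None) -> None:
    """Write a count table; inverse of :func:`read_counts` (bit-exact for integers)."""
    if fmt is None:
        fmt = CountTableFormat(n_rounds=sc.n_rounds, n_reps=sc.n_reps)
    out = sc.annotations.copy()
    for t in range(sc.n_rounds + 1):
        for r in range(1, sc.n_reps + 1):
            col = sc.counts[:, t, r - 1]
            # integers serialize without a decimal point so round-trips are exact
            ser = pd.Series(col).astype("Int64") if np.allclose(
                col[~np.isnan(col)], np.round(col[~np.isnan(col)])
            ) else pd.Series(col)
            out[fmt.count_column(t, r)] = ser
    out.to_csv(path, sep=fmt.sep, index=False)


def write_scores(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialize a score table as delimited text at full float precision.

    The column order is fixed (:data:`SCORE_COLUMNS`).  The target directory
    must exist; nothing is written on error.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty score table")
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    directory = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(directory):
        raise IOError(f"target directory does not exist: {directory}")
    table.loc[:, list(SCORE_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"score table lacks columns {missing}")
    return df


def validate_score_table(table: pd.DataFrame) -> None:
    """Sanity checks on score-table numerics (probability columns in range)."""
    for col in ("raw", "adjusted"):
        vals = table[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"column {col!r} outside [0, 1]")


def screen_from_frame(
    ann: pd.DataFrame, counts: np.ndarray, n_rounds: int, n_reps: int
) -> ScreenCounts:
    """Assemble and validate a :class:`ScreenCounts` from in-memory pieces."""
    ann = ann.copy()
    if "is_wildtype_reference" not in ann.columns:
        ann["is_wildtype_reference"] = False
    sc = ScreenCounts(
        annotations=ann.reset_index(drop=True),
        counts=np.asarray(counts, dtype=float),
        n_rounds=n_rounds,
        n_reps=n_reps,
    )
    sc.validate()
    return sc
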