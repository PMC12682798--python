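"""Streamline-count connectome containers, I/O and normalization.

A structural connectome (SC) is a square, symmetric, nonnegative region-by-region
matrix of white-matter connectivity strengths derived from probabilistic
tractography streamline counts. This module provides the validated containers and
the preprocessing steps applied before gradient extraction: symmetrization,
normalization of the strictly-lower-triangular mass to 1, and hemisphere masking.

Conventions
-----------
* Self-connections (the diagonal) are zeroed on read: tractography self-loops are
  not meaningful and the normalization concerns off-diagonal mass only.
* Row order of a connectome file must match the parcellation table order; no
  name-based reordering is attempted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationInfo",
    "ConnectomeMatrix",
    "read_parcellation",
    "write_parcellation",
    "read_connectome",
    "write_connectome",
    "symmetrize",
    "normalize_connectome",
    "mask_interhemispheric",
]

_SYMMETRY_TOL = 1e-10
_NORMALIZATION_TOL = 1e-9


class ConnectomeValidationError(ValueError):
    """Raised when a connectome violates its invariants."""


@dataclass(frozen=True)
class ParcellationInfo:
    """Ordered region table: ids, hemisphere labels and display names.

    The number of regions fixes the dimension N of every connectome using this
    parcellation. Hemisphere labels must be 'L' or 'R'.
    """

    region_ids: tuple[str, ...]
    hemisphere: tuple[str, ...]
    display_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.display_names:
            object.__setattr__(self, "display_names", self.region_ids)
        if not (len(self.region_ids) == len(self.hemisphere) == len(self.display_names)):
            raise ValueError("region_ids, hemisphere and display_names must have equal length")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        bad = sorted({h for h in self.hemisphere} - {"L", "R"})
        if bad:
            raise ValueError(f"hemisphere labels must be 'L' or 'R'; found {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def left_index(self) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemisphere) if h == "L"], dtype=int)

    @property
    def right_index(self) -> np.ndarray:
        return np.array([i for i, h in enumerate(self.hemisphere) if h == "R"], dtype=int)

    def subset(self, index: np.ndarray) -> "ParcellationInfo":
        return ParcellationInfo(
            region_ids=tuple(self.region_ids[i] for i in index),
            hemisphere=tuple(self.hemisphere[i] for i in index),
            display_names=tuple(self.display_names[i] for i in index),
        )

    @classmethod
    def bilateral(cls, n_regions: int) -> "ParcellationInfo":
        """Generic parcellation with the first half labelled L, second half R.

        For an odd region count the left hemisphere gets the extra region.
        """
        if n_regions < 2:
            raise ValueError("bilateral parcellation needs at least 2 regions")
        half = (n_regions + 1) // 2
        ids = tuple(
            f"{'L' if i < half else 'R'}_region_{(i if i < half else i - half):04d}"
            for i in range(n_regions)
        )
        hemi = ("L",) * half + ("R",) * (n_regions - half)
        return cls(region_ids=ids, hemisphere=hemi)


@dataclass
class ConnectomeMatrix:
    """Validated square symmetric nonnegative connectivity matrix.

    ``normalized`` indicates the strictly-lower-triangular entries sum to 1.
    """

    values: np.ndarray
    parcellation: ParcellationInfo
    subject_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectomeValidationError(f"connectome must be square, got shape {v.shape}")
        if v.shape[0] != self.parcellation.n_regions:
            raise ConnectomeValidationError(
                f"connectome dimension {v.shape[0]} does not match parcellation "
                f"({self.parcellation.n_regions} regions)"
            )
        if not np.all(np.isfinite(v)):
            raise ConnectomeValidationError("connectome contains non-finite entries")
        if np.any(v < 0):
            raise ConnectomeValidationError("connectome contains negative entries")
        asym = np.abs(v - v.T).max(initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ConnectomeValidationError(
                f"connectome is not symmetric (max |A - A.T| = {asym:.3g})"
            )
        if self.normalized:
            s = np.tril(v, k=-1).sum()
            if abs(s - 1.0) > _NORMALIZATION_TOL:
                raise ConnectomeValidationError(
                    f"normalized flag set but lower-triangular sum is {s!r}"
                )
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def copy_with(self, **changes) -> "ConnectomeMatrix":
        return dataclasses.replace(self, **changes)


def read_parcellation(path: str | Path) -> ParcellationInfo:
    """Read a TSV with columns region_id, hemisphere, display_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_id", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
    names = df["display_name"] if "display_name" in df.columns else df["region_id"]
    return ParcellationInfo(
        region_ids=tuple(df["region_id"]),
        hemisphere=tuple(df["hemisphere"]),
        display_names=tuple(names),
    )


def write_parcellation(parcellation: ParcellationInfo, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": parcellation.region_ids,
            "hemisphere": parcellation.hemisphere,
            "display_name": parcellation.display_names,
        }
    ).to_csv(path, sep="\t", index=False)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") >= first.count("\t") and "," in first else "\t"


def read_connectome(
    path: str | Path,
    parcellation: ParcellationInfo,
    *,
    subject_id: str | None = None,
    header: bool = False,
    normalized: bool = False,
) -> ConnectomeMatrix:
    """Read a dense delimited (comma or tab) numeric matrix as a connectome.

    The delimiter is auto-detected from the first line. The diagonal is zeroed.
    Raises on dimension mismatch with the parcellation and on negative, NaN or
    otherwise non-finite entries.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        values = np.loadtxt(path, delimiter=sep, skiprows=1 if header else 0)
    except ValueError as exc:  # non-numeric content
        raise ConnectomeValidationError(f"could not parse {path}: {exc}") from exc
    values = np.atleast_2d(values)
    if values.shape[0] != values.shape[1] or values.shape[0] != parcellation.n_regions:
        raise ConnectomeValidationError(
            f"{path}: matrix of shape {values.shape} does not match parcellation "
            f"with {parcellation.n_regions} regions"
        )
    np.fill_diagonal(values, 0.0)
    return ConnectomeMatrix(
        values=values,
        parcellation=parcellation,
        subject_id=subject_id if subject_id is not None else path.stem,
        normalized=normalized,
    )


def write_connectome(conn: ConnectomeMatrix, path: str | Path, *, delimiter: str = ",") -> None:
    np.savetxt(path, conn.values, delimiter=delimiter, fmt="%.17g")


def symmetrize(
    raw: np.ndarray,
    parcellation: ParcellationInfo | None = None,
    *,
    subject_id: str = "",
) -> ConnectomeMatrix:
    """Symmetrize raw streamline counts as the mean of the matrix and its transpose.

    The arithmetic mean is the common convention; it is a fixed point on already
    symmetric input. If ``parcellation`` is omitted, a generic bilateral one is
    created (first half L, second half R).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ConnectomeValidationError(f"input must be square, got shape {raw.shape}")
    if np.any(raw < 0):
        raise ConnectomeValidationError("raw counts must be nonnegative")
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    if parcellation is None:
        parcellation = ParcellationInfo.bilateral(raw.shape[0])
    return ConnectomeMatrix(values=sym, parcellation=parcellation, subject_id=subject_id)


def normalize_connectome(conn: ConnectomeMatrix) -> ConnectomeMatrix:
    """Divide all entries by the strictly-lower-triangular sum so it equals 1.

    Idempotent; preserves entry ratios. Raises on an all-zero off-diagonal
    matrix (degenerate input with no mass to normalize).
    """
    s = np.tril(conn.values, k=-1).sum()
    if s <= 0:
        raise ConnectomeValidationError(
            "cannot normalize a connectome with zero off-diagonal mass"
        )
    return conn.copy_with(values=conn.values / s, normalized=True)


def mask_interhemispheric(
    conn: ConnectomeMatrix,
) -> tuple[ConnectomeMatrix, ConnectomeMatrix]:
    """Split a connectome into its L x L and R x R principal submatrices.

    Interhemispheric entries are discarded; used for hemisphere-specific
    gradient analysis.
    """
    li = conn.parcellation.left_index
    ri = conn.parcellation.right_index
    if li.size == 0 or ri.size == 0:
        raise ConnectomeValidationError(
            "hemisphere masking requires both L and R regions in the parcellation"
        )
    left = ConnectomeMatrix(
        values=conn.values[np.ix_(li, li)],
        parcellation=conn.parcellation.subset(li),
        subject_id=conn.subject_id,
    )
    right = ConnectomeMatrix(
        values=conn.values[np.ix_(ri, ri)],
        parcellation=conn.parcellation.subset(ri),
        subject_id=conn.subject_id,
    )
    return left, right
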