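"""Dynamical cross-correlation maps, difference maps, and feature extraction.

The map element for sites i, j is the normalized covariance of the Cartesian
displacement vectors about their trajectory means,

    C_ij = ⟨Δr_i · Δr_j⟩ / (⟨Δr_i²⟩ ⟨Δr_j²⟩)^{1/2},

so C_ij = +1 for fully correlated and −1 for fully anticorrelated motion.
Difference maps ΔC = C(modified) − C(wild type) highlight labelling-induced
changes; entries with |ΔC| ≤ 0.25 are conventionally masked as insignificant
and contiguous super-threshold regions are reported as feature blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .structure_io import Trajectory

__all__ = [
    "CorrelationMatrix",
    "DifferenceMatrix",
    "FeatureBlock",
    "CorrelationError",
    "compute_dccm",
    "compute_delta_dccm",
    "threshold_mask",
    "extract_feature_blocks",
    "save_matrix_csv",
    "load_matrix_csv",
]


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    """Residue-indexed symmetric matrix of correlation coefficients."""

    residue_numbers: np.ndarray
    values: np.ndarray  # (n, n), unit diagonal, entries in [-1, 1]
    label: str = ""

    def __post_init__(self) -> None:
        v = self.values
        n = self.residue_numbers.size
        if v.shape != (n, n):
            raise CorrelationError("matrix shape does not match residue count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise CorrelationError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise CorrelationError("correlation coefficients must lie in [-1, 1]")


@dataclass(frozen=True)
class DifferenceMatrix:
    """Element-wise DCCM difference; convention: modified − wild type."""

    residue_numbers: np.ndarray
    values: np.ndarray  # (n, n), zero diagonal, entries in [-2, 2]
    convention: str = "modified - WT"

    def __post_init__(self) -> None:
        v = self.values
        n = self.residue_numbers.size
        if v.shape != (n, n):
            raise CorrelationError("matrix shape does not match residue count")
        if np.any(np.abs(v) > 2 + 1e-12):
            raise CorrelationError("difference coefficients must lie in [-2, 2]")


@dataclass(frozen=True)
class FeatureBlock:
    """Bounding box of one contiguous super-threshold region of a ΔDCCM."""

    row_range: tuple[int, int]   # residue numbers, inclusive
    col_range: tuple[int, int]
    sign: int                    # +1 or -1
    extremal_value: float        # max |ΔC| inside the block


def compute_dccm(
    traj: Trajectory | np.ndarray,
    selection: np.ndarray | None = None,
    residue_numbers: np.ndarray | None = None,
    label: str = "",
) -> CorrelationMatrix:
    """Cross-correlation map of per-site displacement vectors.

    Accepts a (superposed) Trajectory plus a site selection, or directly an
    (n_frames, n_sites, 3) displacement/position array.  Means are removed
    in a single pass over the full trajectory.
    """
    if isinstance(traj, Trajectory):
        coords = traj.coordinates
    else:
        coords = np.asarray(traj, dtype=float)
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int), :]
    n_frames, n_sites = coords.shape[:2]
    if n_frames < 2:
        raise CorrelationError("need at least 2 frames for correlations")
    if n_sites < 2:
        raise CorrelationError("need at least 2 sites for correlations")

    delta = coords - coords.mean(axis=0)
    cov = np.einsum("fia,fja->ij", delta, delta) / n_frames
    var = np.diag(cov).copy()
    zero = np.flatnonzero(var <= 0)
    if zero.size:
        resnums = (
            residue_numbers[zero]
            if residue_numbers is not None
            else (np.asarray(selection)[zero] if selection is not None else zero)
        )
        raise CorrelationError(
            f"zero displacement variance at site(s) {np.atleast_1d(resnums).tolist()}: "
            "correlation undefined"
        )
    norm = np.sqrt(np.outer(var, var))
    C = cov / norm
    # clip numerical overshoot at the |C| = 1 bound
    np.clip(C, -1.0, 1.0, out=C)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    if residue_numbers is None:
        residue_numbers = np.arange(1, n_sites + 1)
    return CorrelationMatrix(
        residue_numbers=np.asarray(residue_numbers, dtype=int), values=C, label=label
    )


def compute_delta_dccm(
    modified: CorrelationMatrix, wildtype: CorrelationMatrix
) -> DifferenceMatrix:
    """ΔC = C_modified − C_wildtype (antisymmetric under argument swap)."""
    if modified.residue_numbers.shape != wildtype.residue_numbers.shape or np.any(
        modified.residue_numbers != wildtype.residue_numbers
    ):
        a = set(modified.residue_numbers.tolist())
        b = set(wildtype.residue_numbers.tolist())
        raise CorrelationError(
            f"residue indexing mismatch; unshared residues: {sorted(a ^ b)}"
        )
    delta = modified.values - wildtype.values
    np.fill_diagonal(delta, 0.0)
    return DifferenceMatrix(
        residue_numbers=modified.residue_numbers.copy(),
        values=delta,
        convention=f"{modified.label or 'modified'} - {wildtype.label or 'WT'}",
    )


def threshold_mask(
    matrix: CorrelationMatrix | DifferenceMatrix, cutoff: float = 0.25
) -> tuple[np.ma.MaskedArray, int]:
    """Mask entries with |value| ≤ cutoff (strict survival, display-only).

    Returns the masked matrix and the survivor count over unordered
    off-diagonal pairs.  Surviving values are never altered.
    """
    if cutoff < 0:
        raise CorrelationError(f"cutoff must be >= 0, got {cutoff}")
    v = matrix.values
    mask = np.abs(v) <= cutoff
    np.fill_diagonal(mask, True)
    masked = np.ma.masked_array(v, mask=mask)
    survivors = int(np.sum(~mask[np.triu_indices_from(v, k=1)]))
    return masked, survivors


def extract_feature_blocks(
    delta: DifferenceMatrix, cutoff: float = 0.25
) -> list[FeatureBlock]:
    """Contiguous super-threshold regions of a ΔDCCM as bounding boxes.

    Survivors (|ΔC| > cutoff) in the upper triangle are grouped into
    8-connected components, separately for positive and negative sign, and
    each component is reported as its bounding residue ranges with the
    extremal |ΔC|.  Blocks are sorted by extremal value, descending.
    """
    v = delta.values
    resnums = delta.residue_numbers
    upper = np.triu(np.ones_like(v, dtype=bool), k=1)
    eight = np.ones((3, 3), dtype=int)
    blocks: list[FeatureBlock] = []
    for sign in (1, -1):
        survivors = (sign * v > cutoff) & upper
        labels, n_comp = ndimage.label(survivors, structure=eight)
        for comp in range(1, n_comp + 1):
            rows, cols = np.nonzero(labels == comp)
            vals = np.abs(v[rows, cols])
            blocks.append(
                FeatureBlock(
                    row_range=(int(resnums[rows.min()]), int(resnums[rows.max()])),
                    col_range=(int(resnums[cols.min()]), int(resnums[cols.max()])),
                    sign=sign,
                    extremal_value=float(vals.max()),
                )
            )
    blocks.sort(key=lambda b: b.extremal_value, reverse=True)
    return blocks


def save_matrix_csv(
    matrix: CorrelationMatrix | DifferenceMatrix, path: str | Path
) -> None:
    """Write a matrix as CSV with residue numbers as header row/column."""
    resnums = matrix.residue_numbers
    df = pd.DataFrame(matrix.values, index=resnums, columns=resnums)
    df.to_csv(path, index_label="residue")


def load_matrix_csv(path: str | Path, label: str = "") -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0)
    return CorrelationMatrix(
        residue_numbers=df.index.to_numpy(dtype=int),
        values=df.to_numpy(dtype=float),
        label=label,
    )
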