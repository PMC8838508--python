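"""Least-squares superposition (Kabsch) and fluctuation statistics.

RMSD per frame and RMSF per site are computed on a Cα selection after
optimal rigid-body superposition onto a reference structure.  Fluctuations
for the RMSF are taken about the trajectory mean position (superposition
target and fluctuation reference are distinct, matching the standard
trajectory-analysis pipeline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import Structure, Trajectory

__all__ = [
    "KabschResult",
    "FluctuationProfile",
    "RmsdSeries",
    "SuperpositionError",
    "kabsch_fit",
    "superpose_trajectory",
    "compute_rmsd_series",
    "compute_rmsf",
]

logger = logging.getLogger(__name__)


class SuperpositionError(ValueError):
    pass


@dataclass(frozen=True)
class KabschResult:
    rotation: np.ndarray     # (3, 3), proper: det = +1
    translation: np.ndarray  # (3,): x' = R @ (x - mobile_centroid) + translation
    rmsd: float              # Å, weighted RMSD after the fit
    mobile_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue RMSF (Å) on the analysis selection."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray
    reference_label: str = ""


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD (Å) to the reference, with frame times in fs."""

    time: np.ndarray
    rmsd: np.ndarray
    reference_label: str = ""


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> KabschResult:
    """Optimal rotation/translation minimizing the (weighted) RMSD.

    Uses the SVD of the weighted covariance matrix; a reflection is
    corrected by flipping the sign of the smallest singular vector so the
    returned rotation is always proper.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise SuperpositionError(
            f"point sets must both be (n, 3); got {X.shape} and {Y.shape}"
        )
    n = X.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 points for a unique fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise SuperpositionError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_x = w @ X
    mu_y = w @ Y
    Xc = X - mu_x
    Yc = Y - mu_y
    cov = Xc.T @ (Yc * w[:, None])
    U, s, Vt = np.linalg.svd(cov)
    if s[-1] < 1e-12 * max(1.0, s[0]):
        # rank-deficient covariance: all points (near-)collinear
        raise SuperpositionError(
            "degenerate covariance (collinear points): rotation not unique"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = Xc @ R.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - Yc) ** 2)))
    return KabschResult(rotation=R, translation=mu_y, rmsd=rmsd, mobile_centroid=mu_x)


def superpose_trajectory(
    traj: Trajectory,
    reference: Structure | np.ndarray,
    selection: np.ndarray,
) -> Trajectory:
    """Superpose every frame onto the reference via its own Kabsch fit.

    The fit is computed on the selection; non-selected atoms are carried
    along by the same rigid transform.
    """
    ref_coords = (
        reference.coordinates if isinstance(reference, Structure) else np.asarray(reference)
    )
    sel = np.asarray(selection, dtype=int)
    if sel.size and (sel.max() >= traj.n_atoms or sel.max() >= ref_coords.shape[0]):
        raise SuperpositionError("selection index out of range")
    ref_sel = ref_coords[sel]
    out = np.empty_like(traj.coordinates)
    for k in range(traj.n_frames):
        fit = kabsch_fit(traj.coordinates[k][sel], ref_sel)
        out[k] = fit.apply(traj.coordinates[k])
    return Trajectory(
        coordinates=out,
        timestep=traj.timestep,
        topology=traj.topology,
        elements=list(traj.elements),
    )


def compute_rmsd_series(
    traj: Trajectory,
    reference: Structure | np.ndarray,
    selection: np.ndarray,
    superpose: bool = True,
    reference_label: str = "reference",
) -> RmsdSeries:
    """Per-frame mass-unweighted RMSD over the selection.

    With ``superpose=True`` each frame gets its own least-squares fit before
    the deviation is measured; otherwise raw coordinates are compared.
    """
    ref_coords = (
        reference.coordinates if isinstance(reference, Structure) else np.asarray(reference)
    )
    sel = np.asarray(selection, dtype=int)
    ref_sel = ref_coords[sel]
    if ref_sel.shape[0] != sel.size:
        raise SuperpositionError("selection does not match reference size")
    rmsds = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame_sel = traj.coordinates[k][sel]
        if superpose:
            rmsds[k] = kabsch_fit(frame_sel, ref_sel).rmsd
        else:
            rmsds[k] = float(np.sqrt(np.mean(np.sum((frame_sel - ref_sel) ** 2, axis=1))))
    return RmsdSeries(time=traj.times, rmsd=rmsds, reference_label=reference_label)


def compute_rmsf(
    traj: Trajectory,
    selection: np.ndarray,
    residue_numbers: np.ndarray | None = None,
    superposed: bool = True,
    reference_label: str = "trajectory mean",
) -> FluctuationProfile:
    """Per-site RMSF about the trajectory mean position.

    RMSF_i = sqrt(⟨|r_i(t) − ⟨r_i⟩|²⟩_t).  The trajectory should already be
    superposed; ``superposed=False`` logs a warning (rigid-body motion then
    inflates the fluctuations) but still computes.
    """
    if traj.n_frames < 2:
        raise SuperpositionError("RMSF needs at least 2 frames")
    if not superposed:
        logger.warning(
            "compute_rmsf called on a trajectory not flagged as superposed; "
            "rigid-body motion will contaminate the fluctuations"
        )
    sel = np.asarray(selection, dtype=int)
    coords = traj.coordinates[:, sel, :]
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    if residue_numbers is None:
        residue_numbers = sel + 1
    return FluctuationProfile(
        residue_numbers=np.asarray(residue_numbers, dtype=int),
        rmsf=rmsf,
        reference_label=reference_label,
    )
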