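"""Rigid-body superposition and deviation/fluctuation metrics.

Implements Kabsch alignment (SVD with determinant correction so only
proper rotations are returned), RMSD time series with independent fit and
measure selections, the region-attribution "RMSD share" metric
(100 x (1 - RMSD without the region / full RMSD)) and per-residue RMSF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Trajectory

__all__ = [
    "Superposition",
    "RmsdShareSeries",
    "kabsch",
    "rmsd_series",
    "rmsd_share",
    "rmsf",
]

log = logging.getLogger(__name__)

#: Frames whose full-selection RMSD falls below this (nm) are skipped in
#: share computations to avoid 0/0 at the reference frame.
ZERO_RMSD_TOL = 1e-6


@dataclass(frozen=True)
class Superposition:
    """Proper rotation + translation minimizing weighted RMSD, plus the
    residual RMSD (nm) at the optimum."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), nm
    rmsd: float  # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Reflections are excluded by the usual sign correction on the smallest
    singular vector.  Degenerate inputs (< 3 points, or collinear points,
    for which the rotation about the line is undetermined) raise.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points for superposition, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm_p = w @ P
    cm_q = w @ Q
    Pc = P - cm_p
    Qc = Q - cm_q
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # collinear clouds leave the rotation about the common axis free
    if S[0] <= 0 or S[1] / S[0] < 1e-10:
        raise ValueError("degenerate geometry: points are (nearly) collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    t = cm_q - R @ cm_p
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _pairwise_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    diff = a - b
    sq = np.einsum("ij,ij->i", diff, diff)
    if weights is None:
        return float(np.sqrt(sq.mean()))
    w = np.asarray(weights, float)
    return float(np.sqrt((w / w.sum()) @ sq))


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (nm) to ``reference_frame``.

    Each frame is superposed on ``fit_selection`` and the RMSD measured on
    ``measure_selection`` (defaults to the fit selection).  Unweighted by
    default; ``weights`` applies to the fit selection.
    """
    fit = _as_selection(traj, fit_selection)
    measure = fit if measure_selection is None else _as_selection(traj, measure_selection)
    ref = traj.coords[reference_frame]
    out = np.empty(traj.n_frames)
    same = measure.shape == fit.shape and np.array_equal(measure, fit)
    for f in range(traj.n_frames):
        sup = kabsch(traj.coords[f][fit], ref[fit], weights=weights)
        if same:
            out[f] = sup.rmsd
        else:
            out[f] = _pairwise_rmsd(sup.apply(traj.coords[f][measure]), ref[measure])
    return out


def _as_selection(traj: Trajectory, selection: np.ndarray | None) -> np.ndarray:
    if selection is None:
        sel = traj.topology.backbone_indices()
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if sel.min() < 0 or sel.max() >= traj.n_atoms:
        raise ValueError("selection indices outside topology")
    return sel


@dataclass
class RmsdShareSeries:
    """Per-frame percentage of the full-backbone RMSD attributed to a
    region, 100 x (1 - RMSD excluding region / full RMSD)."""

    region: str
    frames: np.ndarray  # frame indices the share is defined for
    share: np.ndarray  # percentages, aligned with ``frames``
    n_skipped: int  # frames dropped because full RMSD ~ 0

    @property
    def mean(self) -> float:
        return float(self.share.mean())


def rmsd_share(
    traj: Trajectory,
    region_residues,
    reference_frame: int = 0,
    backbone: np.ndarray | None = None,
    region_label: str = "region",
    fit_mode: str = "self",
) -> RmsdShareSeries:
    """Attribute a fraction of the backbone RMSD to a residue region.

    ``fit_mode='self'`` (default) fits the excluded-region RMSD on its own
    atom set, mirroring single-selection RMSD tools; ``'full'`` fits on the
    full backbone and only measures on the reduced set.
    """
    backbone_sel = _as_selection(traj, backbone)
    region_atoms = set()
    for key in region_residues:
        region_atoms.update(traj.topology.atom_indices(key))
    excluded = np.asarray([i for i in backbone_sel if i not in region_atoms], dtype=int)
    if excluded.size == 0:
        raise ValueError("region covers the entire backbone selection")
    full = rmsd_series(traj, reference_frame, fit_selection=backbone_sel)
    if fit_mode == "self":
        part = rmsd_series(traj, reference_frame, fit_selection=excluded)
    elif fit_mode == "full":
        part = rmsd_series(traj, reference_frame, fit_selection=backbone_sel,
                           measure_selection=excluded)
    else:
        raise ValueError("fit_mode must be 'self' or 'full'")
    keep = full > ZERO_RMSD_TOL
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.info("rmsd_share: skipped %d frame(s) with full RMSD < %g nm",
                 n_skipped, ZERO_RMSD_TOL)
    share = 100.0 * (1.0 - part[keep] / full[keep])
    return RmsdShareSeries(region=region_label, frames=np.flatnonzero(keep),
                           share=share, n_skipped=n_skipped)


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
    reference_frame: int = 0,
) -> "dict[tuple[str, int], float]":
    """Per-residue RMS fluctuation (nm) about the time-average position.

    Frames are first superposed (on ``fit_selection``, defaulting to the
    measured selection) onto ``reference_frame``; the per-atom RMS deviation
    from the mean fitted position is then averaged, unweighted, over each
    residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _as_selection(traj, selection)
    fit = sel if fit_selection is None else _as_selection(traj, fit_selection)
    ref = traj.coords[reference_frame]
    fitted = np.empty((traj.n_frames, sel.size, 3))
    for f in range(traj.n_frames):
        sup = kabsch(traj.coords[f][fit], ref[fit])
        fitted[f] = sup.apply(traj.coords[f][sel])
    mean_pos = fitted.mean(axis=0)
    dev = fitted - mean_pos
    per_atom = np.sqrt(np.einsum("fij,fij->i", dev, dev) / traj.n_frames)
    out: dict[tuple[str, int], list[float]] = {}
    for idx, value in zip(sel, per_atom):
        key = traj.topology.atoms[idx].residue_key
        out.setdefault(key, []).append(float(value))
    return {key: float(np.mean(vals)) for key, vals in out.items()}
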