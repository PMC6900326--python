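"""Rigid-body least-squares superposition (Kabsch) and ensemble alignment.

Frames are fitted on a stable atom subset — by default the protein backbone,
never the waters or the ligand, which are the analytes whose apparent motion
the fit must not absorb — and the fitted transform is then applied to every
atom of the frame, waters included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentSelectionError, DegenerateFitError
from .io import Ensemble, Selection, StructureModel, backbone_selection, select


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")
        if self.fit_rmsd < 0:
            raise ValueError("fit_rmsd must be non-negative")


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Solves for the proper rotation/translation minimizing the (weighted)
    RMSD via SVD of the covariance matrix; a reflection in the solution is
    corrected by flipping the sign of the smallest singular vector.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need >= 3 points to fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    dm = mobile - mu_m
    dr = reference - mu_r
    H = dm.T @ (dr * w[:, None])
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 => points collinear: rotation about the line is undetermined
    if S[1] < 1e-10 * max(S[0], 1e-30) or S[0] == 0.0:
        raise DegenerateFitError("point set is (near-)collinear; fit is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    resid = dm @ R.T - dr
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", resid, resid))))
    return RigidTransform(rotation=R, translation=t, fit_rmsd=rmsd)


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (unfitted) RMSD between two coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d2 = np.einsum("ij,ij->i", a - b, a - b)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _fit_coords(model: StructureModel, sel: Selection, keys: list) -> np.ndarray:
    coords = []
    for key in keys:
        a = model.find_atom(key)
        if a is None:
            raise AlignmentSelectionError(
                f"fit atom {key} missing from frame {model.model_id}"
            )
        coords.append(a.coords)
    return np.array(coords)


def align_ensemble(
    ensemble: Ensemble,
    fit_selection: Selection | str | None = None,
    reference_frame: int = 0,
    reference_model: StructureModel | None = None,
) -> tuple[Ensemble, np.ndarray]:
    """Superpose every frame onto a reference on ``fit_selection`` atoms.

    The reference is frame ``reference_frame`` of the ensemble, or an
    external ``reference_model`` (e.g. a crystal structure) if given.  All
    atoms of each frame, waters included, are carried by the frame's fitted
    transform.  Returns the aligned ensemble and the per-frame fit RMSD
    series (A).
    """
    if isinstance(fit_selection, str):
        fit_selection = Selection.parse(fit_selection)
    if fit_selection is None:
        fit_selection = backbone_selection()
    reference = reference_model or ensemble.frames[reference_frame]
    ref_atoms = select(reference, fit_selection)
    if len(ref_atoms) < 3:
        raise AlignmentSelectionError(
            f"fit selection matches only {len(ref_atoms)} atom(s); need >= 3"
        )
    keys = [a.key for a in ref_atoms]
    ref_coords = np.array([a.coords for a in ref_atoms])

    new_frames = []
    fit_rmsds = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.frames):
        mob = _fit_coords(frame, fit_selection, keys)
        tf = kabsch_fit(mob, ref_coords)
        new_frames.append(frame.with_coords(tf.apply(frame.coords)))
        fit_rmsds[i] = tf.fit_rmsd
    aligned = Ensemble(
        new_frames, frame_interval=ensemble.frame_interval, t0=ensemble.t0
    )
    return aligned, fit_rmsds
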