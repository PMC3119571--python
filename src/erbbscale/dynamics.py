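"""Superposition, RMSD/RMSF and principal component analysis of
Calpha fluctuations.

The PCA follows the standard MD-trajectory recipe: frames are
superposed onto an iteratively refined mean structure (two passes),
the covariance of the selected coordinates is formed with population
normalisation (divide by the number of frames) and diagonalised, and
per-frame projections onto each eigenvector are returned.  With a
mean-structure reference the eigenvalue sum equals the total
positional variance, which the :class:`PCAResult` invariants assert.

Selections default to Calpha atoms; free N-/C-terminal tails are
included unless the caller masks them — tail-dominated low modes are
expected behaviour of kinase-domain trajectories, not an artifact.
PCA here is unweighted (no masses) and uses whatever atoms the
selection names; hydrogen exclusion is the caller's choice via the
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from erbbscale.errors import GeometryError, StatisticsError, UsageError
from erbbscale.io_formats import StructureModel, TrajectoryEnsemble


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation, Angstrom
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PCAResult:
    mean_coords: np.ndarray  # (n_sel, 3)
    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # (3*n_sel, n_modes), columns orthonormal
    projections: np.ndarray  # (n_frames, n_modes)
    selection: np.ndarray  # atom indices the PCA was run over

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.shape[0])


@dataclass(frozen=True)
class FluctuationProfile:
    residue_ids: np.ndarray
    amplitudes: np.ndarray  # Angstrom, >= 0

    def as_records(self) -> list[dict]:
        return [
            {"residue_id": int(r), "amplitude": float(a)}
            for r, a in zip(self.residue_ids, self.amplitudes)
        ]


def _check_selection(coords: np.ndarray, selection: np.ndarray) -> np.ndarray:
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise UsageError("selection is empty")
    if selection.size < 3:
        raise GeometryError("superposition needs at least 3 selected atoms")
    sel = coords[selection]
    centered = sel - sel.mean(axis=0)
    # Rank < 2 means all points are collinear (or coincident).
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("selected atoms are collinear/degenerate")
    return selection


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection=None
) -> SuperpositionResult:
    """Least-squares optimal rigid transform (Kabsch) of mobile onto
    reference over the selection; RMSD over the selection after the
    transform."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise UsageError(
            f"mobile {mobile.shape} and reference {reference.shape} differ in shape"
        )
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = _check_selection(mobile, selection)

    x = mobile[selection]
    y = reference[selection]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    traj: TrajectoryEnsemble, reference: np.ndarray, selection=None
) -> np.ndarray:
    """Frame-wise superposed RMSD against a reference frame."""
    reference = np.asarray(reference, dtype=float)
    return np.array(
        [superpose(frame, reference, selection).rmsd for frame in traj.frames]
    )


def _superpose_to_mean(
    frames: np.ndarray, selection: np.ndarray, passes: int = 2
) -> np.ndarray:
    """Superpose all frames onto their (iteratively refined) mean.

    Two passes: first onto frame 0, then onto the mean of the
    superposed set.  Returns the selected coordinates per frame.
    """
    sel_frames = frames[:, selection, :].copy()
    reference = sel_frames[0]
    n_sel = selection.size
    ident = np.arange(n_sel)
    for _ in range(passes):
        aligned = np.empty_like(sel_frames)
        for i, frame in enumerate(sel_frames):
            res = superpose(frame, reference, ident)
            aligned[i] = res.apply(frame)
        sel_frames = aligned
        reference = sel_frames.mean(axis=0)
    return sel_frames


def rmsf_profile(
    traj: TrajectoryEnsemble, selection=None
) -> FluctuationProfile:
    """Per-atom root-mean-square fluctuation about the mean structure,
    reported per residue (selection defaults to Calpha atoms)."""
    if selection is None:
        selection = traj.topology.select(atom_name="CA")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise UsageError("selection is empty")
    aligned = _superpose_to_mean(traj.frames, selection)
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    resids = np.array(
        [traj.topology.atoms[i].residue_id for i in selection], dtype=int
    )
    # Aggregate per residue (mean over that residue's selected atoms).
    uniq = np.unique(resids)
    per_res = np.array([rmsf[resids == r].mean() for r in uniq])
    return FluctuationProfile(residue_ids=uniq, amplitudes=per_res)


def pca(traj: TrajectoryEnsemble, selection=None) -> PCAResult:
    """PCA of superposed selected coordinates.

    Covariance uses population normalisation (divide by n_frames);
    eigenvalues are returned in descending order and the per-frame
    projections are onto the centered coordinates.
    """
    if traj.n_frames <= 3:
        raise StatisticsError(
            f"PCA needs more than 3 frames, got {traj.n_frames}"
        )
    if selection is None:
        selection = traj.topology.select(atom_name="CA")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise UsageError("selection is empty")
    aligned = _superpose_to_mean(traj.frames, selection)
    mean = aligned.mean(axis=0)
    flat = (aligned - mean).reshape(traj.n_frames, -1)
    # SVD of the centered data matrix is the stable route to the
    # covariance eigensystem; singular values give eigenvalues s^2/n.
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    eigenvalues = s**2 / traj.n_frames
    eigenvectors = vt.T
    projections = flat @ eigenvectors
    return PCAResult(
        mean_coords=mean,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        projections=projections,
        selection=selection,
    )


def variance_explained(result: PCAResult, k: int) -> float:
    """Fraction of total positional variance captured by the top-k modes."""
    if not (1 <= k <= result.n_modes):
        raise UsageError(f"k must be in [1, {result.n_modes}], got {k}")
    total = float(result.eigenvalues.sum())
    if total == 0.0:
        return 1.0  # a static trajectory has no variance to explain
    return float(result.eigenvalues[:k].sum() / total)


def mode_profile(result: PCAResult, topology: StructureModel, mode: int = 0) -> FluctuationProfile:
    """Per-residue displacement amplitude of one eigenmode."""
    if not (0 <= mode < result.n_modes):
        raise UsageError(f"mode must be in [0, {result.n_modes})")
    vec = result.eigenvectors[:, mode].reshape(-1, 3)
    # RMS displacement of the mode over time is sqrt(eigenvalue) per DOF.
    amp = np.linalg.norm(vec, axis=1) * np.sqrt(result.eigenvalues[mode])
    resids = np.array(
        [topology.atoms[i].residue_id for i in result.selection], dtype=int
    )
    uniq = np.unique(resids)
    per_res = np.array([amp[resids == r].mean() for r in uniq])
    return FluctuationProfile(residue_ids=uniq, amplitudes=per_res)


def write_profile_pdb(
    profile: FluctuationProfile, topology: StructureModel, path
) -> None:
    """Write the topology as PDB with per-residue amplitudes in the
    B-factor column (for fluctuation-colored rendering)."""
    amp = dict(zip(profile.residue_ids.tolist(), profile.amplitudes.tolist()))
    with open(path, "w") as fh:
        for atom in topology.atoms:
            b = amp.get(atom.residue_id, 0.0)
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            p = atom.position
            fh.write(
                f"ATOM  {atom.serial:5d} {name:<4s} {atom.residue_name:<3s} "
                f"{atom.chain}{atom.residue_id:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{min(b, 999.99):6.2f}"
                f"          {atom.element:>2s}\n"
            )
        fh.write("END\n")
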