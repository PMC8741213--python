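"""Trajectory loading, selection, superposition and per-residue flexibility.

The central container is :class:`ResidueTrajectory`: per-frame coordinates of
selected atoms grouped by residue, with the author residue numbering of the
topology preserved (e.g. 775-908 for the Cas9 HNH domain).  All downstream
analyses (contact frequencies, generalized correlations, networks) consume
this object, so global rigid-body motion should be removed with
:func:`superpose` before any correlation analysis -- correlations measured in
the laboratory frame conflate overall tumbling with internal motion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InputError

log = logging.getLogger(__name__)

#: aliases accepted by in-memory atom selections
_SELECTION_ALIASES = {
    "ca": "ca",
    "calpha": "ca",
    "c-alpha": "ca",
    "heavy": "heavy",
    "all": "all",
}


@dataclass
class ResidueTrajectory:
    """Per-frame coordinates of selected atoms grouped by residue.

    Parameters
    ----------
    residue_ids
        Ordered integer residue labels (author numbering preserved).
    atom_resindex
        For each atom, the index into ``residue_ids`` of its parent residue.
    atom_names
        PDB-style atom names, one per atom (``CA`` marks the alpha carbon).
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    frame_stride
        Time between stored frames, in arbitrary units (metadata only).
    superposed
        Whether a rigid-body fit has been applied; correlation analyses warn
        when this is False.
    """

    residue_ids: np.ndarray
    atom_resindex: np.ndarray
    atom_names: list[str]
    coords: np.ndarray
    frame_stride: float = 1.0
    superposed: bool = False

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.atom_resindex = np.asarray(self.atom_resindex, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise InputError("trajectory must contain at least one frame")
        if self.coords.shape[1] != len(self.atom_resindex):
            raise InputError("atom_resindex length does not match coords")
        if not np.isfinite(self.coords).all():
            raise InputError("coordinates contain non-finite values")
        if self.atom_resindex.size and (
            self.atom_resindex.min() < 0 or self.atom_resindex.max() >= len(self.residue_ids)
        ):
            raise InputError("atom_resindex out of range of residue_ids")

    # ------------------------------------------------------------------ sizes
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    # -------------------------------------------------------------- selection
    def atom_mask(self, selection: str = "all") -> np.ndarray:
        """Boolean mask over atoms for a selection alias (``ca``/``heavy``/``all``)."""
        key = _SELECTION_ALIASES.get(str(selection).strip().lower())
        if key is None:
            raise InputError(
                f"unknown selection {selection!r}; use one of {sorted(set(_SELECTION_ALIASES))}"
            )
        names = np.array(self.atom_names)
        if key == "ca":
            mask = names == "CA"
        elif key == "heavy":
            mask = ~np.char.startswith(np.char.upper(names.astype(str)), "H")
        else:
            mask = np.ones(self.n_atoms, dtype=bool)
        if not mask.any():
            raise InputError(f"selection {selection!r} matches no atoms")
        return mask

    def select(self, selection: str) -> "ResidueTrajectory":
        """Restrict to a selection, keeping residues that retain >=1 atom."""
        mask = self.atom_mask(selection)
        resindex = self.atom_resindex[mask]
        kept = np.unique(resindex)
        remap = {old: new for new, old in enumerate(kept)}
        dropped = set(range(self.n_residues)) - set(kept.tolist())
        if dropped:
            log.warning("selection %r drops %d residue(s) with no matching atoms",
                        selection, len(dropped))
        return ResidueTrajectory(
            residue_ids=self.residue_ids[kept],
            atom_resindex=np.array([remap[i] for i in resindex], dtype=int),
            atom_names=[n for n, m in zip(self.atom_names, mask) if m],
            coords=self.coords[:, mask, :],
            frame_stride=self.frame_stride,
            superposed=self.superposed,
        )

    def residue_atom_groups(self) -> list[np.ndarray]:
        """Atom indices per residue, in residue order."""
        return [np.flatnonzero(self.atom_resindex == i) for i in range(self.n_residues)]


@dataclass
class RMSDSummary:
    """Per-residue RMSD time series plus box-plot statistics.

    ``series`` has shape ``(n_frames, n_residues)`` in Angstrom; ``stats`` is a
    DataFrame with columns residue, median, q1, q3, whisker_lo, whisker_hi
    (Tukey 1.5*IQR whiskers clipped to the observed range).
    """

    residue_ids: np.ndarray
    series: np.ndarray
    stats: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.stats.to_csv(path, index=False)


def load_trajectory(topology_path, trajectory_path=None, selection="all") -> ResidueTrajectory:
    """Load a topology (+ optional trajectory) file into a :class:`ResidueTrajectory`.

    Accepts any format MDAnalysis reads (PDB topology with XTC/DCD or
    multi-model PDB trajectories).  ``selection`` is either one of the aliases
    ``ca``/``heavy``/``all`` or a full MDAnalysis selection string.
    """
    import MDAnalysis as mda

    alias = _SELECTION_ALIASES.get(str(selection).strip().lower())
    mda_sel = {"ca": "name CA", "heavy": "not name H*", "all": "all"}.get(alias, selection)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = (mda.Universe(str(topology_path), str(trajectory_path))
                 if trajectory_path is not None else mda.Universe(str(topology_path)))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read topology/trajectory "
                         f"({topology_path}, {trajectory_path}): {exc}") from exc
    atoms = u.select_atoms(mda_sel)
    if len(atoms) == 0:
        raise InputError(f"selection {selection!r} matches no atoms in {topology_path}")
    resids = atoms.residues.resids
    rid_index = {rid: i for i, rid in enumerate(resids)}
    atom_resindex = np.array([rid_index[a.resid] for a in atoms], dtype=int)
    coords = np.array([atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return ResidueTrajectory(
        residue_ids=np.asarray(resids, dtype=int),
        atom_resindex=atom_resindex,
        atom_names=[a.name for a in atoms],
        coords=coords,
    )


def discard_equilibration(traj: ResidueTrajectory, n_discard_frames: int) -> ResidueTrajectory:
    """Drop the first ``n_discard_frames`` frames (equilibration trim)."""
    if not 0 <= n_discard_frames < traj.n_frames:
        raise InputError(
            f"n_discard_frames must be in [0, {traj.n_frames}), got {n_discard_frames}"
        )
    if n_discard_frames == 0:
        return traj
    return replace(traj, coords=traj.coords[n_discard_frames:].copy())


def _kabsch_fit(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation + centroids for the least-squares fit of ``mobile`` onto ``ref``."""
    mob_c = mobile.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mobile - mob_c)
    return rot.as_matrix(), mob_c, ref_c


def superpose(traj: ResidueTrajectory, reference_frame: int = 0,
              fit_selection: str = "ca") -> ResidueTrajectory:
    """Rigid-body least-squares fit of every frame onto a reference frame.

    The optimal rotation is found over ``fit_selection`` atoms (Kabsch); the
    transform is then applied to all atoms.  Never increases the fit-region
    RMSD, and is idempotent up to numerical precision.
    """
    mask = traj.atom_mask(fit_selection)
    if mask.sum() < 3:
        raise InputError("superposition needs at least 3 fit atoms")
    ref_fit = traj.coords[reference_frame][mask]
    spread = np.linalg.matrix_rank(ref_fit - ref_fit.mean(axis=0), tol=1e-8)
    if spread < 2:
        raise InputError("fit atoms are collinear; superposition is underdetermined")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        R, mob_c, ref_c = _kabsch_fit(traj.coords[f][mask], ref_fit)
        out[f] = (traj.coords[f] - mob_c) @ R.T + ref_c
    return replace(traj, coords=out, superposed=True)


def per_residue_rmsd(traj: ResidueTrajectory, selection: str = "heavy",
                     reference_frame: int = 0, refit: bool = False) -> RMSDSummary:
    """Per-residue RMSD of selected atoms versus a reference frame, per frame.

    By default deviations are measured with respect to the stored (initial)
    positions without refitting; ``refit=True`` superposes first.  Residues
    with no selected atom are excluded with a logged warning.
    """
    if not 0 <= reference_frame < traj.n_frames:
        raise InputError(f"reference frame {reference_frame} out of range")
    work = superpose(traj, reference_frame) if refit else traj
    sub = work.select(selection)
    ref = sub.coords[reference_frame]
    # sq deviation per atom, then mean within each residue
    sq = ((sub.coords - ref[None]) ** 2).sum(axis=2)  # (F, A)
    groups = sub.residue_atom_groups()
    series = np.sqrt(np.stack([sq[:, g].mean(axis=1) for g in groups], axis=1))
    q1, med, q3 = np.percentile(series, [25, 50, 75], axis=0)
    iqr = q3 - q1
    lo = np.maximum(series.min(axis=0), q1 - 1.5 * iqr)
    hi = np.minimum(series.max(axis=0), q3 + 1.5 * iqr)
    stats = pd.DataFrame({
        "residue": sub.residue_ids, "median": med, "q1": q1, "q3": q3,
        "whisker_lo": lo, "whisker_hi": hi,
    })
    return RMSDSummary(residue_ids=sub.residue_ids, series=series, stats=stats)
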