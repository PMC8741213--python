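"""Contact frequencies and the environmental-perturbation (EP) score.

A contact-frequency matrix M records, for every residue pair (i, j), the
fraction of frames in which any selected-atom pair of the two residues lies
within a threshold radius rt (default 5 A, the typical upper distance for a
measurable NOE).  Comparing a variant's matrix with the wild type gives the
per-residue EP score

    EP_i^x = sum_j | M_ij^x - M_ij^WT |,

a measure of how much residue i's chemical environment is rewired by the
mutation x.  Scores estimated over independent blocks (replicas or trajectory
segments) are then thresholded at one standard deviation above the mean of
the EP data, and the surviving scores summed into the total perturbation
TEP^x = sum_i S_i^x, which can be compared across variants the way total NMR
chemical-shift perturbations are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .trajio import ResidueTrajectory

DEFAULT_RT = 5.0  # Angstrom


@dataclass
class ContactFrequencyMatrix:
    """Fraction of frames each residue pair spends within ``rt``.

    Symmetric, entries in [0, 1], unit diagonal (a residue is always in
    contact with itself).
    """

    residue_ids: np.ndarray
    matrix: np.ndarray
    rt: float = DEFAULT_RT
    selection: str = "heavy"
    n_frames: int = 0

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise InputError("contact matrix must be symmetric")
        if m.min() < 0 or m.max() > 1 + 1e-12:
            raise InputError("contact frequencies must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.residue_ids,
                     columns=self.residue_ids).to_csv(path)


@dataclass
class EPProfile:
    """Per-residue EP scores with the thresholded S_i and total TEP."""

    residue_ids: np.ndarray
    ep: np.ndarray                   # per-residue EP_i (block mean if blocked)
    s: np.ndarray | None = None      # thresholded scores; None before thresholding
    tep: float | None = None
    threshold: float | None = None   # <EP> + sigma actually applied
    ep_blocks: np.ndarray | None = None  # (n_blocks, n_residues) raw block estimates

    def to_frame(self) -> pd.DataFrame:
        data = {"residue": self.residue_ids, "ep": self.ep}
        if self.s is not None:
            data["s"] = self.s
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _min_residue_distance_freq(coords: np.ndarray, starts: np.ndarray,
                               rt: float, chunk: int = 200) -> np.ndarray:
    """Count frames with min inter-residue atom distance < rt.

    ``starts`` are the first-atom indices of each residue (atoms sorted by
    residue).  Frames are processed in chunks to bound memory.
    """
    n_frames = coords.shape[0]
    n_res = len(starts)
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for f0 in range(0, n_frames, chunk):
        block = coords[f0:f0 + chunk]  # (f, A, 3)
        diff = block[:, :, None, :] - block[:, None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1))  # (f, A, A)
        dmin = np.minimum.reduceat(d, starts, axis=1)
        dmin = np.minimum.reduceat(dmin, starts, axis=2)  # (f, R, R)
        counts += (dmin < rt).sum(axis=0)
    return counts


def contact_frequency(traj: ResidueTrajectory, rt: float = DEFAULT_RT,
                      selection: str = "heavy") -> ContactFrequencyMatrix:
    """M_ij = fraction of frames with the minimum selected-atom distance
    between residues i and j below ``rt``.

    The inter-residue distance is the minimum over all selected-atom pairs
    (use ``selection="ca"`` for a faster alpha-carbon-only mode).
    """
    if traj.n_frames < 1:
        raise InputError("contact frequency needs at least one frame")
    if rt <= 0:
        raise InputError(f"rt must be positive, got {rt}")
    sub = traj.select(selection)
    # sort atoms by residue so reduceat segments are contiguous
    order = np.argsort(sub.atom_resindex, kind="stable")
    coords = sub.coords[:, order, :]
    resindex = sub.atom_resindex[order]
    starts = np.searchsorted(resindex, np.arange(sub.n_residues))
    counts = _min_residue_distance_freq(coords, starts, rt)
    m = counts / traj.n_frames
    np.fill_diagonal(m, 1.0)
    return ContactFrequencyMatrix(residue_ids=sub.residue_ids.copy(), matrix=m,
                                  rt=rt, selection=selection,
                                  n_frames=traj.n_frames)


def ep_score(m_variant: ContactFrequencyMatrix,
             m_wt: ContactFrequencyMatrix) -> EPProfile:
    """Per-residue EP: row sums of |M^x - M^WT| over all residues.

    Symmetric under argument exchange.  Self-contacts (unit diagonals in both
    systems) contribute zero.
    """
    if (len(m_variant.residue_ids) != len(m_wt.residue_ids)
            or not np.array_equal(m_variant.residue_ids, m_wt.residue_ids)):
        diff = sorted(set(m_variant.residue_ids.tolist())
                      ^ set(m_wt.residue_ids.tolist()))
        raise InputError(f"contact matrices cover different residues: {diff}")
    ep = np.abs(m_variant.matrix - m_wt.matrix).sum(axis=1)
    return EPProfile(residue_ids=m_wt.residue_ids.copy(), ep=ep)


def split_blocks(traj: ResidueTrajectory, n_blocks: int = 3) -> list[ResidueTrajectory]:
    """Split a trajectory into ``n_blocks`` contiguous segments (stand-ins for
    independent replicas when only one trajectory is available)."""
    from dataclasses import replace
    if n_blocks < 1 or n_blocks > traj.n_frames:
        raise InputError(f"cannot split {traj.n_frames} frames into {n_blocks} blocks")
    edges = np.linspace(0, traj.n_frames, n_blocks + 1).astype(int)
    return [replace(traj, coords=traj.coords[a:b].copy())
            for a, b in zip(edges[:-1], edges[1:])]


def ep_threshold(ep_blocks: np.ndarray | list[EPProfile],
                 residue_ids: np.ndarray | None = None) -> EPProfile:
    """Threshold per-block EP estimates into S_i and the total TEP.

    ``ep_blocks`` holds one EP vector per block (replica or trajectory
    segment).  The per-residue score is the block mean; the significance
    threshold is the mean of all block-level EP values plus one standard
    deviation of that pooled data (the mean + 1 sigma of the EP score data).
    S_i keeps the block-mean EP where it strictly exceeds the threshold and is
    zero elsewhere; TEP = sum_i S_i.
    """
    if isinstance(ep_blocks, (list, tuple)) and ep_blocks and isinstance(ep_blocks[0], EPProfile):
        residue_ids = ep_blocks[0].residue_ids
        for p in ep_blocks[1:]:
            if not np.array_equal(p.residue_ids, residue_ids):
                raise InputError("EP blocks cover different residue sets")
        ep_blocks = np.stack([p.ep for p in ep_blocks])
    blocks = np.atleast_2d(np.asarray(ep_blocks, dtype=float))
    if blocks.shape[0] < 2:
        raise InputError(
            "thresholding needs >=2 blocks; split the trajectory "
            "(allonet.contacts.split_blocks) or provide replica estimates"
        )
    if residue_ids is None:
        residue_ids = np.arange(1, blocks.shape[1] + 1)
    ep_mean = blocks.mean(axis=0)
    threshold = float(blocks.mean() + blocks.std(ddof=0))
    s = np.where(ep_mean > threshold, ep_mean, 0.0)
    return EPProfile(residue_ids=np.asarray(residue_ids), ep=ep_mean, s=s,
                     tep=float(s.sum()), threshold=threshold, ep_blocks=blocks)
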