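"""Synthetic trajectories with planted correlation blocks and contacts.

The generator emulates the object every downstream stage consumes -- an
ensemble of residue coordinates fluctuating around a fixed topology -- with a
fully known ground truth.  Residues are grouped into blocks ("planted
communities"); each block is laid out as a compact cluster on a jittered cubic
lattice so that block members are geometrically in contact, while consecutive
blocks touch only at a narrow interface.  Per-frame displacements are drawn
from a zero-mean multivariate Gaussian whose inter-residue per-axis
correlation matrix is constructed from the planted intra-/inter-block rho
values, with the same correlation applied independently on x, y and z.  This
isotropic model has a closed-form mutual information, MI = -(3/2) ln(1-rho^2),
so the generalized correlation of a planted pair is exactly |rho| -- making
every estimator in the pipeline analytically checkable.

"Mutations" are modelled as perturbations that rewire specified correlation
entries and/or translate residues (changing contact frequencies
geometrically), mirroring how point mutations rewire the dynamic network of a
real protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InputError
from .trajio import ResidueTrajectory

__all__ = [
    "Perturbation",
    "SyntheticSystemSpec",
    "PlantedTruth",
    "generate_topology",
    "generate_trajectory",
    "apply_mutation",
    "write_fixture",
    "planted_network",
]


@dataclass(frozen=True)
class Perturbation:
    """A mutation-like rewiring of the planted correlation/contact structure.

    Parameters
    ----------
    residues
        Residue indices (0-based positions in the chain) the perturbation
        targets.
    rho
        If given, the per-axis correlation between every targeted residue and
        every residue of ``partner_block`` (or, when ``partner_block`` is
        None, among the targeted residues themselves) is set to this value.
    partner_block
        Optional block label; pairs are formed between ``residues`` and all
        members of this block.
    offset
        Optional (3,) translation in Angstrom applied to the base coordinates
        of the targeted residues, changing their contact frequencies
        geometrically.
    """

    residues: tuple[int, ...]
    rho: float | None = None
    partner_block: int | None = None
    offset: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Full description of a synthetic system; identical spec+seed gives
    byte-identical output."""

    n_residues: int
    block_assignment: tuple[int, ...]
    rho_intra: float = 0.8
    rho_inter: float = 0.1
    fluctuation_amplitude: float = 0.7  # Angstrom, typical folded-domain CA RMSF
    contact_spacing: float = 3.8  # Angstrom, lattice constant
    n_frames: int = 5000
    seed: int = 0
    ar1_phi: float = 0.0  # lag-1 temporal correlation; 0 = independent frames
    perturbations: tuple[Perturbation, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_residues < 2:
            raise InputError(f"n_residues must be >= 2, got {self.n_residues}")
        if len(self.block_assignment) != self.n_residues:
            raise InputError("block_assignment must have one label per residue")
        if self.n_frames < 2:
            raise InputError("n_frames must be >= 2")
        for r in (self.rho_intra, self.rho_inter):
            if not 0.0 <= r < 1.0:
                raise InputError(f"rho values must lie in [0, 1), got {r}")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise InputError("ar1_phi must lie in [0, 1)")

    @classmethod
    def with_blocks(cls, block_sizes: tuple[int, ...], **kwargs) -> "SyntheticSystemSpec":
        """Convenience constructor from a tuple of block sizes."""
        assignment = tuple(b for b, size in enumerate(block_sizes) for _ in range(size))
        return cls(n_residues=sum(block_sizes), block_assignment=assignment, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth accompanying a generated trajectory."""

    true_partition: np.ndarray  # residue -> block label
    true_pairwise_rho: np.ndarray  # (N, N) per-axis correlation
    perturbed_pairs: set[tuple[int, int]]
    ar1_phi: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "true_partition": self.true_partition.tolist(),
            "true_pairwise_rho": self.true_pairwise_rho.tolist(),
            "perturbed_pairs": sorted(map(list, self.perturbed_pairs)),
            "ar1_phi": self.ar1_phi,
        }
        Path(path).write_text(json.dumps(payload))


def _pair_set(spec: SyntheticSystemSpec, pert: Perturbation) -> set[tuple[int, int]]:
    for r in pert.residues:
        if not 0 <= r < spec.n_residues:
            raise InputError(f"perturbation residue index {r} out of range "
                             f"[0, {spec.n_residues})")
    pairs: set[tuple[int, int]] = set()
    if pert.partner_block is not None:
        partners = [i for i, b in enumerate(spec.block_assignment)
                    if b == pert.partner_block]
        if not partners:
            raise InputError(f"partner_block {pert.partner_block} has no members")
        for r in pert.residues:
            for p in partners:
                if p != r:
                    pairs.add((min(r, p), max(r, p)))
    else:
        rs = sorted(set(pert.residues))
        for i, a in enumerate(rs):
            for b in rs[i + 1:]:
                pairs.add((a, b))
    return pairs


def correlation_matrix(spec: SyntheticSystemSpec) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Planted per-axis correlation matrix and the set of perturbed pairs.

    Raises :class:`InputError` naming the offending perturbation if the
    resulting matrix is not positive definite.
    """
    blocks = np.asarray(spec.block_assignment)
    same = blocks[:, None] == blocks[None, :]
    rho = np.where(same, spec.rho_intra, spec.rho_inter).astype(float)
    np.fill_diagonal(rho, 1.0)
    perturbed: set[tuple[int, int]] = set()
    for pert in spec.perturbations:
        if pert.rho is None:
            continue
        for (a, b) in _pair_set(spec, pert):
            rho[a, b] = rho[b, a] = pert.rho
            perturbed.add((a, b))
    min_eig = float(np.linalg.eigvalsh(rho).min())
    if min_eig <= 1e-10:
        raise InputError(
            "planted correlation matrix is not positive definite "
            f"(min eigenvalue {min_eig:.3g}); offending rho combination: "
            f"intra={spec.rho_intra}, inter={spec.rho_inter}, "
            f"perturbations={spec.perturbations}"
        )
    return rho, perturbed


def _block_lattice(n: int, spacing: float) -> np.ndarray:
    """Snake-ordered cubic lattice with ``n`` sites and the given constant."""
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for ix in range(side):
        # boustrophedon in y and z so consecutive sites are always one step apart
        ys = range(side) if ix % 2 == 0 else range(side - 1, -1, -1)
        for iy in ys:
            zs = range(side) if (ix + iy) % 2 == 0 else range(side - 1, -1, -1)
            for iz in zs:
                pts.append((ix, iy, iz))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * spacing
    return np.array(pts[:n], dtype=float) * spacing


def generate_topology(spec: SyntheticSystemSpec, n_side_atoms: int = 0) -> ResidueTrajectory:
    """Base coordinates: one pseudo-CA per residue (plus optional side
    pseudo-atoms), blocks as adjacent lattice clusters.

    Blocks are placed side by side along x with a gap of one lattice constant,
    so residues at the interface of consecutive blocks are within contact
    range while block interiors are not.  Returned as a single-frame
    :class:`ResidueTrajectory` (writable as PDB via :func:`write_fixture`).
    """
    blocks = np.asarray(spec.block_assignment)
    labels = sorted(set(blocks.tolist()))
    base = np.zeros((spec.n_residues, 3))
    x_off = 0.0
    for lab in labels:
        members = np.flatnonzero(blocks == lab)
        lat = _block_lattice(len(members), spec.contact_spacing)
        lat[:, 0] += x_off
        base[members] = lat
        x_off = lat[:, 0].max() + spec.contact_spacing
    for pert in spec.perturbations:
        if pert.offset is not None:
            base[list(pert.residues)] += np.asarray(pert.offset, dtype=float)

    coords = [base]
    names = ["CA"] * spec.n_residues
    resindex = list(range(spec.n_residues))
    if n_side_atoms:
        rng = np.random.default_rng(spec.seed + 1_000_003)
        side = []
        for i in range(spec.n_residues):
            for s in range(n_side_atoms):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                side.append(base[i] + 1.5 * direction)
                names.append(f"CB{s}" if s else "CB")
                resindex.append(i)
        coords.append(np.array(side))
    return ResidueTrajectory(
        residue_ids=np.arange(1, spec.n_residues + 1),
        atom_resindex=np.array(resindex, dtype=int),
        atom_names=names,
        coords=np.concatenate(coords, axis=0)[None, :, :],
    )


def generate_trajectory(
    spec: SyntheticSystemSpec,
    truth_out: bool = False,
    n_side_atoms: int = 0,
) -> ResidueTrajectory | tuple[ResidueTrajectory, PlantedTruth]:
    """Sample a trajectory of correlated Gaussian fluctuations around the
    topology.

    Each axis is drawn independently from N(0, R) where R is the planted
    correlation matrix, then scaled by ``fluctuation_amplitude`` and added to
    the base coordinates (side pseudo-atoms ride rigidly with their residue).
    With ``ar1_phi`` > 0 frames follow a stationary AR(1) process with that
    lag-1 coefficient; by default frames are independent.
    """
    rho, perturbed = correlation_matrix(spec)
    topo = generate_topology(spec, n_side_atoms=n_side_atoms)
    L = np.linalg.cholesky(rho)
    rng = np.random.default_rng(spec.seed)
    # innovations: (frames, axes, residues)
    z = rng.standard_normal((spec.n_frames, 3, spec.n_residues))
    disp = z @ L.T
    if spec.ar1_phi > 0.0:
        phi, scale = spec.ar1_phi, np.sqrt(1.0 - spec.ar1_phi ** 2)
        for f in range(1, spec.n_frames):
            disp[f] = phi * disp[f - 1] + scale * disp[f]
    disp = np.transpose(disp, (0, 2, 1)) * spec.fluctuation_amplitude  # (F, N, 3)
    coords = topo.coords[0][None, :, :] + disp[:, topo.atom_resindex, :]
    traj = ResidueTrajectory(
        residue_ids=topo.residue_ids,
        atom_resindex=topo.atom_resindex,
        atom_names=topo.atom_names,
        coords=coords,
        superposed=True,  # no global motion is ever added
    )
    if not truth_out:
        return traj
    truth = PlantedTruth(
        true_partition=np.asarray(spec.block_assignment),
        true_pairwise_rho=rho,
        perturbed_pairs=perturbed,
        ar1_phi=spec.ar1_phi,
    )
    return traj, truth


def apply_mutation(spec: SyntheticSystemSpec, *perturbations: Perturbation) -> SyntheticSystemSpec:
    """Return a new spec with the perturbations appended; the original is
    unmodified and the perturbed correlation matrix is validated eagerly."""
    for pert in perturbations:
        for r in pert.residues:
            if not 0 <= r < spec.n_residues:
                raise InputError(f"perturbation residue index {r} out of range "
                                 f"[0, {spec.n_residues})")
    new = replace(spec, perturbations=spec.perturbations + tuple(perturbations))
    correlation_matrix(new)  # raises InputError if positive definiteness breaks
    return new


def write_fixture(structure: ResidueTrajectory, trajectory: ResidueTrajectory,
                  directory, fmt: str = "DCD") -> dict[str, str]:
    """Write a PDB topology and a trajectory file readable by
    :func:`allonet.trajio.load_trajectory`.

    Returns the paths written.  Round-trip loading reproduces coordinates
    within format precision (~1e-3 A for PDB/DCD).
    """
    import MDAnalysis as mda

    if trajectory.n_frames < 1:
        raise InputError("cannot write a 0-frame trajectory")
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create fixture directory {directory}: {exc}") from exc
    n_res = structure.n_residues
    u = mda.Universe.empty(
        n_atoms=structure.n_atoms, n_residues=n_res,
        atom_resindex=structure.atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", structure.atom_names)
    u.add_TopologyAttr("resids", structure.residue_ids)
    u.add_TopologyAttr("resnames", ["GLY"] * n_res)
    u.add_TopologyAttr("elements", ["C"] * structure.n_atoms)
    top_path = directory / "topology.pdb"
    u.atoms.positions = structure.coords[0]
    u.atoms.write(str(top_path))
    traj_path = directory / f"trajectory.{fmt.lower()}"
    with mda.Writer(str(traj_path), n_atoms=structure.n_atoms) as w:
        for frame in trajectory.coords:
            u.atoms.positions = frame
            w.write(u.atoms)
    return {"topology": str(top_path), "trajectory": str(traj_path)}


def planted_network(
    n_residues: int = 60,
    n_blocks: int = 3,
    gc_intra: float = 0.8,
    gc_inter: float = 0.1,
    seed: int = 0,
    gc_jitter: float = 0.05,
    n_bridges: int = 2,
):
    """Directly construct a contact-filtered dynamic network with planted
    block structure (bypassing trajectory sampling, for fast partition tests).

    Intra-block edges follow the lattice contact graph of
    :func:`generate_topology` including face-diagonal neighbours (so blocks
    are internally dense and cohesive); each consecutive block pair is joined
    by ``n_bridges`` interface edges.  Edge GC values are the planted levels
    plus uniform jitter, clipped to (0, 1).  Returns ``(DynamicNetwork,
    labels)``.
    """
    from .corrnet import DynamicNetwork, weight_from_gc
    import networkx as nx

    if n_residues % n_blocks:
        raise InputError("n_residues must be divisible by n_blocks")
    size = n_residues // n_blocks
    spec = SyntheticSystemSpec.with_blocks((size,) * n_blocks, seed=seed, n_frames=2)
    topo = generate_topology(spec)
    base = topo.coords[0]
    rng = np.random.default_rng(seed)
    blocks = np.asarray(spec.block_assignment)
    G = nx.Graph()
    G.add_nodes_from(int(r) for r in topo.residue_ids)
    # contact graph: lattice neighbours up to the face diagonal (sqrt(2) * a)
    cutoff = spec.contact_spacing * 1.5
    d = np.linalg.norm(base[:, None] - base[None, :], axis=2)
    bridge_budget: dict[tuple[int, int], int] = {}
    for i in range(n_residues):
        for j in range(i + 1, n_residues):
            if d[i, j] > cutoff:
                continue
            intra = blocks[i] == blocks[j]
            if not intra:
                key = (int(blocks[i]), int(blocks[j]))
                used = bridge_budget.get(key, 0)
                if used >= n_bridges:
                    continue
                bridge_budget[key] = used + 1
            gc = gc_intra if intra else gc_inter
            gc = float(np.clip(gc + rng.uniform(-gc_jitter, gc_jitter), 1e-3, 1 - 1e-3))
            u, v = int(topo.residue_ids[i]), int(topo.residue_ids[j])
            G.add_edge(u, v, gc=gc, weight=weight_from_gc(gc), contact=1.0)
    net = DynamicNetwork(graph=G, residue_ids=topo.residue_ids.copy(),
                         contact_fraction=0.75, rt=5.0)
    return net, blocks
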