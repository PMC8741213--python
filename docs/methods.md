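# Methods

## The model in one paragraph

A protein's allosteric communication is represented as a weighted residue
graph built from a molecular-dynamics ensemble: nodes are residues, edges
connect pairs in persistent geometric contact, and edge lengths are
−log GC_ij, the negative log of the mutual-information-based generalized
correlation between the residues' fluctuation vectors.  Short paths are
efficient information channels; communities are groups of residues with
synchronized dynamics; the total edge betweenness (EB) between communities
measures their communication strength.  A mutation is analyzed as a
*difference* between two such networks — per-residue contact rewiring (the
EP score) and inter-community communication change (ΔEB) — and is overlaid
with per-residue NMR observables (composite chemical shifts, CPMG
dispersion) that report on the same physics experimentally.

## Estimators and transforms

**Mutual information.**  MI(x_i, x_j) = H(x_i) + H(x_j) − H(x_i, x_j), in
nats, between two 3-D displacement series.  Three estimators:

- `ksg` (default): Kraskov–Stögbauer–Grassberger algorithm 1 with the
  Chebyshev (max-norm) metric, k = 6 neighbours.  k trades variance (small
  k) against bias (large k); 6 is a standard middle ground.  Marginal
  neighbour counts use strictly-inside radii (`nextafter` below the k-th
  joint distance).  Negative estimates — finite-sample noise under
  independence — are clamped to 0 and logged.
- `gaussian`: ½ log(det Σ_x det Σ_y / det Σ_xy) from sample covariances.
  Exact (up to sampling error) for the synthetic generator's Gaussian
  fluctuations, and far cheaper than KSG; used for the large synthetic
  validation fixtures.
- `histogram`: plug-in estimate on a 6-D joint histogram (default 6
  bins/axis).  Coarse cross-check only: binning discards information while
  undersampling of the bins⁶ cells inflates the estimate.

**GC transform.**  GC = (1 − e^(−2·MI/d))^(1/2) with d = 3; GC(0) = 0,
GC(∞) = 1.  For isotropic per-axis Gaussian correlation ρ,
MI = −(3/2)·ln(1 − ρ²) and hence GC = |ρ| exactly — the closed-form oracle
used throughout the tests.

**Edge weights.**  w = −log GC with GC clamped to [10⁻⁶, 1 − 10⁻⁶] so
weights are finite and strictly positive; clamping events are logged.

## Contacts and the EP score

M_ij is the fraction of frames in which the *minimum* inter-residue
selected-atom distance is below r_t = 5 Å (heavy atoms by default; a
Cα-only mode trades fidelity for speed).  M_ii = 1, so self-contacts cancel
in any difference.  EP_i = Σ_j |M_ij^x − M_ij^WT| is computed per block —
independent replicas, or contiguous trajectory segments when only one
trajectory exists (default 3 blocks).  The significance rule keeps the
block-mean EP_i where it exceeds mean + 1 std of the *pooled* block-level
EP data (all residues × blocks); TEP is the sum of surviving scores.  The
averaging set behind "mean + σ" is genuinely ambiguous in the source
analysis; the pooled convention is this package's documented choice, and
the components are stored on the profile for audit.

## Network, pathways, communities

Edges require M_ij ≥ 0.75 (and i ≠ j).  Pathways: Dijkstra optimum with
lexicographic tie-break on the node sequence; k-shortest (default 10) via
Yen's loopless algorithm, sorted by (weight, node sequence) for
bit-reproducibility; multiple sources/sinks are the Cartesian set of pairs.
Edge betweenness counts all-pairs weighted shortest paths with fractional
splitting among equal-weight ties (the standard betweenness convention; any
all-pairs algorithm equivalent to Floyd–Warshall gives the same counts, and
the implementation is checked against exhaustive enumeration rather than
tied to one algorithm).

Girvan–Newman removes the highest-EB edge (ties: lexicographically smallest
edge) and recomputes EB until the stopping point.  Two stopping rules:

- **Modularity maximum** (default): modularity is evaluated on the original
  graph using GC as the connection-strength weight — using the *distance*
  weight −log GC would invert the meaning of a strong link.
- **Fixed count** (`n_communities`): the partition when the requested number
  of components first appears, the convention used when a reference
  community count is known (e.g. the seven-community convention for the WT
  HNH domain, or the planted block count of a synthetic system).

On sparse nearest-neighbour contact graphs (lattice-like blocks of degree
~4) the modularity maximum can legitimately sit at a finer partition than
the planted blocks, so planted-truth validations use the fixed-count
convention; the modularity rule is validated on denser planted networks
where the two coincide.

**ΔEB.**  Both EB matrices are aggregated on the *WT* partition (enforced
via a partition checksum).  Raw ΔEB = EB^mut − EB^WT per community pair;
normalization divides by max |raw ΔEB| over the off-diagonal pairs of that
comparison, giving values in [−1, 1] (the source analysis states the range
but not the denominator — this is the package's documented choice, and the
attained extreme is therefore always ±1 for any nonzero comparison).
Intra-community (diagonal) changes are excluded from links and zeroed in
the normalized matrix; `include_diagonal=True` restores them.

A consequence worth stating: EB is a shortest-path *count*, so a
perturbation that rescales correlations without changing which edges exist
or which paths are shortest leaves ΔEB exactly zero.  Communication loss in
this framework is carried by topology changes — lost contacts, rerouted
paths — not by uniform weight shifts.

## NMR integration

Composite shift Δδ = sqrt(½[Δδ_H² + (Δδ_N/5)²]) (amide nitrogen scaled to
the proton chemical-shift range).  Significance: 10% trimmed mean (lowest
and highest 10% dropped — 20% of the data) plus 1.5 standard deviations;
σ is taken over all non-broadened composite shifts by default
(`sigma_over="trimmed"` restricts it to the surviving values).  Broadened
residues carry no composite value and are excluded from the statistics but
reported separately.  ΔR_ex is a plain difference on the residues fitted in
both tables.  The CPMG exchange network weights an *adjacent* community
pair (sharing ≥ 1 network edge, or user-supplied adjacency) by
n_active(A)·n_active(B) / (total actives)², which is invariant under
uniform rescaling of the counts; dividing by the total instead is exposed
as `normalization="total"`.

## The synthetic generator

What it emulates: an equilibrated, superposed ensemble of residue
coordinates with (i) block-structured inter-residue correlations (planted
communities), (ii) geometric contacts persisting in a controllable fraction
of frames, and (iii) mutation-like perturbations.  Key defaults, each
chosen once:

| parameter | default | why |
| --- | --- | --- |
| `rho_intra` / `rho_inter` | 0.8 / 0.1 | strong intra-block, weak inter-block coupling; GC of a planted pair equals the ρ planted |
| `fluctuation_amplitude` | 0.7 Å | typical Cα RMSF of a folded domain; keeps lattice contacts (3.8 Å apart) above the 75% persistence rule while face-diagonal pairs stay below it |
| `contact_spacing` | 3.8 Å | the Cα–Cα virtual bond length |
| `n_frames` | 5000 | sample correlations to ±0.05 |
| `ar1_phi` | 0 (independent frames) | none of the estimators requires temporal structure; AR(1) is available and recorded in the truth object |

Blocks are snake-ordered cubic lattice clusters abutting at one lattice
constant, so interface residues of consecutive blocks form a small number
of bridge contacts and blocks are otherwise geometrically separate.
Displacements are drawn per axis from N(0, R) with the same planted
correlation matrix R on x, y, z (Cholesky factorization; positive
definiteness checked eagerly and violations rejected naming the offending
combination), scaled by the amplitude, and added to the base coordinates;
side pseudo-atoms ride rigidly with their residue.  Identical spec + seed
gives byte-identical output.

The packaged "mutation" (`allonet.pipeline.synthetic_compare`) combines the
three effects a point mutation has on a real network: inter-block
decorrelation (ρ → 0 between the perturbed blocks), interface loss (a 3 Å
rigid offset of the mutated block, severing its bridge contacts), and local
repacking (a 1 Å seed-derived jitter of each mutated-block residue, which
perturbs that block's internal contact frequencies).  The first effect
alone would leave ΔEB zero (see above); the offset drives the ΔEB sign; the
jitter distributes EP signal across the mutated block the way a repacked
side chain would.

What it does **not** emulate — and what passing tests therefore do not
show: force-field physics, anisotropic or nonlinear fluctuations,
solvent-mediated contacts, nucleic-acid partners, slow conformational
exchange (the frames are i.i.d. or AR(1)), or the scale of real systems
(60-residue fixtures vs multi-microsecond trajectories of a 1368-residue
complex).  Conclusions about real allosteric systems require real
ensembles; the fixtures establish only that the estimators and graph
machinery recover planted structure correctly.

## Numerical choices and degenerate inputs

- GC clamp ε = 10⁻⁶; MI clamped at 0; diagonal GC fixed to 1.
- KSG symmetry is exact by construction; the matrix is nevertheless
  symmetrized by averaging as a guard for future estimators.
- Superposition: Kabsch via `scipy` rotation alignment; rejects < 3 or
  collinear fit atoms; idempotent to ~10⁻⁶ Å.
- σ conventions: EP threshold uses the population std of the pooled block
  data (ddof = 0, a descriptive summary); the NMR cutoff uses the sample
  std (ddof = 1, an estimate from assigned residues).
- Ties: max-EB edge removal and path ordering break ties lexicographically.
- Degenerate inputs rejected with named errors: 0-frame trajectories,
  empty selections, single-block EP thresholding, mismatched residue sets,
  perturbations breaking positive definiteness, community counts exceeding
  node counts.  Disconnected source/sink pairs are a "no path" result, not
  an error.

## Problem sizes

Validation fixtures are sized for interactive runs on one CPU: 60 residues
× 5000 frames for end-to-end comparisons (seconds with the Gaussian
estimator), 5–10 residue systems for estimator oracles, ≤ 8-node graphs for
exhaustive path/betweenness enumeration (100 seeds), and 20-seed
planted-partition sweeps.  The full test suite runs in about a minute; the
acceptance script in a few seconds.

## Known limitations

- The KSG estimator is O(pairs × n log n); all-pairs GC on hundreds of
  residues and 10⁴ frames is minutes, not seconds.  Use `method="gaussian"`
  for near-Gaussian ensembles or subsampled frames for a first pass.
- Yen's algorithm enumerates loopless paths; on dense graphs with large k
  it can be slow (irrelevant at k = 10 on contact-sparse residue graphs).
- The ΔEB normalization is per comparison; magnitudes are not directly
  comparable across variants (the sign structure and ranking are).
- `girvan_newman` recomputes exact weighted EB per removal — O(E²·V) overall
  — fine for single-domain networks, slow beyond ~10³ edges.
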