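# Methods

## Scope and data model

The package analyzes snapshot trajectories of a two-chain protein complex.
A trajectory is one fixed topology (atom identities from the first PDB
MODEL) plus an ordered stack of coordinate frames in Å and a uniform
sampling interval `dt_ns`. The PDB format carries no time information, so
`dt_ns` is always supplied by the caller; the CLI default of 2 ns matches
the sampling convention the analyses were designed around (a 2 μs run
recorded every 2 ns, i.e. 1001 snapshots counting t = 0). All analyses
assume the topology does not change across frames; a model with missing or
extra atoms is a hard error, not a warning.

## Superposition and RMSD

All deviation measures remove rigid-body motion first. The Kabsch solution
is computed by SVD of the covariance of the centered coordinate sets, with
the smallest singular direction sign-flipped when the raw optimum is a
reflection, so the rotation is always proper. Configurations with fewer
than three atoms, or collinear ones (second singular value ≤ 1e-8 of the
largest), are rejected: the rotation is not determined there. Atoms are
unweighted — the analyses run on backbone or Cα selections where mass
weighting makes no practical difference.

The 2D-RMSD matrix uses backbone atoms {N, CA, C, O} ("main chain"); RMSF
uses one CA per residue. The distinction mirrors the two conventions in
common practice: cluster geometry on the main chain, flexibility per
residue.

## Mean-structure alignment

RMSF, PCA and DCCM measure displacement about the trajectory mean, which
itself depends on the alignment. The fixed-point scheme: align every frame
to frame 0, form the mean, re-align all frames to the mean, and repeat
until the mean moves less than 1e-6 Å RMS (at most 10 iterations; in
practice 2–3 suffice because the update is strongly contractive). A
non-converged alignment raises with the final shift rather than silently
returning a drifting reference. Fluctuation about the *initial* structure
instead of the mean is available behind a flag (`reference="initial"`),
since either convention appears in published RMSF profiles.

## Coarsening and clustering

Snapshots are grouped into frames of `block` consecutive snapshots; any
remainder forms one final smaller frame, so 1001 snapshots with block 10
give 101 frames (100 full + 1 singleton) — reproducing the standard frame
count for the 2 μs / 2 ns protocol. Each frame's structure is the per-atom
mean of its snapshots after superposing block members onto the block's
first snapshot (mean rather than medoid: it suppresses within-block noise;
a medoid variant would be a straightforward extension but is not needed by
any consumer here).

Clusters are connected components of the graph with an edge wherever the
frame–frame RMSD is strictly below the cutoff (2 Å by convention). This is
the transitive closure of the pairwise rule — two frames more than 2 Å
apart can share a cluster through intermediates, which is the intended
reading of threshold clustering on a 2D-RMSD map. Cluster ids are assigned
by earliest member frame, making labels deterministic; the "largest"
cluster is the one with most member frames. The representative is the
member minimizing mean RMSD to the other members, ties broken toward the
earlier frame.

## Contacts and persistence

Hydrogen-bond detection is geometric, VMD-style. Because trajectory files
may or may not retain hydrogens, two modes exist:

* `explicit` — donor–acceptor heavy-atom distance ≤ 3.0 Å and D–H…A
  deviation from linearity ≤ 20°, hydrogens matched to donors within the
  same residue at < 1.25 Å;
* `heavy_only` (default) — donor–acceptor distance ≤ 3.5 Å with no angle
  term.

Donor/acceptor typing comes from standard residue templates (backbone N
donates except proline, backbone O accepts, canonical side-chain types);
non-standard residues are skipped with a warning. Salt bridges use
side-chain oxygens of ASP/GLU against side-chain nitrogens of LYS/ARG
within 3.2 Å; histidine is excluded from the basic set by default because
its protonation state is not knowable from coordinates alone (flag to
include). Backbone atoms never count toward salt bridges.

Persistence aggregates to the residue-pair level: any qualifying atom pair
marks the residue pair present in that snapshot, without multiplicity.
Occupancy tiers use strict inequalities — more than 5% of snapshots
("stable", equal to >100 ns of a 2 μs trajectory), >1% (>20 ns), >0.1%
(>2 ns) — and `duration_ns` is exactly `fraction × n_snapshots × dt_ns`.
Interface residues at a cutoff are those with any heavy atom strictly
within the cutoff of the other chain set; the 6/5/4 Å variants are nested
by construction.

## Dihedral ensembles

φ/ψ follow the IUPAC convention (φ = C(i−1)–N(i)–CA(i)–C(i),
ψ = N(i)–CA(i)–C(i)–N(i+1)), computed with the atan2 cross-product formula
and reported in degrees on (−180, 180] (the boundary maps to +180). Angles
undefined at chain termini are `None`, never 0. Ramachandran occupancy is a
normalized histogram on a g×g grid over the (φ, ψ) torus (default 36×36,
10° bins — fine enough to separate basins, coarse enough that a few hundred
snapshots populate it). Ensembles are compared with the Jensen–Shannon
divergence, base 2, which is symmetric and bounded in [0, 1]; the choice of
a scalar divergence (rather than a basin classifier) reflects that
reference Ramachandran comparisons in this setting are made between
ensembles of the same residue across trajectory periods.

## Essential dynamics

PCA diagonalizes the covariance (not correlation) matrix of the 3N Cα
coordinates about the converged aligned mean — the normalized form is
provided separately as the DCCM. The decomposition uses SVD of the centered
data with population (1/n) normalization, so each mode's projection
variance equals its eigenvalue exactly, and eigenvector signs are fixed by
making the largest-magnitude component positive. Optional `stride_ns`
subsamples snapshots (e.g. every 20 ns) before decomposition. Per-residue
mode mobility is the norm of the mode's residue 3-vector scaled by
√eigenvalue, so squared mobilities sum to the eigenvalue. DCCM rows for
zero-variance residues are zeroed off-diagonal with a warning instead of
propagating 0/0.

## Consensus-interface mapping and energy tables

The consensus interface template (positions of the RhoGAP-family interface
grid with their contacted RhoA residues) and the query-to-template
alignment map are *inputs*, supplied as TSV; the package neither computes
alignments nor asserts any particular template as scientific fact — the
shipped fixtures are synthetic miniatures for testing. Classification is
exact set logic: matched / unmatched / unmapped partition the records.
Binding free energies are likewise consumed as printed tables only; the
percentage ratio is computed on raw values and rounded to one decimal,
which for two negative ΔG values equals the magnitude ratio (mixed signs
raise a warning).

## Synthetic trajectories and what they do (not) show

The generator emulates the statistical structure the analyses assume:

* **States** — per-atom displacement fields active over snapshot intervals.
  A requested separation (Å) is realized exactly by scaling a zero-mean
  zig-zag field (alternating ±z per residue) until the post-superposition
  RMSD from the reference equals it (secant iteration, tolerance 1e-9 Å).
  Zig-zag is used because a uniform shift would be absorbed entirely by
  superposition.
* **Fluctuations** — isotropic Gaussian noise of σ Å per coordinate,
  independent across snapshots (optional AR(1) coefficient for stress
  tests), giving the closed form RMSF = σ√3.
* **Contacts** — a designated atom of chain B is placed at the bound or
  unbound distance from its chain A partner each snapshot, following a
  Bernoulli(duty) or contiguous-block schedule, so occupancy fractions are
  exactly the scheduled ones.
* **Modes** — sinusoids along orthonormal 3N vectors, each contributing an
  eigenvalue of amplitude²/2. Planted vectors should be projected off the
  rigid-body subspace (`rigid_free_modes`), otherwise the superposition
  step absorbs part of the motion and recovery is systematically biased —
  this is a property of essential dynamics itself, not of the generator.

Defaults mirror the reference protocol in miniature: 60 + 40 residues
(Cα-only), 1001 snapshots at 2 ns, σ = 0.5 Å (RMSF ≈ 0.87 Å, typical of a
folded domain). One integer seed makes output bit-identical; noise and
contact schedules use independently spawned generators so ground truth can
re-derive schedules without simulating.

What passing these tests does **not** show: the generator has no physics —
no bonded geometry between snapshots, no solvent, no correlated backbone
dihedral dynamics, no realistic contact formation kinetics. Recovery
results certify the *analysis* implementations (estimators recover planted
parameters under their own statistical assumptions); they say nothing about
force-field accuracy or sampling adequacy of real MD data.

## Problem sizes and numerical tolerances

Validation suites use 50–70 residue complexes with 1000–2000 snapshots —
large enough that binomial/χ² sampling bounds are tight (duty-cycle
recovery tested within 3 binomial SD; RMSF within 5% relative; planted mode
cosine ≥ 0.99) and small enough that the full suite runs in well under a
minute. Degenerate inputs fail loudly everywhere: empty selections,
sub-3-atom or collinear superpositions, empty periods, out-of-range mode
ranks and malformed PDB records all raise typed exceptions rather than
returning silent zeros.

## Known limitations

* PDB only (multi-model, v3.3 columns); no DCD/XTC/mmCIF.
* Protein-only residue templates; HETATM/waters skipped by default and
  never typed as donors/acceptors.
* No π-stacking, cation-π or hydrophobic contact detection.
* Cluster representative is a frame mean structure, not a raw snapshot;
  the frame's snapshot span is reported so the central snapshot can be
  retrieved when a physical structure is needed.
* The DCCM of strongly localized motions is contaminated at the few-percent
  level by the global superposition (a known property of the method).
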