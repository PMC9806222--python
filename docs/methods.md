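# Methods

This note records the models implemented, the choices made where the design
was genuinely open, and what the synthetic validation does and does not
establish about real trajectories.

## Superposition and RMSD

Rigid-body fits minimize the unweighted least-squares deviation over a fit
selection (SVD-based Kabsch with determinant correction, so reflections are
never returned; fewer than three or collinear atoms are rejected because the
rotation is not unique).  RMSD is plain geometric Cα RMSD — no mass
weighting.  When several replica trajectories are given, frames are pooled
with equal weight into one mean ± SD; per-replica series are also available
(`rmsd_series_per_replica`) since pooled-vs-per-replica aggregation
conventions differ between studies.  An equilibration discard is a plain
argument with default 0.

## Essential dynamics and free-energy landscapes

PCA diagonalizes the population covariance of the 3N fitted Cα Cartesian
coordinates (not per-residue scalars).  Replicas are concatenated after
per-frame fitting to the shared reference.  Eigenvector signs are fixed by
making each vector's largest-magnitude component positive, so projections
are reproducible across runs and platforms.  An optional separate fit
selection supports fitting on a rigid core while analyzing other atoms.

The landscape over (PC1, PC2) is ΔG = −k_B T ln(ρ/ρ_max) with
k_B = 0.0019872 kcal mol⁻¹ K⁻¹ and T = 300 K by default (the usual
simulation temperature); the occupied minimum is exactly 0 and empty bins
are NaN.  The default grid is 16×16 over the data extent for the synthetic
demo (80×80 is appropriate for microsecond-scale real data); optional frame
weights allow reweighted ensembles.

Basins are found by flooding occupied bins in order of increasing ΔG with
8-neighbor connectivity.  When two basins meet at level v, the shallower
survives as a separate basin only if its relief v − min exceeds the depth
threshold (default 0.5 kcal/mol ≈ 0.84 k_BT).  Because the statistical error
of a bin's free energy is ~k_B T/√c for count c, sparsely sampled tail bins
would otherwise masquerade as shallow basins; a reported basin's minimum bin
must therefore hold at least `min_support` samples (default 10).  The global
minimum is always reported.

## Dynamical cross-correlation

c_ij = ⟨Δr_i · Δr_j⟩ with Δr the full 3-vector displacement from the
ensemble mean of the *fitted* coordinates, and C_ij = c_ij/(c_ii c_jj)^½.
Fitting first matters: without it a uniformly translating system is
perfectly "correlated" everywhere (this property is tested).  One node per
residue at its Cα.  Zero-variance atoms get NaN rows/columns and an
`undefined` flag instead of a division by zero.  Display masking blanks
|C| < threshold (default 0.4, strict inequality — a coefficient exactly at
the threshold is kept).  For replicas both pooled-frame and
averaged-per-replica matrices are available; the pooled form is the default.

## Contact networks, communities, difference networks

Contact criterion: two residues are in contact in a frame if **any
heavy-atom pair** is within the cutoff (default 4.5 Å); the edge exists if
the contact holds in strictly more than the persistence fraction (default
0.75) of frames.  A Cα–Cα criterion at 4.5 Å would leave real protein graphs
essentially edgeless; the synthetic Cα-only chains in the demo use a 6 Å
cutoff for the same geometric reason (every atom there *is* a Cα).
First sequence neighbors (i, i±1 on one chain) are excluded so trivial
backbone contacts do not dominate betweenness.

Edge distances are D_ij = −ln|C_ij| (natural log; the base only rescales
distances and leaves betweenness orderings unchanged).  The absolute value
makes strongly anti-correlated pairs "close" as information conduits and
keeps D non-negative; edges with C = 0 or undefined C are dropped with a
warning.

Girvan–Newman: repeatedly remove the edge of maximum betweenness
(shortest-path betweenness, weighted by D when distances are attached; ties
broken by lexicographic edge id for determinism) and keep the partition of
maximum unweighted modularity among all partitions visited, including the
initial connected components.  Communities smaller than 3 residues are
omitted from the reported partition but kept in `full_assignment`.  The
oracle test compares against exhaustive maximum-modularity enumeration on
structured ≤10-node graphs (cliques joined by bridges, barbells, triangle
rings, complete and star graphs) — graphs whose optimum is representable by
hierarchical edge removal; Girvan–Newman provably cannot reach, e.g., the
three-arc optimum of a plain cycle, which is an inherent property of the
algorithm, not a defect of this implementation.

Difference networks hold the community partition of the reference state
fixed, sum |C_ij| edge weights between community pairs in each state, and
report the signed per-pair change B − A (antisymmetric under swapping
states).  Connection strength uses correlation magnitude because it reflects
coupling intensity; persistence is the fallback when correlations were never
attached.

## Solvation shells

g(r) is the distance histogram normalized by 4πr²dr shell volumes, frame
count, center count and bulk density; minimum-image distances are used when
box vectors are present (r_max is then capped at half the smallest box
edge).  Bulk density defaults to target count / box volume and can be
overridden.  n(r) is the cumulative pair count per center per frame, i.e.
ρ∫4πs²g(s)ds.  Coordination numbers evaluate n at the first minimum of a
smoothed g(r) after the first peak; a genuine first-shell peak must exceed
g = 2 so featureless profiles raise an error advising an explicit cutoff.
Water targets are oxygens only (the familiar 2.35 Å Ca–O peak is an
ion–oxygen distance).  Coordination-mode catalogues list every oxygen within
the cutoff (default 3.0 Å ≈ the Ca–O first minimum) with its residue and a
category (sidechain O / backbone O / water O); bidentate carboxylates
naturally contribute two records.  A 2.6–3.2 Å sensitivity sweep is emitted
by the analysis driver because published ligand listings rarely state their
cutoff.

The EF-hand NS2 site shipped with the package (`build_ns2_site`) is a
clearly-labelled **synthetic** pentagonal-bipyramidal reconstruction built
from the published ligand roles (sidechain oxygens of Asp56/Asp58/Asn60/
Asp64, the Thr62 backbone carbonyl, bidentate Glu67) at 2.4 Å; deposited
crystal coordinates are not bundled.  Scans of it validate the cataloguing
logic, not crystallography.

## Clustering and representatives

Pairwise frame distances are post-superposition RMSDs.  Clustering is the
deterministic GROMOS neighbor-count scheme: the frame with the most
neighbors within the cutoff seeds a cluster, its members are removed, and
the scan repeats; ties go to the lower frame index.  The representative of a
state is the medoid (minimum summed intra-cluster RMSD) of the most
populated cluster — note the medoid need not be the seed.  The default
cutoff is 2.0 Å Cα; the demo uses 1.2 Å because its substates are separated
by ≈2.3 Å post-fit with ≈0.9 Å intra-substate spread, and the cutoff should
sit between those scales.

## MM–GBSA energetics

Single-trajectory protocol: complex, receptor and ligand geometries come
from the same frame, so internal gas-phase terms cancel and ΔE_ele/ΔE_vdW
reduce to receptor–ligand cross sums.  Coulomb uses k_e = 332.06
kcal mol⁻¹ Å e⁻²; Lennard-Jones is the R*/ε convention (pair minimum at
R*_i + R*_j, depth √(ε_iε_j)).  The polar term is pairwise generalized Born,
E = −½(1/ε_in − 1/ε_out) k_e Σ q_iq_j/f_GB with
f_GB = [r² + R_iR_j exp(−r²/4R_iR_j)]^½ and self terms f = R_i.  Effective
Born radii use Hawkins–Cramer–Truhlar pairwise descreening (validated
against Monte-Carlo integration of the descreening volume integral and the
single-sphere analytic limit); the radius offset defaults to 0 Å so an
isolated sphere's effective radius equals its intrinsic radius exactly, and
both offset and the neighbour scaling factor are arguments.  Defaults
ε_in = 1, ε_out = 78.5.  The nonpolar term is γ·ΔSASA + b with γ = 0.0072
kcal mol⁻¹ Å⁻² and b = 0, over a Shrake–Rupley surface with a deterministic
golden-spiral point set (probe 1.4 Å, 960 points by default; the point set's
orientation dependence is the only non-invariance under rigid rotation and
shrinks with the point count).  TΔS is recorded as "not computed".

Totals are reported in two conventions, with and without the nonpolar term,
because published tables sometimes print gas + polar totals only: the
shipped published table's totals equal ΔE_ele + ΔE_vdW + ΔG_GB exactly,
excluding its ΔG_SA row (and its bound-state ΔE_vdW cell is corrupted in the
source text; the value in `data/published_binding_energies.csv` is
back-solved from the printed total, as noted in the file header).
Parameters arrive as a plain per-atom table (charge, R*, ε, GB radius), not
via force-field file parsing, which keeps the module testable on toys.

## Synthetic generators — what they emulate and what they don't

*Correlated ensembles*: frames are independent draws reference + A·z where z
is a correlated standard normal.  Displacements are isotropic per particle —
one correlated scalar stream per Cartesian axis — which makes the
displacement-vector correlation ground truth exactly the target matrix.  The
matrix square root is the symmetric eigendecomposition form
V·diag(√max(λ,0))·Vᵀ, fixed as part of the reproducibility contract.
Identical spec + seed gives bit-identical output.  Frames have no time
correlation, no anharmonicity and no rotational diffusion, so passing tests
validate estimator correctness, not convergence behavior on real MD, where
autocorrelation inflates statistical errors.

*Two-state mixtures*: i.i.d. Bernoulli(weight) labels select between two
correlated ensembles whose references differ by an internal (hinge)
deformation — a rigid offset would be invisible after superposition.  True
labels are returned for validation.

*Solvation toy*: fixed ion, shell particles at r₀ ± jitter in uniform random
directions, and ideal-gas bulk (uniform in the box, excluded only from a
sphere of r₀ + 3·jitter + 0.5 Å around the ion), making g(r) = 1 the exact
bulk limit.  No water structure, no excluded volume.

*Host–guest binding toy*: a 6-atom charged ring plus a 3-atom probe with
jittered frames, giving every energy term a genuine spread at closed-form
verifiable geometry.

## Demo study conditions

Two chains (32 + 16 residues) on an α-helix-like trace (2.3 Å radius, 100°
per residue, 1.5 Å rise — realistic Cα spacing so the contact graph is
non-trivial), fluctuation amplitude 0.5 Å, intra-block correlation 0.6,
inter-block −0.2 (reference) vs −0.5 (perturbed), 400 frames per state,
8 Å hinge between substates at weight 0.5.  These sizes keep the full demo
and test suite in the tens-of-seconds range while every statistical check
retains comfortable margins (e.g. ±0.05 on correlations needs ~10⁴ frames,
which the dedicated recovery tests use).

## Known limitations

* Girvan–Newman explores only hierarchical partitions (see above).
* The Shrake–Rupley surface is quadrature, not analytic; areas carry ~1/√n
  point noise and a small orientation dependence.
* The GB model is the pairwise HCT form without the OBC tanh rescaling or
  salt terms; it is intended for toys and method comparison, not production
  free energies.
* No periodic-boundary unwrapping: trajectories are assumed whole-molecule
  contiguous (true for the generators; real data should be pre-imaged).
* XTC I/O inherits the format's lossy 10⁻³ nm coordinate rounding.
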