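# Methods

## Elastic network and covariance

The ANM treats the CA trace as beads joined by identical Hookean springs
for every pair within `cutoff_rc`. Defaults are `cutoff_rc = 13 Å`,
`gamma_spring = 1`, `kT = 1`: PRS output is row-normalized, so the
absolute energy and stiffness scales cancel and only the cutoff shapes
the result. The Hessian is assembled densely; construction rejects inputs
that would make the spectrum ill-defined (fewer than three residues,
collinear coordinates, a contact graph that is disconnected at the
cutoff).

`anm_covariance` removes the six smallest-magnitude modes **by count**
and verifies that exactly six eigenvalues fall below
`zero_mode_tol · λ_max` (default 1e-8). Counting rather than thresholding
makes hidden mechanisms loud: a disconnected or hinged structure fails
with a clear error instead of silently contributing a near-singular mode
to the covariance.

`ensemble_covariance` superposes every frame onto an iteratively refined
mean (two passes of mean → superpose → re-mean), which removes the
dependence on frame order, then averages outer products of the flattened
deviations with a 1/F normalization. On frames drawn from an ANM's
thermal ensemble it recovers the generating covariance to ≈5 % relative
Frobenius error at F = 5000 (the sampling error scales as F^−1/2; the
F = 500 vs F = 5000 comparison in the tests checks that shrinkage).

## Perturbation response scanning

Unit force directions come from the golden-angle Fibonacci spiral:
z_k = 1 − 2(k+0.5)/M, φ_k = kπ(3−√5). M = 100 per scan is the default;
at that M the sampled response differs from the exact spherical average
tr(AᵀA)/3 by < 0.3 % on the helix benchmark, and the `analytic` scheme
provides the exact limit both as a fast path and as the oracle the
sampled path is tested against.

The response magnitude is the **mean squared** displacement norm. The
squared form admits the closed-form isotropic average used for
verification; a linear-magnitude variant would differ only monotonically
and not change rankings.

Normalization divides row i by `response[i, i]`. On soft structures the
normalized coupling of a strongly co-moving pair can exceed 1 (a residue
can respond more than the perturbed residue itself); the pathway layer
clips couplings to [ε, 1] before taking logs, so such edges simply get
zero weight and path selection falls back to the hop-count/lexicographic
tie-break.

Key residues are effector-profile outliers at a z-score threshold
(default 1.0, exposed as a flag). A constant profile returns an empty
list with a warning rather than an error. Note a structural fact of this
row normalization: residues that carry the softest collective modes have
the *largest* self-response and therefore rank low as effectors — in the
two-domain benchmark the bridge residues are top sensors, not top
effectors, and the effector outliers are stiff, well-anchored residues.

## Pathways

The graph is restricted to spatial CA contacts (default 10 Å) so paths
are chains of physically touching residues; a complete PRS-coupling graph
would make every route a trivial single hop. Edge weight
w = −ln(clip(p, ε, 1)) with ε = 1e-6 turns the product of couplings along
a path into an additive cost. Dijkstra is implemented directly (heap on
(weight, hops, node-sequence) tuples) because the deterministic
tie-break — fewer hops, then lexicographically smallest sequence — is
part of the output contract; networkx serves as an independent
path-length oracle in the tests, and exhaustive simple-path enumeration
on ≤ 8-node graphs checks optimality and the tie-break together.
Mediation counts interior nodes only, so endpoints never inflate their
own score.

## The synthetic benchmark (what it does and does not show)

`make_dumbbell` plants ground truth for pathway recovery: two
rejection-packed random domains (excluded volume 3.5 Å) whose only
connection is a channel of beads — an arc hugging each domain's surface
cap plus a single "waist" bead between the arcs. Everything on one side
of the waist is farther than the contact cutoff from everything on the
other side, so the waist is a graph cut vertex: channel traversal and
waist-dominated mediation hold by construction, which is exactly what
makes the fixture a benchmark rather than a demonstration.

A single-point articulation would leave rigid pivot mechanisms in an
elastic network built at the contact cutoff, so the generator guarantees
the clean six-zero-mode spectrum at a larger `anm_cutoff`
(default 16 Å = 1.6 × the contact cutoff), where the arc ends flanking
the waist come into spring range and pin the hinge; the generator
asserts all graph and spectral properties at generation time and
re-draws on failure. Coplanar channel beads would leave an exact torsion
mechanism about the inter-domain axis, so channel beads get small seeded
off-plane jitter.

What the fixtures do **not** emulate: real side-chain packing, sequence
effects, solvent, or the heterogeneous spring stiffnesses of a real
protein. Passing the planted-channel tests shows the machinery (covariance
→ PRS → weights → Dijkstra → mediation) is correct, not that a given real
protein's mediator call is right.

`sample_anm_ensemble` draws frames from the exact Gaussian equilibrium
distribution of the network (mode amplitudes √(kT/λ_k) · z_k), so the
population covariance equals the ANM covariance by construction — the
parameter-recovery tests are therefore consistency checks with a known
truth, not fits.

## Trajectory metrics

* Kabsch superposition uses the centered cross-covariance SVD with the
  determinant sign correction; collinear point sets are rejected because
  the in-line rotation is undetermined. A quaternion-based implementation
  in the tests serves as the independent oracle.
* RMSD series are measured against the first frame by default.
* RMSF superposes all frames to the iterated mean before measuring
  per-atom fluctuations.
* SASA is Shrake–Rupley with 960 Fibonacci test points and a 1.4 Å probe
  (both exposed); neighbor search uses a k-d tree. 960 points put the
  two-sphere benchmark within 1 % of the analytic spherical-cap area and
  halving the discretization error again (1920 points) moves totals by
  < 0.5 %.
* Hydrogen bonds use inclusive geometric criteria: donor–acceptor heavy
  distance ≤ 3.0 Å and D–H···A angle ≥ 135°, both exposed as parameters.
  Donor hydrogens are found by a 1.25 Å covalent-distance heuristic; a
  (D, A) pair counts at most once per frame.
* Histograms use 50 equal-width bins spanning [min, max] with
  right-inclusive last bin and frequencies normalized to 1.
* Frame clustering is k-means (k-means++ seeding, single init, ≤ 500
  iterations, tolerance 1e-6, fixed seed → bit-reproducible) on
  superposed flattened coordinates — a documented approximation to
  pairwise-RMSD clustering that is exact in the limit of small
  fluctuations. The representative of a cluster is its member frame
  nearest the centroid; k = 10 by default.

## Energetics

The energetics layer is bookkeeping, not a solver: ΔG_gas = ΔE_ele +
ΔE_vdW, ΔG_solv = ΔG_PB + ΔG_SA with ΔG_SA = γΔSASA + β, ΔH = ΔG_gas +
ΔG_solv, and optionally ΔG_bind = ΔH − TΔS with a user-supplied entropy
term (never computed here). Units are kJ/mol throughout; no conversion is
guessed. Per-snapshot tables are averaged with the standard error of the
mean. `audit_consistency` re-derives every aggregate present in a table
and flags mismatches above 0.01 kJ/mol — tight enough to catch
last-digit typesetting slips in published tables, which is its purpose.

## Problem sizes and numerical choices

Verification runs use a 20-residue helix (PRS, covariance, metrics),
10-residue-per-domain dumbbells with 3-bead channels over 20 seeds
(pathways), 5000-frame mode ensembles (covariance recovery), and 100
random ≤ 8-node graphs (Dijkstra) — sizes at which every claimed identity
can also be checked by brute force. Floating-point text output is
written at 6 significant digits; all stochastic components accept
explicit seeds and are bit-reproducible under them.

## Known limitations

* PDB support is the fixed-column ATOM/HETATM dialect (plus multi-model
  and plain XYZ frames); no mmCIF, no binary trajectory formats.
* The residue interaction graph is CA-contact based; side-chain-mediated
  couplings are invisible to it.
* One shortest path per residue pair (no k-shortest alternatives), and
  mediation is restricted to the supplied source/sink sets rather than
  all-pairs betweenness.
* The ensemble covariance assumes frames are pre-aligned conformers of
  one molecule; it does not handle alternate topologies or missing atoms.
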