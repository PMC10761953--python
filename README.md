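# prspath

Coarse-grained allostery analysis for proteins: **perturbation response
scanning** (PRS) over elastic-network or ensemble covariances,
**allosteric pathway extraction** by shortest paths on a PRS-weighted
residue contact graph, **trajectory stability metrics**
(RMSD/RMSF/R<sub>g</sub>/SASA/hydrogen bonds/clustering), and the
**MM-PBSA aggregation identities** for end-point binding free energies.

The package is aimed at structural bioinformaticians studying how a
binding event at one site of a protein (for example a non-competitive
peptide inhibitor docked away from the catalytic center) propagates to a
distal active site, and which residues mediate that communication.

## The model

A protein of N residues is reduced to its CA trace and represented as an
anisotropic network model (ANM): identical springs of stiffness γ connect
every residue pair within a cutoff r_c (default 13 Å). The 3N×3N Hessian
**H** has off-diagonal super-elements

    H_ij = -γ d_ij d_ijᵀ / |d_ij|²,   d_ij = r_j − r_i,

with diagonal super-elements enforcing zero row sums. Removing the six
rigid-body modes and inverting the rest gives the positional covariance
**C** = kT Σ_k λ_k⁻¹ v_k v_kᵀ (alternatively, **C** is estimated directly
from a superposed coordinate ensemble).

Linear response theory maps an external force **F** applied at one residue
to the first-order displacement everywhere: Δ**R** = (1/kT) **C F**. PRS
applies M = 100 unit forces per residue, generated quasi-uniformly with
the Fibonacci-sphere algorithm, and records the mean squared displacement
at every other residue:

    response[i, j] = (1/M) Σ_m |C_block(j,i) u_m|² / kT².

The exact isotropic limit ⟨|A u|²⟩ = tr(AᵀA)/3 is available as the
`analytic` scheme. Rows are normalized by self-response (unit diagonal);
row means and column means give effector and sensor profiles.

For pathways, residues within a contact cutoff (default 10 Å) form a
graph whose edges are weighted by w_ij = −ln p_ij, where p_ij is the
symmetrized normalized PRS coupling clipped to [ε, 1]. Dijkstra's
algorithm (deterministic tie-breaking) yields one minimum-weight path per
(binding-site, active-site) residue pair, and the **most-mediated
residue** is the one appearing as an interior node in the most paths.

## Worked example

`examples/02_allosteric_paths.py` builds a synthetic two-domain benchmark
whose domains are joined only through a planted three-residue channel,
then asks whether PRS-weighted shortest paths rediscover it:

```
dumbbell: 23 residues, planted channel = [11, 12, 13]
paths computed: 100; paths crossing the channel: 100
most-mediated residue(s): [11, 12, 13]
example path 1->14: [1, 3, 11, 12, 13, 17, 14] (total weight 0.000)
```

All 100 domain-A → domain-B shortest paths cross the channel, and the
mediation profile ranks exactly the channel residues on top — the same
calculation that, on a real structure, nominates the hub residue through
which allosteric signals converge on the active site. The other examples
cover the PRS scan itself (`01`), trajectory metrics on a synthetic
ensemble (`03`), and binding-energy aggregation with a table-consistency
audit (`04`); each prints the numbers it computes and a line on what they
mean.

A thin CLI wraps the same library calls:

```sh
prspath fixtures --kind dumbbell --n 10 --channel 3 --seed 1 --out work
prspath paths --pdb work/dumbbell.pdb --sources 1-10 --sinks 14-23 \
        --cutoff 16 --out work
```

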