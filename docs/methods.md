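# Methods

## Model

The protein is reduced to its Cα trace and treated as a 3-D elastic network:
nodes at the Cα positions, every pair *i, j* connected by a harmonic spring

    V = Σ_{i<j} γ_ij (|r_ij| − |r⁰_ij|)² / 2 ,

with the equilibrium geometry taken from the input structure. The spring
constants are distance-weighted, `γ_ij = γ / r²_ij` for **all** pairs —
there is no interaction cutoff, so the weighting itself attenuates distant
contacts smoothly instead of truncating them. The Hessian of this potential
at equilibrium has off-diagonal 3×3 blocks `H_ij = −γ_ij d dᵀ / r²` (with
`d` the pair separation vector) and diagonal blocks equal to the negated
off-diagonal row sums, which enforces translation invariance identically. A
uniform-spring cutoff mode (`weighting="cutoff"`) is kept for cross-checks
only.

Near equilibrium, an applied force maps to displacement through the
pseudo-inverse, `ΔR = H⁻¹ ΔF`. The pseudo-inverse is computed by
eigendecomposition, discarding eigenvalues below `1e-10 · λ_max`
(a threshold *relative* to the largest mode, so it is insensitive to
structure size). A non-degenerate 3-D body sheds exactly 6 zero modes
(3 translations + 3 rotations); any other count — 7 for a collinear
3-residue chain, 2N+1 for an N-residue line, N+3 for a strictly planar
body — is reported with a warning rather than an error, because the
pseudo-inverse remains well-defined.

### Perturbation response and the flexibility index

Perturbation Response Scanning applies unit forces at one residue at a time
and reads the displacement of all residues off the corresponding three
columns of `H⁻¹`. Two estimators of the N×N response matrix are available:

- **monte_carlo** — `A[i,j]` is the displacement magnitude of residue *j*
  averaged over k random unit force directions at residue *i*. Directions
  are drawn as k/2 uniform unit vectors plus their antipodes, so the force
  set has an *exactly* zero vector sum (isotropy holds by construction, not
  just in expectation). Default k = 10, the historical choice. The raw
  recipe averages the response *vector* over directions, but for any
  zero-sum force set that average vanishes by linearity; averaging the
  *magnitude* is the meaningful reading and the one implemented. An
  `average="rms"` variant is provided because the root-mean-square of the
  magnitudes is the quantity whose k→∞ limit is the analytic matrix below.
- **analytic** — the exact isotropic average: for a unit force uniformly
  distributed on the sphere, the RMS displacement magnitude of residue *j*
  is `sqrt(trace(G_ji G_jiᵀ)/3)` with `G_ji` the 3×3 block of `H⁻¹`.
  Deterministic, and the default.

The per-residue total response is the column mean `S_j = ⟨A[i,j]⟩_i`. The
self-perturbation row (i = j) is included by default — the matrix-mean
formulation — with `include_self=False` available; the two differ by
O(1/N). The index is the normalized total, `dfi_j = S_j / Σ_m S_m`
(so Σ dfi = 1 identically), and `%dfi` is the within-protein percentile
rank `100·rank/N` with average ranks for ties, which puts the most flexible
residue at exactly 100 and makes profiles from different proteins poolable
by concatenation.

The mean-of-magnitudes and RMS estimators differ slightly for anisotropic
response blocks (mean ≤ RMS by Jensen's inequality), but the *ranking* they
induce is nearly identical: at the default k = 10 the Spearman correlation
between Monte-Carlo and analytic dfi profiles on a 50-residue globule is
≥ 0.97 across seeds, and the RMS-combined Monte-Carlo matrix converges to
the analytic one within ~1% per entry at k = 10⁴.

### Spring-constant bookkeeping

dfi is a ratio, so the global spring constant γ cancels exactly — in exact
arithmetic. To make that cancellation hold in floating point as well, γ is
kept symbolic: the Hessian is stored and eigendecomposed at γ = 1, and only
scale-carrying outputs (the response matrix and S, in Å per unit force) are
multiplied by 1/γ on access. Rescaling all springs therefore changes no dfi
value in any bit, which the test suite asserts literally. Units are Å and
unit force throughout; every downstream quantity is relative, so the
choices cancel.

### Effective mobility

For comparison, `gnm_mobility` computes the slow-mode profile of the
one-dimensional (Kirchhoff/Gaussian-network) version of the same network:
the N×N connectivity matrix under the same inverse-square weighting is
pseudo-inverted and the mode sum `Σ u_k u_kᵀ / λ_k` is accumulated over the
`n_slow_modes` smallest nonzero modes (default 10 — the mode count used in
published mobility comparisons varies, so it is an explicit parameter).
Mode selection never splits a degenerate eigenvalue multiplet: truncating
inside a tied pair would make the sum depend on the arbitrary eigenvector
basis LAPACK returns (on a symmetric ring it would break the uniformity the
symmetry dictates), so the selection is extended to the end of the tied
group. The diagonal of the mode sum is the mobility; it is reported with
its percentile rank (%EM).

## Downstream statistics

- **Binning** uses the five categories <20, 20–40, 40–60, 60–80, ≥80
  (left-closed, right-open, last bin closed at 100); boundaries are
  parameters.
- **Enrichment**: with n_i profiled positions in category i out of N, and M
  variants total, the expected count is `E_i = (n_i/N)·M`; the statistic is
  `χ² = Σ (O_i − E_i)²/E_i` over categories with `E_i > 0`, with
  `dof = (#categories with E_i > 0) − 1` (totals fixed at M) and an
  upper-tail p-value. Empty categories are excluded with a warning.
  Variants are counted with multiplicity; positions carrying several labels
  enter each analysis independently.
- **Sliding-window correlation**: residues sorted by %dfi, windows of
  `window_size` residues advanced by `step` (defaults `max(50, N/20)` and
  half-window), Pearson correlation between window-mean %dfi and
  window-mean rate. The windows — and hence the rate series — depend on the
  sort key only through its ordering; the Pearson value itself uses the
  window-mean %dfi, so it is exactly invariant under affine rescalings and
  empirically stable (sign and ordering preserved) under general monotone
  transforms. A permutation helper re-computes the statistic under random
  rate shufflings.
- **Conservation groups**: r = 0 (ultra-conserved), 0 < r ≤ 1
  (well-conserved), r > 1 (less conserved), with five-number %dfi summaries
  per group; empty groups report as absent.
- **Group differences** use Welch's unequal-variance t-test
  (Welch–Satterthwaite degrees of freedom, two-sided); two constant groups
  with equal means return t = 0, p = 1 by convention.

## Synthetic fixtures

The generator produces four structure families with known ground truth:

- **linear_chain** — collinear beads at 3.8 Å. Deliberately degenerate
  (2N+1 zero modes): exercises the null-space bookkeeping and the
  end-effect prediction (terminal residues most flexible).
- **ring** — N beads with equal 3.8 Å adjacent distances. A strictly planar
  ring of central-force springs is degenerate (every out-of-plane
  displacement costs no energy to first order, N+3 zero modes), so rings
  with even N are crown-puckered: vertices alternate ±spacing/4 out of
  plane, with the radius adjusted so adjacent distances still equal the
  spacing. The crown is vertex-transitive, so dfi is uniform and the
  response matrix circulant, while the structure is a genuine 3-D body with
  6 rigid modes. Odd N falls back to the planar, degenerate ring.
- **globule** — self-avoiding uniform points in a sphere, minimum pair
  distance 3.5 Å, packed at 0.006 residues/Å³ (≈165 Å³ per residue, the
  density of a folded domain). Rejection sampling; an infeasible request
  fails after 10⁴ attempts with advice to lower the density. The simplest
  fixture with 6 rigid modes and a heterogeneous profile.
- **dumbbell** — two globular lobes whose centres are separated by the
  linker span `(n_link+1)·spacing`, joined by collinear linker beads on the
  axis; the minimum pair distance is enforced globally, so the lobes pack
  against the linker at the interface the way domains pack around a real
  hinge. Residue order: lobe A, linker, lobe B.

Annotation tables are planted with known parameters: variant positions are
sampled (with replacement by default) with probability proportional to a
per-category weight vector — the shipped example weights (1.45, 1, 1, 1,
0.65) mirror the enrichment/depletion magnitudes reported for
disease-associated variants — and per-site rates follow
`r = slope·(%dfi/100) + N(0, σ)` truncated at zero. Both are exactly
recoverable by the analysis module within sampling error, which is the
package's core self-consistency loop.

What the fixtures do *not* emulate: chain connectivity (globule residues
are a spatial cloud, not a polymer), secondary structure, side chains,
heterogeneous contact anisotropy, and real variant/rate data. Passing tests
therefore demonstrate that the machinery is correct and calibrated — not
that any biological conclusion holds for a particular protein.

### The hinge check and its limits

On the dumbbell, the linker's *end* beads — clamped between the linker and
a lobe — are reproducibly the most rigid residues in the structure (ranks
1–3 of 43 across packings). The *middle* bead of a straight central-force
strand, however, receives no transverse restoring force from its own
axial neighbours (central springs are first-order blind to perpendicular
displacement), so its transverse support comes only from stochastically
placed lobe contacts; it lands at rank ≈ N/9 (typically %dfi 7–16) and
falls inside the strict lowest decile in only about half of random
packings, at every lobe size (18–100 residues) and density (0.0015–0.012
Å⁻³) examined. The test suite therefore asserts two levels: the robust
property (linker ends in the lowest decile, whole linker in the lowest
quintile) as a standing regression test, and the strict all-linker-decile
property as an acceptance check on the canonical fixture, which is
expected to fail for many packings and is documented as such.

## Numerical choices

- Zero-mode threshold: `1e-10 · λ_max`, relative.
- Percentile convention: `100·rank/N`, ties averaged; values lie in
  (0, 100].
- Degenerate geometries warn and proceed where the pseudo-inverse exists;
  coincident residues are an error.
- PDB coordinates are rounded to 3 decimals on reading (the field
  precision), which makes read → write → read round-trips bit-exact.
- Altloc handling keeps the highest-occupancy conformer, ties to the
  first listed; multi-model files default to the first model; MSE
  (selenomethionine) HETATM records are treated as polymer by default;
  waters and ligands are ignored.
- Monte-Carlo standard errors of dfi (spread of per-direction profiles over
  the k directions) are attached to Monte-Carlo results as a convergence
  diagnostic.

## Problem sizes

The shipped tests and the acceptance script use fixtures of 10–500
residues: large enough for 6-mode rigid-body structure, heterogeneous
profiles and stable category counts, small enough that the full suite runs
in seconds. Monte-Carlo convergence is checked at k = 10⁴ on a 50-residue
globule; enrichment recovery uses 10⁴ variants over 500 positions;
chi-squared calibration uses 2 000 null replicates of 200 variants each.

## Known limitations

- mmCIF input is not supported (PDB only), and no sequence-level mapping to
  reference proteins is attempted: annotations must already use the
  structure's author numbering.
- The directional/allosteric side of response scanning (asymmetric
  perturbation-specific pathways) is out of scope; only the isotropic index
  is computed.
- Evolutionary rates, structural-motif labels, and functional-site flags
  are consumed as inputs; the package does not estimate them.
- The dense `eigh` pseudo-inverse is O(N³): comfortable to a few thousand
  residues, not intended for megacomplexes.
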