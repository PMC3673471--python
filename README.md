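# dfiscan

Per-residue **dynamic flexibility index (dfi)** from elastic-network models of
protein structures, together with the downstream statistics used to relate
flexibility to variants, functional sites, and evolutionary rates.

## The problem and the method

A folded protein is constantly perturbed — by collisions in the crowded cell,
by ligands, by mutations. Some residue positions absorb such perturbations
almost without moving (dynamically robust, hinge-like sites); others are
easily displaced (flexible sites). The dfi quantifies this per position, so
that structural dynamics can be used alongside conservation when judging
which positions matter: disease-associated variants concentrate at
dynamically robust positions, catalytic residues sit at rigid sites, and
slowly evolving positions have low flexibility.

The model is a coarse-grained elastic network on the Cα trace. Every residue
pair *i, j* is connected by a harmonic spring whose stiffness is weighted by
the inverse square of the pair distance (no interaction cutoff), giving the
3N×3N Hessian **H** of the network potential. Linear response theory turns an
applied force into a displacement:

    ΔR = H⁻¹ ΔF

where **H**⁻¹ is the pseudo-inverse with the six rigid-body modes removed.
Perturbation Response Scanning (PRS) applies unit forces at each residue *i*
in turn — by default k = 10 random directions built as antipodal pairs, so
the force set has an exactly zero angular average — and records the average
displacement magnitude of every residue *j*, giving the N×N response matrix
*A*. The per-residue totals and their normalization define the index:

    Sⱼ = ⟨A[i, j]⟩ᵢ        dfiⱼ = Sⱼ / Σₘ Sₘ

High dfi marks flexible sites; low dfi marks robust, hinge-like sites.
Because dfi is protein-specific, profiles are pooled across proteins through
the within-protein percentile rank **%dfi**. An exact `analytic` mode
replaces the Monte-Carlo direction average with the closed-form
root-mean-square response under isotropic forcing,
`A[i,j] = sqrt(trace(G_ji G_jiᵀ)/3)` with `G_ji` the 3×3 coupling block of
**H**⁻¹.

On top of the index, the `analysis` module implements:

- **Variant enrichment**: observed vs expected variant counts in %dfi
  categories (<20, 20–40, 40–60, 60–80, ≥80), with `E_i = (n_i/N)·M` and a
  chi-squared goodness-of-fit test;
- **Flexibility distributions** of labelled residue sets (catalytic/binding);
- **Sliding-window correlation** of per-site evolutionary rates
  (substitutions/site/Byr) with %dfi, plus conservation-group summaries
  (r = 0, 0 < r ≤ 1, r > 1) and a Welch unequal-variance group test;
- **Effective mobility (%EM)**: the slow-mode Gaussian-network profile the
  3-D index is contrasted with.

A `fixtures` module generates toy structures (chains, rings, self-avoiding
globules, two-domain dumbbells) and planted annotation tables so every stage
is testable with known ground truth and no downloads.

## Worked example

Generate a two-domain dumbbell (two 20-residue lobes joined by a 3-residue
linker), score it, and test a planted variant table for enrichment:

```bash
dfi fixtures --kind dumbbell --n 43 --seed 7 --out toy.pdb
dfi compute toy.pdb --mode analytic --out toy.dfi.tsv --pdb-out toy_colored.pdb
```

```text
Dynamic Flexibility Index Results
==============================================
residues:        43
weighting:       inverse_square (gamma=1)
estimator:       analytic
zero modes:      6
sum(dfi):        1.000000000000
dfi range:       [1.271e-02, 3.781e-02]
most rigid:      ALA A21 (%dfi=2.3)
most flexible:   ALA A27 (%dfi=100.0)
==============================================
```

Residue 21 — the interdomain linker — is the most rigid position in the
structure: it sits at the hinge and barely moves whatever is perturbed.
`toy.dfi.tsv` holds one row per residue (`S`, `dfi`, `pct_dfi`), and
`toy_colored.pdb` carries %dfi in the B-factor column for ribbon colouring.

```bash
dfi fixtures-annotations --profile toy.dfi.tsv --weights 1.45,1,1,1,0.65 \
    --m 1000 --seed 7 --out ann.tsv
dfi enrich --profiles toy.dfi.tsv --annotations ann.tsv --label disease
```

```text
# label = disease; bins = 20,40,60,80; N = 43; M = 1000
     bin  n_positions  observed   expected    ratio
  [0,20)          8.0     283.0 186.046512 1.521125
 [20,40)          9.0     217.0 209.302326 1.036778
 [40,60)          8.0     164.0 186.046512 0.881500
 [60,80)          9.0     200.0 209.302326 0.955556
[80,100]          9.0     136.0 209.302326 0.649778
chi2 = 79.5060, dof = 4, p = 2.22e-16
```

Variants were planted 1.45× enriched in the most rigid category and 0.65×
depleted in the most flexible one; the observed/expected ratios recover both
weights and the chi-squared test rejects uniform placement.

The same pipeline is available as a library:

```python
from dfiscan import DynamicFlexibilityModel

model = DynamicFlexibilityModel.from_pdb("toy.pdb")   # or from a structure
res = model.fit()                                     # analytic estimator
res.pct_dfi                                           # per-residue %dfi
print(res.summary())
```

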