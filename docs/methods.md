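# Methods

## Molecule representation

A mononuclear transition-metal complex with `N` heavy atoms is a point cloud
`x = [r, h_a, h_L, h_c]`:

- `r` — Cartesian coordinates in Å, translated so the metal sits at the
  origin. Fixing the metal removes the translational degree of freedom, so
  the network only has to handle rotations (and reflections).
- `h_a` — one-hot atom type over the 15 heavy elements of the curated
  vocabulary {C, N, O, F, P, S, Cl, Br, Cr, Mn, Fe, Co, Ni, Cu, Zn}.
  Hydrogens are stripped on ingest; re-addition is a backend hook, not
  implemented chemistry. Structures whose centre is a d-block metal outside
  this vocabulary parse fine but cannot be embedded (typed error).
- `h_L` — one-hot ligand membership with `l_max = 12` slots. Slot 0 is
  reserved for the metal centre; requesting more codes than `l_max` raises a
  context-overflow error rather than silently truncating.
- `h_c` — one-hot coordination code with 7 slots: slot 0 marks the metal,
  slots 1–6 carry the denticity class of the atom's owning ligand. The code
  conditions at ligand granularity (donor atoms are not distinguished from
  non-donor atoms within a ligand); for generated ligands it carries the
  *assigned* denticity from LD_g. Giving the metal its own slot keeps the
  invariant that every one-hot row sums to exactly 1.

`h_L` and `h_c` concatenate to the conditioning channel `h_Lc`. The feature
scaling `(0.1, 0.25, 1.0)` for `(r, h_a, h_Lc)` — emphasising the
conditioning channel — is recorded on every embedding and applied inside the
denoiser's featurizer; the stored arrays stay in physical units, so the
scaling can never be applied twice.

## Bond perception and ligand partitioning

Atoms `i, j` bond iff `d(i,j) ≤ r_cov(i) + r_cov(j) + 0.4 Å` (Cordero radii
via RDKit). Metal–donor dative bonds are longer, so donor detection uses the
same rule with a 0.6 Å tolerance. Both tolerances are config keys. Ligands
are the connected components of the bond graph after deleting the metal
vertex, ordered deterministically by smallest contained atom index; a
component with no atom inside the metal cutoff is kept with denticity 0 and
flagged invalid downstream. Denticity = number of ligand atoms inside the
metal cutoff; the complex coordination number CN is the sum over ligands.

## Masking combinatorics and denticity control

Training expansion masks every non-empty ligand subset: `2^l − 1` samples
per complex, counted by position, not by multiset (six identical monodentate
ligands still give 63). Each masking frees `CN_g = CN − CN_c`; the
denticities of the ligands to be generated form an integer partition of
`CN_g`, enumerated in descending lexicographic canonical form and labelled
by digit concatenation ("21"). Sizes are assigned per generated ligand:
during training expansion uniformly ≤ 10 heavy atoms for denticity < 3 and
uniformly 10–30 for denticity ≥ 3 (matching the corpus correlation between
denticity and ligand size); the SCO screen caps sizes at 10. Requesting a
polydentate ligand with ≤ 3 atoms (or fewer atoms than its denticity) warns:
undersized requests are the documented failure mode where the realised
denticity falls short of the assigned one.

## Diffusion process

Variance-preserving convention: `x_t = α_t x_0 + σ_t ε` with
`α_t² + σ_t² = 1`, `α_0 = 1` exactly, `α_T` clipped to stay positive. Only
the masked block's `r` and `h_a` are noised; `h_Lc`, the metal and all
context atoms are untouched at every step. Defaults: `T = 1000` with the
smooth polynomial schedule `α_t = (1 − (t/T)²)²`; a cosine schedule is also
available. Both the schedule family and `T` are config keys because the
method does not hinge on either.

The categorical `h_a` is diffused as a continuous one-hot vector under the
same Gaussian process and decoded by argmax after the final reverse step
(ties break to the lowest channel index). Generated atoms decode over the
8 non-metal channels only — a generated ligand is by definition metal-free,
and without the restriction a poorly trained network could emit a second
metal centre.

Reverse sampling is standard ancestral sampling from the ε-prediction, with
the exact posterior coefficients `α_{t|s} = α_t/α_s`,
`σ_{t|s}² = σ_t² − α_{t|s}² σ_s²`, and a deterministic denoised estimate
`x_0 = (x_1 − σ_1 ε̂)/α_1` at the last step. Masked coordinates are
initialised from a standard normal without mean-centring: the frozen context
fixes the frame. One integer seed fans out to per-ligand substreams
(`SeedSequence.spawn`), so requesting an additional ligand never perturbs an
earlier ligand's draws; within a ligand, draws are consumed in a fixed
(step, atom) order independent of orientation. Per-draw Gaussian noise is
only rotation-invariant in distribution, so the sampler exposes a
`noise_transform` hook that maps each coordinate draw; passing the rotation
itself makes sampling commute with rotation exactly, which is how the
equivariance of the full reverse chain is tested.

## The denoiser φ

Each atom carries invariant scalar features and O(3)-equivariant vector
features, updated by geometric-vector-perceptron blocks: vector channels are
linearly recombined, their norms feed the scalar path, and the scalar path
gates the vector output. Initial scalars are the scaled `h_a ⊕ h_Lc`, an
8-channel sinusoidal encoding of `t/T`, and the masked flag; initial vectors
are the (scaled) displacements from the metal-centred origin. Messages run
over the complete graph — every atom except the atom itself is a neighbour,
which at ≤ 200 atoms is tractable and captures global structure; the metal
participates as a neighbour to all. Edge features are 8 Gaussian radial
basis functions of the interatomic distance plus the unit displacement
vector. Aggregation is by mean (size-robust across 6–200-atom complexes)
and each layer updates residually, so a zero-weight network is the identity
on the trunk features. The coordinate-noise readout is a plain linear map
over vector channels (no bias — a bias would break equivariance); the
type-noise readout is linear in the scalars. Because every vector operation
is a channel-space linear map or an invariant gate, the network is
equivariant under the full orthogonal group, reflections included, to
machine precision.

Defaults: 5 layers, 128 scalar channels, 16 vector channels — modest sizes
chosen for CPU-scale training; all config keys.

The network, loss (MSE between predicted and injected noise over masked
atoms' `r` and `h_a` channels, step drawn uniformly from 1..T per sample)
and Adam optimizer are float64 NumPy with hand-written reverse-mode
gradients. A finite-difference check (central differences, 1e-4 agreement)
guards every parameter tensor's backward path.

## Synthetic fixtures

Toy complexes place donor atoms on ideal coordination shells (octahedral,
trigonal planar, tetrahedral, square planar, trigonal bipyramidal, square
pyramidal) at element-typical metal–donor distances (2.0 Å for N/O/C/P,
2.3 Å for S/Cl), with template ligands of denticity 1–4: single atoms,
short chains, and chelates whose backbone carbons bridge consecutive donor
sites. Bridge geometry was chosen with ≥ 0.2 Å margin against every
bond/cutoff rule, so the default 0.05 Å uniform jitter cannot flip
connectivity or denticity (a construction-time assertion double-checks).
Chelates are only placed on site pairs at ~90°, i.e. octahedral- and
square-planar-like shells; wider-angled geometries get monodentate templates
only. Corpus generation mixes metals (Cr–Zn), geometries (70% octahedral)
and compositions reproducibly from one seed, and reproduces the
size–denticity correlation (polydentate ⇒ larger).

What the fixtures do *not* emulate: real bond-length/angle diversity,
conformational flexibility, aromaticity, charge effects, or crystal-packing
artefacts. Tests passing on fixtures demonstrate that the machinery —
masking, conditioning, equivariance, sampling, metrics — is correct, not
that the model generates publishable chemistry; that requires training on a
curated experimental corpus at full scale, which is outside this package's
scope (as is reproducing the headline metric scores of such a model).

The parameter-recovery task isolates learnability end to end: the masked
ligand is always a single nitrogen at exactly 2.0 Å, trans to a unique
sulfur marker donor, under a random global rotation per sample. The
acceptance experiment trains 30 epochs on 500 samples (3 layers, width 64,
8 vector channels, T = 200 — reduced via config keys to keep the run at a
few CPU-minutes) and requires ≥ 80% of 50 generated atoms within 0.3 Å of
the target metal distance, with an untrained network failing the same bound.

## Metrics

- Ligand validity: RDKit sanitization of the perceived single-bond graph
  (implicit hydrogens fill valences; a pentavalent carbon fails).
- Connectivity: one bond-graph component, computed over valid ligands only,
  so the connectivity denominator equals the validity numerator.
- Complex validity re-implements the intent of the external structure
  checker as four explicit, individually toggleable rules: every generated
  ligand valid *and* connected; realised total denticity equals the target
  CN (skipped when no target is recorded, e.g. structures read from plain
  XYZ); no interatomic distance below 0.7× the covalent sum; every
  generated ligand keeps ≥ 1 donor inside the metal cutoff.
- Novelty/uniqueness compare hydrogen-free canonical SMILES of the metal-
  excised ligands, without stereo flags (the corpus is hydrogen-stripped
  and bond orders are not perceived). Sanitization failures fall back to an
  unsanitized canonical string so every ligand is comparable.
- All ratios carry exact integer numerator/denominator, making batch
  concatenation exactly count-additive; the CLI aggregates independent runs
  as mean ± std.
- Conformer RMSD: Kabsch superposition (proper rotations, via SciPy's
  `align_vectors`) with correspondence given by atom order.

## SCO screening

The pipeline enumerates, for each reference complex, all maskings × all
LD_g partitions (a two-tridentate reference gives 17 variations), generates
candidates, validates them, runs pass-through hydrogen/charge hooks, asks an
energy backend to optimize both spin states, classifies the ground state
(HS iff E_HS < E_LS; exact ties log a warning and count as LS) and retains
candidates with |E_HS − E_LS| ≤ 10 kcal/mol — boundary inclusive, and the
gap is taken in absolute value since both HS- and LS-ground candidates are
of interest. Energies are handled in kcal/mol; backends declaring hartree
are converted at ingestion (627.509474 kcal/mol per hartree). Multiplicities
are per-run inputs (default (5, 1), the Fe(II) HS/LS pair). Every stage
reports input = retained + dropped, so attrition accounting is conservative
by construction. The bundled mock backend reads energies from a JSON table
or synthesises deterministic pseudo-energies from a hash; it performs no
chemistry and exists to make the pipeline testable offline.

## Numerical choices and limitations

- Float64 throughout; norm computations carry a 1e-8 floor so gradients
  stay finite at zero vectors.
- Schedule α clipped to [1e-4, 1] and strictly decreasing to keep posterior
  ratios stable.
- Argmax ties (element decoding) break to the lowest channel index.
- The checkpoint container (`.npz`) stores parameters plus hyperparameters,
  element vocabulary and schedule metadata, so a checkpoint is
  self-describing.
- Known limitations: no bond-order perception (everything is a single bond
  to the valence checker), no charge/oxidation-state assignment, no
  stereochemistry in novelty comparisons, no classifier guidance or
  post-generation geometry optimization, and the atom-type vocabulary is
  fixed at build time.
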