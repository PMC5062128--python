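# Methods

## Scope and model

`tcrfootprint` turns per-variant SPR observations of TCR binding to
alanine/glycine-scanned pMHC, plus a complex structure, into a
decomposition of the interaction energy. The chain of models:

1. **Equilibrium affinity.** Steady-state response at analyte
   concentration C follows the 1:1 Langmuir isotherm
   `bound = Max·C/(C + K_D)`. Both parameters are fitted per series by
   bounded least squares (scipy `curve_fit`, trust-region reflective,
   relative tolerance 1e-8), initialized at `Max₀ = 1.1 × max response`
   and `K_D₀ =` the concentration whose response is nearest half-maximum;
   failed fits retry from three geometrically perturbed starts. Standard
   errors come from the local linearization (fit covariance).
2. **Dissociation kinetics.** The post-injection decay follows
   `R(t) = R0·exp(−k_off·t)` (optional constant baseline), fitted over a
   window that may skip initial seconds (bulk-shift artifacts);
   initialization by log-linear regression. Non-decaying traces are a
   degenerate-data error, not a fit result.
3. **Association rate.** `k_on = k_off/K_D`, derived algebraically (the
   two assays are never fitted jointly); its relative error is the
   quadrature of the input relative errors, so two 10 % inputs give 14 %.
4. **Energetics.** `ΔG° = RT ln K_D` (K_D molar), `ΔΔG = RT
   ln(K_D,mut/K_D,wt)`, contribution = −ΔΔG. The total interaction energy
   subtracts an association entropy `S_assoc` from ΔG°: at the 1 M
   standard state, confining two reactants costs roughly 4–6 kcal/mol, so
   the default is 5 ± 1 kcal/mol and is assumed complex-independent.

## Censoring

An affinity can be too weak to quantify. A fit is censored when the
fitted K_D exceeds `censor_factor` (default 5) × the highest tested
concentration, or when the fit cannot bound K_D — operationalized as a
K_D standard error exceeding the estimate itself, which also catches
noise-level series collapsing onto degenerate tiny-Max solutions.
Censored fits carry the finite bound `K_D ≥ censor_factor × top
concentration` and no point estimate. A variant with *any* censored
replicate is censored (a replicate that cannot bound K_D contradicts a
sibling point estimate; the conservative call keeps the variant as a
bound). Censored variants propagate as ΔΔG lower limits; any such member
makes ΣΔΔG itself a lower limit, which is how the pipeline reports every
ΣΔΔG as a *minimum* MHC contribution.

## Replicates and uncertainties

Replicates are fitted independently and aggregated afterwards: the
central value is the replicate mean; the *reported* spread is the range
for n = 2 and the SD for n ≥ 3 (the convention of the source assays). The
uncertainty *used downstream* is `max(spread, mean fit SE)`: with two
replicates the range is an unreliable scale estimate — it is arbitrarily
small with non-negligible probability — and propagating it alone makes
nominal 2σ intervals under-cover badly; the fit covariance supplies a
noise floor. This distinction (reported spread vs propagated σ) is
deliberate and documented here rather than hidden.

Every ΔΔG in a panel shares the same WT K_D estimate, so ΔΔG errors are
correlated. `EnergyValue` keeps the WT-derived error component separate
from the variant-specific one; sums (ΣΔΔG, deviations in additivity
tests) combine independent components in quadrature and the shared
component linearly (it appears with a net coefficient of n in an n-term
sum, and of 1 in the additivity deviation). Plain values with no shared
component reduce to ordinary quadrature, which is what reproduces the
printed table errors — except `Total_calc`, where linear addition
`σ(ΔG°) + σ(S_assoc)` is used because it is the unique rule consistent
with the printed ±1.12/±1.06 totals; the mode is configurable
(`total_error_mode`).

## Structural footprint

Heavy atoms only (crystal structures rarely resolve hydrogens); author
residue numbering end to end; alternate locations resolved to the
highest-occupancy conformer (ties → first listed); waters and
heteroatoms excluded. A residue contacts a group when its minimum
heavy-atom distance to any group atom is ≤ 4 Å; the 6 Å threshold defines
the proximity selection used to pick scannable residues (it admits
longer-range electrostatic contributors). Side chains are heavy atoms
minus backbone N/CA/C/O (+OXT); glycine's proxy is its CA. Two residues
are *adjacent* when their minimum side-chain distance is ≤ 4.5 Å — the
adjacency threshold is an inference (slightly above the contact
threshold), flagged as configurable because the underlying analysis never
defines "adjacent" numerically. Clusters are connected components of the
adjacency graph over candidate residues (those whose single mutation
qualifies for inclusion), so chained adjacency merges transitively.

## ΣΔΔG assembly rules

A single-mutant residue is **included** iff it contacts the TCR, does not
contact the peptide, and its ΔΔG ≥ 0.25 kcal/mol (≈1.5-fold K_D at
25 °C; the threshold is configurable since no numeric cutoff is canonical
for "reduces the binding energy"). Peptide-contacting residues are
excluded because their mutation may act through the peptide — making
every ΣΔΔG a conservative minimum. Affinity-enhancing mutations
(ΔΔG < 0) are tallied but excluded by default (`include_enhancing`
switches this). Each identified cluster is counted through its measured
double mutant, its members contributing zero individually (no double
counting); a cluster without a measured double falls back to the sum of
singles with an explicit naive-additivity warning. When no complex
structure exists for a TCR, the pipeline runs in panel-wide mode: all
mutants analysed, exclusions supplied manually via config.

Additivity of a double mutant is accepted when
`|ΔΔG_ab − ΔΔG_a − ΔΔG_b| ≤ max(k·σ_dev, floor)` with k = 2 and
floor = 0.3 kcal/mol — the floor keeps near-zero-σ noiseless data from
flagging trivial deviations.

The kinetic footprint uses the strict criterion: fold-decrease of k_on
(variant mean vs WT mean) > 2.0; exactly 2-fold is a non-member.
Energetic color-bins (<1.5, 1.5–2, 2–4, >4 fold K_D increase,
"enhancing" below 1) are presentation-only and never affect ΣΔΔG.

## Synthetic-data generator

The generator is first-class code: it defines the study conditions under
which every stage is validated. It emulates: mutant affinities satisfying
`K_D,mut = K_D,wt·exp(ΔΔG/RT)` exactly before noise; equilibrium
titrations over 8 two-fold dilutions spanning 0.1–12.8 × the WT K_D with
homoscedastic Gaussian response noise, σ = 2 % of Max (chosen to
reproduce ≤10 % replicate spread in K_D and k_off, the outcome-level
bound the assays report); dissociation traces over 4/k_off seconds with
σ = 1 RU; 2 replicates per variant; planted k_on fold-effects (k_off
follows from k_on·K_D); censored variants (true K_D = 40 × the ladder
top); additive and ε-perturbed doubles; and toy multi-chain PDBs that
realize the designed contact/proximity/cluster geometry with ≥ 1 Å
margins (one side-chain pseudo-atom per residue; TCR pseudo-atoms 3.5 Å
above contacting side chains, 5.5 Å above proximal-only ones; cluster
partners 4.0 Å apart). Default WT parameters — K_D = 5 μM,
k_off = 0.05 s⁻¹ (k_on = 10⁴ M⁻¹s⁻¹), Max = 100 RU, R0 = 50 RU — are
typical of TCR/pMHC 1:1 kinetics.

What the generator does **not** emulate: sensorgram drift, bulk
refractive-index jumps, mass-transport limitation, heteroscedastic or
correlated noise, surface heterogeneity, or real side-chain geometry.
Passing tests therefore demonstrate correctness of the estimation and
assembly logic under the stated statistical model, not robustness to
instrument artifacts.

**Planted-truth design constraints.** For recovery tests to be
well-posed, planted effects must sit away from decision boundaries
relative to measurement noise: included singles are planted ≥ 0.40
kcal/mol (≈6σ above the 0.25 inclusion threshold), excluded ones ≤ 0.15;
double mutants are kept within the titration ladder's well-determined
range (K_D ≲ 8 × WT; beyond ~13× the top concentration the Max–K_D
degeneracy inflates errors sharply); the non-additive cluster is planted
sub-additive (members 0.50 + 0.50, ε = −0.55, double ΔΔG 0.45), which
simultaneously keeps its members qualifying, its double well-measured,
and its interaction term detectable against the 0.3 kcal/mol additivity
floor. The default scenario uses 20 MHC positions, three clusters, two
non-adjacent additivity pairs and one censored variant, matching the
scale of a single-TCR panel so full-pipeline suites run in seconds.

## Numerical and reporting choices

* Concentrations are molar internally; μM/nM input columns are converted
  on read (ΔG° requires K_D in M).
* Stored values are never rounded; display rounding is energies to two
  decimals (trailing zeros stripped) and percents to whole numbers,
  applied only at the reporting layer.
* Monte-Carlo suite sizes: 2000 series for the equilibrium-recovery
  median (the single-series estimator sits at the Cramér–Rao bound for
  this design, rel SE 6.6 %, so the median of only a few hundred draws
  would be dominated by sampling error); 200 traces/variants for k_off
  and ΔΔG coverage; 50 random structures for the contact oracle; 50 seeds
  for pipeline closure.
* Rigid-body invariance of contact maps holds to the 3-decimal precision
  of PDB coordinates (~1e-3 Å).
* Ledger JSON serializes floats at full precision and round-trips
  bit-identically; identical config + seed gives byte-identical
  machine-readable outputs (the manifest carries a timestamp and is
  excluded from that guarantee).

## Known limitations

* No mass-transport-limited or bivalent kinetic models; no global
  association-phase fitting; no drift/bulk-shift correction.
* The association entropy is a fixed offset with an assumed uncertainty;
  %MHC inherits it directly.
* Exclusion of peptide-contacting residues means reported ΣΔΔG values are
  lower limits by construction, not unbiased estimates.
* mmCIF structures and hydrogen-bond-based interface definitions are out
  of scope; contacts are purely distance-based.
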