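# Methods

This note records the model, the numerical choices, and what the synthetic
fixtures do and do not establish. Units throughout: angstrom, kcal/mol,
picosecond, elementary charge; k_B = 0.0019872041 kcal/(mol·K), T = 298 K
unless stated (k_BT ≈ 0.592 kcal/mol).

## The coarse-grained model

Each residue is two interaction sites: a backbone bead (BB) on the Cα
position and a side-chain bead (SC) at the side-chain centroid. Glycine also
carries a (small) SC bead, so the bead count is always twice the residue
count. Bonds are BB(i)–BB(i+1) (3.8 Å) and BB(i)–SC(i) (per-residue length
from the bead table). The energy decomposes as

U = U_FENE + U_EXV + U_ELE + U_BB + U_BS + U_SS

- **U_FENE** = −(k R₀²/2) Σ ln[1 − (r−r₀)²/R₀²] over bonds, k = 20
  kcal/mol/Å², R₀ = 2 Å. Stretching a bond to |r−r₀| ≥ R₀ is a hard error
  that names the bond.
- **U_EXV**: ε(σ_ij/r)⁶ pure repulsion between non-bonded beads of residues
  1–2 apart in sequence (the angle-level pairs), ε = 1 kcal/mol,
  σ_ij = (σ_i+σ_j)/2.
- **Nonbonded classes** (sequence separation ≥ 3, or any interchain pair):
  12-6 form ε[(σ_ij/r)¹² − 2(σ_ij/r)⁶], which has its minimum −ε exactly at
  r = σ_ij. ε is 0.12 (BB–BB), 0.18 (BB–SC), and a per-pair table value for
  SC–SC. Because parameters are resolved per bead and per pair class, an
  interchain pair of residues automatically interacts exactly as the same
  intrachain pair — the property dimerization runs rely on.
- **U_ELE**: Debye–Hückel screened Coulomb between charged SC beads in the
  nonbonded class, 332.0637·q_iq_j/(ε_r r)·exp(−r/λ_D), ε_r = 78, λ_D = 10 Å
  (physiological monovalent salt). D/E carry −1, K/R +1; the chain termini
  contribute +1/−1 on the terminal SC beads (configurable).

No nonbonded cutoff is applied by default (systems here are ≤ 200 beads; an
optional cutoff field exists for larger systems, with the neglected tails
undocumented beyond this sentence).

### Parameter provenance

All numbers live in three checksummed whitespace tables under
`nstarkit/data`, versioned in their headers. Bead diameters and Cα–SC bond
lengths are derived from standard amino-acid van der Waals volumes and
geometries. The SC–SC well-depth matrix is a **synthetic stand-in**
(`ss_contact_synthetic.tsv`): ε_ab = 0.05 + 0.35·√(h_a h_b) with h the
Kyte–Doolittle hydropathy normalised to [0, 1]. It is symmetric and ranks
hydrophobic pairs as stickiest, which is the qualitative behaviour of
statistical contact potentials, but it is *not calibrated*: absolute
populations, barriers and MFPTs computed with it are not quantitative
predictions for real Aβ. Calibration is explicitly out of scope; every
algorithmic claim in the test-suite is checked against constructions whose
answer is independent of these tables.

## Brownian dynamics

The Ermak–McCammon update in the high-friction limit:
Δq = (Δt/γ)F + √(2k_BT Δt/γ)ξ. The per-bead friction is γ = 6πη a_h with
η = 10⁻³ Pa·s and a single hydrodynamic radius a_h = 2.8817 Å for all beads.
This pins the natural time unit τ_HF = γa²/k_BT (a = 1 Å) at 13.20 ps, which
is the package's time conversion: a production-scale run of 8×10⁶ steps at
Δt = 0.05 τ_HF corresponds to 5.28 μs.

**Step size.** With the shipped FENE stiffness, k·Δt/γ ≈ 1.7 at
Δt = 0.05 τ_HF — beyond the overdamped-Euler stability range — and
integration fails by overstretch cascade. The package default is therefore
Δt = 0.01 τ_HF, the largest value observed stable for these tables
(Δt = 0.02 still fails on a 12-residue chain). A bounded retry (≤ 5 halvings
with fresh noise, each event logged) absorbs rare excursions; exhausting the
retries raises. The 0.05 τ_HF convention is retained in the time-bookkeeping
helpers.

**Hydrodynamic interactions** use the Rotne–Prager–Yamakawa pairwise
mobility with the standard overlap-regularised form below r = 2a_h, which
keeps μ symmetric positive definite for any configuration (checked by
eigenvalue tests, including heavily overlapping beads). Drift is μF;
correlated noise is √(2k_BT Δt)·Lξ with μ = LLᵀ by dense Cholesky — systems
here are small, so no Chebyshev/Krylov approximations are used. The RPY
tensor is divergence-free, so no spurious drift correction is needed. HI
changes kinetics only: the harmonic-dimer stationary variance matches
k_BT/k with and without it.

The monomer centre of mass is not pinned; all analyses are functions of
internal distances, so diffusive drift is harmless. One seeded NumPy
generator drives each trajectory; the seed and a config hash are stored in
the trajectory metadata, and identical configs reproduce trajectories
bit-for-bit.

## Order parameters

χ_fib counts the fraction of reference pair distances reproduced to within
d; the tolerance d = 2 Å (of the order of a bead radius) is configuration,
recorded with every classification, because the source convention does not
fix it. Pair lists are BB–BB pairs with sequence separation ≥ 3 among the
residues resolved in the reference — sensitive to distance topology without
trivially satisfied bonded pairs. A conformation is assembly-competent when
χ_fib ≥ χ_c = 0.30 (strict "≥": χ = 0.29 classifies as RC); with several
references the highest qualifying χ wins, ties broken by reference order.
Whether SC beads should enter the pair list is left as configuration
(default: BB only).

χ_fib against a *compact* reference has a chain-length-dependent baseline:
short chains share most of their short-range distances with any compact
fold (for 12-mers the RC baseline χ is ≈ 0.35), while at peptide-relevant
lengths (36–42 residues) disordered chains sit well below the 0.30
threshold (≥ 95–100% of RC frames). Classification-based statements in the
tests are therefore made at those lengths.

DRID features: per centroid (all BB beads when a topology is available),
the mean of reciprocal distances to all non-bonded, non-self beads, plus
the square root of the second and cube root of the third central moments.
The DRID distance is the RMS over the concatenated features,
√(Σ(a−b)²/(3·n_centroids)) — one fixed normalisation convention; clustering
is invariant to it.

## Landscape construction

Frames are clustered by k-means (10 restarts, fixed seed) in DRID space.
The cluster count is chosen by knee-point analysis: maximum
distance-to-chord on the normalised dispersion-versus-k curve, with one
special case — if some k reaches (numerically) zero dispersion, the
smallest such k is selected, which makes zero-jitter synthetic landscapes
recover their planted state count exactly.

Transitions are counted with sliding (overlapping) windows at the chosen
lag, never across trajectory boundaries. Counts are symmetrised,
(n_ij+n_ji)/2, enforcing detailed balance; stationary weights π_i are the
symmetrised row sums, F_i = −k_BT ln π_i. The lag default is one save
stride; implied-timescale flatness across lags is the Markovianity check.

Barriers between minima sets are max-flow/min-cut values on the network
with undirected edge capacities n_ij + n_ji, converted by
F‡ = −k_BT ln(c_cut/N_total) with N_total the total transition count. The
additive constant in this convention is immaterial for the TRDG, which only
uses merge order and barrier differences. All-pairs cuts come from a
Gomory–Hu tree; the TRDG is the single-linkage merge of minima by
increasing pairwise barrier, which is ultrametric by construction.
Disconnected pairs have infinite barrier and are reported per component.

Each TRDG leaf is annotated with the minimum and maximum member χ_fib and
the member fraction with χ ≥ χ_c; the branch-colouring quantity is the
minimum (the conservative "every member at least this similar" measure).

The roughness density on a free-energy grid of width ΔF is
ρ_LB = (branches alive at the bin midpoint − 1)/(n_minima·ΔF), where a
branch is alive at level E if its subtree contains a leaf with F ≤ E and it
has not merged with the rest below E. A single funnel gives ρ_LB = 0
everywhere; doubling ΔF halves peak density. The normalisation is fixed
only up to the convention stated here.

## Kinetics

The transition matrix row-normalises the symmetrised counts; eigenvalues
are computed on the symmetric similarity transform S_ij/√(r_i r_j) (real
spectrum under detailed balance, dense `eigh`). Implied timescales
t_i = −τ/ln|λ_i|; |λ| numerically 0 maps to t = 0 and duplicate unit
eigenvalues flag disconnection.

MFPTs are exact by graph transformation: iterative elimination of every
node outside {source} ∪ targets with renormalisation
P'_ij = P_ij + P_ix P_xj/(1−P_xx) and waiting-time accumulation
t'_i = t_i + P_ix t_x/(1−P_xx), after which the MFPT from the source is its
accumulated waiting time divided by its escape probability into the target
set. Elimination order is a minimum-degree heuristic (cost only; the result
is order-independent and verified against the (I−T_QQ)m = τ1 linear solve
on 10³ random chains to < 10⁻⁸ relative). Set-to-set MFPTs weight sources
by the stationary distribution restricted to the source set.

Empirical FPT samples carry per-trajectory censoring flags; censored
trajectories are excluded from the mean but the censoring fraction is
always reported, and trajectories that *start* in the target class are
excluded and counted separately. Errors are delete-one jackknife. Two
distributional diagnostics are attached: a single-Gaussian fit to log₁₀ FPT
(unimodality / absence of deep traps) and a single-exponential fit
(Poissonian two-state kinetics), both scored by a KS test with p ≥ 0.01 as
the default acceptance.

## Dimerization

Two chains are merged into one topology (no bonds across chains) and
propagated with the force field plus a harmonic COM–COM restraint
(k = 5 kcal/mol/Å² by default — "stiff" relative to k_BT over ångström
displacements but thermodynamically transparent, rather than a rigid
constraint). The restraint target is meant to be the thermally averaged
monomer R_g computed from a monomer ensemble by the caller; nothing is
hard-coded. Initial poses place the chains at the target separation with a
seeded random mutual orientation, re-drawn (bounded) on steric clash.

Contacts: interchain bead pairs within 6 Å (inclusive); a dimer is called
when the instantaneous count exceeds 5 in at least one saved frame — the
threshold is part of the contact convention, no dwell requirement is
imposed. HMM networks fit a diagonal-covariance Gaussian HMM (Baum–Welch,
seeded, likelihood checked non-decreasing) on the feature series
(per-chain χ per reference, contact count); the state count is user
configuration (8 and 16 are the conventional choices for the two Aβ
alloforms), states are labelled by dominant per-chain composition and dimer
status, and non-convergence returns the best model with a warning.

## Synthetic fixtures and what they show

- **Toy references** (hairpin-U, meander-S, extended) use the same
  two-bead conventions as the real model. Strands of the folded shapes are
  compressed zig-zags so that even short-range BB distances differ from the
  extended shape by more than d = 2 Å; consequently χ(extended, folded
  ref) = 0 exactly, and the two folded shapes score ≈ 0.27 < χ_c against
  each other.
- **Toy Markov landscapes** emit rigid per-state templates plus isotropic
  Gaussian jitter (σ = 0.5 Å default, small against d). All ground truth —
  stationary weights, the full MFPT matrix, implied timescales — is
  computed by linear algebra from the jump matrix, never by simulation, so
  recovery tests are genuine parameter-recovery checks.
- **RC ensembles** are hard-sphere self-avoiding chains (bond 3.8 Å, EV
  diameter 4.0 Å between beads ≥ 2 apart) sampled by the pivot algorithm
  (12N attempted pivots to equilibrate from the rod, ≥ 2N between frames;
  Rg decorrelates within a few N attempts). In good solvent they swell
  relative to ideal chains and scale as R_g ~ N^ν. At desk-scale lengths
  (N = 16–120) the *effective* exponent is ≈ 0.62–0.64: thick hard-sphere
  chains approach the asymptotic self-avoiding-walk value 0.588 slowly from
  above, so ν ≈ 0.6 holds at the precision that statement carries.

The fixtures emulate the *statistical structure* the analyses assume — a
dominant disordered class plus sparse geometrically distinct excitations
with Markovian exchange. They do not emulate the real Aβ landscape
quantitatively; passing tests establish the correctness of the machinery,
not the biophysics of a particular sequence.

## Desk-scale study sizes

The test-suite and acceptance script run minutes, not CPU-months, by scaling
the problem down while keeping every code path the production one: monomer
phenomenology uses a 6×10⁴-step, 42-residue run (≈ 8 ns) classified against
42-residue toy references; dimerization ordering uses 12-residue chains,
3 replicas × 5×10³ steps per initial-state class; scaling uses 5–6 chain
lengths × 100–150 frames; oracle equivalences use 10³ random chains of 3–20
states. The qualitative conclusions these support — fibril-like excitations
are a rare minority population of a disordered ensemble, compact fibril-like
seeds accumulate interchain contacts faster than disordered seeds — are
exactly the claims the scaled-down checks assert, and nothing quantitative
beyond them is claimed at this scale.

## Known limitations

- The SC–SC contact table is synthetic (above); no force-field calibration
  or comparison against experimental observables is included.
- Free-energy disconnectivity graphs from unimolecular rates, alternative
  frustration metrics, and curated multi-polymorph PDB panels are out of
  scope; the reference-import path handles any single-chain PDB.
- Trajectory storage is extended-XYZ plus a JSON sidecar only; the sidecar
  is mandatory on read so units are never guessed.
- The min-cut barrier convention fixes the additive constant via
  c_cut/N_total; only barrier differences and merge order are meaningful.
- Censoring treatment of first-passage means is exclusion-with-reporting;
  for heavily censored desk-scale samples the mean is biased low and the
  censoring fraction must be consulted.
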