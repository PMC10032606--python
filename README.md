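# nstarkit

Coarse-grained Brownian dynamics and energy-landscape kinetics for short
amyloidogenic intrinsically disordered peptides (IDPs) such as the amyloid-β
alloforms Aβ40 and Aβ42.

The monomers of aggregating IDPs are overwhelmingly disordered: ensemble
averages (R_g, FRET efficiencies) are dominated by a random-coil (RC) ground
state that obeys Flory scaling, R_g ≈ a₀N^ν with ν ≈ 0.6. What drives
aggregation is not the ground state but sparsely populated *N\* states* —
excitations on the monomer free-energy landscape that already carry the
structural signature of a fibril polymorph (e.g. the U-bend strand-loop-strand
or S-bend motifs) and act as templates for dimerization and growth. `nstarkit`
provides the machinery to detect and quantify these excitations for any short
IDP sequence:

- **Model.** Two interaction sites per residue (a backbone bead on Cα and a
  side-chain bead), with energy
  `U = U_FENE + U_EXV + U_ELE + U_BB + U_BS + U_SS`:
  finitely extensible bonds, short-range repulsion, Debye–Hückel screened
  electrostatics, and three 12-6 Lennard-Jones classes, with side-chain pair
  energies from a symmetric contact-energy table. All parameters ship as
  versioned plain-text data files.
- **Dynamics.** Overdamped (Ermak–McCammon) Brownian dynamics,
  `dq = -(dt/γ)∇U + √(2k_BT dt/γ) ξ`, optionally with
  Rotne–Prager–Yamakawa hydrodynamic coupling (positive-definite
  overlap-regularised form, correlated noise via dense Cholesky). Time is
  measured in the natural Brownian unit τ_HF = γa²/k_BT ≈ 13.2 ps.
- **Order parameters.** The fibril-overlap
  `χ_fib = (1/N_p) Σ_j H[d − |r_j − r_j⁰|]` against one or more reference
  fibril monomer structures (a conformation is assembly-competent when
  χ_fib ≥ χ_c = 0.30), DRID reciprocal-distance features, interchain contact
  counts, and R_g.
- **Landscapes.** DRID k-means clustering with knee-point model selection,
  lag-time transition counting, effective barriers by max-flow/min-cut on the
  capacitated count network (F‡ = −k_BT ln(c_cut/N_total)), transition
  disconnectivity graphs (TRDG) by single-linkage merging of pairwise
  min-cut barriers, and the Levy–Becker roughness density ρ_LB.
- **Kinetics.** Implied timescales t_i = −τ/ln|λ_i(τ)|, exact mean
  first-passage times by graph transformation (cross-checked against the
  linear-system solution), and empirical first-passage statistics with
  delete-one jackknife errors, log-FPT Gaussian and single-exponential
  diagnostics.
- **Dimerization.** Two-chain runs with a harmonic centre-of-mass separation
  restraint, contact kinetics (dimer at N_contacts > 5 with a 6 Å cutoff),
  and Gaussian-HMM transition networks of the dimerization routes.
- **Fixtures.** Deterministic toy references (hairpin-U / meander-S /
  extended), hidden-Markov toy landscapes with closed-form kinetics, and
  pivot-sampled self-avoiding RC ensembles.

## Worked example

Map a toy two-state landscape — a disordered ground state exchanging slowly
with a fibril-like excitation — and read off its thermodynamics and kinetics:

```python
import numpy as np
from nstarkit.fixtures import (ToyLandscapeSpec, make_toy_reference,
                               simulate_toy_markov, toy_template)
from nstarkit.kinetics import (implied_timescales, mfpt_graph_transform,
                               transition_matrix)
from nstarkit.landscape import (annotate_states, build_trdg,
                                cluster_trajectories, count_transitions,
                                mincut_barrier)
from nstarkit.order_params import chi_fib_frames

P = np.array([[0.98, 0.02],      # ground state: 2% escape per frame
              [0.08, 0.92]])     # excitation:   8% relaxation per frame
spec = ToyLandscapeSpec(
    transition=P, n_frames=20000, jitter=0.3, seed=0, dt_frame_ps=660.0,
    templates=np.stack([toy_template("extended"), toy_template("meander-S")]))
res = simulate_toy_markov(spec)

model = cluster_trajectories([res.trajectory], k_range=range(1, 6), seed=0)
net = count_transitions(model.labels_per_trajectory(), lag=1,
                        dt_frame_ps=660.0)
chi = chi_fib_frames(res.trajectory.coords, make_toy_reference("meander-S"))
ann = annotate_states(model.labels, chi, chi_c=0.30)
tree = build_trdg(net, ann)

ground = net.states[np.argmax(net.pi)]
excited = net.states[np.argmin(net.pi)]
tm = transition_matrix(net)
print("clusters found:", model.k)
print("stationary weights:", np.round(np.sort(net.pi)[::-1], 3))
print("excitation free energy: %.2f kcal/mol above ground"
      % (net.free_energies[net.index_of(excited)]
         - net.free_energies[net.index_of(ground)]))
print("fibril-like fraction in excited minimum: %.2f"
      % ann[excited]["fibril_fraction"])
print("slowest implied timescale: %.1f ns" % (implied_timescales(tm)[0] / 1e3))
barrier, cut = mincut_barrier(net, [ground], [excited])
print("min-cut barrier: %.2f kcal/mol (cut value %d)" % (barrier, cut))
mfpt = mfpt_graph_transform(tm, [ground], [excited])
print("MFPT ground -> excitation: %.1f ns (analytic: %.1f ns)"
      % (mfpt / 1e3, res.ground_truth["mfpt"][0, 1] / 1e3))
```

Output:

```
clusters found: 2
stationary weights: [0.807 0.193]
excitation free energy: 0.85 kcal/mol above ground
fibril-like fraction in excited minimum: 1.00
slowest implied timescale: 5.6 ns
min-cut barrier: 2.00 kcal/mol (cut value 688)
MFPT ground -> excitation: 31.0 ns (analytic: 33.0 ns)
```

The clustering recovers both planted states; the excitation sits
0.85 kcal/mol above the disordered minimum (≈19% population), every frame in
it is fibril-like under the χ ≥ 0.30 criterion, and the graph-transformation
MFPT agrees with the generator's closed-form value to within sampling error.

The same pipeline runs from the shell:

```bash
nstarkit simulate-monomer --seq ab42.fasta --seed 1 --out runs/m.xyz
nstarkit build-landscape --traj 'runs/*.xyz' --refs refs/ --lag 1 --out landscape/
nstarkit timescales --net landscape/network.json --lags 1,2,5,10
nstarkit mfpt --net landscape/network.json --from 1 --to 4
```

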