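"""Two-chain dimerization simulations and HMM transition networks.

Two peptide chains are simulated together with a stiff harmonic restraint on
their centre-of-mass (COM) separation, mimicking the critical protein
concentration needed for an encounter.  The restraint target is the
thermally averaged monomer radius of gyration (computed from a monomer
ensemble, not hard-coded).  Interchain nonbonded interactions are identical
to intrachain ones for the same residue pair, which follows automatically
from the per-bead parameter resolution of the force field.

The extent of dimerization is monitored through the number of interchain
contacts (bead pairs on different chains within 6 A); a dimer is called
once more than 5 contacts are present.  Dimerization routes are summarised
by fitting a Gaussian hidden Markov model to the featurised trajectories
(per-chain fibril overlaps plus the contact count) and reading off its
transition network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bd import (CompositePotential, IntegratorConfig, Potential,
                 SOPPotential, Trajectory, run_trajectory)
from .forcefield import (Conformation, ForceField, Topology,
                         merge_topologies)
from .order_params import (CHI_C_DEFAULT, ReferenceStructure,
                           chi_fib_frames, interchain_contacts)

__all__ = [
    "DimerSystem",
    "DimerTrajectory",
    "HMMNetwork",
    "COMSeparationRestraint",
    "setup_dimer",
    "run_dimerization",
    "contact_timeseries",
    "featurize_dimer_trajectory",
    "fit_hmm_network",
]

logger = logging.getLogger(__name__)


class COMSeparationRestraint:
    """Harmonic restraint on the COM-COM distance of two bead groups.

    U = k/2 (d - d0)^2 with mass-uniform centres; the restraint force is
    distributed equally over the beads of each group.
    """

    def __init__(self, group_a: np.ndarray, group_b: np.ndarray,
                 target: float, stiffness: float = 5.0):
        if target <= 0:
            raise ValueError("target separation must be positive")
        self.group_a = np.asarray(group_a, dtype=int)
        self.group_b = np.asarray(group_b, dtype=int)
        self.target = float(target)
        self.stiffness = float(stiffness)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        ca = coords[self.group_a].mean(axis=0)
        cb = coords[self.group_b].mean(axis=0)
        delta = cb - ca
        d = float(np.linalg.norm(delta))
        F = np.zeros_like(coords)
        if d < 1e-12:
            return 0.5 * self.stiffness * self.target ** 2, F
        u = 0.5 * self.stiffness * (d - self.target) ** 2
        # dU/d(cb) = k (d - d0) * delta/d, spread uniformly over the group
        g = self.stiffness * (d - self.target) * (delta / d)
        F[self.group_b] -= g / len(self.group_b)
        F[self.group_a] += g / len(self.group_a)
        return u, F


@dataclass
class DimerSystem:
    """Two chains, a joint conformation and the COM restraint settings."""

    topology: Topology  # merged two-chain topology
    conformation: Conformation
    separation: float  # restraint target, A
    stiffness: float  # kcal/mol/A^2
    chain_slices: tuple  # (slice for chain A beads, slice for chain B beads)

    @property
    def restraint(self) -> COMSeparationRestraint:
        a = np.arange(self.chain_slices[0].start, self.chain_slices[0].stop)
        b = np.arange(self.chain_slices[1].start, self.chain_slices[1].stop)
        return COMSeparationRestraint(a, b, self.separation, self.stiffness)


@dataclass
class DimerTrajectory:
    """Joint trajectory plus the contact/overlap time series."""

    trajectory: Trajectory
    n_contacts: np.ndarray  # per saved frame
    chain_slices: tuple
    chain_labels: list | None = None  # per frame: (label_A, label_B)
    chain_chis: np.ndarray | None = None  # (n_frames, n_refs, 2)

    @property
    def is_dimer(self) -> np.ndarray:
        return self.n_contacts > 5


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def setup_dimer(confA: Conformation, confB: Conformation,
                topoA: Topology, topoB: Topology,
                separation: float, stiffness: float = 5.0,
                seed: int = 0, clash_distance: float = 2.0,
                max_jitter: int = 50) -> DimerSystem:
    """Place two chains at a COM separation with a random mutual orientation.

    Chain B is randomly rotated (seeded) and translated so the COM-COM
    distance equals ``separation`` along a random direction.  If any
    interchain bead pair is closer than ``clash_distance`` the placement is
    jittered (new direction/orientation) up to ``max_jitter`` times before
    failing.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    a = confA.coords - confA.coords.mean(axis=0)
    b0 = confB.coords - confB.coords.mean(axis=0)
    from scipy.spatial.distance import cdist

    for attempt in range(max_jitter):
        R = _random_rotation(rng)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        b = b0 @ R.T + separation * direction
        if cdist(a, b).min() >= clash_distance:
            break
    else:
        raise RuntimeError(
            f"could not place chains without steric clash after "
            f"{max_jitter} attempts (separation {separation} A)")
    topo = merge_topologies(topoA, topoB)
    coords = np.vstack([a, b])
    slices = (slice(0, topoA.n_beads),
              slice(topoA.n_beads, topoA.n_beads + topoB.n_beads))
    return DimerSystem(topology=topo, conformation=Conformation(coords),
                       separation=separation, stiffness=stiffness,
                       chain_slices=slices)


def contact_timeseries(traj: Trajectory, chain_slices, cutoff: float = 6.0
                       ) -> np.ndarray:
    """Interchain contact counts per saved frame."""
    sa, sb = chain_slices
    return np.array([
        interchain_contacts(frame[sa], frame[sb], cutoff=cutoff)[0]
        for frame in traj.coords
    ])


def run_dimerization(system: DimerSystem, cfg: IntegratorConfig,
                     ff: ForceField,
                     refs: list[ReferenceStructure] | None = None,
                     chi_c: float = CHI_C_DEFAULT,
                     extra_potential: Potential | None = None
                     ) -> DimerTrajectory:
    """Propagate a dimer system and record contact/overlap observables.

    The propagation potential is the force field plus the COM restraint
    (plus an optional extra term, used by tests).  When references are
    given, each chain of every saved frame is scored against them and
    labelled N*/RC.
    """
    terms = [SOPPotential(system.topology, ff), system.restraint]
    if extra_potential is not None:
        terms.append(extra_potential)
    potential = CompositePotential(*terms)
    traj = run_trajectory(system.conformation, system.topology, ff, cfg,
                          potential=potential)
    n_contacts = contact_timeseries(traj, system.chain_slices)

    chain_labels = None
    chain_chis = None
    if refs:
        sa, sb = system.chain_slices
        chis = []
        for ref in refs:
            chi_a = chi_fib_frames(traj.coords[:, sa], ref)
            chi_b = chi_fib_frames(traj.coords[:, sb], ref)
            chis.append(np.stack([chi_a, chi_b], axis=1))
        chain_chis = np.stack(chis, axis=1)  # (frames, refs, 2)
        labels = [r.label for r in refs]
        chain_labels = []
        for f in range(chain_chis.shape[0]):
            pair = []
            for c in range(2):
                col = chain_chis[f, :, c]
                best = int(np.argmax(col))
                pair.append(labels[best] if col[best] >= chi_c else "RC")
            chain_labels.append(tuple(pair))
    return DimerTrajectory(trajectory=traj, n_contacts=n_contacts,
                           chain_slices=system.chain_slices,
                           chain_labels=chain_labels, chain_chis=chain_chis)


# ---------------------------------------------------------------------------
# HMM transition networks
# ---------------------------------------------------------------------------

@dataclass
class HMMNetwork:
    """A fitted HMM over dimerization features, read as a transition network."""

    n_states: int
    transmat: np.ndarray
    populations: np.ndarray  # fraction of frames assigned to each state
    state_labels: list  # e.g. "U-bend:RC dimer"
    means: np.ndarray  # per-state emission means
    converged: bool
    loglik_history: np.ndarray

    def to_edges(self, min_prob: float = 0.0) -> list[tuple]:
        return [(self.state_labels[i], self.state_labels[j],
                 float(self.transmat[i, j]))
                for i in range(self.n_states)
                for j in range(self.n_states)
                if i != j and self.transmat[i, j] > min_prob]


def featurize_dimer_trajectory(dimer_traj: DimerTrajectory) -> np.ndarray:
    """Feature matrix (chi per reference per chain, contact count)."""
    if dimer_traj.chain_chis is None:
        raise ValueError("trajectory carries no chi annotations; pass refs "
                         "to run_dimerization")
    chis = dimer_traj.chain_chis  # (frames, refs, 2)
    n = chis.shape[0]
    flat = chis.reshape(n, -1)
    return np.hstack([flat, dimer_traj.n_contacts[:, None].astype(float)])


def _label_state(mean: np.ndarray, ref_labels: list, chi_c: float) -> str:
    # feature layout: [chi_ref0_A, chi_ref0_B, chi_ref1_A, chi_ref1_B, ..., n_contacts]
    n_refs = len(ref_labels)
    chain_names = []
    for c in range(2):
        chis = np.array([mean[2 * r + c] for r in range(n_refs)])
        best = int(np.argmax(chis))
        chain_names.append(ref_labels[best] if chis[best] >= chi_c else "RC")
    tag = "dimer" if mean[-1] > 5 else "monomers"
    return f"{chain_names[0]}:{chain_names[1]} {tag}"


def fit_hmm_network(dimer_trajs, n_states: int, seed: int = 0,
                    ref_labels: list | None = None,
                    chi_c: float = CHI_C_DEFAULT,
                    n_iter: int = 200) -> HMMNetwork:
    """Fit a diagonal-covariance Gaussian HMM to dimerization features.

    ``dimer_trajs`` is a list of DimerTrajectory objects or raw feature
    matrices.  Baum-Welch log-likelihoods are checked to be non-decreasing;
    non-convergence within ``n_iter`` returns the best model with a
    warning.  States are labelled by their dominant per-chain composition
    and dimer status when ``ref_labels`` is given.
    """
    from hmmlearn.hmm import GaussianHMM

    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    mats = []
    for t in dimer_trajs:
        if isinstance(t, DimerTrajectory):
            mats.append(featurize_dimer_trajectory(t))
        else:
            mats.append(np.asarray(t, dtype=float))
    X = np.vstack(mats)
    lengths = [len(m) for m in mats]

    model = GaussianHMM(n_components=n_states, covariance_type="diag",
                        n_iter=n_iter, random_state=seed, tol=1e-4,
                        min_covar=1e-5)
    model.fit(X, lengths)
    history = np.array(model.monitor_.history)
    converged = bool(model.monitor_.converged)
    if not converged:
        logger.warning("HMM did not converge within %d iterations", n_iter)

    states = model.predict(X, lengths)
    populations = np.bincount(states, minlength=n_states) / len(states)
    if ref_labels:
        labels = [_label_state(model.means_[i], ref_labels, chi_c)
                  for i in range(n_states)]
    else:
        labels = [f"state-{i}" for i in range(n_states)]
    return HMMNetwork(n_states=n_states, transmat=model.transmat_.copy(),
                      populations=populations, state_labels=labels,
                      means=model.means_.copy(), converged=converged,
                      loglik_history=history)
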