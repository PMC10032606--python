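"""Synthetic data generators for exercising the analysis stack.

Three families of fixtures make every analysis stage testable without any
external structures or long simulations:

* rigid toy reference geometries (hairpin-U, meander-S, extended) built on
  the same two-beads-per-residue conventions as the real model, mutually
  distinguishable under the fibril-overlap order parameter;
* discrete Markov-chain trajectories with geometric emissions, whose
  stationary weights, mean first-passage times and relaxation spectra are
  known in closed form (exhaustive linear algebra, never simulation);
* random-coil ensembles: self-avoiding chains sampled with the pivot
  algorithm, emulating the disordered ground state of an IDP monomer.
  In good solvent their radius of gyration scales as R_g ~ N^nu with the
  Flory exponent nu ~= 0.6.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .bd import Trajectory
from .order_params import (CHI_TOLERANCE_DEFAULT, ReferenceStructure,
                           bb_pair_list)

__all__ = [
    "TOY_SHAPES",
    "ToyLandscapeSpec",
    "ToyMarkovResult",
    "make_toy_reference",
    "toy_template",
    "simulate_toy_markov",
    "make_rc_ensemble",
    "fit_flory_exponent",
    "flory_scaling_experiment",
]

TOY_SHAPES = ("hairpin-U", "meander-S", "extended")

# geometry constants (A): straight-strand spacing for the extended shape,
# compressed zig-zag strands for the folded shapes, so that even short-range
# backbone distances differ between shapes by more than the default overlap
# tolerance of 2 A.
_EXT_SPACING = 3.8
_ZIG_DX = 2.8
_ZIG_AMP = 2.0
_STRAND_SEP = 4.8
_SC_OFFSET = 2.0


def _bb_path(shape: str, n_res: int) -> np.ndarray:
    if shape == "extended":
        xyz = np.zeros((n_res, 3))
        xyz[:, 0] = _EXT_SPACING * np.arange(n_res)
        return xyz
    if shape == "hairpin-U":
        h = n_res // 2
        xyz = np.zeros((n_res, 3))
        for k in range(n_res):
            if k < h:
                xyz[k] = (_ZIG_DX * k, 0.0, _ZIG_AMP * (k % 2))
            else:
                xyz[k] = (_ZIG_DX * (n_res - 1 - k), _STRAND_SEP,
                          _ZIG_AMP * (k % 2))
        return xyz
    if shape == "meander-S":
        t = int(np.ceil(n_res / 3))
        xyz = np.zeros((n_res, 3))
        for k in range(n_res):
            strand, pos = divmod(k, t)
            x = _ZIG_DX * (pos if strand % 2 == 0 else t - 1 - pos)
            xyz[k] = (x, _STRAND_SEP * strand, _ZIG_AMP * (k % 2))
        return xyz
    raise ValueError(f"unknown toy shape {shape!r}; options: {TOY_SHAPES}")


def toy_template(shape: str, n_res: int = 12) -> np.ndarray:
    """Deterministic bead coordinates (2 beads/residue) for a toy shape."""
    bb = _bb_path(shape, n_res)
    coords = np.zeros((2 * n_res, 3))
    coords[0::2] = bb
    # SC beads sit off the zig-zag plane, alternating sides along the chain
    sc = bb.copy()
    sc[:, 2] += _SC_OFFSET * np.where(np.arange(n_res) % 2 == 0, 1.0, -1.0)
    coords[1::2] = sc
    return coords


def make_toy_reference(shape: str, n_res: int = 12,
                       tolerance: float = CHI_TOLERANCE_DEFAULT,
                       min_separation: int = 3) -> ReferenceStructure:
    """A toy fibril-monomer reference with its BB-BB pair list.

    The hairpin-U and meander-S shapes stand in for the U-bend and S-bend
    fibril polymorph units; they are mutually distinguishable under the
    overlap order parameter (chi of one template against the other
    reference stays below the 0.30 classification threshold).
    """
    coords = toy_template(shape, n_res)
    pairs = bb_pair_list(n_res, min_separation=min_separation)
    return ReferenceStructure.from_coords(coords, pairs, tolerance=tolerance,
                                          label=shape)


# ---------------------------------------------------------------------------
# toy Markov landscapes
# ---------------------------------------------------------------------------

@dataclass
class ToyLandscapeSpec:
    """A hidden Markov landscape with geometric emissions.

    ``transition`` is the row-stochastic per-frame jump matrix.  Each state
    emits a rigid bead template plus isotropic Gaussian jitter (sigma in A,
    small against the 2 A overlap tolerance so state assignment stays
    unambiguous at the defaults).
    """

    transition: np.ndarray
    n_frames: int = 1000
    jitter: float = 0.5
    seed: int = 0
    n_res: int = 12
    templates: np.ndarray | None = None  # (n_states, n_beads, 3)
    dt_frame_ps: float = 1.0
    start_state: int | None = None

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.ndim != 2 or \
                self.transition.shape[0] != self.transition.shape[1]:
            raise ValueError("transition must be square")
        if np.any(self.transition < 0):
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if self.templates is None:
            self.templates = _default_templates(self.n_states, self.n_res)
        self.templates = np.asarray(self.templates, dtype=float)

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


def _default_templates(n_states: int, n_res: int) -> np.ndarray:
    shapes = list(TOY_SHAPES)
    templates = []
    for s in range(n_states):
        if s < len(shapes):
            templates.append(toy_template(shapes[s], n_res))
        else:
            # additional rigid templates: deterministic compact random walks
            rng = np.random.default_rng(987_000 + s)
            steps = rng.standard_normal((2 * n_res, 3))
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            templates.append(3.0 * np.cumsum(steps, axis=0))
    return np.stack(templates)


@dataclass
class ToyMarkovResult:
    trajectory: Trajectory
    states: np.ndarray  # ground-truth hidden path (1-based labels)
    ground_truth: dict  # analytic stationary/MFPT/timescales


def _analytic_kinetics(P: np.ndarray, dt: float) -> dict:
    """Closed-form stationary distribution, MFPT matrix and timescales."""
    n = P.shape[0]
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, i]))
    pi /= pi.sum()

    mfpt = np.zeros((n, n))
    for target in range(n):
        q = [s for s in range(n) if s != target]
        m = np.linalg.solve(np.eye(n - 1) - P[np.ix_(q, q)],
                            np.full(n - 1, dt))
        for k, s in enumerate(q):
            mfpt[s, target] = m[k]

    eig = np.sort(np.abs(np.linalg.eigvals(P)))[::-1]
    timescales = np.array([
        np.inf if m >= 1 - 1e-12 else (0.0 if m <= 0 else -dt / np.log(m))
        for m in eig[1:]
    ])
    return {"stationary": pi, "mfpt": mfpt, "implied_timescales": timescales,
            "dt_frame_ps": dt}


def simulate_toy_markov(spec: ToyLandscapeSpec) -> ToyMarkovResult:
    """Sample a hidden-state path and emit jittered bead frames.

    The returned ground truth (stationary weights, MFPT matrix in physical
    units, implied timescales) is computed analytically from the jump
    matrix, never from the sampled path.
    """
    rng = np.random.default_rng(spec.seed)
    P = spec.transition
    n = spec.n_states
    truth = _analytic_kinetics(P, spec.dt_frame_ps)

    if spec.start_state is not None:
        state = int(spec.start_state)
    else:
        state = int(rng.choice(n, p=truth["stationary"]))
    states = np.empty(spec.n_frames, dtype=int)
    cum = np.cumsum(P, axis=1)
    u = rng.random(spec.n_frames)
    for f in range(spec.n_frames):
        states[f] = state
        state = int(np.searchsorted(cum[state], u[f]))
    coords = spec.templates[states]
    if spec.jitter > 0:
        coords = coords + rng.normal(0.0, spec.jitter, coords.shape)
    traj = Trajectory(coords, dt_save_ps=spec.dt_frame_ps,
                      metadata={"seed": spec.seed, "kind": "toy-markov"})
    return ToyMarkovResult(trajectory=traj, states=states + 1,
                           ground_truth=truth)


# ---------------------------------------------------------------------------
# random-coil ensembles
# ---------------------------------------------------------------------------

def _pivot_chain(rng: np.random.Generator, n: int, bond: float,
                 ev_diameter: float, n_attempts: int,
                 start: np.ndarray | None = None) -> np.ndarray:
    """Pivot-algorithm moves on a bead chain with hard-sphere self-avoidance.

    ``ev_diameter <= 0`` disables excluded volume (ideal chain).  Bond
    lengths are preserved exactly by the rigid pivot rotations.
    """
    if start is None:
        pos = np.zeros((n, 3))
        pos[:, 0] = bond * np.arange(n)
    else:
        pos = start.copy()
    for _ in range(n_attempts):
        p = int(rng.integers(1, n - 1))
        R = Rotation.random(rng=rng).as_matrix()
        tail = (pos[p + 1:] - pos[p]) @ R.T + pos[p]
        if ev_diameter > 0:
            d = cdist(pos[:p + 1], tail)
            d[p, 0] = np.inf  # bonded pair across the pivot
            if d.min() < ev_diameter:
                continue
        pos[p + 1:] = tail
    return pos


def make_rc_ensemble(n_res: int, n_frames: int, seed: int = 0,
                     mode: str = "good_solvent", bond: float = 3.8,
                     ev_diameter: float = 4.0, sc_offset: float = _SC_OFFSET,
                     dt_frame_ps: float = 1.0) -> Trajectory:
    """An ensemble of disordered (random-coil) two-bead-per-residue chains.

    Backbones are self-avoiding chains sampled with the pivot algorithm
    (``mode="good_solvent"``) or ideal chains (``mode="ideal"``); SC beads
    are attached at a fixed offset in a random direction.  Suitable as the
    RC-class fixture and for chain-dimension scaling checks.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    if mode not in ("good_solvent", "ideal"):
        raise ValueError("mode must be 'good_solvent' or 'ideal'")
    ev = ev_diameter if mode == "good_solvent" else 0.0
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, 2 * n_res, 3))
    bb = _pivot_chain(rng, n_res, bond, ev, n_attempts=12 * n_res)
    stride = max(30, 2 * n_res)
    for f in range(n_frames):
        if f > 0:
            bb = _pivot_chain(rng, n_res, bond, ev, n_attempts=stride,
                              start=bb)
        frames[f, 0::2] = bb
        u = rng.standard_normal((n_res, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        frames[f, 1::2] = bb + sc_offset * u
    return Trajectory(frames, dt_save_ps=dt_frame_ps,
                      metadata={"seed": seed, "kind": f"rc-{mode}",
                                "n_res": n_res})


def fit_flory_exponent(lengths, rg_values) -> tuple[float, float]:
    """Fit R_g ~ a0 N^nu by linear regression of log R_g on log N.

    Returns ``(nu, prefactor_a0)``.
    """
    lengths = np.asarray(lengths, dtype=float)
    rg = np.asarray(rg_values, dtype=float)
    if len(lengths) < 2:
        raise ValueError("need at least two chain lengths")
    slope, intercept = np.polyfit(np.log(lengths), np.log(rg), 1)
    return float(slope), float(np.exp(intercept))


def flory_scaling_experiment(lengths=(16, 24, 36, 54, 80, 120),
                             n_frames: int = 120, seed: int = 0,
                             mode: str = "good_solvent") -> dict:
    """Measure the chain-dimension scaling exponent of RC ensembles.

    Generates an ensemble at each chain length, averages the backbone
    radius of gyration, and fits the scaling exponent.  Returns a dict with
    per-length mean R_g, the exponent nu and prefactor.
    """
    from .order_params import radius_of_gyration

    mean_rg = []
    for i, n in enumerate(lengths):
        traj = make_rc_ensemble(n, n_frames, seed=seed + 1000 * i, mode=mode)
        rg = [radius_of_gyration(frame[0::2]) for frame in traj.coords]
        mean_rg.append(float(np.mean(rg)))
    nu, a0 = fit_flory_exponent(lengths, mean_rg)
    return {"lengths": list(lengths), "mean_rg": mean_rg,
            "nu": nu, "prefactor": a0, "mode": mode, "n_frames": n_frames}
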