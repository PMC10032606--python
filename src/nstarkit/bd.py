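"""Overdamped Brownian dynamics with optional hydrodynamic interactions.

The equations of motion are integrated in the high-friction (inertialess)
limit with the Ermak-McCammon scheme.  Without hydrodynamic coupling each
bead obeys

    dq_i = -(dt/gamma) grad_i U + sqrt(2 kB T dt / gamma) xi,

with xi standard normal.  With hydrodynamic interactions the drift uses the
configuration-dependent Rotne-Prager-Yamakawa mobility tensor mu (with the
overlap-regularised form for bead separations below two hydrodynamic radii)
and the noise covariance is 2 kB T mu dt, realised through a dense Cholesky
factorisation of mu.

Time bookkeeping: the integration step is expressed in units of the natural
Brownian time tau_HF = gamma a^2 / kB T (a = 1 A by convention), so a step
``dt`` corresponds to ``dt * tau_HF`` picoseconds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Protocol

import numpy as np

from . import constants
from .forcefield import (Conformation, FeneOverstretchError, ForceField,
                         Topology, energy_and_forces)

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "Potential",
    "SOPPotential",
    "CompositePotential",
    "FunctionPotential",
    "natural_time_unit",
    "rpy_mobility",
    "step_free_draining",
    "step_hydrodynamic",
    "run_trajectory",
]

logger = logging.getLogger(__name__)


def natural_time_unit(gamma: float, a: float = 1.0,
                      energy_scale: float | None = None) -> float:
    """Natural Brownian time unit gamma a^2 / E.

    With gamma in kcal ps / (mol A^2), ``a`` in A and the energy scale in
    kcal/mol the result is in picoseconds.  The energy scale defaults to the
    thermal energy at 298 K.  The inputs are unit-agnostic: in SI units
    (kg/s, m, J) the result is in seconds.
    """
    if energy_scale is None:
        energy_scale = constants.kBT()
    if gamma <= 0 or a <= 0 or energy_scale <= 0:
        raise ValueError("gamma, a and energy_scale must be positive")
    return gamma * a * a / energy_scale


@dataclass
class IntegratorConfig:
    """Integrator settings.

    ``dt`` is in units of tau_HF; temperature in K.  The per-bead friction
    is derived from the solvent viscosity and a single hydrodynamic radius
    shared by all beads, gamma = 6 pi eta a_h.

    The default step of 0.01 tau_HF is the largest that integrates the
    shipped force-field tables stably (the FENE bonds are the stiffest
    term); see docs/methods.md.
    """

    dt: float = 0.01  # units of tau_HF
    temperature: float = constants.DEFAULT_TEMPERATURE  # K
    viscosity: float = constants.WATER_VISCOSITY_PAS  # Pa s
    hydro_radius: float = constants.DEFAULT_HYDRO_RADIUS  # A
    hydrodynamics: str = "off"  # "off" | "rpy"
    seed: int = 0
    n_steps: int = 1000
    save_stride: int = 100
    max_retries: int = 5  # bonded-overstretch step halvings

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.hydrodynamics not in ("off", "rpy"):
            raise ValueError("hydrodynamics must be 'off' or 'rpy'")

    @property
    def gamma(self) -> float:
        """Per-bead friction, kcal ps / (mol A^2)."""
        return constants.stokes_friction(self.hydro_radius, self.viscosity)

    @property
    def kbt(self) -> float:
        return constants.kBT(self.temperature)

    @property
    def tau_hf(self) -> float:
        """Natural time unit gamma a^2 / kB T with a = 1 A, in ps."""
        return natural_time_unit(self.gamma, 1.0, self.kbt)

    @property
    def dt_ps(self) -> float:
        return self.dt * self.tau_hf

    @property
    def duration_ps(self) -> float:
        """Physical duration of a full run, ps."""
        return self.n_steps * self.dt_ps

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Trajectory:
    """Time-ordered bead coordinates with uniform frame spacing.

    ``coords`` has shape (n_frames, n_beads, 3); frame 0 is the initial
    condition.  ``dt_save_ps`` is the physical time between saved frames.
    """

    coords: np.ndarray
    dt_save_ps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_save_ps

    def frame(self, i: int) -> Conformation:
        return Conformation(self.coords[i], time=float(i * self.dt_save_ps))


class Potential(Protocol):
    """Anything exposing forces (and energy) on a coordinate array."""

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        ...


class SOPPotential:
    """Adapter binding the coarse-grained force field to the integrator."""

    def __init__(self, topo: Topology, ff: ForceField):
        self.topo = topo
        self.ff = ff

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        breakdown, F = energy_and_forces(coords, self.topo, self.ff)
        return breakdown.total, F

    def check_bonds(self, coords: np.ndarray) -> bool:
        """True if no FENE bond is at or beyond its divergence length."""
        bi, bj = self.topo.bonds[:, 0], self.topo.bonds[:, 1]
        r = np.linalg.norm(coords[bj] - coords[bi], axis=1)
        return bool(np.all(np.abs(r - self.topo.bond_r0) < self.ff.fene_R0))


class FunctionPotential:
    """Wrap a plain function U(coords) -> (energy, forces)."""

    def __init__(self, fn: Callable[[np.ndarray], tuple[float, np.ndarray]]):
        self.fn = fn

    def energy_forces(self, coords):
        return self.fn(coords)


class CompositePotential:
    """Sum of several potentials (e.g. force field + restraint)."""

    def __init__(self, *terms: Potential):
        self.terms = terms

    def energy_forces(self, coords):
        total = 0.0
        F = np.zeros_like(coords)
        for term in self.terms:
            u, f = term.energy_forces(coords)
            total += u
            F += f
        return total, F

    def check_bonds(self, coords):
        ok = True
        for term in self.terms:
            if hasattr(term, "check_bonds"):
                ok = ok and term.check_bonds(coords)
        return ok


def _resolve_potential(topo, ff, potential) -> Potential:
    if potential is not None:
        return potential
    if topo is None or ff is None:
        raise ValueError("either a potential or (topology, force field) required")
    return SOPPotential(topo, ff)


# ---------------------------------------------------------------------------
# mobility tensor
# ---------------------------------------------------------------------------

def rpy_mobility(coords: np.ndarray, hydro_radius: float,
                 viscosity: float = constants.WATER_VISCOSITY_PAS) -> np.ndarray:
    """Rotne-Prager-Yamakawa mobility tensor, shape (3N, 3N).

    Uses the positive-definite regularised form for overlapping beads
    (separations below 2 a_h).  Units: A / (kcal/mol) / ps^-1, i.e. the
    inverse of the friction units, so that mu_ii = 1/(6 pi eta a_h) I.
    """
    a = hydro_radius
    eta = constants.viscosity_internal(viscosity)
    n = coords.shape[0]
    mu = np.zeros((n, 3, n, 3))
    mu0 = 1.0 / (6.0 * math.pi * eta * a)
    eye = np.eye(3)
    for i in range(n):
        mu[i, :, i, :] = mu0 * eye
    for i in range(n):
        rij = coords[i + 1:] - coords[i]
        r = np.linalg.norm(rij, axis=1)
        for k, j in enumerate(range(i + 1, n)):
            d = r[k]
            if d < 1e-12:
                block = mu0 * eye  # coincident beads: self-mobility limit
            else:
                u = rij[k] / d
                uu = np.outer(u, u)
                if d >= 2.0 * a:
                    c1 = 1.0 + 2.0 * a * a / (3.0 * d * d)
                    c2 = 1.0 - 2.0 * a * a / (d * d)
                    block = (1.0 / (8.0 * math.pi * eta * d)) * (c1 * eye + c2 * uu)
                else:
                    c1 = 1.0 - 9.0 * d / (32.0 * a)
                    c2 = 3.0 * d / (32.0 * a)
                    block = mu0 * (c1 * eye + c2 * uu)
            mu[i, :, j, :] = block
            mu[j, :, i, :] = block
    return mu.reshape(3 * n, 3 * n)


# ---------------------------------------------------------------------------
# steppers
# ---------------------------------------------------------------------------

def _attempt_fd(coords, F, dt_ps, gamma, kbt, rng):
    noise = rng.standard_normal(coords.shape)
    return (coords + (dt_ps / gamma) * F
            + math.sqrt(2.0 * kbt * dt_ps / gamma) * noise)


def step_free_draining(conf: Conformation, topo: Topology | None,
                       ff: ForceField | None, cfg: IntegratorConfig,
                       rng: np.random.Generator,
                       potential: Potential | None = None) -> Conformation:
    """One Ermak-McCammon step without hydrodynamic coupling.

    If the step overstretches a FENE bond it is retried with a halved time
    step (fresh noise) up to ``cfg.max_retries`` times.
    """
    potential = _resolve_potential(topo, ff, potential)
    coords = conf.coords
    _, F = potential.energy_forces(coords)
    dt_ps = cfg.dt_ps
    for attempt in range(cfg.max_retries + 1):
        new = _attempt_fd(coords, F, dt_ps, cfg.gamma, cfg.kbt, rng)
        if not hasattr(potential, "check_bonds") or potential.check_bonds(new):
            t = (conf.time or 0.0) + cfg.dt_ps
            return Conformation(new, time=t)
        dt_ps *= 0.5
        logger.warning("bond overstretch, retrying with dt/2 (attempt %d)",
                       attempt + 1)
    raise FeneOverstretchError(-1, -1, -1, float("nan"), float("nan"),
                               ff.fene_R0 if ff is not None else float("nan"))


def step_hydrodynamic(conf: Conformation, topo: Topology | None,
                      ff: ForceField | None, cfg: IntegratorConfig,
                      rng: np.random.Generator,
                      potential: Potential | None = None) -> Conformation:
    """One Ermak-McCammon step with RPY hydrodynamic coupling.

    Drift uses mu F; the correlated noise is sqrt(2 kB T dt) L xi with
    mu = L L^T (dense Cholesky).  The RPY divergence term vanishes
    identically, so no extra drift correction is needed.
    """
    potential = _resolve_potential(topo, ff, potential)
    coords = conf.coords
    n = coords.shape[0]
    _, F = potential.energy_forces(coords)
    mu = rpy_mobility(coords, cfg.hydro_radius, cfg.viscosity)
    try:
        L = np.linalg.cholesky(mu)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "mobility tensor not positive definite; configuration:\n"
            + np.array2string(coords, precision=3)) from exc
    dt_ps = cfg.dt_ps
    for attempt in range(cfg.max_retries + 1):
        xi = rng.standard_normal(3 * n)
        disp = dt_ps * (mu @ F.ravel()) + math.sqrt(2.0 * cfg.kbt * dt_ps) * (L @ xi)
        new = coords + disp.reshape(n, 3)
        if not hasattr(potential, "check_bonds") or potential.check_bonds(new):
            t = (conf.time or 0.0) + cfg.dt_ps
            return Conformation(new, time=t)
        dt_ps *= 0.5
        # re-scale the Cholesky noise amplitude through dt only; mu is fixed
        logger.warning("bond overstretch under HI, retrying with dt/2 "
                       "(attempt %d)", attempt + 1)
    raise FeneOverstretchError(-1, -1, -1, float("nan"), float("nan"),
                               ff.fene_R0 if ff is not None else float("nan"))


def run_trajectory(initial: Conformation, topo: Topology | None,
                   ff: ForceField | None, cfg: IntegratorConfig,
                   potential: Potential | None = None,
                   callback: Callable[[int, Conformation], None] | None = None
                   ) -> Trajectory:
    """Propagate ``cfg.n_steps`` steps, saving every ``cfg.save_stride``.

    Frame 0 of the returned trajectory is the initial conformation.  The
    metadata records the seed, config hash and physical duration; identical
    configs and initial conditions give bit-identical trajectories.
    """
    potential = _resolve_potential(topo, ff, potential)
    rng = np.random.default_rng(cfg.seed)
    stepper = step_hydrodynamic if cfg.hydrodynamics == "rpy" else step_free_draining
    frames = [initial.coords.copy()]
    conf = Conformation(initial.coords.copy(), time=0.0)
    for step in range(1, cfg.n_steps + 1):
        conf = stepper(conf, topo, ff, cfg, rng, potential=potential)
        if step % cfg.save_stride == 0:
            frames.append(conf.coords.copy())
            if callback is not None:
                callback(step, conf)
    metadata = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_steps": cfg.n_steps,
        "dt_tauhf": cfg.dt,
        "tau_hf_ps": cfg.tau_hf,
        "duration_ps": cfg.duration_ps,
        "temperature_K": cfg.temperature,
        "hydrodynamics": cfg.hydrodynamics,
    }
    return Trajectory(np.array(frames), dt_save_ps=cfg.save_stride * cfg.dt_ps,
                      metadata=metadata)
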