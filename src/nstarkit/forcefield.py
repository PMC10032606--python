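"""Coarse-grained two-beads-per-residue topology and energy function.

Each amino acid is represented by a backbone bead (BB, centred on the C-alpha
position) and a side-chain bead (SC, centred on the side-chain centroid;
glycine also carries a small SC bead).  The potential energy decomposes as

    U = U_FENE + U_EXV + U_ELE + U_BB + U_BS + U_SS

* ``U_FENE``  -- finitely extensible bonds along the backbone and between each
  BB bead and its SC bead.
* ``U_EXV``   -- purely repulsive ``eps (sigma/r)^6`` interactions between
  beads of nearby residues (sequence separation 1-2) that are not bonded,
  preventing unphysical overlap.
* ``U_ELE``   -- Debye-Hueckel screened Coulomb interactions between charged
  side-chain beads.
* ``U_BB/U_BS/U_SS`` -- 12-6 Lennard-Jones interactions
  ``eps [(sigma/r)^12 - 2 (sigma/r)^6]`` between beads of residues separated
  by at least 3 positions (or on different chains).  The SS well depths encode
  sequence specificity through a symmetric pairwise contact-energy table.

All interaction parameters are data: they are read from versioned
whitespace-delimited tables under ``nstarkit/data`` (see the table headers for
provenance; the side-chain contact matrix shipped here is a synthetic
stand-in built from a hydrophobicity scale).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

from .constants import COULOMB

__all__ = [
    "AMINO_ACIDS",
    "AB40_SEQUENCE",
    "AB42_SEQUENCE",
    "Sequence",
    "Bead",
    "Topology",
    "ForceField",
    "Conformation",
    "EnergyBreakdown",
    "FeneOverstretchError",
    "build_topology",
    "merge_topologies",
    "energy",
    "forces",
    "energy_and_forces",
    "default_forcefield",
    "extended_conformation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
AB40_SEQUENCE = AB42_SEQUENCE[:40]


class FeneOverstretchError(ValueError):
    """A FENE bond was stretched beyond its divergence length R0."""

    def __init__(self, bond_index: int, i: int, j: int, r: float, r0: float, R0: float):
        self.bond_index = bond_index
        self.beads = (i, j)
        super().__init__(
            f"FENE bond {bond_index} between beads {i} and {j} overstretched: "
            f"r={r:.3f} A, r0={r0:.3f} A, R0={R0:.3f} A"
        )


@dataclass(frozen=True)
class Sequence:
    """A peptide sequence in one-letter amino-acid codes."""

    residues: str
    id: str = "peptide"

    def __post_init__(self):
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        for pos, code in enumerate(self.residues, start=1):
            if code not in AMINO_ACIDS:
                raise ValueError(
                    f"unknown residue code {code!r} at position {pos} "
                    f"in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_fasta(cls, text: str, id: str | None = None) -> "Sequence":
        """Parse the first record of a FASTA string (or a raw sequence)."""
        lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty FASTA input")
        if lines[0].startswith(">"):
            header = lines[0][1:].split()[0] if len(lines[0]) > 1 else "peptide"
            body = []
            for ln in lines[1:]:
                if ln.startswith(">"):
                    break
                body.append(ln)
            return cls("".join(body).upper(), id=id or header)
        return cls("".join(lines).upper(), id=id or "peptide")


@dataclass(frozen=True)
class Bead:
    index: int
    resid: int  # 1-based residue number
    residue: str  # one-letter code
    site: str  # "BB" or "SC"
    charge: float  # e
    sigma: float  # vdW diameter, A
    chain: int = 0


@dataclass
class Conformation:
    """Cartesian bead coordinates in angstrom."""

    coords: np.ndarray
    time: float | None = None  # ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol; ``total`` is their sum."""

    fene: float
    exv: float
    ele: float
    bb: float
    bs: float
    ss: float

    @property
    def total(self) -> float:
        return self.fene + self.exv + self.ele + self.bb + self.bs + self.ss

    def as_dict(self) -> dict:
        return {
            "FENE": self.fene, "EXV": self.exv, "ELE": self.ele,
            "BB": self.bb, "BS": self.bs, "SS": self.ss, "total": self.total,
        }


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

def _read_table(name: str) -> list[list[str]]:
    """Read a shipped whitespace-delimited table, verifying its checksum."""
    text = resources.files("nstarkit.data").joinpath(name).read_text()
    checksum = None
    rows: list[list[str]] = []
    data_lines: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped.lower().startswith("# sha256:"):
                checksum = stripped.split(":", 1)[1].strip()
            continue
        data_lines.append(stripped)
        rows.append(stripped.split())
    if checksum is not None:
        digest = hashlib.sha256("\n".join(data_lines).encode()).hexdigest()
        if digest != checksum:
            raise ValueError(f"checksum mismatch in parameter table {name}")
    return rows


def _load_scalars() -> dict:
    rows = _read_table("forcefield_scalars.tsv")
    return {key: float(value) for key, value in rows}


def _load_bead_params() -> dict:
    rows = _read_table("bead_params.tsv")
    header, body = rows[0], rows[1:]
    assert header == ["res", "sc_sigma", "charge", "bb_sc_bond"]
    return {
        res: {"sc_sigma": float(sig), "charge": float(q), "bb_sc_bond": float(b)}
        for res, sig, q, b in body
    }


def _load_ss_matrix() -> dict:
    rows = _read_table("ss_contact_synthetic.tsv")
    header, body = rows[0], rows[1:]
    cols = header[1:]
    eps = {}
    for row in body:
        a = row[0]
        for b, value in zip(cols, row[1:]):
            eps[(a, b)] = float(value)
    for (a, b), value in eps.items():
        if abs(value - eps[(b, a)]) > 1e-12:
            raise ValueError(f"side-chain contact table is not symmetric at {a},{b}")
    return eps


@dataclass
class ForceField:
    """Interaction parameters for the coarse-grained model.

    All numeric parameters originate from the plain-text tables under
    ``nstarkit/data`` (or from explicit keyword overrides); the code treats
    them purely as data.
    """

    fene_k: float  # kcal/mol/A^2
    fene_R0: float  # A
    bb_bond: float  # A, BB(i)-BB(i+1) equilibrium length
    bb_sigma: float  # A, backbone bead vdW diameter
    eps_bb: float  # kcal/mol
    eps_bs: float  # kcal/mol
    eps_exv: float  # kcal/mol
    dielectric: float
    debye_length: float  # A
    bead_params: dict
    ss_eps: dict
    charged_termini: bool = True
    cutoff: float | None = None  # optional nonbonded cutoff, A

    @classmethod
    def default(cls, **overrides) -> "ForceField":
        scalars = _load_scalars()
        ff = cls(
            fene_k=scalars["fene_k"],
            fene_R0=scalars["fene_R0"],
            bb_bond=scalars["bb_bond"],
            bb_sigma=scalars["bb_sigma"],
            eps_bb=scalars["eps_bb"],
            eps_bs=scalars["eps_bs"],
            eps_exv=scalars["eps_exv"],
            dielectric=scalars["dielectric"],
            debye_length=scalars["debye_length"],
            bead_params=_load_bead_params(),
            ss_eps=_load_ss_matrix(),
        )
        for key, value in overrides.items():
            if not hasattr(ff, key):
                raise TypeError(f"unknown force-field parameter {key!r}")
            setattr(ff, key, value)
        ff.validate()
        return ff

    def validate(self) -> None:
        if self.fene_R0 <= 0 or self.fene_k <= 0:
            raise ValueError("FENE parameters must be positive")
        if self.bb_sigma <= 0 or self.debye_length <= 0:
            raise ValueError("sigma and Debye length must be positive")
        for res, p in self.bead_params.items():
            if p["sc_sigma"] <= 0 or p["bb_sc_bond"] <= 0:
                raise ValueError(f"non-positive bead parameter for residue {res}")
        for eps in self.ss_eps.values():
            if eps < 0:
                raise ValueError("SS well depths must be non-negative")


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Bead graph of one or more chains.

    Beads are interleaved per residue: bead ``2i`` is BB of residue ``i``
    (0-based internal index; residue numbering is 1-based) and bead ``2i+1``
    is its SC bead.  Bonds connect BB(i)-BB(i+1) within a chain and
    BB(i)-SC(i).
    """

    beads: list
    bonds: np.ndarray  # (n_bonds, 2) int
    bond_r0: np.ndarray  # (n_bonds,) A
    sequence_ids: tuple = ("peptide",)

    _pair_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.bonds = np.asarray(self.bonds, dtype=int)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return self.n_beads // 2

    @property
    def bb_indices(self) -> np.ndarray:
        return np.array([b.index for b in self.beads if b.site == "BB"], dtype=int)

    @property
    def sc_indices(self) -> np.ndarray:
        return np.array([b.index for b in self.beads if b.site == "SC"], dtype=int)

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([b.sigma for b in self.beads])

    @property
    def chains(self) -> np.ndarray:
        return np.array([b.chain for b in self.beads], dtype=int)

    def bonded_neighbors(self) -> list[set]:
        nbrs: list[set] = [set() for _ in range(self.n_beads)]
        for i, j in self.bonds:
            nbrs[i].add(j)
            nbrs[j].add(i)
        return nbrs


def build_topology(seq: Sequence | str, ff: ForceField | None = None,
                   chain: int = 0) -> Topology:
    """Build the two-beads-per-residue topology for a sequence.

    Parameters are resolved from the force-field tables at build time, so
    the returned topology carries per-bead charges/diameters and per-bond
    equilibrium lengths.  Terminal charges (+1 on the first residue, -1 on
    the last) are placed on the terminal SC beads when
    ``ff.charged_termini`` is set.
    """
    if isinstance(seq, str):
        seq = Sequence(seq)
    if ff is None:
        ff = default_forcefield()

    beads: list[Bead] = []
    bonds: list[tuple[int, int]] = []
    bond_r0: list[float] = []
    n = len(seq.residues)
    for i, res in enumerate(seq.residues):
        params = ff.bead_params[res]
        charge = params["charge"]
        if ff.charged_termini:
            if i == 0:
                charge += 1.0
            if i == n - 1:
                charge -= 1.0
        bb = Bead(2 * i, i + 1, res, "BB", 0.0, ff.bb_sigma, chain)
        sc = Bead(2 * i + 1, i + 1, res, "SC", charge, params["sc_sigma"], chain)
        beads.extend([bb, sc])
        bonds.append((2 * i, 2 * i + 1))
        bond_r0.append(params["bb_sc_bond"])
        if i > 0:
            bonds.append((2 * (i - 1), 2 * i))
            bond_r0.append(ff.bb_bond)
    return Topology(beads, np.array(bonds), np.array(bond_r0),
                    sequence_ids=(seq.id,))


def merge_topologies(a: Topology, b: Topology) -> Topology:
    """Combine two chains into one topology (no bonds across chains).

    Interchain nonbonded parameters are automatically identical to
    intrachain ones for the same residue pair, because parameters are
    resolved per bead and per pair class.
    """
    offset = a.n_beads
    chain_offset = int(a.chains.max()) + 1
    beads = list(a.beads)
    for bead in b.beads:
        beads.append(Bead(bead.index + offset, bead.resid, bead.residue,
                          bead.site, bead.charge, bead.sigma,
                          bead.chain + chain_offset))
    bonds = np.vstack([a.bonds, b.bonds + offset])
    bond_r0 = np.concatenate([a.bond_r0, b.bond_r0])
    return Topology(beads, bonds, bond_r0,
                    sequence_ids=a.sequence_ids + b.sequence_ids)


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------

class _PairTables:
    """Precomputed index/parameter arrays for vectorised energy evaluation."""

    def __init__(self, topo: Topology, ff: ForceField):
        resid = np.array([b.resid for b in topo.beads])
        chain = topo.chains
        site = np.array([b.site for b in topo.beads])
        residue = np.array([b.residue for b in topo.beads])
        sigma = topo.sigmas
        charge = topo.charges
        n = topo.n_beads

        bonded = set(map(tuple, np.sort(topo.bonds, axis=1)))

        iu, ju = np.triu_indices(n, k=1)
        same_chain = chain[iu] == chain[ju]
        sep = np.abs(resid[iu] - resid[ju])

        is_bonded = np.fromiter(
            ((min(i, j), max(i, j)) in bonded for i, j in zip(iu, ju)),
            dtype=bool, count=len(iu))

        # Repulsive-only class: near neighbours along the chain.
        exv_mask = same_chain & (sep <= 2) & ~is_bonded
        # Attractive nonbonded class: sequence separation >= 3 or interchain.
        nb_mask = (~same_chain) | (sep >= 3)

        self.exv_i, self.exv_j = iu[exv_mask], ju[exv_mask]
        self.exv_sigma = 0.5 * (sigma[self.exv_i] + sigma[self.exv_j])

        nb_i, nb_j = iu[nb_mask], ju[nb_mask]
        nb_sigma = 0.5 * (sigma[nb_i] + sigma[nb_j])
        both_bb = (site[nb_i] == "BB") & (site[nb_j] == "BB")
        both_sc = (site[nb_i] == "SC") & (site[nb_j] == "SC")
        mixed = ~both_bb & ~both_sc

        nb_eps = np.empty(len(nb_i))
        nb_eps[both_bb] = ff.eps_bb
        nb_eps[mixed] = ff.eps_bs
        if np.any(both_sc):
            nb_eps[both_sc] = [
                ff.ss_eps[(a, b)]
                for a, b in zip(residue[nb_i[both_sc]], residue[nb_j[both_sc]])
            ]
        self.nb_i, self.nb_j = nb_i, nb_j
        self.nb_sigma, self.nb_eps = nb_sigma, nb_eps
        self.nb_class = np.where(both_bb, 0, np.where(mixed, 1, 2))

        qprod = charge[nb_i] * charge[nb_j]
        ele = qprod != 0.0
        self.ele_i, self.ele_j = nb_i[ele], nb_j[ele]
        self.ele_qq = qprod[ele]


def _tables(topo: Topology, ff: ForceField) -> _PairTables:
    key = id(ff)
    tables = topo._pair_cache.get(key)
    if tables is None:
        tables = _PairTables(topo, ff)
        topo._pair_cache[key] = tables
    return tables


# ---------------------------------------------------------------------------
# energy and forces
# ---------------------------------------------------------------------------

def _evaluate(coords: np.ndarray, topo: Topology, ff: ForceField,
              want_forces: bool) -> tuple[EnergyBreakdown, np.ndarray | None]:
    if coords.shape != (topo.n_beads, 3):
        raise ValueError(
            f"conformation has {coords.shape[0]} beads, topology expects "
            f"{topo.n_beads}")
    t = _tables(topo, ff)
    F = np.zeros_like(coords) if want_forces else None

    n_beads = topo.n_beads

    def accumulate(i_idx, j_idx, dU_dr, unit):
        # unit points i -> j; F_i = +dU/dr * unit, F_j = -dU/dr * unit
        contrib = dU_dr[:, None] * unit
        for d in range(3):
            F[:, d] += np.bincount(i_idx, contrib[:, d], minlength=n_beads)
            F[:, d] -= np.bincount(j_idx, contrib[:, d], minlength=n_beads)

    # FENE bonds
    bi, bj = topo.bonds[:, 0], topo.bonds[:, 1]
    rvec = coords[bj] - coords[bi]
    r = np.linalg.norm(rvec, axis=1)
    dr = r - topo.bond_r0
    x = (dr / ff.fene_R0) ** 2
    if np.any(x >= 1.0):
        k = int(np.argmax(x))
        raise FeneOverstretchError(k, int(bi[k]), int(bj[k]),
                                   float(r[k]), float(topo.bond_r0[k]),
                                   ff.fene_R0)
    u_fene = float(-0.5 * ff.fene_k * ff.fene_R0 ** 2 * np.log1p(-x).sum())
    if want_forces:
        dU_dr = ff.fene_k * dr / (1.0 - x)
        accumulate(bi, bj, dU_dr, rvec / r[:, None])

    # repulsive excluded volume (1-2/1-3 level, non-bonded near pairs)
    u_exv = 0.0
    if len(t.exv_i):
        rvec = coords[t.exv_j] - coords[t.exv_i]
        r = np.linalg.norm(rvec, axis=1)
        s6 = (t.exv_sigma / r) ** 6
        u = ff.eps_exv * s6
        u_exv = float(u.sum())
        if want_forces:
            accumulate(t.exv_i, t.exv_j, -6.0 * u / r, rvec / r[:, None])

    # nonbonded 12-6 classes
    u_cls = np.zeros(3)
    if len(t.nb_i):
        rvec = coords[t.nb_j] - coords[t.nb_i]
        r = np.linalg.norm(rvec, axis=1)
        mask = np.ones(len(r), dtype=bool)
        if ff.cutoff is not None:
            mask = r <= ff.cutoff
        s6 = (t.nb_sigma / r) ** 6
        u = t.nb_eps * (s6 * s6 - 2.0 * s6) * mask
        for c in range(3):
            u_cls[c] = u[t.nb_class == c].sum()
        if want_forces:
            dU_dr = -12.0 * t.nb_eps / r * (s6 * s6 - s6) * mask
            accumulate(t.nb_i, t.nb_j, dU_dr, rvec / r[:, None])

    # screened electrostatics
    u_ele = 0.0
    if len(t.ele_i):
        rvec = coords[t.ele_j] - coords[t.ele_i]
        r = np.linalg.norm(rvec, axis=1)
        mask = np.ones(len(r), dtype=bool)
        if ff.cutoff is not None:
            mask = r <= ff.cutoff
        u = COULOMB * t.ele_qq / (ff.dielectric * r) * np.exp(-r / ff.debye_length) * mask
        u_ele = float(u.sum())
        if want_forces:
            accumulate(t.ele_i, t.ele_j, -u * (1.0 / r + 1.0 / ff.debye_length),
                       rvec / r[:, None])

    breakdown = EnergyBreakdown(fene=u_fene, exv=u_exv, ele=u_ele,
                                bb=float(u_cls[0]), bs=float(u_cls[1]),
                                ss=float(u_cls[2]))
    return breakdown, F


def energy(conf: Conformation | np.ndarray, topo: Topology,
           ff: ForceField) -> EnergyBreakdown:
    """Decomposed potential energy of a conformation, kcal/mol."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    breakdown, _ = _evaluate(coords, topo, ff, want_forces=False)
    return breakdown


def forces(conf: Conformation | np.ndarray, topo: Topology,
           ff: ForceField) -> np.ndarray:
    """Forces -grad U on every bead, kcal/mol/A, shape (n_beads, 3)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    _, F = _evaluate(coords, topo, ff, want_forces=True)
    return F


def energy_and_forces(conf: Conformation | np.ndarray, topo: Topology,
                      ff: ForceField) -> tuple[EnergyBreakdown, np.ndarray]:
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    return _evaluate(coords, topo, ff, want_forces=True)


def extended_conformation(topo: Topology, jitter: float = 0.0,
                          rng: np.random.Generator | None = None) -> Conformation:
    """A valid fully extended starting conformation for a topology.

    BB beads are placed along x at the backbone bond length; each SC bead is
    offset perpendicular to the chain at its bond length (alternating sides).
    Optional Gaussian ``jitter`` (A) breaks exact collinearity.
    """
    bond_len = {tuple(sorted(b)): r for b, r in zip(topo.bonds.tolist(),
                                                    topo.bond_r0)}
    coords = np.zeros((topo.n_beads, 3))
    chains = topo.chains
    for chain in np.unique(chains):
        idx = np.where(chains == chain)[0]
        bb = [i for i in idx if topo.beads[i].site == "BB"]
        z_off = 30.0 * chain  # separate chains
        for k, i in enumerate(bb):
            if k > 0:
                step = bond_len.get(tuple(sorted((bb[k - 1], i))), 3.8)
                coords[i] = coords[bb[k - 1]] + [step, 0.0, 0.0]
            else:
                coords[i] = [0.0, 0.0, z_off]
            sc = i + 1
            if sc < topo.n_beads and topo.beads[sc].site == "SC":
                r0 = bond_len.get(tuple(sorted((i, sc))), 2.0)
                coords[sc] = coords[i] + [0.0, r0 * (1 if k % 2 == 0 else -1), 0.0]
    if jitter > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    return Conformation(coords)


_DEFAULT_FF: ForceField | None = None


def default_forcefield() -> ForceField:
    """The force field built from the shipped parameter tables (cached)."""
    global _DEFAULT_FF
    if _DEFAULT_FF is None:
        _DEFAULT_FF = ForceField.default()
    return _DEFAULT_FF
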