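"""File formats, configuration and run manifests.

* Reference structures are imported from PDB files: C-alpha atoms become BB
  beads, the centroid of the side-chain heavy atoms becomes the SC bead
  (residues with no side-chain atoms get an SC bead at a small offset from
  the C-alpha, with a warning).  The BB-BB pair list is built over the
  residues actually resolved in the file.
* Trajectories are stored as extended-XYZ text with a mandatory JSON
  sidecar carrying units, frame spacing and the full metadata (config
  hash, seed); loading without the sidecar is an error.
* Run configuration is a flat YAML document with a documented schema;
  unknown keys are rejected and every run artifact embeds the config hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bd import Trajectory
from .forcefield import Conformation, Topology
from .order_params import (CHI_C_DEFAULT, CHI_TOLERANCE_DEFAULT,
                           ReferenceStructure, bb_pair_list)

__all__ = [
    "RunConfig",
    "read_reference_pdb",
    "save_reference_tsv",
    "load_reference_tsv",
    "save_trajectory",
    "load_trajectory",
    "write_pdb",
    "write_manifest",
]

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


def read_reference_pdb(path, tolerance: float = CHI_TOLERANCE_DEFAULT,
                       min_separation: int = 3, chain: str | None = None,
                       model: int = 0, label: str | None = None
                       ) -> ReferenceStructure:
    """Coarse-grain one chain of a PDB file into a fibril reference.

    Only residues with a C-alpha record are used; the pair list covers
    BB-BB pairs among resolved residues with sequence separation at least
    ``min_separation``.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ValueError(f"no models in PDB file {path}")
    mdl = models[model]
    chains = list(mdl)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"chain {chain!r} not found in {path}")
    ch = chains[0]

    bb, sc, resids = [], [], []
    for residue in ch:
        if "CA" not in residue:
            continue
        ca = residue["CA"].coord.astype(float)
        side = [atom.coord.astype(float) for atom in residue
                if atom.element != "H" and atom.get_name() not in _BACKBONE_ATOMS]
        if side:
            centroid = np.mean(side, axis=0)
        else:
            warnings.warn(
                f"residue {residue.get_id()[1]} has no side-chain atoms; "
                "placing SC bead at CA + 1 A offset")
            centroid = ca + np.array([1.0, 0.0, 0.0])
        bb.append(ca)
        sc.append(centroid)
        resids.append(residue.get_id()[1])
    if not bb:
        raise ValueError(f"no CA records found in {path}")

    n = len(bb)
    coords = np.zeros((2 * n, 3))
    coords[0::2] = bb
    coords[1::2] = sc
    # map residue numbers to bead indices over resolved residues only
    bb_index = {resid: 2 * k for k, resid in enumerate(resids)}
    pairs = bb_pair_list(n, min_separation=min_separation, bb_index=bb_index)
    return ReferenceStructure.from_coords(
        coords, pairs, tolerance=tolerance,
        label=label or path.stem)


def save_reference_tsv(ref: ReferenceStructure, path) -> Path:
    """Export a reference pair list as TSV for exact reproducibility."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label: {ref.label}\n")
        fh.write(f"# tolerance_A: {ref.tolerance}\n")
        fh.write("i\tj\tr0_A\n")
        for (i, j), r0 in zip(ref.pairs, ref.r0):
            fh.write(f"{i}\t{j}\t{r0:.6f}\n")
    return path


def load_reference_tsv(path) -> ReferenceStructure:
    path = Path(path)
    label, tolerance = path.stem, CHI_TOLERANCE_DEFAULT
    pairs, r0 = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# label:"):
                label = line.split(":", 1)[1].strip()
            elif line.startswith("# tolerance_A:"):
                tolerance = float(line.split(":", 1)[1])
            continue
        if line.startswith("i\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        pairs.append((int(fields[0]), int(fields[1])))
        r0.append(float(fields[2]))
    return ReferenceStructure(pairs=np.array(pairs), r0=np.array(r0),
                              tolerance=tolerance, label=label)


# ---------------------------------------------------------------------------
# trajectory storage (extended-XYZ + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_trajectory(traj: Trajectory, path, precision: int = 5) -> Path:
    """Write a trajectory as extended-XYZ plus a JSON metadata sidecar."""
    path = Path(path)
    n_frames, n_beads, _ = traj.coords.shape
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n_beads}\n")
            fh.write(f'Frame={f} Time_ps={f * traj.dt_save_ps:.6f} '
                     f'Properties=species:S:1:pos:R:3\n')
            for xyz in traj.coords[f]:
                fh.write("X %.*f %.*f %.*f\n" % (precision, xyz[0],
                                                 precision, xyz[1],
                                                 precision, xyz[2]))
    meta = {
        "format": "extended-xyz",
        "units": {"length": "angstrom", "time": "ps"},
        "n_frames": n_frames,
        "n_beads": n_beads,
        "dt_save_ps": traj.dt_save_ps,
        "metadata": _jsonable(traj.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def load_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory; the metadata sidecar is mandatory."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar}; refusing to guess units")
    meta = json.loads(sidecar.read_text())
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        block = lines[i + 2:i + 2 + n]
        frames.append([list(map(float, ln.split()[1:4])) for ln in block])
        i += 2 + n
    coords = np.array(frames)
    if coords.shape[0] != meta["n_frames"] or coords.shape[1] != meta["n_beads"]:
        raise ValueError(f"trajectory {path} does not match its sidecar")
    return Trajectory(coords, dt_save_ps=float(meta["dt_save_ps"]),
                      metadata=meta.get("metadata", {}))


def write_pdb(conf: Conformation, topo: Topology, path) -> Path:
    """PDB-style snapshot: BB beads as CA records, SC beads as CB records."""
    path = Path(path)
    with open(path, "w") as fh:
        serial = 1
        for bead in topo.beads:
            x, y, z = conf.coords[bead.index]
            name = "CA" if bead.site == "BB" else "CB"
            chain_id = chr(ord("A") + bead.chain % 26)
            fh.write(
                f"ATOM  {serial:5d}  {name:<3s}{_three_letter(bead.residue):>4s}"
                f" {chain_id}{bead.resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n")
            serial += 1
        fh.write("END\n")
    return path


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _three_letter(code: str) -> str:
    return _THREE.get(code, "UNK")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_network(net, path) -> Path:
    """Persist a transition network (states, counts, lag) as JSON."""
    path = Path(path)
    payload = {
        "states": _jsonable(list(net.states)),
        "counts": net.counts.tolist(),
        "lag": net.lag,
        "kbt": net.kbt,
        "dt_frame_ps": net.dt_frame_ps,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_network(path):
    from .landscape import TransitionNetwork

    data = json.loads(Path(path).read_text())
    return TransitionNetwork(states=np.array(data["states"]),
                             counts=np.array(data["counts"]),
                             lag=int(data["lag"]), kbt=float(data["kbt"]),
                             dt_frame_ps=data.get("dt_frame_ps"))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    # simulation
    "sequence": str, "dt": float, "temperature": float, "viscosity": float,
    "hydro_radius": float, "hydrodynamics": str, "n_steps": int,
    "save_stride": int, "seed": int,
    # analysis thresholds
    "chi_c": float, "chi_tolerance": float, "pair_min_separation": int,
    "lag": int, "k_min": int, "k_max": int,
    # dimerization
    "separation": float, "restraint_stiffness": float, "hmm_states": int,
}

_CONFIG_DEFAULTS = {
    "dt": 0.01, "temperature": 298.0, "viscosity": 1.0e-3,
    "hydro_radius": 2.8817, "hydrodynamics": "off",
    "n_steps": 100_000, "save_stride": 100, "seed": 0,
    "chi_c": CHI_C_DEFAULT, "chi_tolerance": CHI_TOLERANCE_DEFAULT,
    "pair_min_separation": 3, "lag": 1, "k_min": 2, "k_max": 15,
    "separation": 12.0, "restraint_stiffness": 5.0, "hmm_states": 8,
}


@dataclass
class RunConfig:
    """Flat declarative run configuration with a stable hash."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(_CONFIG_DEFAULTS)
        for key, value in self.values.items():
            if key not in _CONFIG_SCHEMA:
                raise KeyError(f"unknown configuration key {key!r}")
            merged[key] = _CONFIG_SCHEMA[key](value)
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration must be a flat mapping")
        return cls(values=data)

    def with_overrides(self, **overrides) -> "RunConfig":
        values = {k: v for k, v in self.values.items()}
        values.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(values=values)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.values, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def integrator(self, **overrides):
        from .bd import IntegratorConfig

        kwargs = {
            "dt": self["dt"], "temperature": self["temperature"],
            "viscosity": self["viscosity"],
            "hydro_radius": self["hydro_radius"],
            "hydrodynamics": self["hydrodynamics"],
            "n_steps": self["n_steps"], "save_stride": self["save_stride"],
            "seed": self["seed"],
        }
        kwargs.update(overrides)
        return IntegratorConfig(**kwargs)


def write_manifest(out_dir, config: RunConfig, inputs: dict,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest next to a run's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.values,
        "config_hash": config.config_hash,
        "inputs": _jsonable(inputs),
        "code_version": __version__,
    }
    if extra:
        manifest.update(_jsonable(extra))
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
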