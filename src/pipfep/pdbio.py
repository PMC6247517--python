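"""File formats and run configuration.

Trajectories travel as multi-model PDB (MODEL/ENDMDL delimited) so every
fixture stays human-inspectable; parsing and writing go through gemmi.
Toy alchemical systems are described by a small YAML schema (documented in
:func:`dump_system_yaml`), window samples as CSV (see :mod:`pipfep.sampler`),
and reports as CSV plus full-precision JSON with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_TEMPERATURE
from .fep import DEFAULT_LAMBDAS
from .potentials import (
    AlchemicalSystem,
    AlchemicalTag,
    FlatBottomWell,
    HarmonicWell,
    InteractionParams,
)
from .traj_stats import ATOM_COLUMNS, _WATER_RESNAMES, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "RunConfig",
    "dump_system_yaml",
    "load_system_yaml",
    "write_reports",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name if atom.element else ""
    if not name or name == "X":
        # infer from the atom name: first alphabetic character
        for ch in atom.name:
            if ch.isalpha():
                return ch.upper()
        return "X"
    return name.upper()


def read_pdb(path) -> Trajectory:
    """Read a (possibly multi-model) fixed-column PDB into a Trajectory.

    ATOM and HETATM records are kept; MODEL/ENDMDL blocks become frames;
    elements are inferred from atom names when the element column is blank.
    All models must contain the same atoms in the same order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: contains no models")

    def model_atoms(model):
        rows = []
        xyz = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    elem = _element_of(atom)
                    rows.append(
                        {
                            "serial": atom.serial,
                            "name": atom.name,
                            "resname": residue.name,
                            "chain": chain.name,
                            "resid": residue.seqid.num,
                            "element": elem,
                            "is_heavy": elem != "H",
                            "is_water": residue.name in _WATER_RESNAMES,
                        }
                    )
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return rows, np.asarray(xyz, dtype=float)

    rows0, xyz0 = model_atoms(st[0])
    if not rows0:
        raise PDBParseError(f"{path}: first model contains no atoms")
    frames = [xyz0]
    for model in list(st)[1:]:
        rows, xyz = model_atoms(model)
        if len(rows) != len(rows0):
            raise PDBParseError(
                f"{path}: model atom counts differ ({len(rows)} vs {len(rows0)})"
            )
        frames.append(xyz)
    atoms = pd.DataFrame(rows0, columns=ATOM_COLUMNS)
    return Trajectory(coords=np.stack(frames), atoms=atoms)


def write_pdb(traj: Trajectory, path) -> Path:
    """Write a Trajectory as a multi-model fixed-column PDB."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st = gemmi.Structure()
    st.name = path.stem
    atoms = traj.atoms
    # group atom rows by chain, then by residue, preserving file order
    # (gemmi add_* methods copy, so build each level completely before adding)
    chain_order: list[str] = []
    chain_residues: dict[str, list[tuple[tuple, list[int]]]] = {}
    for i in range(traj.n_atoms):
        row = atoms.iloc[i]
        cname = str(row["chain"])
        key = (int(row["resid"]), str(row["resname"]))
        if cname not in chain_residues:
            chain_residues[cname] = []
            chain_order.append(cname)
        residues = chain_residues[cname]
        if not residues or residues[-1][0] != key:
            residues.append((key, []))
        residues[-1][1].append(i)
    for f in range(traj.n_frames):
        model = gemmi.Model(f + 1)
        for cname in chain_order:
            chain = gemmi.Chain(cname)
            for (resid, resname), atom_idx in chain_residues[cname]:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resid, " ")
                for i in atom_idx:
                    row = atoms.iloc[i]
                    res.het_flag = "H" if row["is_water"] else "A"
                    atom = gemmi.Atom()
                    atom.name = str(row["name"])
                    atom.serial = int(row["serial"])
                    atom.element = gemmi.Element(str(row["element"]).capitalize())
                    x, y, z = traj.coords[f, i]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    st.write_pdb(str(path), doc_opts)
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Protocol constants for one pipeline run; round-trips through YAML.

    Cutoffs: ligand contact 5 A, vdW truncation 12 A, first hydration shell
    3.5 A.  Pressure is recorded for provenance only (the toy sampler is
    isochoric).
    """

    schedule: tuple[float, ...] = DEFAULT_LAMBDAS
    temperature: float = DEFAULT_TEMPERATURE
    pressure_atm: float = 1.0
    n_equil: int = 4000
    n_prod: int = 200_000
    n_runs: int = 5
    step_size: float = 0.5
    seed: int = 0
    contact_cutoff: float = 5.0
    vdw_cutoff: float = 12.0
    hydration_shell: float = 3.5
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "vdw_cutoff", "hydration_shell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.schedule = tuple(float(v) for v in self.schedule)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "schedule": list(self.schedule),
            "temperature": self.temperature,
            "pressure_atm": self.pressure_atm,
            "n_equil": self.n_equil,
            "n_prod": self.n_prod,
            "n_runs": self.n_runs,
            "step_size": self.step_size,
            "seed": self.seed,
            "contact_cutoff": self.contact_cutoff,
            "vdw_cutoff": self.vdw_cutoff,
            "hydration_shell": self.hydration_shell,
            "out_dir": self.out_dir,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["schedule"] = tuple(payload.get("schedule", DEFAULT_LAMBDAS))
        return cls(**payload)

    def config_hash(self) -> str:
        canon = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# system specification files
# ---------------------------------------------------------------------------

_TAG_NAMES = {t.value: t for t in AlchemicalTag}


def dump_system_yaml(system: AlchemicalSystem, path) -> Path:
    """Write an alchemical system specification.

    Schema: top-level keys ``alpha``, ``cutoff``, ``box`` and ``atoms``; each
    atom lists label, xyz (A), epsilon (kcal/mol), sigma (A), charge (e),
    vdw_radius (A), tag (unperturbed/appearing/disappearing), mobile flag and
    wells.  Harmonic wells carry per-axis end-state stiffnesses ``k_initial``
    / ``k_final`` (kcal/mol/A^2) and a center; flat-bottom wells a single
    stiffness, radius and center.
    """
    atoms = []
    for i in range(system.n_atoms):
        p = system.params[i]
        wells = []
        for w in system.wells[i]:
            if isinstance(w, HarmonicWell):
                wells.append(
                    {
                        "type": "harmonic",
                        "k_initial": list(w.k_initial),
                        "k_final": list(w.k_final),
                        "center": list(w.center),
                    }
                )
            else:
                wells.append(
                    {
                        "type": "flat_bottom",
                        "k": w.k,
                        "radius": w.radius,
                        "center": list(w.center),
                    }
                )
        atoms.append(
            {
                "label": system.labels[i],
                "xyz": [float(v) for v in system.coordinates[i]],
                "epsilon": p.epsilon,
                "sigma": p.sigma,
                "charge": p.charge,
                "vdw_radius": p.vdw_radius,
                "tag": system.tags[i].value,
                "mobile": bool(system.mobile[i]),
                "wells": wells,
            }
        )
    payload = {
        "alpha": system.alpha,
        "cutoff": system.cutoff,
        "box": None if system.box is None else [float(v) for v in system.box],
        "atoms": atoms,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_system_yaml(path) -> AlchemicalSystem:
    """Read an alchemical system specification written by dump_system_yaml."""
    payload = yaml.safe_load(Path(path).read_text())
    coords, params, tags, wells, mobile, labels = [], [], [], [], [], []
    for entry in payload["atoms"]:
        coords.append(entry["xyz"])
        params.append(
            InteractionParams(
                epsilon=float(entry["epsilon"]),
                sigma=float(entry["sigma"]),
                charge=float(entry.get("charge", 0.0)),
                vdw_radius=float(entry.get("vdw_radius", 1.7)),
            )
        )
        tag = entry.get("tag", "unperturbed")
        if tag not in _TAG_NAMES:
            raise ValueError(f"unknown alchemical tag {tag!r}")
        tags.append(_TAG_NAMES[tag])
        atom_wells = []
        for w in entry.get("wells", []):
            if w["type"] == "harmonic":
                atom_wells.append(
                    HarmonicWell(
                        tuple(w["k_initial"]), tuple(w["k_final"]), tuple(w["center"])
                    )
                )
            elif w["type"] == "flat_bottom":
                atom_wells.append(
                    FlatBottomWell(float(w["k"]), float(w["radius"]), tuple(w["center"]))
                )
            else:
                raise ValueError(f"unknown well type {w['type']!r}")
        wells.append(atom_wells)
        mobile.append(bool(entry.get("mobile", True)))
        labels.append(str(entry.get("label", f"X{len(labels)}")))
    return AlchemicalSystem(
        coordinates=np.asarray(coords, dtype=float),
        params=params,
        tags=tags,
        wells=wells,
        mobile=mobile,
        box=payload.get("box"),
        cutoff=payload.get("cutoff"),
        alpha=float(payload.get("alpha", 0.5)),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_reports(results: dict, out_dir, config: Optional[RunConfig] = None) -> dict:
    """Write named results deterministically; returns {name: path}.

    DataFrames become CSV (header row always present), everything else
    full-precision JSON.  A run manifest recording the config hash, seed and
    package version accompanies the outputs; no timestamps enter any file.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in sorted(results):
        value = results[name]
        if isinstance(value, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            value.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(value, indent=2, sort_keys=True, default=float) + "\n")
        written[name] = p
    manifest = {
        "package": "pipfep",
        "version": __version__,
        "outputs": {k: str(v.name) for k, v in written.items()},
        "seed": None if config is None else config.seed,
        "config_hash": None if config is None else config.config_hash(),
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = mp
    return written
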