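"""Trajectory statistics: contacts, hydration, salt bridges, pore radii.

The statistics here are the ones used to rationalise phosphoinositide
specificity on a tetrameric channel:

* residue-specific atomic contact ratios q_r -- for each heavy atom of a
  residue, the fraction of (frame, subunit) pairs in which it lies within a
  cutoff (default 5 A, boundary inclusive) of any ligand heavy atom; q_r is
  the sum of those per-atom probabilities, so 0 <= q_r <= heavy-atom count;
* contact-change tables dq = q_MUT - q_WT with positive/negative aggregates
  and a highlight criterion |dq| > 0.5;
* first-hydration-shell water counts (water oxygen within a shell radius of
  any solute heavy atom) and the free-minus-bound desolvation difference;
* minimum heavy-atom distances (salt-bridge geometry);
* pore-radius profiles along the membrane normal (z), via a per-slice
  inscribed-sphere search on a bounded (x, y) grid;
* RMSD/RMSF plumbing with optimal rigid superposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "Selection",
    "ContactTable",
    "ContactDiff",
    "PoreProfile",
    "HydrationResult",
    "BONDI_RADII",
    "atomic_contact_probability",
    "residue_contact_ratio",
    "contact_table",
    "contact_diff",
    "hydration_count",
    "desolvation_count",
    "min_heavy_distance",
    "pore_profile",
    "rmsd_rmsf",
]

#: Bondi van der Waals radii, Angstrom, used for pore profiling.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
}

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "TIP", "SPC"}

ATOM_COLUMNS = ["serial", "name", "resname", "chain", "resid", "element", "is_heavy", "is_water"]


@dataclass
class Trajectory:
    """Frames of coordinates plus per-atom metadata.

    coords : (n_frames, n_atoms, 3) float array, Angstrom
    atoms : DataFrame with columns serial, name, resname, chain, resid,
        element, is_heavy, is_water (one row per atom, same order as coords)
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atoms table lacks columns: {sorted(missing)}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atoms table and coordinate frames disagree on atom count")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_chains(self) -> int:
        return self.atoms["chain"].nunique()

    def select(self, sel: "Selection") -> np.ndarray:
        return sel.indices(self.atoms)


def _as_set(value) -> Optional[set]:
    if value is None:
        return None
    if isinstance(value, (str, int)):
        return {value}
    return set(value)


@dataclass(frozen=True)
class Selection:
    """Exact-match atom selection: chain / resid / resname / atom name / element.

    Each field may be a single value or a collection; None matches everything.
    ``heavy_only`` restricts to non-hydrogen atoms.
    """

    chain: Union[str, Sequence[str], None] = None
    resid: Union[int, Sequence[int], None] = None
    resname: Union[str, Sequence[str], None] = None
    name: Union[str, Sequence[str], None] = None
    element: Union[str, Sequence[str], None] = None
    heavy_only: bool = False

    def indices(self, atoms: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        for col, value in (
            ("chain", _as_set(self.chain)),
            ("resid", _as_set(self.resid)),
            ("resname", _as_set(self.resname)),
            ("name", _as_set(self.name)),
            ("element", _as_set(self.element)),
        ):
            if value is not None:
                mask &= atoms[col].isin(value).to_numpy()
        if self.heavy_only:
            mask &= atoms["is_heavy"].to_numpy()
        return np.flatnonzero(mask)


def _heavy_indices(traj: Trajectory, sel: Selection, what: str) -> np.ndarray:
    idx = traj.select(sel)
    if idx.size == 0:
        raise ValueError(f"{what} selection matches no atoms")
    heavy = idx[traj.atoms["is_heavy"].to_numpy()[idx]]
    if heavy.size == 0:
        raise ValueError(f"{what} selection contains no heavy atoms")
    return heavy


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _contact_matrix(
    traj: Trajectory, atom_idx: np.ndarray, ligand_idx: np.ndarray, cutoff: float
) -> np.ndarray:
    """Boolean (n_frames, len(atom_idx)): within cutoff of ANY ligand atom."""
    out = np.empty((traj.n_frames, atom_idx.size), dtype=bool)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, atom_idx], traj.coords[f, ligand_idx])
        out[f] = (d <= cutoff).any(axis=1)
    return out


def atomic_contact_probability(
    traj: Trajectory,
    atom: Selection,
    ligand: Selection,
    cutoff: float = 5.0,
) -> float:
    """Fraction of (frame, subunit copy) pairs with the atom near the ligand.

    The atom selection typically matches one equivalent atom per subunit
    chain; the contact criterion is distance <= cutoff to ANY ligand heavy
    atom (boundary inclusive), and the probability averages over frames and
    all selected copies.
    """
    atom_idx = traj.select(atom)
    if atom_idx.size == 0:
        raise ValueError("atom selection matches no atoms")
    ligand_idx = _heavy_indices(traj, ligand, "ligand")
    return float(_contact_matrix(traj, atom_idx, ligand_idx, cutoff).mean())


def residue_contact_ratio(
    traj: Trajectory,
    residue: Selection,
    ligand: Selection,
    cutoff: float = 5.0,
) -> float:
    """Contact ratio q_r: summed heavy-atom contact probabilities of a residue.

    Equivalent copies of the residue across subunit chains are averaged (per
    frame and chain) before the per-atom probabilities are summed, so
    0 <= q_r <= number of heavy atoms in one residue copy.
    """
    res_idx = _heavy_indices(traj, residue, "residue")
    ligand_idx = _heavy_indices(traj, ligand, "ligand")
    n_copies = max(1, traj.atoms.loc[res_idx, "chain"].nunique())
    contacts = _contact_matrix(traj, res_idx, ligand_idx, cutoff)
    # total contacts / (frames * chain copies) == sum over atom names of the
    # per-copy-averaged probabilities
    return float(contacts.sum() / (traj.n_frames * n_copies))


@dataclass
class ContactTable:
    """Per-residue contact ratios q_r at one cutoff."""

    entries: dict[str, float]
    cutoff: float = 5.0
    ligand_label: str = ""

    def __post_init__(self) -> None:
        for r, q in self.entries.items():
            if q < 0:
                raise ValueError(f"contact ratio of {r} is negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": list(self.entries), "q": list(self.entries.values())}
        )


def contact_table(
    traj: Trajectory,
    residues: Mapping[str, Selection],
    ligand: Selection,
    cutoff: float = 5.0,
    ligand_label: str = "",
) -> ContactTable:
    """Compute q_r for a labelled set of residue selections."""
    entries = {
        label: residue_contact_ratio(traj, sel, ligand, cutoff)
        for label, sel in residues.items()
    }
    return ContactTable(entries=entries, cutoff=cutoff, ligand_label=ligand_label)


@dataclass
class ContactDiff:
    """Per-residue contact changes dq = q_MUT - q_WT with aggregates.

    dq_all = dq_pos + dq_neg exactly; ``highlighted`` lists residues with
    |dq| above the threshold (default 0.5).
    """

    deltas: dict[str, float]
    threshold: float = 0.5

    @property
    def dq_pos(self) -> float:
        return float(sum(v for v in self.deltas.values() if v > 0))

    @property
    def dq_neg(self) -> float:
        return float(sum(v for v in self.deltas.values() if v < 0))

    @property
    def dq_all(self) -> float:
        return self.dq_pos + self.dq_neg

    @property
    def highlighted(self) -> list[str]:
        return [r for r, v in self.deltas.items() if abs(v) > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": list(self.deltas),
                "dq": list(self.deltas.values()),
                "highlighted": [abs(v) > self.threshold for v in self.deltas.values()],
            }
        )


def contact_diff(
    wt: ContactTable, mut: ContactTable, threshold: float = 0.5
) -> ContactDiff:
    """Difference table between mutant and wild-type contact tables.

    Residues present in only one table are treated as q = 0 in the other.
    The tables must share their contact cutoff.
    """
    if wt.cutoff != mut.cutoff:
        raise ValueError(
            f"contact tables use different cutoffs ({wt.cutoff} vs {mut.cutoff})"
        )
    residues = list(dict.fromkeys(list(wt.entries) + list(mut.entries)))
    deltas = {
        r: mut.entries.get(r, 0.0) - wt.entries.get(r, 0.0) for r in residues
    }
    return ContactDiff(deltas=deltas, threshold=threshold)


# ---------------------------------------------------------------------------
# hydration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HydrationResult:
    """Mean and per-frame first-shell water counts."""

    mean: float
    per_frame: np.ndarray
    shell_radius: float


def hydration_count(
    traj: Trajectory,
    solute: Selection,
    shell_radius: float = 3.5,
) -> HydrationResult:
    """Waters whose oxygen lies within the shell of any solute heavy atom.

    Boundary inclusive (distance == shell_radius counts).  Returns the mean
    over frames together with the per-frame series; a trajectory without
    waters yields zero with a logged warning.
    """
    if shell_radius <= 0:
        raise ValueError("shell_radius must be > 0")
    solute_idx = _heavy_indices(traj, solute, "solute")
    atoms = traj.atoms
    water_o = np.flatnonzero(
        atoms["is_water"].to_numpy() & (atoms["element"].to_numpy() == "O")
    )
    if water_o.size == 0:
        logger.warning("trajectory contains no water molecules; hydration count is 0")
        return HydrationResult(0.0, np.zeros(traj.n_frames), shell_radius)
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, water_o], traj.coords[f, solute_idx])
        counts[f] = int((d.min(axis=1) <= shell_radius).sum())
    return HydrationResult(float(counts.mean()), counts, shell_radius)


def desolvation_count(n_free: float, n_bound: float) -> float:
    """Waters lost from the first shell upon binding: n_free - n_bound."""
    if n_free < 0 or n_bound < 0:
        raise ValueError("shell counts must be >= 0")
    return n_free - n_bound


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def min_heavy_distance(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    frame: int = 0,
) -> float:
    """Minimum pairwise heavy-atom distance between two selections, one frame.

    Hydrogens are excluded even if the selections match them.
    """
    idx_a = _heavy_indices(traj, sel_a, "first")
    idx_b = _heavy_indices(traj, sel_b, "second")
    d = cdist(traj.coords[frame, idx_a], traj.coords[frame, idx_b])
    return float(d.min())


# ---------------------------------------------------------------------------
# pore profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoreProfile:
    """Pore radii along the channel (z) axis."""

    z: np.ndarray
    radius: np.ndarray
    max_radius: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "radius": self.radius})


def _atom_radii(atoms: pd.DataFrame, radii) -> np.ndarray:
    if radii is None:
        table = BONDI_RADII
        return np.array(
            [table.get(str(e).upper(), 1.7) for e in atoms["element"]], dtype=float
        )
    if isinstance(radii, Mapping):
        return np.array(
            [radii.get(str(e).upper(), 1.7) for e in atoms["element"]], dtype=float
        )
    arr = np.asarray(radii, dtype=float)
    if arr.shape != (len(atoms),):
        raise ValueError("per-atom radii must match the atom count")
    return arr


def pore_profile(
    traj: Trajectory,
    frame: int = 0,
    z_range: Optional[tuple[float, float]] = None,
    z_step: float = 0.5,
    axis_xy: Optional[tuple[float, float]] = None,
    search_radius: float = 5.0,
    grid_step: float = 0.2,
    max_radius: float = 15.0,
    radii=None,
    selection: Optional[Selection] = None,
) -> PoreProfile:
    """Largest inscribed-probe radius in each z slice along the pore axis.

    At each z, probe centers (x, y) are searched on a bounded square grid
    around the pore axis (default: the structure's x/y center of geometry);
    the radius at a center is the clearance min_a(|p - a| - vdw_a) over all
    atoms, and the slice radius is the maximum clearance, clipped to
    [0, max_radius].  Slices with no nearby atoms report the cap.
    """
    if traj.n_atoms == 0:
        raise ValueError("structure has no atoms")
    atoms = traj.atoms
    coords = traj.coords[frame]
    if selection is not None:
        idx = traj.select(selection)
        if idx.size == 0:
            raise ValueError("pore selection matches no atoms")
        atoms = atoms.iloc[idx]
        coords = coords[idx]
    r_atom = _atom_radii(atoms, radii)
    if axis_xy is None:
        axis_xy = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    if z_range is None:
        z_range = (float(coords[:, 2].min()), float(coords[:, 2].max()))
    z_lo, z_hi = z_range
    n_slices = max(1, int(round((z_hi - z_lo) / z_step)) + 1)
    z_values = z_lo + z_step * np.arange(n_slices)
    # bounded (x, y) probe grid, guaranteed to contain the axis point
    ng = int(math.ceil(search_radius / grid_step))
    offsets = grid_step * np.arange(-ng, ng + 1)
    gx, gy = np.meshgrid(axis_xy[0] + offsets, axis_xy[1] + offsets)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    keep = (
        np.hypot(grid[:, 0] - axis_xy[0], grid[:, 1] - axis_xy[1]) <= search_radius + 1e-9
    )
    grid = grid[keep]
    radius_out = np.empty(n_slices)
    for k, z in enumerate(z_values):
        # clearance of every grid point against every atom (3-D distance)
        dxy2 = cdist(grid, coords[:, :2], "sqeuclidean")
        dz2 = (coords[:, 2] - z) ** 2
        clearance = np.sqrt(dxy2 + dz2[None, :]) - r_atom[None, :]
        radius_out[k] = float(np.clip(clearance.min(axis=1).max(), 0.0, max_radius))
    return PoreProfile(z=z_values, radius=radius_out, max_radius=max_radius)


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def _superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition (Kabsch) of one frame onto a reference."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def rmsd_rmsf(
    traj: Trajectory,
    selection: Optional[Selection] = None,
    reference_frame: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-frame RMSD (after superposition) and per-residue RMSF.

    RMSD is against the reference frame after optimal rigid superposition of
    the selected atoms; RMSF is the per-atom fluctuation about the mean
    superposed structure, averaged within each (chain, resid) residue.
    """
    idx = (
        traj.select(selection)
        if selection is not None
        else np.arange(traj.n_atoms)
    )
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    ref = traj.coords[reference_frame, idx]
    superposed = np.empty((traj.n_frames, idx.size, 3))
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sup = _superpose(traj.coords[f, idx], ref)
        superposed[f] = sup
        rmsd[f] = math.sqrt(float(((sup - ref) ** 2).sum(axis=1).mean()))
    mean_structure = superposed.mean(axis=0)
    per_atom = np.sqrt(((superposed - mean_structure) ** 2).sum(axis=2).mean(axis=0))
    meta = traj.atoms.iloc[idx]
    rmsf_df = (
        pd.DataFrame(
            {
                "chain": meta["chain"].to_numpy(),
                "resid": meta["resid"].to_numpy(),
                "rmsf": per_atom,
            }
        )
        .groupby(["chain", "resid"], as_index=False)["rmsf"]
        .mean()
    )
    return rmsd, rmsf_df
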