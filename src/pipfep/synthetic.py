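"""Synthetic inputs with known ground truth.

Every stage of the pipeline gets a generator whose output carries its own
reference answer:

* :func:`gen_harmonic_alchemy` -- a particle whose harmonic well stiffness
  morphs k1 -> k2 under lambda; the exact free energy is the closed-form
  partition-function ratio (dims * kT/2) ln(k2/k1);
* :func:`gen_gaussian_work` -- i.i.d. Gaussian forward differences, for which
  the exponential average has the closed form mu - sigma^2 / (2 kT);
* :func:`gen_toy_binding` -- a bound/free pair of few-particle systems whose
  relative binding free energy is computed by low-dimensional numerical
  quadrature of both partition-function ratios (:func:`quadrature_delta_g`);
* :func:`gen_trajectory` -- a 4-chain multi-model trajectory in which tagged
  atoms sit inside the ligand contact shell with prescribed Bernoulli
  probabilities and a fixed number of waters occupies the hydration shell;
* :func:`gen_cylinder_channel` -- stacked atom rings whose pore radius at
  each ring is ring_radius - vdw_radius by construction.

All randomness flows from a single integer seed; fixed seed means
byte-identical outputs.  Generators can write their files (PDB / YAML / CSV)
plus a JSON ground-truth sidecar next to them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kT
from .potentials import (
    AlchemicalSystem,
    AlchemicalTag,
    FlatBottomWell,
    HarmonicWell,
    InteractionParams,
    compile_window,
)
from .sampler import WindowSamples
from .traj_stats import ATOM_COLUMNS, Trajectory

__all__ = [
    "HarmonicAlchemy",
    "ToyBinding",
    "ResidueContactSpec",
    "gen_harmonic_alchemy",
    "gen_gaussian_work",
    "gen_toy_binding",
    "gen_trajectory",
    "gen_cylinder_channel",
    "quadrature_delta_g",
]


def _write_sidecar(prefix: Path, truth: dict) -> Path:
    sidecar = prefix.with_suffix(".truth.json")
    sidecar.parent.mkdir(parents=True, exist_ok=True)
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True, default=float) + "\n")
    return sidecar


# ---------------------------------------------------------------------------
# harmonic alchemy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicAlchemy:
    """A harmonic-well mutation with its analytic free energy."""

    system: AlchemicalSystem
    delta_g: float
    k1: float
    k2: float
    dims: int
    temperature: float

    def reversed(self) -> "HarmonicAlchemy":
        """The same mutation run in the opposite direction (k2 -> k1)."""
        return gen_harmonic_alchemy(self.k2, self.k1, self.dims, self.temperature)


def gen_harmonic_alchemy(
    k1: float = 1.0,
    k2: float = 4.0,
    dims: int = 3,
    temperature: float = DEFAULT_TEMPERATURE,
) -> HarmonicAlchemy:
    """Single particle whose well stiffness morphs k1 -> k2 along lambda.

    The stiffness interpolates linearly on the first ``dims`` axes; remaining
    axes keep a lambda-independent stiffness k1 so the particle stays bounded
    while contributing nothing to the perturbation.  Analytic truth:
    dG = (dims * kT / 2) ln(k2 / k1).
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("force constants must be positive")
    if dims not in (1, 2, 3):
        raise ValueError("dims must be 1, 2 or 3")
    k_i = tuple(k1 for _ in range(3))
    k_f = tuple(k2 if ax < dims else k1 for ax in range(3))
    system = AlchemicalSystem(
        coordinates=np.zeros((1, 3)),
        params=[InteractionParams(epsilon=0.0, sigma=1.0, charge=0.0)],
        tags=[AlchemicalTag.UNPERTURBED],
        wells=[[HarmonicWell(k_i, k_f, (0.0, 0.0, 0.0))]],
        labels=["HP"],
    )
    delta_g = dims * kT(temperature) / 2.0 * math.log(k2 / k1)
    return HarmonicAlchemy(system, delta_g, k1, k2, dims, temperature)


# ---------------------------------------------------------------------------
# Gaussian work samples
# ---------------------------------------------------------------------------


def gen_gaussian_work(
    mu: float,
    sigma: float,
    n: int,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[WindowSamples, float]:
    """I.i.d. normal forward differences with the closed-form reference.

    For dV ~ N(mu, sigma^2) the exponential average gives exactly
    dG = mu - sigma^2 / (2 kT).  The samples are stored in the external
    component (no pair interactions are implied).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dv = mu + sigma * rng.standard_normal(n)
    zeros = np.zeros(n)
    ws = WindowSamples(
        lam=0.0,
        lam_next=1.0,
        dV_total=dv,
        dV_elec=zeros,
        dV_vdw=zeros.copy(),
        dV_ext=dv.copy(),
        run_id=0,
    )
    reference = mu - sigma**2 / (2.0 * kT(temperature))
    return ws, reference


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------

_QUAD_MAX_DIMS = 6


def _check_separable(system: AlchemicalSystem) -> None:
    mobile = set(system.mobile_indices)
    if 3 * len(mobile) > _QUAD_MAX_DIMS:
        raise ValueError(
            f"quadrature oracle limited to {_QUAD_MAX_DIMS} dimensions "
            f"({len(mobile)} mobile atoms requested)"
        )
    if system.box is not None:
        raise ValueError("quadrature oracle does not support periodic boxes")
    for lam in (0.0, 1.0):
        ctx = compile_window(system, lam)
        for (i, j, *_rest) in ctx.pairs:
            if i in mobile and j in mobile:
                raise ValueError(
                    "quadrature oracle requires mobile atoms not to interact "
                    f"with each other (atoms {i}, {j} do)"
                )
    for i in range(system.n_atoms):
        if i in mobile:
            continue
        if system.tags[i] is not AlchemicalTag.UNPERTURBED:
            raise ValueError("frozen atoms must be unperturbed for the oracle")
        for w in system.wells[i]:
            if isinstance(w, HarmonicWell) and w.k_initial != w.k_final:
                raise ValueError("frozen atoms must have lambda-independent wells")


def _atom_bounds(system: AlchemicalSystem, a: int, temperature: float) -> tuple[np.ndarray, np.ndarray]:
    """Bounding box outside which the atom's Boltzmann weight is negligible."""
    pad_energy = 40.0 * kT(temperature)  # e^-40 ~ 4e-18
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    found = False
    for w in system.wells[a]:
        if isinstance(w, FlatBottomWell) and w.k > 0:
            reach = w.radius + math.sqrt(2.0 * pad_energy / w.k)
            c = np.asarray(w.center)
            lo = np.minimum(lo, c - reach)
            hi = np.maximum(hi, c + reach)
            found = True
        elif isinstance(w, HarmonicWell):
            kmin = min(min(w.k_initial), min(w.k_final))
            if kmin > 0:
                reach = math.sqrt(2.0 * pad_energy / kmin)
                c = np.asarray(w.center)
                lo = np.minimum(lo, c - reach)
                hi = np.maximum(hi, c + reach)
                found = True
    if not found:
        raise ValueError(f"mobile atom {a} has no confining well; oracle needs one")
    return lo, hi


def _atom_log_z(
    system: AlchemicalSystem,
    a: int,
    lam: float,
    temperature: float,
    n_nodes: int,
) -> float:
    """log of the one-atom configurational integral at fixed lambda.

    Tensor Gauss-Legendre quadrature over the atom's bounding box; all other
    atoms sit at their reference coordinates (they are frozen by contract).
    """
    ctx = compile_window(system, lam)
    pair_terms, harm_terms, flat_terms = ctx.atom_terms(a)
    lo, hi = _atom_bounds(system, a, temperature)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    axes = []
    logw_axes = []
    for d in range(3):
        half = 0.5 * (hi[d] - lo[d])
        mid = 0.5 * (hi[d] + lo[d])
        axes.append(mid + half * nodes)
        logw_axes.append(np.log(weights * half))
    beta = 1.0 / kT(temperature)
    coords = system.coordinates
    Y, Z = np.meshgrid(axes[1], axes[2], indexing="ij")
    logw_yz = (logw_axes[1][:, None] + logw_axes[2][None, :]).ravel()
    slab_logs = np.empty(n_nodes)
    pts = np.empty((Y.size, 3))
    pts[:, 1] = Y.ravel()
    pts[:, 2] = Z.ravel()
    for ix, x in enumerate(axes[0]):  # one x-slab at a time to bound memory
        pts[:, 0] = x
        energy = np.zeros(len(pts))
        for (j, qq, eps4, shift, sig6, cutoff2) in pair_terms:
            d = pts - coords[j]
            r2 = np.einsum("ij,ij->i", d, d)
            if qq != 0.0:
                energy += qq / np.sqrt(r2)
            if eps4 != 0.0:
                s = sig6 / (shift + r2 * r2 * r2)
                term = eps4 * (s * s - s)
                if cutoff2 is not None:
                    term = np.where(r2 <= cutoff2, term, 0.0)
                energy += term
        for (kx, ky, kz, cx, cy, cz) in harm_terms:
            energy += 0.5 * (
                kx * (pts[:, 0] - cx) ** 2
                + ky * (pts[:, 1] - cy) ** 2
                + kz * (pts[:, 2] - cz) ** 2
            )
        for (k, radius, cx, cy, cz) in flat_terms:
            d = np.linalg.norm(pts - np.array([cx, cy, cz]), axis=1)
            energy += 0.5 * k * np.maximum(0.0, d - radius) ** 2
        slab_logs[ix] = logsumexp(-beta * energy + logw_yz) + logw_axes[0][ix]
    return float(logsumexp(slab_logs))


def quadrature_delta_g(
    system: AlchemicalSystem,
    lam0: float = 0.0,
    lam1: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    n_nodes: int = 128,
    rtol: float = 1e-6,
) -> float:
    """Brute-force free energy -kT ln(Z(lam1)/Z(lam0)) by quadrature.

    Requires mobile atoms that do not interact with each other (the integral
    then factorizes into per-atom 3-D integrals) and at most 6 integration
    dimensions.  The result is cross-checked against a grid with doubled
    resolution and must agree to ``rtol`` relative.
    """
    _check_separable(system)

    def total(n: int) -> float:
        acc = 0.0
        for a in system.mobile_indices:
            acc += _atom_log_z(system, a, lam1, temperature, n) - _atom_log_z(
                system, a, lam0, temperature, n
            )
        return -kT(temperature) * acc

    coarse = total(n_nodes)
    fine = total(2 * n_nodes)
    scale = max(1.0, abs(fine))
    if abs(fine - coarse) > rtol * scale:
        raise RuntimeError(
            f"quadrature did not converge: {coarse} vs {fine} at n={n_nodes}"
        )
    return fine


# ---------------------------------------------------------------------------
# toy binding systems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyBinding:
    """Bound/free system pair with quadrature ground truth (kcal/mol)."""

    bound: AlchemicalSystem
    free: AlchemicalSystem
    dg_bound: float
    dg_free: float
    ddg: float
    parameters: dict


def gen_toy_binding(
    charge_old: float = -0.35,
    charge_new: float = -0.30,
    site_charge: float = 0.30,
    site2_charge: float = 0.12,
    site_eps: float = 0.15,
    anchor_charge: float = 0.15,
    confinement_k: float = 300.0,
    confinement_radius: float = 0.75,
    temperature: float = DEFAULT_TEMPERATURE,
    n_nodes: int = 128,
    compute_oracle: bool = True,
) -> ToyBinding:
    """Desk-scale stand-in for a ligand-mutation thermodynamic cycle.

    The "ligand" is a charged group being mutated: a disappearing atom (the
    old phosphate position) and an appearing atom (the new position), both
    held near their positions by stiff flat-bottom wells -- the stand-in for
    the bonded terms that keep a real phosphate on its ring carbon, which also
    keeps oppositely charged atoms out of the Coulomb singularity at
    intermediate coupling -- and interacting with a fixed anchor atom (the
    ligand scaffold).  The bound system adds two frozen cationic site
    atoms (salt-bridge partners, one near each phosphate position); the free
    system is the ligand alone.  Ground-truth leg free energies come from
    :func:`quadrature_delta_g`, and ddG = dG_bound - dG_free.

    The old position sits close to the stronger site charge, the new one near
    the weaker; with the defaults the mutation therefore weakens binding
    (ddG > 0), mirroring a phosphate moved off its salt-bridge partners.
    """
    params = dict(
        charge_old=charge_old,
        charge_new=charge_new,
        site_charge=site_charge,
        site2_charge=site2_charge,
        site_eps=site_eps,
        anchor_charge=anchor_charge,
        confinement_k=confinement_k,
        confinement_radius=confinement_radius,
        temperature=temperature,
    )
    lig_eps, lig_sigma = 0.2, 3.0
    site_sigma = 3.2

    def ligand_atoms():
        coords = [
            [0.0, 0.0, 0.0],  # anchor (frozen scaffold)
            [3.0, 0.0, 0.0],  # old phosphate, disappearing
            [-2.5, 0.0, 0.0],  # new phosphate, appearing (off the mirror axis)
        ]
        atom_params = [
            InteractionParams(0.1, 3.5, anchor_charge),
            InteractionParams(lig_eps, lig_sigma, charge_old),
            InteractionParams(lig_eps, lig_sigma, charge_new),
        ]
        tags = [
            AlchemicalTag.UNPERTURBED,
            AlchemicalTag.DISAPPEARING,
            AlchemicalTag.APPEARING,
        ]
        wells = [
            [],
            [FlatBottomWell(confinement_k, confinement_radius, (3.0, 0.0, 0.0))],
            [FlatBottomWell(confinement_k, confinement_radius, (-2.5, 0.0, 0.0))],
        ]
        mobile = [False, True, True]
        labels = ["ANC", "OLD", "NEW"]
        return coords, atom_params, tags, wells, mobile, labels

    coords, atom_params, tags, wells, mobile, labels = ligand_atoms()
    free = AlchemicalSystem(
        coordinates=np.asarray(coords),
        params=atom_params,
        tags=tags,
        wells=wells,
        mobile=mobile,
        labels=labels,
    )

    coords_b, params_b, tags_b, wells_b, mobile_b, labels_b = ligand_atoms()
    coords_b += [[5.5, 0.0, 0.0], [-5.0, 2.0, 0.0]]
    params_b += [
        InteractionParams(site_eps, site_sigma, site_charge),
        InteractionParams(site_eps, site_sigma, site2_charge),
    ]
    tags_b += [AlchemicalTag.UNPERTURBED, AlchemicalTag.UNPERTURBED]
    wells_b += [[], []]
    mobile_b += [False, False]
    labels_b += ["ST1", "ST2"]
    bound = AlchemicalSystem(
        coordinates=np.asarray(coords_b),
        params=params_b,
        tags=tags_b,
        wells=wells_b,
        mobile=mobile_b,
        labels=labels_b,
    )

    if compute_oracle:
        dg_bound = quadrature_delta_g(bound, temperature=temperature, n_nodes=n_nodes)
        dg_free = quadrature_delta_g(free, temperature=temperature, n_nodes=n_nodes)
    else:
        dg_bound = dg_free = math.nan
    return ToyBinding(
        bound=bound,
        free=free,
        dg_bound=dg_bound,
        dg_free=dg_free,
        ddg=dg_bound - dg_free,
        parameters=params,
    )


# ---------------------------------------------------------------------------
# synthetic trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueContactSpec:
    """Prescribed per-heavy-atom contact probabilities for one residue."""

    resname: str
    resid: int
    atom_probs: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, p in self.atom_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability of {name} outside [0, 1]: {p}")

    @property
    def label(self) -> str:
        return f"{self.resname}{self.resid}"

    @property
    def q(self) -> float:
        return float(sum(self.atom_probs.values()))


#: A small Kir-flavoured default contact specification.
DEFAULT_CONTACT_SPEC: tuple[ResidueContactSpec, ...] = (
    ResidueContactSpec("ARG", 78, {"CZ": 0.9, "NH1": 0.7, "NH2": 0.6}),
    ResidueContactSpec("LYS", 189, {"NZ": 0.5, "CE": 0.25}),
    ResidueContactSpec("SER", 87, {"OG": 0.1}),
)

_ELEMENT_FROM_NAME = {"C": "C", "N": "N", "O": "O", "P": "P", "S": "S", "H": "H"}


def _element_from_name(name: str) -> str:
    return _ELEMENT_FROM_NAME.get(name[0].upper(), "C")


def gen_trajectory(
    contact_spec: Sequence[ResidueContactSpec] = DEFAULT_CONTACT_SPEC,
    n_chains: int = 4,
    n_frames: int = 200,
    n_waters_in: int = 7,
    n_waters_out: int = 5,
    shell_radius: float = 3.5,
    contact_cutoff: float = 5.0,
    seed: int = 0,
    out_prefix=None,
) -> tuple[Trajectory, dict]:
    """Multi-chain trajectory with prescribed contact and hydration structure.

    Each chain carries a 4-atom ligand (resname PIP) and one copy of every
    residue in ``contact_spec``; per frame and chain, each tagged heavy atom
    sits at its in-shell position (3.2 A from a ligand atom) with its
    prescribed Bernoulli probability, otherwise at an out-of-shell position
    (15 A away).  Each residue also carries one hydrogen that always sits in
    the shell, to exercise heavy-atom filtering.  Waters (3-site, chain W)
    are placed so that exactly ``n_waters_in`` oxygens lie inside the
    hydration shell of chain A's ligand every frame and ``n_waters_out``
    well outside.

    Returns the trajectory and a ground-truth dict; with ``out_prefix`` the
    multi-model PDB and a JSON sidecar are written.
    """
    if n_chains < 1 or n_frames < 1:
        raise ValueError("need at least one chain and one frame")
    if shell_radius <= 2.6:
        raise ValueError("shell_radius too small to place water oxygens")
    n_lig_heavy = 4
    capacity = int(0.5 * n_lig_heavy * (4.0 / 3.0) * math.pi * shell_radius**3 / 29.9)
    if n_waters_in > capacity:
        raise ValueError(
            f"cannot place {n_waters_in} waters in a shell of radius "
            f"{shell_radius} A (capacity ~{capacity})"
        )
    rng = np.random.default_rng(seed)
    chain_names = [chr(ord("A") + c) for c in range(n_chains)]
    chain_offset = 140.0

    rows = []
    template = []  # static coordinates (ligand atoms); dynamic filled per frame
    serial = 0

    def add_atom(name, resname, chain, resid, element, xyz):
        nonlocal serial
        serial += 1
        rows.append(
            {
                "serial": serial,
                "name": name,
                "resname": resname,
                "chain": chain,
                "resid": resid,
                "element": element,
                "is_heavy": element != "H",
                "is_water": resname == "HOH",
            }
        )
        template.append(list(xyz))
        return len(template) - 1

    lig_offsets = np.array(
        [[0.0, 0.0, 0.0], [1.6, 0.0, 0.0], [0.0, 1.6, 0.0], [0.0, 0.0, 1.6]]
    )
    # per (chain, spec-atom): index, in position, out position, probability
    tagged = []
    for c, cname in enumerate(chain_names):
        origin = np.array([chain_offset * c, 0.0, 0.0])
        for k, off in enumerate(lig_offsets):
            add_atom(f"P{k + 1}", "PIP", cname, 500, "P" if k == 0 else "O", origin + off)
        for spec in contact_spec:
            names = list(spec.atom_probs)
            for j, aname in enumerate(names):
                # distinct directions per atom so copies do not coincide
                theta = 2.0 * math.pi * (j + 1) / (len(names) + 1)
                direction = np.array([math.cos(theta), math.sin(theta), 0.35])
                direction /= np.linalg.norm(direction)
                pos_in = origin + 3.2 * direction
                pos_out = origin + 15.0 * direction
                idx = add_atom(
                    aname, spec.resname, cname, spec.resid, _element_from_name(aname), pos_in
                )
                tagged.append((idx, pos_in, pos_out, spec.atom_probs[aname]))
            # a hydrogen parked permanently inside the shell
            add_atom("HB", spec.resname, cname, spec.resid, "H", origin + np.array([0.0, 0.0, 2.0]))

    # waters around chain A's ligand
    water_entries = []  # (o_idx, h1_idx, h2_idx, inside flag)
    originA = np.zeros(3)
    for wi in range(n_waters_in + n_waters_out):
        inside = wi < n_waters_in
        o = add_atom("O", "HOH", "W", 1000 + wi, "O", originA)
        h1 = add_atom("H1", "HOH", "W", 1000 + wi, "H", originA)
        h2 = add_atom("H2", "HOH", "W", 1000 + wi, "H", originA)
        water_entries.append((o, h1, h2, inside))

    template = np.asarray(template, dtype=float)
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    lig_A = template[0:n_lig_heavy]  # chain A ligand coordinates

    def random_unit(n):
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    frames = np.empty((n_frames, len(template), 3))
    for f in range(n_frames):
        frame = template.copy()
        for idx, pos_in, pos_out, p in tagged:
            frame[idx] = pos_in if rng.random() < p else pos_out
        for (o, h1, h2, inside) in water_entries:
            anchor = lig_A[rng.integers(0, n_lig_heavy)]
            if inside:
                r = rng.uniform(2.7, shell_radius)
            else:
                r = rng.uniform(shell_radius + 5.0, shell_radius + 12.0)
            opos = anchor + r * random_unit(1)[0]
            if not inside:
                # guard against landing in another ligand atom's shell
                while np.linalg.norm(lig_A - opos, axis=1).min() <= shell_radius + 1.0:
                    opos = anchor + r * random_unit(1)[0]
            frame[o] = opos
            hdir = random_unit(2)
            frame[h1] = opos + 0.96 * hdir[0]
            frame[h2] = opos + 0.96 * hdir[1]
        frames[f] = frame

    traj = Trajectory(coords=frames, atoms=atoms)
    truth = {
        "q": {spec.label: spec.q for spec in contact_spec},
        "atom_probs": {
            spec.label: dict(spec.atom_probs) for spec in contact_spec
        },
        "n_waters_in": n_waters_in,
        "n_waters_out": n_waters_out,
        "shell_radius": shell_radius,
        "contact_cutoff": contact_cutoff,
        "n_chains": n_chains,
        "n_frames": n_frames,
        "seed": seed,
    }
    if out_prefix is not None:
        from .pdbio import write_pdb

        prefix = Path(out_prefix)
        write_pdb(traj, prefix.with_suffix(".pdb"))
        _write_sidecar(prefix, truth)
    return traj, truth


# ---------------------------------------------------------------------------
# cylinder channels
# ---------------------------------------------------------------------------


def gen_cylinder_channel(
    ring_radii: Sequence[float],
    vdw_radius: float = 1.7,
    z_positions: Optional[Sequence[float]] = None,
    atoms_per_ring: int = 16,
    out_prefix=None,
) -> tuple[Trajectory, dict]:
    """Stacked atom rings centered on the z axis, with analytic pore radii.

    The exact inscribed-probe radius at a ring's z is
    min_k sqrt(R_k^2 + (z - z_k)^2) - vdw_radius (an adjacent narrower ring
    can shadow a wide one); the default ring spacing is chosen so that no
    ring encroaches on its neighbours and the radius at each ring reduces to
    ring_radius - vdw_radius.  Atoms are written as carbons; pass
    ``vdw_radius`` on to the profiler when it differs from the Bondi carbon
    radius.
    """
    ring_radii = [float(r) for r in ring_radii]
    if not ring_radii:
        raise ValueError("need at least one ring")
    if any(r <= vdw_radius for r in ring_radii):
        raise ValueError("every ring radius must exceed the atom vdW radius")
    if z_positions is None:
        # spacing such that sqrt(R_min^2 + dz^2) >= R_max: neighbours never
        # shadow a ring, so the per-ring truth is exactly R - vdw_radius
        spread = max(ring_radii) ** 2 - min(ring_radii) ** 2
        spacing = math.sqrt(spread) + 2.0
        z_positions = [spacing * j for j in range(len(ring_radii))]
    z_positions = [float(z) for z in z_positions]
    if len(z_positions) != len(ring_radii):
        raise ValueError("z_positions and ring_radii must have equal length")
    rows = []
    xyz = []
    serial = 0
    for j, (R, z) in enumerate(zip(ring_radii, z_positions)):
        for a in range(atoms_per_ring):
            serial += 1
            phi = 2.0 * math.pi * a / atoms_per_ring
            rows.append(
                {
                    "serial": serial,
                    "name": f"C{a + 1}",
                    "resname": "RNG",
                    "chain": "A",
                    "resid": j + 1,
                    "element": "C",
                    "is_heavy": True,
                    "is_water": False,
                }
            )
            xyz.append([R * math.cos(phi), R * math.sin(phi), z])
    traj = Trajectory(
        coords=np.asarray(xyz)[None, :, :],
        atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS),
    )
    pore_radii = [
        min(
            math.sqrt(Rk**2 + (z - zk) ** 2)
            for Rk, zk in zip(ring_radii, z_positions)
        )
        - vdw_radius
        for z in z_positions
    ]
    truth = {
        "ring_radii": ring_radii,
        "z_positions": z_positions,
        "vdw_radius": vdw_radius,
        "pore_radii": pore_radii,
        "atoms_per_ring": atoms_per_ring,
    }
    if out_prefix is not None:
        from .pdbio import write_pdb

        prefix = Path(out_prefix)
        write_pdb(traj, prefix.with_suffix(".pdb"))
        _write_sidecar(prefix, truth)
    return traj, truth
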