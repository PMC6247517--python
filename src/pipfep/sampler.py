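"""Seeded Metropolis Monte Carlo sampling of toy alchemical systems.

The study this package models sampled each lambda window with molecular
dynamics; for desk-scale toy systems only Boltzmann sampling of the
configurational distribution at V(lambda) is needed, so a Metropolis chain
replaces the integrator.  Each window chain is equilibrated (with step-size
auto-tuning toward ~40% acceptance, frozen before production), then records
the forward potential-energy difference V(lambda_next) - V(lambda) at every
sweep, split into electrostatic / van der Waals / external components.

Replicate runs differ only by a derived seed (seed + run_id) and a small
jitter of the initial coordinates, standing in for independent starting
configurations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kT
from .potentials import (
    AlchemicalSystem,
    FlatBottomWell,
    HarmonicWell,
    WindowContext,
    compile_window,
    frames_energy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "WindowSamples",
    "LegSamples",
    "ConfigurationError",
    "sample_window",
    "run_fep_leg",
    "windows_to_csv",
    "windows_from_csv",
]


class ConfigurationError(ValueError):
    """Raised for unsampleable systems (e.g. unbounded mobile atoms)."""


@dataclass(frozen=True)
class SamplerConfig:
    """Monte Carlo protocol settings.

    temperature : K
    n_equil : equilibration sweeps discarded before production
    n_prod : production sweeps (one recorded sample per sweep)
    step_size : initial maximum per-coordinate displacement, Angstrom
    seed : base RNG seed; replicate r uses seed + r
    n_runs : independent replicates
    """

    temperature: float = DEFAULT_TEMPERATURE
    n_equil: int = 4000
    n_prod: int = 200_000
    step_size: float = 0.5
    seed: int = 0
    n_runs: int = 5

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_equil < 0:
            raise ValueError("n_equil must be >= 0")
        if self.n_prod < 1:
            raise ValueError("n_prod must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class WindowSamples:
    """Forward potential-energy-difference samples at one lambda window.

    dV_* are series of V(lam_next) - V(lam) over recorded configurations,
    kcal/mol; dV_total = dV_elec + dV_vdw + dV_ext sample-wise by
    construction.
    """

    lam: float
    lam_next: float
    dV_total: np.ndarray
    dV_elec: np.ndarray
    dV_vdw: np.ndarray
    dV_ext: np.ndarray
    run_id: int = 0
    acceptance_rate: float = math.nan
    step_size: float = math.nan

    def __post_init__(self) -> None:
        self.dV_total = np.asarray(self.dV_total, dtype=float)
        self.dV_elec = np.asarray(self.dV_elec, dtype=float)
        self.dV_vdw = np.asarray(self.dV_vdw, dtype=float)
        self.dV_ext = np.asarray(self.dV_ext, dtype=float)
        n = len(self.dV_total)
        if not (len(self.dV_elec) == len(self.dV_vdw) == len(self.dV_ext) == n):
            raise ValueError("all dV series must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.dV_total)


@dataclass
class LegSamples:
    """All window samples of one alchemical leg: by_run[run][window]."""

    lambdas: list[float]
    by_run: list[list[WindowSamples]]

    @property
    def n_runs(self) -> int:
        return len(self.by_run)

    def all_windows(self) -> list[WindowSamples]:
        return [w for run in self.by_run for w in run]


# ---------------------------------------------------------------------------
# boundedness check
# ---------------------------------------------------------------------------


def _atom_is_bounded(system: AlchemicalSystem, a: int) -> bool:
    if system.box is not None:
        return True
    for w in system.wells[a]:
        if isinstance(w, FlatBottomWell) and w.k > 0:
            return True
        if isinstance(w, HarmonicWell):
            if all(k1 > 0 and k2 > 0 for k1, k2 in zip(w.k_initial, w.k_final)):
                return True
    return False


def _check_bounded(system: AlchemicalSystem) -> None:
    for a in system.mobile_indices:
        if not _atom_is_bounded(system, a):
            raise ConfigurationError(
                f"mobile atom {a} has no confining well and no box; "
                "the chain would be unbounded"
            )


# ---------------------------------------------------------------------------
# the Metropolis chain
# ---------------------------------------------------------------------------

_TUNE_INTERVAL = 200  # sweeps between step-size adjustments during equilibration
_TARGET_ACCEPTANCE = 0.4


def _atom_energy(pos: list, a3: int, pair_terms, harm_terms, flat_terms, box) -> float:
    """Energy of all terms involving one atom; pure-float inner loop."""
    x = pos[a3]
    y = pos[a3 + 1]
    z = pos[a3 + 2]
    e = 0.0
    for (j, qq, eps4, shift, sig6, cutoff2) in pair_terms:
        j3 = 3 * j
        dx = x - pos[j3]
        dy = y - pos[j3 + 1]
        dz = z - pos[j3 + 2]
        if box is not None:
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if qq != 0.0:
            e += qq / math.sqrt(r2)
        if eps4 != 0.0 and (cutoff2 is None or r2 <= cutoff2):
            denom = shift + r2 * r2 * r2
            if denom == 0.0:
                return math.inf
            s = sig6 / denom
            e += eps4 * (s * s - s)
    for (kx, ky, kz, cx, cy, cz) in harm_terms:
        dx = x - cx
        dy = y - cy
        dz = z - cz
        e += 0.5 * (kx * dx * dx + ky * dy * dy + kz * dz * dz)
    for (k, radius, cx, cy, cz) in flat_terms:
        dx = x - cx
        dy = y - cy
        dz = z - cz
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d > radius:
            e += 0.5 * k * (d - radius) ** 2
    return e


def _run_chain(
    system: AlchemicalSystem,
    ctx: WindowContext,
    coords0: np.ndarray,
    n_equil: int,
    n_prod: int,
    step0: float,
    beta: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Run one Metropolis chain; returns (frames, acceptance_rate, step)."""
    mobile = system.mobile_indices
    n_mob = len(mobile)
    pos = [float(v) for v in np.asarray(coords0, dtype=float).ravel()]
    box = None if ctx.box is None else [float(b) for b in ctx.box]
    terms = {a: ctx.atom_terms(a) for a in mobile}
    step = step0
    frames = np.empty((n_prod, system.n_atoms, 3))
    exp = math.exp

    def run_block(n_sweeps: int, record_offset: Optional[int]) -> tuple[int, int]:
        accepted = 0
        proposed = 0
        # chunked RNG: one batch of displacements/uniforms per block
        disp = rng.random((n_sweeps, n_mob, 3)).tolist()
        uni = rng.random((n_sweeps, n_mob)).tolist()
        for s in range(n_sweeps):
            drow = disp[s]
            urow = uni[s]
            for k in range(n_mob):
                a = mobile[k]
                a3 = 3 * a
                pt, ht, ft = terms[a]
                e_old = _atom_energy(pos, a3, pt, ht, ft, box)
                ox, oy, oz = pos[a3], pos[a3 + 1], pos[a3 + 2]
                dk = drow[k]
                pos[a3] = ox + step * (2.0 * dk[0] - 1.0)
                pos[a3 + 1] = oy + step * (2.0 * dk[1] - 1.0)
                pos[a3 + 2] = oz + step * (2.0 * dk[2] - 1.0)
                e_new = _atom_energy(pos, a3, pt, ht, ft, box)
                dE = e_new - e_old
                if dE <= 0.0 or urow[k] < exp(-beta * dE):
                    accepted += 1
                else:
                    pos[a3], pos[a3 + 1], pos[a3 + 2] = ox, oy, oz
                proposed += 1
            if record_offset is not None:
                frames[record_offset + s] = np.asarray(pos).reshape(-1, 3)
        return accepted, proposed

    # equilibration with step-size tuning, frozen before production
    remaining = n_equil
    while remaining > 0:
        block = min(_TUNE_INTERVAL, remaining)
        acc, prop = run_block(block, None)
        rate = acc / prop if prop else 0.0
        if rate < _TARGET_ACCEPTANCE - 0.05:
            step = max(step * 0.8, 1e-4)
        elif rate > _TARGET_ACCEPTANCE + 0.05:
            step = min(step * 1.2, 20.0)
        remaining -= block

    accepted, proposed = run_block(n_prod, 0)
    rate = accepted / proposed if proposed else 0.0
    return frames, rate, step


def sample_window(
    system: AlchemicalSystem,
    lam: float,
    lam_next: float,
    config: SamplerConfig,
    initial_coordinates: Optional[np.ndarray] = None,
    run_id: int = 0,
    rng: Optional[np.random.Generator] = None,
    return_final: bool = False,
):
    """Sample one window at lambda and record forward differences to lam_next.

    The chain samples the Boltzmann distribution of V(lambda) at the
    configured temperature; after ``n_equil`` discarded sweeps, ``n_prod``
    samples of V(lam_next) - V(lam) (with elec/vdW/external components) are
    recorded, one per sweep.  Identical seed and config give bit-identical
    output.
    """
    if not 0.0 <= lam <= lam_next <= 1.0:
        raise ValueError(f"need 0 <= lam <= lam_next <= 1, got {lam}, {lam_next}")
    if not system.mobile_indices:
        raise ConfigurationError("system has no mobile atoms to sample")
    _check_bounded(system)
    if rng is None:
        rng = np.random.default_rng(config.seed + run_id)
    coords0 = system.coordinates if initial_coordinates is None else initial_coordinates
    ctx = compile_window(system, lam)
    beta = 1.0 / kT(config.temperature)
    frames, rate, step = _run_chain(
        system, ctx, coords0, config.n_equil, config.n_prod, config.step_size, beta, rng
    )
    logger.debug(
        "window lam=%.6g run=%d acceptance=%.3f step=%.3g", lam, run_id, rate, step
    )
    ctx_next = compile_window(system, lam_next)
    e1, v1, x1 = frames_energy(ctx, frames)
    e2, v2, x2 = frames_energy(ctx_next, frames)
    d_elec = e2 - e1
    d_vdw = v2 - v1
    d_ext = x2 - x1
    ws = WindowSamples(
        lam=lam,
        lam_next=lam_next,
        dV_total=d_elec + d_vdw + d_ext,
        dV_elec=d_elec,
        dV_vdw=d_vdw,
        dV_ext=d_ext,
        run_id=run_id,
        acceptance_rate=rate,
        step_size=step,
    )
    if return_final:
        return ws, frames[-1]
    return ws


def run_fep_leg(
    system: AlchemicalSystem,
    schedule,
    config: SamplerConfig,
    jitter: float = 0.1,
) -> LegSamples:
    """Sample every consecutive window pair of a schedule, for each replicate.

    Replicates use derived seeds (config.seed + run_id) and initial mobile
    coordinates jittered by a Gaussian of width ``jitter`` Angstrom, standing
    in for independent starting configurations.  Each window chain starts
    from the final configuration of the previous window.
    """
    lambdas = list(getattr(schedule, "values", schedule))
    if len(lambdas) < 2:
        raise ValueError("schedule must contain at least 2 lambda values")
    _check_bounded(system)
    by_run: list[list[WindowSamples]] = []
    for run_id in range(config.n_runs):
        rng = np.random.default_rng(config.seed + run_id)
        coords = system.coordinates.copy()
        for a in system.mobile_indices:
            coords[a] += jitter * rng.standard_normal(3)
        windows: list[WindowSamples] = []
        for w, (lam, lam_next) in enumerate(zip(lambdas[:-1], lambdas[1:])):
            ws, coords = sample_window(
                system,
                lam,
                lam_next,
                config,
                initial_coordinates=coords,
                run_id=run_id,
                rng=rng,
                return_final=True,
            )
            windows.append(ws)
        by_run.append(windows)
    return LegSamples(lambdas=lambdas, by_run=by_run)


# ---------------------------------------------------------------------------
# tabular round trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "lam",
    "lam_next",
    "run_id",
    "sample_index",
    "dV_total",
    "dV_elec",
    "dV_vdw",
    "dV_ext",
]


def windows_to_csv(leg: LegSamples, path) -> None:
    """Write all window samples of a leg to one CSV file."""
    chunks = []
    for run in leg.by_run:
        for ws in run:
            chunks.append(
                pd.DataFrame(
                    {
                        "lam": ws.lam,
                        "lam_next": ws.lam_next,
                        "run_id": ws.run_id,
                        "sample_index": np.arange(ws.n_samples),
                        "dV_total": ws.dV_total,
                        "dV_elec": ws.dV_elec,
                        "dV_vdw": ws.dV_vdw,
                        "dV_ext": ws.dV_ext,
                    }
                )
            )
    df = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=_CSV_COLUMNS)
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def windows_from_csv(path) -> LegSamples:
    """Read a leg's window samples back from CSV (estimation without re-sampling)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"window CSV {path} lacks columns: {sorted(missing)}")
    lambdas: list[float] = []
    by_run: list[list[WindowSamples]] = []
    for run_id, run_df in df.groupby("run_id", sort=True):
        windows = []
        for (lam, lam_next), wdf in run_df.groupby(["lam", "lam_next"], sort=True):
            wdf = wdf.sort_values("sample_index")
            windows.append(
                WindowSamples(
                    lam=float(lam),
                    lam_next=float(lam_next),
                    dV_total=wdf["dV_total"].to_numpy(),
                    dV_elec=wdf["dV_elec"].to_numpy(),
                    dV_vdw=wdf["dV_vdw"].to_numpy(),
                    dV_ext=wdf["dV_ext"].to_numpy(),
                    run_id=int(run_id),
                )
            )
        by_run.append(windows)
        lams = [w.lam for w in windows] + [windows[-1].lam_next]
        if len(lams) > len(lambdas):
            lambdas = lams
    return LegSamples(lambdas=lambdas, by_run=by_run)
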