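"""Free-energy estimation by per-window exponential averaging.

Each window contributes the Zwanzig free-energy increment

    dG_lambda = -kT ln < exp(-beta [V(lambda + dlambda) - V(lambda)]) >_lambda,

computed in log space for overflow safety; a leg's total is the sum of its
window increments.  The default schedule is the 21-point lambda ladder with
dense spacing near both end points, as used with soft-core coupling for
ligand-mutation legs.  Replicate aggregation is a plain mean over runs with
the standard error of that mean.

The electrostatic and van der Waals components are estimated with the same
exponential average applied to the stored per-sample components; the
residual "coupling" term is then defined by the bookkeeping identity
dG_couple = dG - dG_elec - dG_vdW, never estimated directly, so the identity
holds exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kT
from .sampler import LegSamples, WindowSamples

__all__ = [
    "LambdaSchedule",
    "FreeEnergyResult",
    "DEFAULT_LAMBDAS",
    "default_schedule",
    "window_delta_g",
    "component_delta_g",
    "accumulate",
    "estimate_leg",
    "bootstrap_se",
    "leg_report",
    "load_leg_report",
]

#: The 21-window lambda ladder (dense near the end points for soft-core legs).
DEFAULT_LAMBDAS: tuple[float, ...] = (
    0.0,
    0.00001,
    0.0001,
    0.001,
    0.01,
    0.05,
    0.1,
    0.2,
    0.3,
    0.4,
    0.5,
    0.6,
    0.7,
    0.8,
    0.9,
    0.95,
    0.99,
    0.999,
    0.9999,
    0.99999,
    0.999999,
)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered ladder of coupling values, starting at 0, strictly increasing."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("schedule needs at least 2 lambda values")
        if vals[0] != 0.0:
            raise ValueError("schedule must start at lambda = 0")
        if any(b <= a for a, b in zip(vals[:-1], vals[1:])):
            raise ValueError("schedule must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("lambda values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.values[:-1], self.values[1:]))


def default_schedule() -> LambdaSchedule:
    """The 21-window soft-core schedule."""
    return LambdaSchedule(DEFAULT_LAMBDAS)


@dataclass(frozen=True)
class FreeEnergyResult:
    """Leg free energy with components and replicate standard errors.

    dG_couple = dG - dG_elec - dG_vdw holds exactly (it is defined that way,
    per run, before averaging).  Standard errors are over replicate runs
    (sd / sqrt(n_runs)); NaN marks "not available" when n_runs < 2.
    """

    dG: float
    dG_elec: float
    dG_vdw: float
    dG_couple: float
    se: float
    se_elec: float
    se_vdw: float
    se_couple: float
    n_runs: int
    leg_label: str = ""
    per_run: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.leg_label not in ("", "bound", "free"):
            raise ValueError("leg_label must be 'bound', 'free' or empty")

    @classmethod
    def from_components(
        cls,
        dG: float,
        dG_elec: float,
        dG_vdw: float,
        se: float = math.nan,
        se_elec: float = math.nan,
        se_vdw: float = math.nan,
        se_couple: float = math.nan,
        n_runs: int = 1,
        leg_label: str = "",
    ) -> "FreeEnergyResult":
        """Build a result with the coupling term derived from the identity."""
        return cls(
            dG=dG,
            dG_elec=dG_elec,
            dG_vdw=dG_vdw,
            dG_couple=dG - dG_elec - dG_vdw,
            se=se,
            se_elec=se_elec,
            se_vdw=se_vdw,
            se_couple=se_couple,
            n_runs=n_runs,
            leg_label=leg_label,
        )

    def to_dict(self) -> dict:
        return {
            "leg_label": self.leg_label,
            "n_runs": self.n_runs,
            "dG": self.dG,
            "dG_elec": self.dG_elec,
            "dG_vdw": self.dG_vdw,
            "dG_couple": self.dG_couple,
            "se": self.se,
            "se_elec": self.se_elec,
            "se_vdw": self.se_vdw,
            "se_couple": self.se_couple,
        }


def _zwanzig(dv: np.ndarray, temperature: float) -> float:
    dv = np.asarray(dv, dtype=float)
    if dv.size == 0:
        raise ValueError("window has no samples")
    if not np.all(np.isfinite(dv)):
        raise ValueError("window contains non-finite dV samples")
    kt = kT(temperature)
    return -kt * (logsumexp(-dv / kt) - math.log(dv.size))


def window_delta_g(samples: WindowSamples, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Zwanzig estimate -kT ln<exp(-beta dV_total)> for one window."""
    return _zwanzig(samples.dV_total, temperature)


def component_delta_g(
    samples: WindowSamples, temperature: float = DEFAULT_TEMPERATURE
) -> tuple[float, float]:
    """(dG_elec, dG_vdw) by exponential averaging of the stored components."""
    return (
        _zwanzig(samples.dV_elec, temperature),
        _zwanzig(samples.dV_vdw, temperature),
    )


def accumulate(window_dGs: Sequence[float]) -> float:
    """Sum window increments into a leg free energy."""
    vals = list(window_dGs)
    if not vals:
        raise ValueError("no window free energies to accumulate")
    return float(np.sum(vals))


def bootstrap_se(
    samples: WindowSamples,
    temperature: float = DEFAULT_TEMPERATURE,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of the Zwanzig estimate of one window."""
    rng = np.random.default_rng(seed)
    dv = np.asarray(samples.dV_total, dtype=float)
    n = dv.size
    stats = np.empty(n_boot)
    for b in range(n_boot):
        resampled = dv[rng.integers(0, n, size=n)]
        stats[b] = _zwanzig(resampled, temperature)
    return float(np.std(stats, ddof=1))


def estimate_leg(
    leg: LegSamples,
    temperature: float = DEFAULT_TEMPERATURE,
    leg_label: str = "",
) -> FreeEnergyResult:
    """Estimate a leg free energy with components and replicate errors.

    Per run, the total and component window increments are accumulated over
    the schedule and the coupling term is derived from the bookkeeping
    identity; the reported values are means over runs, with se =
    sd / sqrt(n_runs) (NaN when a single run gives no scatter estimate).
    """
    if not leg.by_run:
        raise ValueError("leg contains no runs")
    n_windows = len(leg.by_run[0])
    per_run: list[tuple[float, float, float, float]] = []
    for run in leg.by_run:
        if len(run) != n_windows:
            raise ValueError("every run must cover every window pair")
        tot = accumulate([window_delta_g(w, temperature) for w in run])
        elec = accumulate([component_delta_g(w, temperature)[0] for w in run])
        vdw = accumulate([component_delta_g(w, temperature)[1] for w in run])
        per_run.append((tot, elec, vdw, tot - elec - vdw))
    arr = np.asarray(per_run)
    means = arr.mean(axis=0)
    n_runs = len(per_run)
    if n_runs >= 2:
        ses = arr.std(axis=0, ddof=1) / math.sqrt(n_runs)
    else:
        ses = np.full(4, math.nan)
    return FreeEnergyResult(
        dG=float(means[0]),
        dG_elec=float(means[1]),
        dG_vdw=float(means[2]),
        dG_couple=float(means[0] - means[1] - means[2]),
        se=float(ses[0]),
        se_elec=float(ses[1]),
        se_vdw=float(ses[2]),
        se_couple=float(ses[3]),
        n_runs=n_runs,
        leg_label=leg_label,
        per_run=tuple(per_run),
    )


# ---------------------------------------------------------------------------
# leg reports
# ---------------------------------------------------------------------------


def leg_report(result: FreeEnergyResult, out_prefix) -> tuple[Path, Path]:
    """Write a leg report as JSON (full precision) and CSV; returns the paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    json_path = out_prefix.with_suffix(".json")
    csv_path = out_prefix.with_suffix(".csv")
    payload = result.to_dict()
    payload["per_run"] = [list(r) for r in result.per_run]
    json_path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    df = pd.DataFrame(
        [
            {
                "quantity": q,
                "value": payload[f"dG{suffix}"],
                "se": payload[f"se{suffix}"],
            }
            for q, suffix in [
                ("dG", ""),
                ("dG_elec", "_elec"),
                ("dG_vdw", "_vdw"),
                ("dG_couple", "_couple"),
            ]
        ]
    )
    df.to_csv(csv_path, index=False)
    return json_path, csv_path


def load_leg_report(path) -> FreeEnergyResult:
    """Read a leg report written by :func:`leg_report` (JSON form)."""
    payload = json.loads(Path(path).read_text())
    return FreeEnergyResult(
        dG=payload["dG"],
        dG_elec=payload["dG_elec"],
        dG_vdw=payload["dG_vdw"],
        dG_couple=payload["dG_couple"],
        se=payload["se"],
        se_elec=payload["se_elec"],
        se_vdw=payload["se_vdw"],
        se_couple=payload["se_couple"],
        n_runs=payload["n_runs"],
        leg_label=payload.get("leg_label", ""),
        per_run=tuple(tuple(r) for r in payload.get("per_run", [])),
    )
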