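"""Thermodynamic-cycle bookkeeping for relative binding free energies.

A ligand mutation (e.g. PI(4,5)P2 -> PI(3,4,5)P3) is run as two alchemical
legs -- once with the ligand bound to the receptor and once with the ligand
free -- and the relative binding free energy is the closed-cycle difference

    ddG = dG_bound - dG_free,

with the same subtraction applied component-wise (electrostatic, van der
Waals, coupling).  Leg standard errors are propagated in quadrature under the
assumption that the two legs are statistically independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .fep import FreeEnergyResult

__all__ = [
    "ThermoCycle",
    "CycleResult",
    "relative_binding",
    "component_ddg",
    "cycle_report",
]


@dataclass(frozen=True)
class ThermoCycle:
    """Paired bound/free legs of one ligand mutation."""

    mutation_label: str
    bound: FreeEnergyResult
    free: FreeEnergyResult

    def __post_init__(self) -> None:
        if self.bound.leg_label not in ("bound", ""):
            raise ValueError("bound leg carries a non-'bound' label")
        if self.free.leg_label not in ("free", ""):
            raise ValueError("free leg carries a non-'free' label")


@dataclass(frozen=True)
class CycleResult:
    """Relative binding free energy with component breakdown.

    ddG = ddG_elec + ddG_vdw + ddG_couple holds exactly because each leg
    obeys the same identity.
    """

    mutation_label: str
    ddG: float
    ddG_elec: float
    ddG_vdw: float
    ddG_couple: float
    se: float
    se_elec: float
    se_vdw: float
    se_couple: float


def relative_binding(bound_dG: float, free_dG: float) -> float:
    """ddG = dG_bound - dG_free."""
    if not (math.isfinite(bound_dG) and math.isfinite(free_dG)):
        raise ValueError(f"leg free energies must be finite, got {bound_dG}, {free_dG}")
    return bound_dG - free_dG


def _quad(a: float, b: float) -> float:
    if math.isnan(a) or math.isnan(b):
        return math.nan
    return math.hypot(a, b)


def component_ddg(cycle: ThermoCycle) -> CycleResult:
    """Component-wise ddG with standard errors combined in quadrature."""
    b, f = cycle.bound, cycle.free
    for leg in (b, f):
        if not (math.isfinite(leg.dG_elec) and math.isfinite(leg.dG_vdw)):
            raise ValueError("both legs must carry finite elec/vdW components")
    return CycleResult(
        mutation_label=cycle.mutation_label,
        ddG=relative_binding(b.dG, f.dG),
        ddG_elec=b.dG_elec - f.dG_elec,
        ddG_vdw=b.dG_vdw - f.dG_vdw,
        ddG_couple=b.dG_couple - f.dG_couple,
        se=_quad(b.se, f.se),
        se_elec=_quad(b.se_elec, f.se_elec),
        se_vdw=_quad(b.se_vdw, f.se_vdw),
        se_couple=_quad(b.se_couple, f.se_couple),
    )


def _fmt(x: float) -> str:
    """Round-half-even display to one decimal; missing values as ''."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{round(x, 1):.1f}"


def cycle_report(
    cycles: Sequence[ThermoCycle],
    out_prefix=None,
) -> pd.DataFrame:
    """Render mutation blocks (bound row, free row, ddG row) as a table.

    Display values round half-even to one decimal; if ``out_prefix`` is given,
    a display CSV and a full-precision JSON are written alongside.
    """
    if not cycles:
        raise ValueError("need at least one cycle to report")
    rows = []
    payload = []
    for cyc in cycles:
        res = component_ddg(cyc)
        for label, leg in (("bound", cyc.bound), ("free", cyc.free)):
            rows.append(
                {
                    "mutation": cyc.mutation_label,
                    "row": label,
                    "dG": _fmt(leg.dG),
                    "dG_elec": _fmt(leg.dG_elec),
                    "dG_vdw": _fmt(leg.dG_vdw),
                    "dG_couple": _fmt(leg.dG_couple),
                    "se": _fmt(leg.se),
                    "se_elec": _fmt(leg.se_elec),
                    "se_vdw": _fmt(leg.se_vdw),
                    "se_couple": _fmt(leg.se_couple),
                }
            )
        rows.append(
            {
                "mutation": cyc.mutation_label,
                "row": "ddG",
                "dG": _fmt(res.ddG),
                "dG_elec": _fmt(res.ddG_elec),
                "dG_vdw": _fmt(res.ddG_vdw),
                "dG_couple": _fmt(res.ddG_couple),
                "se": _fmt(res.se),
                "se_elec": _fmt(res.se_elec),
                "se_vdw": _fmt(res.se_vdw),
                "se_couple": _fmt(res.se_couple),
            }
        )
        payload.append(
            {
                "mutation": cyc.mutation_label,
                "bound": cyc.bound.to_dict(),
                "free": cyc.free.to_dict(),
                "ddG": res.__dict__,
            }
        )
    df = pd.DataFrame(rows)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_prefix.with_suffix(".csv"), index=False)
        out_prefix.with_suffix(".json").write_text(
            json.dumps(payload, indent=2, allow_nan=True) + "\n"
        )
    return df
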