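"""MM-PBSA aggregation identities and consistency auditing.

This is the bookkeeping layer of an end-point binding free-energy
calculation: it combines pre-computed component terms

    dG_gas  = dE_ele + dE_vdW
    dG_solv = dG_PB + dG_SA,   dG_SA = gamma * dSASA + beta
    dH      = dG_gas + dG_solv
    dG_bind = dH - T dS        (entropy optional, user-supplied)

and audits published component tables for internal additivity.  No
Poisson-Boltzmann solver or force-field evaluation lives here.  All
energies are kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BindingEnergyComponents:
    """Per-system (or per-snapshot) binding energy components, kJ/mol."""

    e_ele: float
    e_vdw: float
    g_pb: float
    g_sa: float

    def __post_init__(self):
        for name in ("e_ele", "e_vdw", "g_pb", "g_sa"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_solvation_total(
        cls, e_ele: float, e_vdw: float, g_solv: float
    ) -> "BindingEnergyComponents":
        """Build from a table that prints only the combined solvation term."""
        return cls(e_ele=e_ele, e_vdw=e_vdw, g_pb=g_solv, g_sa=0.0)


@dataclass
class NonpolarParams:
    """Surface-tension model for the nonpolar solvation term, kJ/(mol A^2) and kJ/mol."""

    gamma_surface: float
    beta_offset: float

    def __post_init__(self):
        if not (math.isfinite(self.gamma_surface) and math.isfinite(self.beta_offset)):
            raise ValueError("nonpolar parameters must be finite")


@dataclass
class EnergySummary:
    g_gas: float
    g_solv: float
    g_total: float
    g_bind: float | None = None  # only when an entropy term is supplied


def nonpolar_term(delta_sasa: float, params: NonpolarParams) -> float:
    """Nonpolar solvation energy ``gamma * dSASA + beta`` (kJ/mol)."""
    if not math.isfinite(delta_sasa):
        raise ValueError("delta_sasa must be finite")
    return params.gamma_surface * delta_sasa + params.beta_offset


def combine_components(
    components: BindingEnergyComponents, t_delta_s: float | None = None
) -> EnergySummary:
    """Sum component terms into gas-phase, solvation, and total energies.

    ``t_delta_s`` is the optional entropy term T*dS; when given,
    ``g_bind = g_total - t_delta_s``.
    """
    g_gas = components.e_ele + components.e_vdw
    g_solv = components.g_pb + components.g_sa
    g_total = g_gas + g_solv
    g_bind = None if t_delta_s is None else g_total - t_delta_s
    return EnergySummary(g_gas=g_gas, g_solv=g_solv, g_total=g_total, g_bind=g_bind)


def audit_consistency(
    reported: dict[str, float], tolerance: float = 0.01
) -> list[str]:
    """Check a published component table for internal additivity.

    ``reported`` may contain any of: e_ele, e_vdw, g_gas, g_solv, g_total.
    Each derivable identity present in the table is checked to ``tolerance``
    kJ/mol; a list of human-readable flag strings is returned (empty when
    consistent).  Typesetting slips in published tables — a gas-phase sum
    that does not match its addends, or a solvation term duplicating
    another column — show up here.
    """
    flags = []
    g = reported.get
    if all(k in reported for k in ("e_ele", "e_vdw", "g_gas")):
        s = g("e_ele") + g("e_vdw")
        if abs(s - g("g_gas")) > tolerance:
            flags.append(
                f"g_gas inconsistency: e_ele + e_vdw = {s:.2f} "
                f"but reported g_gas = {g('g_gas'):.2f}"
            )
    if all(k in reported for k in ("g_gas", "g_solv", "g_total")):
        s = g("g_gas") + g("g_solv")
        if abs(s - g("g_total")) > tolerance:
            flags.append(
                f"g_total inconsistency: g_gas + g_solv = {s:.2f} "
                f"but reported g_total = {g('g_total'):.2f}"
            )
    if all(k in reported for k in ("e_ele", "e_vdw", "g_solv", "g_total")):
        s = g("e_ele") + g("e_vdw") + g("g_solv")
        if abs(s - g("g_total")) > tolerance:
            flags.append(
                f"component-sum inconsistency: e_ele + e_vdw + g_solv = {s:.2f} "
                f"but reported g_total = {g('g_total'):.2f}"
            )
    return flags


def summarize_snapshots(table: pd.DataFrame | str) -> dict[str, dict[str, float]]:
    """Average a per-snapshot component table with standard errors.

    ``table`` is a DataFrame or a TSV path with columns e_ele, e_vdw, g_pb,
    g_sa (one row per snapshot).  Returns, for each component and each
    aggregate (g_gas, g_solv, g_total), the mean and the standard error of
    the mean; a single-row table returns the row as-is with zero error.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table, sep="\t")
    required = ["e_ele", "e_vdw", "g_pb", "g_sa"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"snapshot table missing columns: {missing}")
    df = table[required].astype(float).copy()
    df["g_gas"] = df["e_ele"] + df["e_vdw"]
    df["g_solv"] = df["g_pb"] + df["g_sa"]
    df["g_total"] = df["g_gas"] + df["g_solv"]
    n = len(df)
    out = {}
    for col in df.columns:
        sem = 0.0 if n == 1 else float(df[col].std(ddof=1) / np.sqrt(n))
        out[col] = {"mean": float(df[col].mean()), "sem": sem, "n": n}
    return out
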