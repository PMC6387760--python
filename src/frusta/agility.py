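"""Relative turning-agility indices and the per-specimen trait table.

Two comparative indices are computed for each specimen and each turning
scenario.  ``Agility_force = A_ilium / I_y`` divides the muscle-force proxy
(ilium lateral area, cm^2) by the yaw inertia resisting the turn.
``Agility_moment = tau_relative / I_y`` additionally scales for moment arms:

    tau_relative = (m^(1/3) / 100) * A_ilium * 20 N/cm^2

with mass in kg, a sub-maximal concentric specific tension of 20 N/cm^2,
and an arbitrary /100 linear adjustment that keeps the index in an intuitive
range without affecting between-taxon ratios.  Both are indices, not
physical torques or angular accelerations.

The *planted* scenario uses the axial body's inertia about its own COM; the
*en pointe* scenario uses the body + swing leg inertia about their
collective COM, which is never smaller, so en pointe agilities are never
larger than planted ones.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TorqueIndex",
    "SchemaError",
    "agility_force",
    "tau_relative",
    "agility_moment",
    "build_specimen_table",
    "validate_specimen_table",
    "load_reference_traits",
    "REQUIRED_COLUMNS",
]


class SchemaError(ValueError):
    """Raised when a specimen record lacks a required field."""


@dataclass(frozen=True)
class TorqueIndex:
    """Configuration constants of the relative-torque index.

    ``specific_tension`` is in N/cm^2; ``moment_scale_divisor`` is the
    arbitrary linear adjustment and must never affect between-taxon ratios.
    """

    specific_tension: float = 20.0
    moment_scale_divisor: float = 100.0

    def __post_init__(self) -> None:
        if self.specific_tension <= 0 or self.moment_scale_divisor <= 0:
            raise ValueError("torque-index constants must be positive")


REQUIRED_COLUMNS = ("taxon", "ilium_area_cm2", "mass_kg", "iy_body", "iy_body_leg")

#: Printed agility columns checked by the fixture validator, with the
#:  inertia column each one divides by.
_AGILITY_COLUMNS = {
    "agility_force_planted": ("force", "iy_body"),
    "agility_moment_planted": ("moment", "iy_body"),
    "agility_force_pointe": ("force", "iy_body_leg"),
    "agility_moment_pointe": ("moment", "iy_body_leg"),
}


def agility_force(a_ilium: float, i_y: float) -> float:
    """Force-based agility index: ilium area divided by yaw inertia."""
    if i_y <= 0:
        raise ValueError("yaw inertia must be positive")
    return a_ilium / i_y


def tau_relative(mass: float, a_ilium: float, cfg: TorqueIndex = TorqueIndex()) -> float:
    """Relative torque index (not a physical torque; no real moment arms)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (mass ** (1.0 / 3.0) / cfg.moment_scale_divisor) * a_ilium * cfg.specific_tension


def agility_moment(tau: float, i_y: float) -> float:
    """Moment-based agility index: relative torque divided by yaw inertia."""
    if i_y <= 0:
        raise ValueError("yaw inertia must be positive")
    return tau / i_y


def build_specimen_table(records: pd.DataFrame,
                         cfg: TorqueIndex = TorqueIndex()) -> pd.DataFrame:
    """Populate all four agility columns from per-specimen inputs.

    ``records`` must carry taxon, ilium_area_cm2, mass_kg, iy_body and
    iy_body_leg columns.  Returns a copy with computed columns
    ``agility_{force,moment}_{planted,pointe}`` (any same-named input columns
    are treated as printed values and preserved under a ``printed_`` prefix
    for the validator).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"specimen table missing column(s): {', '.join(missing)}")
    df = records.copy()
    for col in _AGILITY_COLUMNS:
        if col in df.columns:
            df = df.rename(columns={col: f"printed_{col}"})
    tau = np.array([tau_relative(m, a, cfg)
                    for m, a in zip(df["mass_kg"], df["ilium_area_cm2"])])
    df["tau_relative"] = tau
    df["agility_force_planted"] = df["ilium_area_cm2"] / df["iy_body"]
    df["agility_moment_planted"] = tau / df["iy_body"]
    df["agility_force_pointe"] = df["ilium_area_cm2"] / df["iy_body_leg"]
    df["agility_moment_pointe"] = tau / df["iy_body_leg"]
    return df


def _printed_decimals(value: float) -> int:
    s = f"{value!r}"
    if "." in s:
        return len(s.split(".")[1])
    return 0


def validate_specimen_table(table: pd.DataFrame,
                            cfg: TorqueIndex = TorqueIndex()) -> pd.DataFrame:
    """Consistency flags for a specimen table.

    Three checks per row: (i) any printed agility cell is compared with the
    value recomputed from the same row's mass, ilium area and inertia, to a
    tolerance of one unit in the cell's last printed decimal (printed tables
    round intermediate quantities); (ii) composed inertia must not be below
    the axial-body inertia (the parallel-axis composition forbids it);
    (iii) masses, areas and inertias must be positive.  Returns a long-format
    frame with columns taxon, check, detail.
    """
    flags: list[dict] = []
    computed = build_specimen_table(table, cfg)
    for idx, row in computed.iterrows():
        taxon = row["taxon"]
        for col in ("ilium_area_cm2", "mass_kg", "iy_body", "iy_body_leg"):
            if not row[col] > 0:
                flags.append({"taxon": taxon, "check": "non_positive",
                              "detail": f"{col} = {row[col]}"})
        if row["iy_body_leg"] < row["iy_body"]:
            flags.append({
                "taxon": taxon,
                "check": "inertia_impossible",
                "detail": (f"iy_body_leg {row['iy_body_leg']} < iy_body "
                           f"{row['iy_body']}; composed inertia cannot shrink"),
            })
        for col in _AGILITY_COLUMNS:
            printed_col = f"printed_{col}"
            if printed_col not in computed.columns or pd.isna(row[printed_col]):
                continue
            printed = float(row[printed_col])
            recomputed = float(row[col])
            # one unit in the last printed decimal, floored well above
            # float round-trip noise for full-precision columns
            tol = max(10.0 ** (-_printed_decimals(printed)), 1e-9)
            if abs(recomputed - printed) > tol:
                flags.append({
                    "taxon": taxon,
                    "check": "agility_mismatch",
                    "detail": (f"{col}: printed {printed} vs recomputed "
                               f"{recomputed:.4g} (tol {tol:g})"),
                })
    return pd.DataFrame(flags, columns=["taxon", "check", "detail"])


def load_reference_traits() -> pd.DataFrame:
    """Packaged reference trait table of 20 theropod specimens.

    Columns: taxon, specimen, group (tyrannosaurid_adult /
    tyrannosaurid_juvenile / other), ilium area (cm^2), mass (kg), log10
    mass, yaw inertias for body, leg and body+leg, and the four printed
    agility indices.  Used as the statistics-stage input and as the
    validator's canonical test case (it contains known-inconsistent cells).
    """
    with importlib.resources.files("frusta.data").joinpath("table3_traits.csv").open() as fh:
        return pd.read_csv(fh)
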