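"""End-to-end orchestration: bodies -> mass properties -> agility -> statistics.

A run is configured by a single YAML/JSON mapping (densities, superellipse
exponent, tail modifiers, torque-index constants, statistics options, seeds)
and emits comma-separated tables: per-specimen mass properties, a tail-width
sensitivity table (baseline vs widened tail with % of initial), the specimen
agility table with validator flags, and a regression + grade-ANCOVA report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agility import TorqueIndex, build_specimen_table, validate_specimen_table
from .body import (DEFAULT_DENSITIES, LegSeries, StationSeries,
                   apply_tail_modifiers, leg_to_frusta, slice_to_frusta)
from .massprops import iy_body_plus_leg, leg_mass_properties, mass_properties
from .phylo import PGLS, PhylANCOVA, calibrate_tree, tree_from_newick

__all__ = [
    "RunConfig",
    "compute_specimen",
    "tail_sensitivity_table",
    "run_pipeline",
    "validate_fixture",
]

log = logging.getLogger("frusta")


@dataclass
class RunConfig:
    """Configuration of a pipeline run; defaults reproduce the standard setup.

    The default superellipse exponent is the terrestrial-vertebrate
    "best estimate" k = 2.3; densities, the 20 N/cm^2 specific tension, the
    /100 moment divisor and the x1.4 upper-bound tail width are all
    pre-filled so a bare run uses the standard settings.
    """

    superellipse_k: float = 2.3
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    tail_width_factor: float = 1.4
    tail_depth_factor: float = 1.0
    torque: TorqueIndex = field(default_factory=TorqueIndex)
    lambda_mode: str = "ml"          # "ml" or a fixed float
    grade_slopes: bool = False
    seed: int = 0
    output_dir: str = "frusta_out"
    specimen_table: str | None = None
    tree_file: str | None = None
    occurrence_table: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        torque = raw.pop("torque", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if torque:
            cfg.torque = TorqueIndex(**torque)
        for name in ("specimen_table", "tree_file", "occurrence_table"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def compute_specimen(body: StationSeries, leg: LegSeries,
                     ilium_area_cm2: float, k: float = 2.3,
                     densities: dict[str, float] | None = None,
                     torque: TorqueIndex = TorqueIndex()) -> dict:
    """Mass properties and agility indices for one body + swing leg.

    Returns a flat record: total mass (body plus both legs), the axial-body
    COM, yaw inertias for the planted and en pointe scenarios, and the four
    agility indices.
    """
    from .agility import agility_force, agility_moment, tau_relative

    chain = slice_to_frusta(body, k=k, densities=densities)
    body_props = mass_properties(chain)
    leg_chain = leg_to_frusta(leg, k=k,
                              rho=(densities or DEFAULT_DENSITIES).get("leg", 1060.0))
    leg_props = leg_mass_properties(leg_chain, z_offset=leg.z_offset, x_hip=leg.x_hip)
    iy_bl = iy_body_plus_leg(body_props, leg_props)
    mass_total = body_props.mass + 2 * leg_props.mass
    tau = tau_relative(mass_total, ilium_area_cm2, torque)
    return {
        "ilium_area_cm2": ilium_area_cm2,
        "mass_kg": mass_total,
        "mass_body_kg": body_props.mass,
        "mass_leg_kg": leg_props.mass,
        "log10_mass": float(np.log10(mass_total)),
        "com_x": body_props.com_x,
        "com_y": body_props.com_y,
        "com_z": body_props.com_z,
        "iy_body": body_props.i_y,
        "iy_leg": leg_props.i_y,
        "iy_body_leg": iy_bl,
        "agility_force_planted": agility_force(ilium_area_cm2, body_props.i_y),
        "agility_moment_planted": agility_moment(tau, body_props.i_y),
        "agility_force_pointe": agility_force(ilium_area_cm2, iy_bl),
        "agility_moment_pointe": agility_moment(tau, iy_bl),
    }


def tail_sensitivity_table(bodies: dict[str, tuple[StationSeries, LegSeries, float]],
                           cfg: RunConfig) -> pd.DataFrame:
    """Baseline vs widened-tail mass/COM/inertia, with percent-of-initial columns.

    ``bodies`` maps a specimen name to (body, leg, ilium_area_cm2).  The tail
    width factor comes from the config (default 1.4, the adult-crocodylian
    upper bound).
    """
    rows = []
    for name, (body, leg, a_cm2) in bodies.items():
        base = compute_specimen(body, leg, a_cm2, cfg.superellipse_k, cfg.densities,
                                cfg.torque)
        wide_body = apply_tail_modifiers(body, width_factor=cfg.tail_width_factor,
                                         depth_factor=cfg.tail_depth_factor)
        wide = compute_specimen(wide_body, leg, a_cm2, cfg.superellipse_k,
                                cfg.densities, cfg.torque)
        rows.append({
            "taxon": name,
            "mass_initial_kg": base["mass_kg"],
            "mass_wide_tail_kg": wide["mass_kg"],
            "com_initial_m": base["com_x"],
            "com_wide_tail_m": wide["com_x"],
            "iy_initial": base["iy_body"],
            "iy_wide_tail": wide["iy_body"],
            "mass_pct_initial": 100.0 * wide["mass_kg"] / base["mass_kg"],
            "com_pct_initial": 100.0 * wide["com_x"] / base["com_x"],
            "iy_pct_initial": 100.0 * wide["iy_body"] / base["iy_body"],
        })
    return pd.DataFrame(rows)


def validate_fixture(table: pd.DataFrame, torque: TorqueIndex = TorqueIndex()) -> pd.DataFrame:
    """Per-row consistency flags for a specimen table (see agility module)."""
    return validate_specimen_table(table, torque)


def _stats_report(traits: pd.DataFrame, tree, cfg: RunConfig) -> dict[str, pd.DataFrame | str]:
    """PGLS + grade-ANCOVA report for the four agility responses."""
    out: dict[str, pd.DataFrame | str] = {}
    reg_rows, comp_frames, summaries = [], [], []
    lambda_mode = cfg.lambda_mode if cfg.lambda_mode == "ml" else float(cfg.lambda_mode)
    for scenario, col in (("planted", "agility_force_planted"),
                          ("planted", "agility_moment_planted"),
                          ("pointe", "agility_force_pointe"),
                          ("pointe", "agility_moment_pointe")):
        response = "force" if "force" in col else "moment"
        y = np.log10(traits[col].to_numpy(float))
        x = traits["log10_mass"].to_numpy(float)
        taxa = traits["taxon"].tolist()
        fit = PGLS(y, x, tree, taxa=taxa).fit(lambda_=lambda_mode)
        reg_rows.append({
            "scenario": scenario, "response": response,
            "slope": fit.slope, "intercept": fit.intercept,
            "slope_se": fit.bse[1], "intercept_se": fit.bse[0],
            "lambda": fit.lambda_, "r2_gls": fit.rsquared, "r2_raw": fit.rsquared_raw,
            "f": fit.fvalue, "p": fit.f_pvalue,
        })
        anc = PhylANCOVA(y, x, tree, traits["group"].to_numpy(object), taxa=taxa)
        rep = anc.fit(slopes=cfg.grade_slopes, lambda_=lambda_mode)
        frame = rep.to_frame()
        frame.insert(0, "response", response)
        frame.insert(0, "scenario", scenario)
        comp_frames.append(frame)
        summaries.append(f"## {scenario} / {response}\n{fit.summary()}\n{rep.summary()}")
    out["regression"] = pd.DataFrame(reg_rows)
    out["ancova"] = pd.concat(comp_frames, ignore_index=True)
    out["summary"] = "\n\n".join(summaries)
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the statistics stages over a specimen table (+ optional tree).

    Emits the recomputed agility table, validator flags, and (when a tree
    and occurrence table are configured) the PGLS/ANCOVA report.  Returns a
    name -> path mapping of everything written.  Synthetic geometry stages
    are driven through the CLI ``simulate`` command or the library API.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    logpath = outdir / "run_log.txt"
    handler = logging.FileHandler(logpath, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("frusta %s; seed=%d; config=%s", __version__, cfg.seed,
                 json.dumps(cfg.to_dict(), default=str))
        if cfg.specimen_table is None:
            raise ValueError("config must name a specimen_table for the statistics stages")
        traits = pd.read_csv(cfg.specimen_table)
        table = build_specimen_table(traits, cfg.torque)
        path = outdir / "specimen_table.csv"
        table.to_csv(path, index=False)
        written["specimen_table"] = path
        flags = validate_fixture(traits, cfg.torque)
        path = outdir / "validator_flags.csv"
        flags.to_csv(path, index=False)
        written["validator_flags"] = path
        log.info("validator raised %d flag(s)", len(flags))
        if cfg.tree_file is not None:
            tree = tree_from_newick(Path(cfg.tree_file).read_text())
            if cfg.occurrence_table is not None:
                occ = pd.read_csv(cfg.occurrence_table)
                tree = calibrate_tree(tree, occ)
                log.info("tree calibrated from %s", cfg.occurrence_table)
            report = _stats_report(table, tree, cfg)
            for name in ("regression", "ancova"):
                path = outdir / f"{name}.csv"
                report[name].to_csv(path, index=False)
                written[name] = path
            path = outdir / "stats_summary.txt"
            path.write_text(report["summary"])  # type: ignore[arg-type]
            written["stats_summary"] = path
        log.info("pipeline complete: %s", sorted(written))
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    written["log"] = logpath
    return written
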