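"""End-to-end orchestration: synthetic cohort -> solver -> contact chain -> stats.

`run_comparison` mirrors a full pressure-comparison study: for every
subject x compression class x position it solves the worn equilibrium on a
rigid mannequin leg (the P_LM arm) and on the same geometry backed by each
soft-tissue stiffness level (the P_LS arm), emulates instrument readings of
the mannequin pressures (the P_rigid arm), pushes the rigid/soft pair
through the Hertz contact chain to get the pressure-diversity ratio dP, and
runs the validation statistics battery.  `make_report` writes the result
tables as deterministic CSV + JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .garment_solver import (
    GarmentFit,
    SolverConfig,
    pressure_gradient_profile,
    solve_equilibrium,
)
from .hertz_contact import DeltaPInputs, PressureRatio, pressure_ratio, surface_displacement, unit_pressure
from .leg_geometry import POSITION_ORDER
from .materials import FabricSpec, TissueModel
from .units import mmhg_to_pa
from .synthetic_data import (
    CohortSpec,
    as_rigid,
    generate_garment_set,
    generate_leg,
    simulate_picopress,
    with_tissue,
)
from .validation_stats import (
    PairedPressureSet,
    dro_table,
    mean_dro,
    paired_t_bonferroni,
    pearson_r,
    shapiro_wilk,
)

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "delta_p_chain",
    "run_comparison",
    "make_report",
    "stiffness_significance_fraction",
    "cohort_true_pressures",
]

logger = logging.getLogger(__name__)

# seed name spaces for measurement emulation inside a run
_NS_RIGID_MEAS, _NS_GROUP_MEAS = 10, 11


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end comparison run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    solver: SolverConfig = field(default_factory=SolverConfig)
    stiffness_levels: tuple[float, ...] = (1400.0, 2200.0, 3000.0)
    rigid_modulus: float = 3.0e9
    output_dir: str | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.stiffness_levels or any(s <= 0 for s in self.stiffness_levels):
            raise ValueError("stiffness_levels must be non-empty and positive")
        if self.rigid_modulus < 1e9:
            raise ValueError("rigid_modulus below 1 GPa would not trigger the rigid path")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration (any omitted block keeps its default)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortSpec(**raw.get("cohort", {}))
    solver = SolverConfig(**raw.get("solver", {}))
    return RunConfig(
        cohort=cohort,
        solver=solver,
        stiffness_levels=tuple(raw.get("stiffness_levels", (1400.0, 2200.0, 3000.0))),
        rigid_modulus=float(raw.get("rigid_modulus", 3.0e9)),
        output_dir=raw.get("output_dir"),
        seed=int(raw.get("seed", 1)),
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full configuration, for provenance logs."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def delta_p_chain(
    P_pa: float,
    tissue_rigid: TissueModel,
    tissue_soft: TissueModel,
    fabric: FabricSpec,
    patch_radius: float,
) -> PressureRatio:
    """Pressure-diversity ratio from the contact chain at matched load.

    The per-element load is the interface pressure over the contact patch,
    F = P * pi * a0^2; at matched (q, a) the rigid- and soft-leg surface
    displacements follow from the Hertz displacement formula with the two
    mismatch-factor sums, and the ratio collapses to dP = 1 exactly.  This
    is the quantitative statement that pressure delivery is insensitive to
    leg tissue stiffness.
    """
    if P_pa <= 0:
        raise ValueError("need a positive interface pressure")
    a = patch_radius
    F = P_pa * math.pi * a**2
    q = unit_pressure(F, a)
    k_F = fabric.mismatch
    w_r = surface_displacement(tissue_rigid.k, k_F, q, a)
    w_s = surface_displacement(tissue_soft.k, k_F, q, a)
    return pressure_ratio(
        DeltaPInputs(w_r=w_r, w_s=w_s, k_r=tissue_rigid.k, k_s=tissue_soft.k, k_F=k_F)
    )


def _measure_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def run_comparison(cfg: RunConfig) -> dict:
    """Run the full synthetic comparison study.

    Returns a dict with the per-position pressure table (one row per
    subject x class x position x arm), the dP table, the statistics
    battery per class, and a provenance block.
    """
    t0 = time.time()
    cohort = cfg.cohort
    rigid_tissue = TissueModel.from_modulus(cfg.rigid_modulus, nu=0.3)
    rows: list[dict] = []
    dp_rows: list[dict] = []
    logger.info(
        "run_comparison start: %d subjects, classes %s, %d stiffness levels",
        cohort.n_subjects, cohort.classes, len(cfg.stiffness_levels),
    )
    for s in range(cohort.n_subjects):
        soft_geo = generate_leg(cohort, s)
        rigid_leg = as_rigid(soft_geo, E=cfg.rigid_modulus, nu=0.3)
        for ci, cls in enumerate(cohort.classes):
            garments = generate_garment_set(cls, cohort.seed, soft_geo, subject_index=s)
            fits = [GarmentFit(garments[p], rigid_leg, p) for p in garments]
            profile = pressure_gradient_profile(rigid_leg, fits, cfg.solver)
            meas_rng = _measure_rng(cfg.seed, _NS_RIGID_MEAS, s, ci)
            for res in profile.results:
                fabric = garments[res.position]
                common = {
                    "subject": f"SYN{s:02d}",
                    "class": cls,
                    "position": res.position,
                    "degressive": profile.degressive,
                }
                rows.append(
                    common
                    | {
                        "arm": "P_LM",
                        "E_s_Pa": cfg.rigid_modulus,
                        "P_mmHg": res.P_mmhg,
                        "P_Pa": res.P_pa,
                        "T_N_per_m": res.T,
                        "strain": res.strain,
                        "w_mm": res.w * 1e3,
                        "iterations": res.iterations,
                        "converged": res.converged,
                    }
                )
                measured = simulate_picopress(res.P_mmhg, rng=meas_rng)
                rows.append(
                    common
                    | {
                        "arm": "P_rigid",
                        "E_s_Pa": cfg.rigid_modulus,
                        "P_mmHg": float(measured),
                        "P_Pa": mmhg_to_pa(float(measured)),
                        "T_N_per_m": np.nan,
                        "strain": np.nan,
                        "w_mm": np.nan,
                        "iterations": 0,
                        "converged": True,
                    }
                )
                for E_level in cfg.stiffness_levels:
                    soft_leg = with_tissue(soft_geo, E_level)
                    soft_res = solve_equilibrium(
                        GarmentFit(fabric, soft_leg, res.position), cfg.solver
                    )
                    rows.append(
                        common
                        | {
                            "arm": f"P_LS[{E_level:g}]",
                            "E_s_Pa": E_level,
                            "P_mmHg": soft_res.P_mmhg,
                            "P_Pa": soft_res.P_pa,
                            "T_N_per_m": soft_res.T,
                            "strain": soft_res.strain,
                            "w_mm": soft_res.w * 1e3,
                            "iterations": soft_res.iterations,
                            "converged": soft_res.converged,
                        }
                    )
                    chain = delta_p_chain(
                        res.P_pa,
                        rigid_tissue,
                        soft_leg.tissue,
                        fabric,
                        cfg.solver.patch_radius,
                    )
                    dp_rows.append(
                        {
                            "subject": f"SYN{s:02d}",
                            "class": cls,
                            "position": res.position,
                            "E_s_Pa": E_level,
                            "delta_p": chain.delta_p,
                            "w_ratio": chain.w_ratio,
                            "k_ratio": chain.k_ratio,
                        }
                    )
    pressures = pd.DataFrame(rows)
    order = {p: i for i, p in enumerate(POSITION_ORDER)}
    pressures["_pos"] = pressures["position"].map(order)
    pressures = (
        pressures.sort_values(["subject", "class", "_pos", "arm"], kind="mergesort")
        .drop(columns="_pos")
        .reset_index(drop=True)
    )
    delta_p = pd.DataFrame(dp_rows)
    if not delta_p.empty:
        delta_p["_pos"] = delta_p["position"].map(order)
        delta_p = (
            delta_p.sort_values(["subject", "class", "_pos", "E_s_Pa"], kind="mergesort")
            .drop(columns="_pos")
            .reset_index(drop=True)
        )

    stats = _stats_battery(cfg, pressures)
    meta = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "ctpress_version": __version__,
        "numpy_version": np.__version__,
        "n_pressure_rows": int(len(pressures)),
        "n_delta_p_rows": int(len(delta_p)),
        "elapsed_s": round(time.time() - t0, 3),
    }
    logger.info("run_comparison done in %.2f s (%d rows)", meta["elapsed_s"], len(pressures))
    return {"pressures": pressures, "delta_p": delta_p, "stats": stats, "meta": meta}


def _stats_battery(cfg: RunConfig, pressures: pd.DataFrame) -> dict:
    """Per-class DRO, normality, correlation and stiffness-group tests."""
    stats: dict[str, dict] = {}
    for ci, cls in enumerate(cfg.cohort.classes):
        sub = pressures[pressures["class"] == cls]
        sim = sub[sub["arm"] == "P_LM"].sort_values(["subject", "position"])
        meas = sub[sub["arm"] == "P_rigid"].sort_values(["subject", "position"])
        sim_p = sim["P_mmHg"].to_numpy()
        meas_p = meas["P_mmHg"].to_numpy()
        labels = list(zip(sim["subject"], sim["position"]))
        entry: dict = {
            "n": int(len(sim_p)),
            "mean_DRO_percent": mean_dro(meas_p, sim_p),
            "dro": dro_table(meas_p, sim_p, labels=[f"{s}/{p}" for s, p in labels]).to_dict(
                orient="records"
            ),
        }
        try:
            w_sim, p_sim = shapiro_wilk(sim_p)
            w_meas, p_meas = shapiro_wilk(meas_p)
            entry["normality"] = {
                "simulated": {"W": w_sim, "p": p_sim},
                "measured": {"W": w_meas, "p": p_meas},
            }
        except ValueError as exc:  # e.g. tiny cohorts
            entry["normality"] = {"note": str(exc)}
        try:
            rho, p_rho = pearson_r(meas_p, sim_p)
            entry["pearson"] = {"rho": rho, "p": p_rho}
        except ValueError as exc:
            entry["pearson"] = {"note": str(exc)}
        entry["stiffness_tests"] = _stiffness_tests(cfg, cls, ci, sim_p)
        stats[cls] = entry
    return stats


def _stiffness_tests(cfg: RunConfig, cls: str, ci: int, true_mmhg: np.ndarray):
    """Paired tests across the stiffness levels on stiffness-matched pressures.

    The contact chain gives dP = 1, so the true pressure set is identical
    across levels; each level's set is read through the instrument model and
    the pairwise paired t tests (Bonferroni-corrected) look for a stiffness
    effect that, by construction of the physics, is not there.
    """
    levels = cfg.stiffness_levels
    if len(levels) < 2:
        return {"note": "n/a: fewer than two stiffness levels, no paired tests"}
    if len(true_mmhg) < 3:
        return {"note": "n/a: too few observations for paired tests"}
    readings = {}
    for li, E in enumerate(levels):
        rng = _measure_rng(cfg.seed, _NS_GROUP_MEAS, ci, li)
        readings[E] = simulate_picopress(true_mmhg, rng=rng)
    groups = []
    for i, Ei in enumerate(levels):
        for Ej in levels[i + 1 :]:
            groups.append(
                PairedPressureSet(
                    x=tuple(readings[Ei]),
                    y=tuple(readings[Ej]),
                    name=f"E{Ei:g}_vs_E{Ej:g}",
                )
            )
    table = paired_t_bonferroni(groups)
    return {
        "comparisons": table.to_dict(orient="records"),
        "any_significant": bool(table["significant"].any()),
    }


def stiffness_significance_fraction(
    true_mmhg,
    n_levels: int = 3,
    n_seeds: int = 100,
    seed: int = 0,
    noise_mmhg: float = 3.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of instrument-noise realisations with no stiffness effect.

    For each realisation the same true pressure set (stiffness-matched,
    dP = 1) is read ``n_levels`` times through the +/-noise instrument
    model and all pairwise paired t tests are Bonferroni-corrected; a
    realisation counts as clean when none is significant at ``alpha``.
    """
    true_mmhg = np.asarray(true_mmhg, dtype=float)
    clean = 0
    for s in range(n_seeds):
        readings = []
        for li in range(n_levels):
            rng = _measure_rng(seed, _NS_GROUP_MEAS, s, li)
            readings.append(simulate_picopress(true_mmhg, rng=rng, noise_mmhg=noise_mmhg))
        groups = [
            PairedPressureSet(x=tuple(readings[i]), y=tuple(readings[j]), name=f"{i}v{j}")
            for i in range(n_levels)
            for j in range(i + 1, n_levels)
        ]
        table = paired_t_bonferroni(groups, alpha=alpha)
        if not table["significant"].any():
            clean += 1
    return clean / n_seeds


def cohort_true_pressures(
    cohort: CohortSpec,
    solver: SolverConfig | None = None,
    compression_class: str = "I",
    rigid_modulus: float = 3.0e9,
) -> np.ndarray:
    """Rigid-leg equilibrium pressures (mmHg) over a cohort, one per
    subject x position — the stiffness-matched true pressure set."""
    solver = solver or SolverConfig()
    out = []
    for s in range(cohort.n_subjects):
        leg = as_rigid(generate_leg(cohort, s), E=rigid_modulus, nu=0.3)
        garments = generate_garment_set(compression_class, cohort.seed, leg, subject_index=s)
        for pos in POSITION_ORDER:
            if pos in garments:
                res = solve_equilibrium(GarmentFit(garments[pos], leg, pos), solver)
                out.append(res.P_mmhg)
    return np.asarray(out)


def make_report(results: dict, output_dir: str | Path) -> dict[str, Path]:
    """Write the comparison tables and stats as CSV + JSON (stable ordering).

    mmHg columns are rounded to 2 decimal places in the CSV tables; the
    JSON report keeps full precision and carries the provenance block.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pressures = results["pressures"].copy()
    pressures["P_mmHg"] = pressures["P_mmHg"].round(2)
    pressures["w_mm"] = pressures["w_mm"].round(4)
    paths["pressures"] = outdir / "pressures.csv"
    pressures.to_csv(paths["pressures"], index=False)

    if len(results.get("delta_p", [])):
        paths["delta_p"] = outdir / "delta_p.csv"
        results["delta_p"].to_csv(paths["delta_p"], index=False)

    paths["stats"] = outdir / "stats.json"
    with open(paths["stats"], "w") as fh:
        json.dump(results.get("stats", {}), fh, indent=2, sort_keys=True, default=float)

    paths["report"] = outdir / "report.json"
    report = {
        "meta": results.get("meta", {}),
        "stats": results.get("stats", {}),
        "pressures": json.loads(
            results["pressures"].to_json(orient="records", double_precision=10)
        ),
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    logger.info("report written to %s", outdir)
    return paths
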