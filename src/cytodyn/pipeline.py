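"""End-to-end orchestration: data -> filter -> stats -> DyNA -> velocities -> DyHyp -> Boolean.

A :class:`PipelineConfig` fully determines a run; outputs land under one
directory with a JSON manifest recording, per stage, the parameters, output
files and SHA-256 checksums, so identical config+seed gives identical
checksums. Stages form a dependency chain on the data side (the Boolean
model is independent of the measurement data); a stage failure is recorded
in the manifest and its dependents are skipped while independent stages
still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import core_data, dyhyp, dyna, group_stats, rate_of_change, switch, synthetic

logger = logging.getLogger("cytodyn")

#: Stage order and data-dependency parents.
STAGE_DEPS = {
    "data": (),
    "filter": ("data",),
    "stats": ("filter",),
    "dyna": ("filter", "stats"),
    "velocity": ("filter",),
    "dyhyp": ("velocity",),
    "boolean": (),
}


@dataclass
class PipelineConfig:
    """Everything one run needs.

    ``input_path`` loads a CSV/TSV table; if None, a synthetic cohort is
    generated from ``cohort_config`` (defaulting to the study-shaped cohort).
    Velocity contrasts are (from, to, duration, unit) tuples; by default the
    7-day surgery contrasts and the 3-hour LPS contrasts.
    """

    input_path: str | None = None
    cohort_config: synthetic.CohortConfig | None = None
    out_dir: str = "cytodyn_out"
    seed: int = 0
    k_sd: float = 2.0
    p_gate: float = 0.05
    alpha: float = 0.05
    r_threshold: float = 0.90
    strong_threshold: float = 0.95
    lps_r_threshold: float = 0.95
    contrasts: tuple = synthetic.VELOCITY_CONTRASTS
    conditions: tuple = ("baseline", "sham", "vagotomy")
    boolean_n_runs: int = 1000
    boolean_steps: int = 10
    boolean_injury: int = 0
    stages: tuple = tuple(STAGE_DEPS)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        for name, p in (("p_gate", self.p_gate), ("alpha", self.alpha)):
            if not 0 < p < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        for name, r in (("r_threshold", self.r_threshold),
                        ("strong_threshold", self.strong_threshold)):
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.stages) - set(STAGE_DEPS)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and return the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    done: set[str] = set()
    ctx: dict = {}

    def record(stage: str, params: dict, files: list[Path]):
        manifest["stages"][stage] = {
            "status": "ok",
            "parameters": params,
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
        }
        done.add(stage)

    def fail(stage: str, err: Exception):
        logger.error("stage %s failed: %s", stage, err)
        manifest["stages"][stage] = {"status": "error", "reason": str(err)}

    for stage in [s for s in STAGE_DEPS if s in config.stages]:
        missing = [d for d in STAGE_DEPS[stage] if d in config.stages and d not in done]
        if missing:
            manifest["stages"][stage] = {
                "status": "skipped",
                "reason": f"dependency failed: {', '.join(missing)}",
            }
            continue
        try:
            if stage == "data":
                if config.input_path is not None:
                    table = core_data.load_measurements(config.input_path)
                    truth = None
                else:
                    cc = config.cohort_config or synthetic.study_default_config(
                        seed=config.seed
                    )
                    table, truth = synthetic.generate_cohort(cc)
                f = out / "measurements.csv"
                table.to_csv(f, index=False)
                files = [f]
                if truth is not None:
                    g = out / "ground_truth.json"
                    g.write_text(json.dumps(truth.to_json(), indent=1))
                    files.append(g)
                ctx["table"] = table
                record(stage, {"input": config.input_path or "synthetic",
                               "n_records": len(table)}, files)
            elif stage == "filter":
                filtered, report = core_data.remove_outliers(ctx["table"], config.k_sd)
                f = out / "measurements_filtered.csv"
                filtered.to_csv(f, index=False)
                r = out / "outlier_report.json"
                r.write_text(json.dumps(report.to_json_records(), indent=1))
                ctx["filtered"] = filtered
                record(stage, {"k_sd": config.k_sd,
                               "n_removed": len(report.removed)}, [f, r])
            elif stage == "stats":
                df = ctx["filtered"]
                comparisons, gates = [], {}
                for tissue in sorted(df["tissue"].unique()):
                    meds = sorted(
                        df.loc[df["tissue"] == tissue, "mediator"].unique()
                    )
                    for mediator in meds:
                        try:
                            comparisons.append(
                                group_stats.anova_tukey(
                                    df, tissue, mediator, config.conditions,
                                    alpha=config.alpha,
                                )
                            )
                        except group_stats.InsufficientDataError as e:
                            logger.info("anova skipped: %s", e)
                    for cond in config.conditions:
                        if cond == "baseline":
                            continue
                        gates[(tissue, cond)] = group_stats.gate_mediators(
                            df, tissue, cond, meds, p_threshold=config.p_gate
                        )
                f = out / "anova_tukey.csv"
                group_stats.comparisons_to_frame(comparisons).to_csv(f, index=False)
                g = out / "change_gates.json"
                g.write_text(json.dumps(
                    [
                        {"tissue": t, "condition": c, "mediator": gate.mediator,
                         "p": gate.t_p, "passes": gate.passes}
                        for (t, c), gs in sorted(gates.items()) for gate in gs
                    ],
                    indent=1,
                ))
                ctx["gates"] = gates
                record(stage, {"alpha": config.alpha, "p_gate": config.p_gate}, [f, g])
            elif stage == "dyna":
                df = ctx["filtered"]
                networks = []
                for (tissue, cond), gs in sorted(ctx["gates"].items()):
                    thr = (config.lps_r_threshold if cond.endswith("_lps")
                           else config.r_threshold)
                    net = dyna.build_dyna(
                        df, tissue, cond, gs,
                        r_threshold=thr,
                        strong_threshold=config.strong_threshold,
                    )
                    networks.append(net)
                    net.write_graphml(out / f"dyna_{tissue.replace(' ', '_')}_{cond}.graphml")
                f = out / "dyna_complexity.csv"
                dyna.complexity_table(networks).to_csv(f, index=False)
                ctx["networks"] = networks
                files = [f] + sorted(out.glob("dyna_*.graphml"))
                record(stage, {"r_threshold": config.r_threshold,
                               "strong_threshold": config.strong_threshold}, files)
            elif stage == "velocity":
                df = ctx["filtered"]
                conditions = set(df["condition"].unique())
                velocities, profiles = [], []
                for from_c, to_c, duration, unit in config.contrasts:
                    if from_c not in conditions or to_c not in conditions:
                        continue
                    tissues = sorted(
                        set(df.loc[df["condition"] == from_c, "tissue"])
                        & set(df.loc[df["condition"] == to_c, "tissue"])
                    )
                    mediators = sorted(df["mediator"].unique())
                    for mediator in mediators:
                        per_tissue = []
                        for tissue in tissues:
                            try:
                                v = rate_of_change.compute_velocity(
                                    df, tissue, mediator, from_c, to_c,
                                    duration, per=unit,
                                )
                            except core_data.MissingGroupError:
                                continue
                            per_tissue.append(v)
                        velocities.extend(per_tissue)
                        if per_tissue:
                            prof = rate_of_change.rank_tissue_velocities(per_tissue)
                            rate_of_change.fit_logistic(prof)
                            profiles.append(prof)
                f = out / "velocities.csv"
                rate_of_change.velocity_table(velocities).to_csv(f, index=False)
                p = out / "ranked_profiles.json"
                p.write_text(json.dumps(
                    [
                        {"mediator": pr.mediator, "condition": pr.condition,
                         "tissues": pr.tissues, "velocities": pr.velocities,
                         "zero_crossing_index": pr.zero_crossing_index,
                         "logistic_fit": pr.logistic_fit}
                        for pr in profiles
                    ],
                    indent=1,
                ))
                ctx["velocities"] = velocities
                record(stage, {"contrasts": [list(c) for c in config.contrasts]},
                       [f, p])
            elif stage == "dyhyp":
                by_pair: dict = {}
                for v in ctx["velocities"]:
                    by_pair.setdefault((v.from_condition, v.to_condition), []).append(v)
                files = []
                for (from_c, to_c), vels in sorted(by_pair.items()):
                    by_tissue: dict = {}
                    for v in vels:
                        by_tissue.setdefault(v.tissue, []).append(v)
                    edge_sets = [
                        dyhyp.select_edge_mediators(vs)
                        for vs in by_tissue.values()
                    ]
                    model = dyhyp.build_dyhyp(edge_sets)
                    tag = f"{from_c}_to_{to_c}"
                    f = out / f"dyhyp_{tag}.json"
                    nets = [n for n in ctx.get("networks", [])
                            if n.condition == to_c]
                    f.write_text(json.dumps(dyhyp.overlay_dyna(model, nets), indent=1))
                    d = out / f"dyhyp_{tag}_edge_distribution.csv"
                    dyhyp.edge_distribution(model).to_csv(d, index=False)
                    files += [f, d]
                record(stage, {"rule": "one SD beyond sign-class mean"}, files)
            elif stage == "boolean":
                files = []
                for variant in switch.VARIANTS:
                    traj = switch.simulate_ensemble(
                        variant,
                        injury=config.boolean_injury,
                        n_runs=config.boolean_n_runs,
                        steps=config.boolean_steps,
                        seed=config.seed,
                    )
                    f = out / f"switch_{variant}_trajectory.csv"
                    traj.to_frame().to_csv(f, index=False)
                    diagram = switch.build_transition_diagram(
                        variant, injury=config.boolean_injury
                    )
                    g = out / f"switch_{variant}_states.json"
                    g.write_text(json.dumps(
                        {
                            "complexity": diagram.complexity,
                            "fixed_points": [list(s) for s in diagram.fixed_points],
                        },
                        indent=1,
                    ))
                    d = out / f"switch_{variant}.dot"
                    d.write_text(diagram.to_dot())
                    files += [f, g, d]
                record(stage, {"n_runs": config.boolean_n_runs,
                               "steps": config.boolean_steps,
                               "injury": config.boolean_injury}, files)
        except Exception as e:  # noqa: BLE001 — stage isolation by design
            fail(stage, e)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
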