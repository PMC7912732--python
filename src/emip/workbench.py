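"""End-to-end pipeline orchestration from a single structured config.

A run config (YAML or dict) names an ordered subset of stages —
``fixtures, simulate, cavities, aim, calibrate, eis, thickness`` — with
one parameter block per stage, an output directory and a global seed.
Each stage writes its outputs (CSV + files) into its own subdirectory
and appends to a consolidated plain-text report.  Per-stage seeds fan
out deterministically from the global seed, so re-running an identical
config reproduces every numeric output; completed stages whose
parameter checksum and outputs are intact are skipped on re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aim as aim_mod
from . import cavity as cavity_mod
from . import electro, mc, synthetic
from .topology import read_topology, read_trajectory, write_topology, \
    write_trajectory

log = logging.getLogger("emip")

STAGE_ORDER = ("fixtures", "simulate", "cavities", "aim", "calibrate",
               "eis", "thickness")


class PipelineError(RuntimeError):
    pass


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), STAGE_ORDER.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_done(stage_dir: Path, digest: str) -> bool:
    stamp = stage_dir / "stage.json"
    if not stamp.exists():
        return False
    try:
        return json.loads(stamp.read_text()).get("checksum") == digest
    except (json.JSONDecodeError, OSError):
        return False


def _mark_done(stage_dir: Path, digest: str) -> None:
    (stage_dir / "stage.json").write_text(
        json.dumps({"checksum": digest}) + "\n")


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {source} did not parse to a mapping")
    return cfg


def run_pipeline(source, output_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order; returns the output dir.

    Raises :class:`PipelineError` naming the failing stage.
    """
    cfg = load_config(source)
    out = Path(output_dir or cfg.get("output_dir", "emip_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages")
    if not stages:
        raise PipelineError("config must list at least one stage")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
    stages = sorted(set(stages), key=STAGE_ORDER.index)
    report_lines = [f"emip pipeline run (seed {seed})", ""]
    context: dict = {}
    for stage in stages:
        params = cfg.get(stage, {}) or {}
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        digest = _checksum({"params": params, "seed": seed})
        try:
            runner = _RUNNERS[stage]
            if _stage_done(stage_dir, digest) and stage not in \
                    ("simulate", "cavities"):
                log.info("stage %s up to date, skipping", stage)
                lines = [f"[{stage}] skipped (outputs up to date)"]
                _reload_context(stage, stage_dir, context)
            else:
                lines = runner(params, stage_dir,
                               _stage_seed(seed, stage), context)
                _mark_done(stage_dir, digest)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        report_lines.extend(lines + [""])
    report = out / "report.txt"
    report.write_text("\n".join(report_lines) + "\n")
    return out


def _reload_context(stage: str, stage_dir: Path, context: dict) -> None:
    """Minimal context restore so later stages can reuse skipped outputs."""
    if stage == "fixtures":
        for key, name in (("calibration_csv", "calibration.csv"),
                          ("eis_csv", "eis.csv"), ("bcp_csv", "bcp.csv")):
            p = stage_dir / name
            if p.exists():
                context[key] = p
    elif stage == "simulate":
        p = stage_dir / "trajectory.xyz"
        if p.exists():
            context["trajectory"] = p


# ---------------------------------------------------------------------------
# stage runners — each returns report lines and updates the shared context
# ---------------------------------------------------------------------------

def _run_fixtures(params: dict, stage_dir: Path, seed: int,
                  context: dict) -> list[str]:
    lines = ["[fixtures]"]
    cal_params = params.get("calibration", {})
    df, truth = synthetic.gen_calibration(seed=seed, **cal_params)
    cal_csv = stage_dir / "calibration.csv"
    df.to_csv(cal_csv, index=False)
    (stage_dir / "calibration.truth.json").write_text(
        json.dumps(truth, indent=1) + "\n")
    context["calibration_csv"] = cal_csv
    lines.append(f"calibration series: {len(df)} points -> {cal_csv.name}")

    eis_params = params.get("eis", {})
    spectrum, truth = synthetic.gen_eis(seed=seed, **eis_params)
    eis_csv = stage_dir / "eis.csv"
    pd.DataFrame({"frequency": spectrum.frequency,
                  "z_real": spectrum.z_real,
                  "z_imag": spectrum.z_imag}).to_csv(eis_csv, index=False)
    (stage_dir / "eis.truth.json").write_text(
        json.dumps(truth, indent=1) + "\n")
    context["eis_csv"] = eis_csv
    lines.append(f"EIS spectrum: {spectrum.frequency.size} points -> "
                 f"{eis_csv.name}")

    bcp_params = params.get("bcp", {})
    table, labels = synthetic.gen_bcp_table(seed=seed, **bcp_params)
    bcp_csv = stage_dir / "bcp.csv"
    table.to_csv(bcp_csv, index=False)
    (stage_dir / "bcp.truth.json").write_text(
        json.dumps({"labels": labels}, indent=1) + "\n")
    context["bcp_csv"] = bcp_csv
    lines.append(f"BCP table: {len(table)} rows -> {bcp_csv.name}")
    return lines


def _run_simulate(params: dict, stage_dir: Path, seed: int,
                  context: dict) -> list[str]:
    template, monomer, solvent = synthetic.make_toy_system()
    for topo in (template, monomer, solvent):
        write_topology(topo, stage_dir / f"{topo.name}.top")
    spec_params = dict(params.get("spec", {}))
    spec_params.setdefault("rng_seed", seed)
    spec = mc.SimulationSpec(**spec_params)
    initial = mc.build_layered_initial(
        template, monomer, solvent,
        n_monomer=int(params.get("n_monomer", 30)),
        n_solvent=int(params.get("n_solvent", 60)),
        target_density=float(params.get("density", 0.75)),
        temperature=spec.temperature, pressure=spec.pressure, seed=seed)
    frames, records = mc.run_simulation(initial, spec, collect_records=True)
    traj = stage_dir / "trajectory.xyz"
    write_trajectory(frames, traj)
    context["trajectory"] = traj
    context["topologies"] = {t.name: t for t in (template, monomer, solvent)}
    stats = pd.DataFrame([{"move_kind": r.move_kind,
                           "accepted": r.accepted} for r in records])
    summary = stats.groupby("move_kind")["accepted"].agg(["count", "mean"])
    summary.to_csv(stage_dir / "move_stats.csv")
    lines = ["[simulate]",
             f"{spec.n_parallel_runs} run(s), {spec.n_production} production "
             f"steps each, stride {spec.snapshot_stride} -> "
             f"{len(frames)} frames"]
    for kind, row in summary.iterrows():
        lines.append(f"{kind}: {int(row['count'])} moves, acceptance "
                     f"{row['mean']:.2f}")
    return lines


def _run_cavities(params: dict, stage_dir: Path, seed: int,
                  context: dict) -> list[str]:
    topologies = context.get("topologies")
    if topologies is None:
        topo_files = params.get("topologies")
        if not topo_files:
            raise PipelineError(
                "cavities stage needs simulate output or 'topologies' files")
        topos = [read_topology(p) for p in topo_files]
        topologies = {t.name: t for t in topos}
    traj = context.get("trajectory") or params.get("trajectory")
    if traj is None:
        raise PipelineError("cavities stage needs a trajectory")
    frames = read_trajectory(traj, topologies)
    cutoff = params.get("shell_cutoff", cavity_mod.DEFAULT_SHELL_CUTOFF)
    if cutoff == "auto":
        cutoff = cavity_mod.shell_cutoff_from_rdf(frames)
    cavities = [cavity_mod.extract_first_shell(f, float(cutoff))
                for f in frames]
    report = cavity_mod.population_report(cavities)
    pop = cavity_mod.population_frame(report)
    pop.to_csv(stage_dir / "population.csv", index=False)
    lines = ["[cavities]",
             f"{len(frames)} frames, shell cutoff {float(cutoff):.2f} Å",
             f"population groups: {len(report)} "
             f"(sizes {pop.n_monomers.min()}–{pop.n_monomers.max()})"]
    funnel_params = params.get("funnel")
    if funnel_params:
        fspec = cavity_mod.FunnelSpec(
            stage1_cutoff=float(funnel_params.get("stage1_cutoff", 10.0)),
            stage2_cutoff=float(funnel_params.get("stage2_cutoff", 5.0)),
            group_range=tuple(funnel_params.get("group_range", (16, 25))))
        fr = cavity_mod.funnel_select(cavities, fspec)
        fr.to_frame().to_csv(stage_dir / "funnel.csv", index=False)
        lines.append(f"funnel: {fr.total_stage1_survivors} stage-1 / "
                     f"{fr.total_stage2_survivors} stage-2 survivors")
    context["cavities"] = cavities
    return lines


def _run_aim(params: dict, stage_dir: Path, seed: int,
             context: dict) -> list[str]:
    bcp_csv = params.get("table") or context.get("bcp_csv")
    if bcp_csv is None:
        raise PipelineError("aim stage needs a BCP table (fixtures stage "
                            "or 'table' parameter)")
    records = aim_mod.read_bcp_table(
        bcp_csv, h_tol=float(params.get("htol", aim_mod.DEFAULT_H_TOL)))
    aim_mod.write_bcp_table(records, stage_dir / "bcp_annotated.csv")
    summary = aim_mod.cavity_interaction_summary(records)
    summary.to_csv(stage_dir / "interaction_summary.csv", index=False)
    total = summary[summary.cavity_id == "TOTAL"].iloc[0]
    return ["[aim]",
            f"{len(records)} BCPs, {int(total.n_noncovalent)} non-covalent, "
            f"sum BE {total.sum_BE:.3f} kcal/mol "
            f"(mean |BE| {total.mean_abs_BE:.3f})"]


def _run_calibrate(params: dict, stage_dir: Path, seed: int,
                   context: dict) -> list[str]:
    csv = params.get("table") or context.get("calibration_csv")
    if csv is None:
        raise PipelineError("calibrate stage needs a calibration table")
    df = pd.read_csv(csv)
    result = electro.fit_calibration(
        df["concentration"], df["current"],
        lod_rule=params.get("lod_rule", "intercept_se"),
        s_blank=params.get("s_blank"))
    pd.DataFrame([vars(result)]).to_csv(stage_dir / "calibration_fit.csv",
                                        index=False)
    return ["[calibrate]",
            f"slope {result.slope:.4e} A/(mol/L), intercept "
            f"{result.intercept:.3e} A, r² {result.r_squared:.5f}",
            f"LOD {result.lod:.3e} mol/L, LOQ {result.loq:.3e} mol/L"]


def _run_eis(params: dict, stage_dir: Path, seed: int,
             context: dict) -> list[str]:
    csv = params.get("table") or context.get("eis_csv")
    if csv is None:
        raise PipelineError("eis stage needs a spectrum table")
    df = pd.read_csv(csv)
    spectrum = electro.EISSpectrum(df["frequency"].to_numpy(),
                                   df["z_real"].to_numpy(),
                                   df["z_imag"].to_numpy())
    fit = electro.fit_randles(spectrum)
    row = {**vars(fit.model),
           **{f"se_{k}": v for k, v in fit.stderr.items()},
           "residual_norm": fit.residual_norm,
           "pinned": ";".join(fit.pinned), "converged": fit.converged}
    pd.DataFrame([row]).to_csv(stage_dir / "randles_fit.csv", index=False)
    return ["[eis]",
            f"R_s {fit.model.r_s:.1f} Ω, R_ct {fit.model.r_ct:.1f} Ω, "
            f"CPE Q {fit.model.cpe_q:.3e} S·s^n, n {fit.model.cpe_n:.3f}"]


def _run_thickness(params: dict, stage_dir: Path, seed: int,
                   context: dict) -> list[str]:
    inp = electro.FilmThicknessInput(
        q=float(params["q"]), M=float(params.get("M", 108.14)),
        rho=float(params.get("rho", 1.2)), A=float(params.get("A", 0.1257)),
        n_electrons=int(params.get("n_electrons", 2)))
    h = electro.film_thickness(inp)
    pd.DataFrame([{**vars(inp), "h_nm": h}]).to_csv(
        stage_dir / "thickness.csv", index=False)
    return ["[thickness]", f"film thickness {h:.2f} nm"]


_RUNNERS = {
    "fixtures": _run_fixtures,
    "simulate": _run_simulate,
    "cavities": _run_cavities,
    "aim": _run_aim,
    "calibrate": _run_calibrate,
    "eis": _run_eis,
    "thickness": _run_thickness,
}
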