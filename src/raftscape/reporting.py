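"""End-to-end pipeline orchestration and report assembly.

One YAML configuration tree drives four stages on a single synthetic
cohort: simulate (cohort generation), stats (forest table, PCA,
correlation heatmaps, slope regressions), viscosity (anisotropy
synthesis, model fit, group fluidity contrast) and abm (group membrane
simulations).  Every stage writes plain CSV/JSON keyed by the manifest,
and everything is deterministic given the configured seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lipid_core import SubjectRecord, read_cohort, write_cohort
from .raft_abm import AbmConfig, composition_from_profiles, simulate_group
from .stats_pipeline import (
    compare_slopes,
    correlation_heatmap,
    forest_table,
    pca_signature,
    simple_regression,
    subject_table,
)
from .synthetic_cohort import default_config, generate_anisotropy, generate_cohort, load_config
from .viscosity import (
    ViscosityParams,
    calibrate_intercept,
    compare_group_viscosity,
    fit_viscosity_model,
    perrin_viscosity,
)

__all__ = ["RunManifest", "run_pipeline", "render_report", "PipelineConfigError",
           "run_stats_stage", "run_viscosity_stage", "run_abm_stage"]

log = logging.getLogger("raftscape")

#: default heatmap axes: phospholipid/sphingolipid classes vs the fatty-acid
#: group variables the correlation analysis focuses on
HEATMAP_ROWS = ("PC", "PE", "PS", "PI", "PG", "SM", "SULF")
HEATMAP_COLS = (
    "total_dma", "total_n3", "total_n6", "total_lcpufa", "sat_unsat_ratio",
    "20:4n-6", "22:6n-3",
)

STAGES = ("simulate", "stats", "viscosity", "abm")


class PipelineConfigError(ValueError):
    """Aggregated configuration validation failure."""


@dataclass
class RunManifest:
    config_path: str
    config_hash: str
    seed: int
    version: str = __version__
    outputs: dict[str, list[str]] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def _validate(cfg: dict) -> None:
    problems = []
    if "seed" not in cfg:
        problems.append("missing top-level 'seed'")
    if "out_dir" not in cfg:
        problems.append("missing top-level 'out_dir'")
    cohort = cfg.get("cohort")
    if cohort is None:
        problems.append("missing 'cohort' section")
    elif "config" not in cohort and not (
        "n_nsl" in cohort and "n_als" in cohort
    ):
        problems.append("cohort section needs 'config' or both 'n_nsl' and 'n_als'")
    if problems:
        raise PipelineConfigError("; ".join(problems))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_stats_stage(
    records: Sequence[SubjectRecord], out_dir: Path,
    heatmap_rows: Sequence[str] = HEATMAP_ROWS,
    heatmap_cols: Sequence[str] = HEATMAP_COLS,
    n_components: int = 2,
) -> list[str]:
    """Forest table, PCA, heatmaps and CHO-SE regressions; returns file list."""
    outputs = []
    table = subject_table(records)

    forest = forest_table(records)
    p = out_dir / "forest_table.csv"
    forest.to_csv(p)
    outputs.append(str(p))

    variables = [c for c in table.columns if c != "group" and table[c].notna().all()]
    pca = pca_signature(table[variables], table["group"].to_numpy(), n_components=n_components)
    payload = {
        "variance_fraction": pca.variance_fraction.tolist(),
        "anova_f": pca.anova_f.tolist(),
        "anova_p": pca.anova_p.tolist(),
        "loadings": pca.loadings.to_dict(),
        "scores": pca.scores.to_dict(),
        "dropped": list(pca.dropped),
    }
    p = out_dir / "pca.json"
    p.write_text(json.dumps(payload, indent=2, default=_json_default))
    outputs.append(str(p))

    heat = correlation_heatmap(records, heatmap_rows, heatmap_cols, value_frame=table)
    for g, mat in heat.r_squared.items():
        p = out_dir / f"heatmap_{g.lower()}.csv"
        mat.to_csv(p)
        outputs.append(str(p))
    p = out_dir / "heatmap_diff.csv"
    heat.difference_q.to_csv(p)
    outputs.append(str(p))

    cho = table["CHO"].to_numpy(dtype=float)
    se = table["SE"].to_numpy(dtype=float)
    pooled = simple_regression(cho, se)
    slopes = compare_slopes(cho, se, table["group"].to_numpy())
    reg_payload = {
        "cho_se_pooled": dataclasses.asdict(pooled),
        "cho_se_slopes": dataclasses.asdict(slopes),
    }
    p = out_dir / "regressions.json"
    p.write_text(json.dumps(reg_payload, indent=2, default=_json_default))
    outputs.append(str(p))
    return outputs


def run_viscosity_stage(
    records: Sequence[SubjectRecord], out_dir: Path,
    noise_sd: float = 0.005, target_pct_fluidity: float = 14.8, seed: int = 0,
    anisotropy: dict[str, float] | None = None,
) -> list[str]:
    """Synthesize (or take) anisotropies, fit the model, compare groups."""
    base = ViscosityParams()
    if anisotropy is None:
        params_true = calibrate_intercept(records, base, target_pct_fluidity)
        anisotropy = generate_anisotropy(records, params_true, noise_sd=noise_sd, seed=seed)
    eta_obs = {
        sid: perrin_viscosity(r, base) for sid, r in anisotropy.items()
    }
    fitted = fit_viscosity_model(records, eta_obs)
    result = compare_group_viscosity(records, eta_obs=eta_obs)
    payload = {
        "fitted": {
            "coefficients": fitted.coefficients,
            "intercept": fitted.intercept,
            "r_squared": fitted.r_squared,
            "coef_se": fitted.coef_se,
            "r0": fitted.r0,
            "calib_c": fitted.calib_c,
        },
        "comparison": {
            "group_means": result.group_means,
            "pct_fluidity_change": result.pct_fluidity_change,
            "cohens_d": result.effect_d,
            "ci": list(result.effect_ci),
        },
        "anisotropy": anisotropy,
    }
    p = out_dir / "viscosity.json"
    p.write_text(json.dumps(payload, indent=2, default=_json_default))
    return [str(p)]


def _group_mean_composition(records: Sequence[SubjectRecord], group: str):
    members = [r for r in records if r.group == group]
    comps = [composition_from_profiles(r.fatty_acids, r.lipid_classes) for r in members]
    keys = comps[0].keys()
    mean = {g: float(np.mean([c[g] for c in comps])) for g in keys}
    total = sum(mean.values())
    return {g: v / total for g, v in mean.items()}


def run_abm_stage(
    records: Sequence[SubjectRecord], out_dir: Path,
    lattice_size: int = 64, sweeps_burnin: int = 500, sweeps_measure: int = 200,
    replicates: int = 5, seed: int = 0,
) -> list[str]:
    """Simulate each group's mean membrane composition."""
    payload = {}
    for i, group in enumerate(sorted({r.group for r in records})):
        comp = _group_mean_composition(records, group)
        res = simulate_group(
            comp,
            n_replicates=replicates,
            seed=seed + i,
            lattice_size=lattice_size,
            sweeps_burnin=sweeps_burnin,
            sweeps_measure=sweeps_measure,
        )
        payload[group] = {
            "composition": {g.name: v for g, v in comp.items()},
            **res,
        }
    p = out_dir / "abm_summary.json"
    p.write_text(json.dumps(payload, indent=2, default=_json_default))
    return [str(p)]


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute simulate -> stats -> viscosity -> abm from one YAML config."""
    config_path = Path(config_path)
    raw = config_path.read_text()
    cfg = yaml.safe_load(raw)
    _validate(cfg)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_path=str(config_path),
        config_hash=hashlib.sha256(raw.encode()).hexdigest()[:16],
        seed=seed,
    )
    log.info("pipeline start: config=%s hash=%s seed=%d", config_path, manifest.config_hash, seed)

    stages_enabled = cfg.get("stages", list(STAGES))

    records = None
    for stage in STAGES:
        if stage not in stages_enabled:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                c = cfg["cohort"]
                if c.get("config"):
                    cohort_cfg = load_config(c["config"])
                else:
                    cohort_cfg = default_config(
                        n_nsl=int(c["n_nsl"]), n_als=int(c["n_als"]), seed=seed
                    )
                records = generate_cohort(cohort_cfg)
                p = out_dir / "cohort.csv"
                write_cohort(records, p)
                manifest.outputs["simulate"] = [str(p)]
            elif stage == "stats":
                records = records or read_cohort(out_dir / "cohort.csv")
                s = cfg.get("stats", {})
                manifest.outputs["stats"] = run_stats_stage(
                    records, out_dir,
                    heatmap_rows=s.get("heatmap_rows", HEATMAP_ROWS),
                    heatmap_cols=s.get("heatmap_cols", HEATMAP_COLS),
                    n_components=int(s.get("n_components", 2)),
                )
            elif stage == "viscosity":
                records = records or read_cohort(out_dir / "cohort.csv")
                v = cfg.get("viscosity", {})
                manifest.outputs["viscosity"] = run_viscosity_stage(
                    records, out_dir,
                    noise_sd=float(v.get("noise_sd", 0.005)),
                    target_pct_fluidity=float(v.get("target_pct_fluidity", 14.8)),
                    seed=seed,
                )
            elif stage == "abm":
                records = records or read_cohort(out_dir / "cohort.csv")
                a = cfg.get("abm", {})
                manifest.outputs["abm"] = run_abm_stage(
                    records, out_dir,
                    lattice_size=int(a.get("lattice_size", 64)),
                    sweeps_burnin=int(a.get("sweeps_burnin", 500)),
                    sweeps_measure=int(a.get("sweeps_measure", 200)),
                    replicates=int(a.get("replicates", 5)),
                    seed=seed,
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.wall_clock[stage] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", stage, manifest.wall_clock[stage])

    manifest.save(out_dir / "manifest.json")
    for files in manifest.outputs.values():
        for f in files:
            assert Path(f).exists(), f"manifest lists missing output {f}"
    return manifest


_SECTIONS = (
    ("forest", "Effect sizes (forest table)", "stats", "forest_table.csv"),
    ("pca", "PCA lipid signature", "stats", "pca.json"),
    ("heatmap", "Correlation heatmaps", "stats", "heatmap_diff.csv"),
    ("slopes", "CHO-SE regression", "stats", "regressions.json"),
    ("viscosity", "Microviscosity comparison", "viscosity", "viscosity.json"),
    ("abm", "Membrane simulation contrast", "abm", "abm_summary.json"),
)


def render_report(manifest: RunManifest, out_path: str | Path | None = None) -> str:
    """Assemble a markdown report with one section per analysis product.

    Sections whose stage did not run are flagged as absent rather than
    silently dropped; an empty manifest is an error.
    """
    if not manifest.outputs:
        raise ValueError("empty manifest: no stage outputs to report")
    lines = [
        "# raftscape run report",
        "",
        f"- config: `{manifest.config_path}` (sha256 `{manifest.config_hash}`)",
        f"- seed: {manifest.seed}",
        f"- version: {manifest.version}",
        "",
    ]
    produced = {Path(f).name: Path(f) for files in manifest.outputs.values() for f in files}
    for key, title, stage, filename in _SECTIONS:
        lines.append(f"## {title}")
        lines.append("")
        if filename not in produced:
            lines.append(f"*absent — stage `{stage}` did not run*")
            lines.append("")
            continue
        path = produced[filename]
        if filename == "forest_table.csv":
            df = pd.read_csv(path, index_col=0)
            large = df[df["large_effect"] == True]  # noqa: E712
            lines.append(f"{len(df)} variables; {len(large)} large effects (|d| > 0.8):")
            lines.append("")
            lines.append(large[["d", "ci_low", "ci_high", "p_value", "pct_change"]]
                         .round(3).to_markdown())
        elif filename == "pca.json":
            d = json.loads(path.read_text())
            vf = [round(100 * v, 1) for v in d["variance_fraction"]]
            lines.append(f"variance explained (%): {vf}")
            lines.append(f"factor-score ANOVA p: {[f'{p:.3g}' for p in d['anova_p']]}")
        elif filename == "heatmap_diff.csv":
            df = pd.read_csv(path, index_col=0)
            lines.append("Cohen's q for the between-group correlation difference:")
            lines.append("")
            lines.append(df.round(2).to_markdown())
        elif filename == "regressions.json":
            d = json.loads(path.read_text())
            s = d["cho_se_slopes"]
            lines.append(
                f"per-group CHO->SE slopes: {s['beta_by_group']}; "
                f"interaction F = {s['f_stat']:.2f}, p = {s['p_value']:.3g}"
            )
        elif filename == "viscosity.json":
            d = json.loads(path.read_text())
            c = d["comparison"]
            lines.append(
                f"group mean eta (poise): {c['group_means']}; "
                f"fluidity change = {c['pct_fluidity_change']:.1f}%; "
                f"Cohen's d = {c['cohens_d']:.2f}"
            )
        elif filename == "abm_summary.json":
            d = json.loads(path.read_text())
            for group, res in d.items():
                agg = res["aggregate"]
                lines.append(
                    f"- **{group}**: rafts {agg['n_rafts']['mean']:.1f}, "
                    f"mean size {agg['mean_size']['mean']:.1f}, "
                    f"area fraction {agg['area_fraction']['mean']:.3f}, "
                    f"raft mobility {agg['mobility_raft']['mean']:.3f}, "
                    f"non-raft mobility {agg['mobility_nonraft']['mean']:.3f}"
                )
        lines.append("")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
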