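"""End-to-end orchestration: fitness table -> epistasis, paths, ANOVA reports.

``run_pipeline`` takes a :class:`RunConfig`, loads (or simulates) a tidy
fitness table, and writes one reproducible bundle of reports to the output
directory: the per-cell landscape summary, a per-environment epistasis table,
path and edge reports, the factorial ANOVA with its class-level variance
partition (when exactly two environments are analysed), and a plain-text
summary of the headline statistics.  Every decision flag (alpha, error
propagation, epistasis scale, accessibility mode, correction, seed) lives on
the config, and the config itself is serialized into the output directory so
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import epistasis as ep
from . import gxe_anova, paths
from .landscape import LocusSet, load_fitness_table, summarize
from .synthetic import default_spec, fitness_table_frame, simulate_fitness_table

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    fitness_table: str | None = None  # CSV path; None -> simulate the default spec
    locus_order: tuple[str, ...] = ("r", "t", "s", "g", "p")
    alpha: float = 0.05
    error_propagation: str = "quadrature"  # or "linear"
    epistasis_scale: str = "absolute"  # or "relative"
    accessibility_mode: str = "mean"  # or "significant"
    correction: str = "none"  # per-genotype epistasis calls
    edge_correction: str = "bonferroni"  # per-step classification
    anova_environments: tuple[str, str] | None = None
    seed: int = 0
    output_dir: str = "epiland_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("locus_order", "anova_environments"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["locus_order"] = list(self.locus_order)
        if self.anova_environments is not None:
            data["anova_environments"] = list(self.anova_environments)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        data = asdict(self)
        data.pop("output_dir")
        payload = json.dumps(data, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A stage-named failure of the analysis pipeline."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the in-memory results keyed by report name."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci = LocusSet(tuple(config.locus_order))

    # -- input ------------------------------------------------------------
    try:
        if config.fitness_table is not None:
            observations = load_fitness_table(config.fitness_table, loci)
        else:
            spec = default_spec()
            observations = simulate_fitness_table(spec, config.seed)
            _write(fitness_table_frame(observations), out / "fitness_table.csv")
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        landscape = summarize(observations)
    except ValueError as exc:
        raise PipelineError("summarize", str(exc)) from exc
    landscape.to_frame().to_csv(out / "landscape_summary.csv", index=False,
                                float_format=FLOAT_FORMAT)

    results: dict = {"landscape": landscape, "config": config}
    summary_lines = [f"epiland run (config {config.digest()}, seed {config.seed})", ""]

    # -- per-environment epistasis and paths ------------------------------
    envs = landscape.environments
    results["epistasis"] = {}
    results["paths"] = {}
    for env in envs:
        try:
            table = ep.epistasis_table(
                landscape, env,
                method=config.error_propagation,
                alpha=config.alpha,
                correction=config.correction,
            )
        except (ValueError, KeyError) as exc:
            raise PipelineError("epistasis", f"{env}: {exc}") from exc
        _write(table, out / f"epistasis_{env}.csv")
        results["epistasis"][env] = table
        m = ep.mean_epistasis(table["eps"])
        fit = ep.diminishing_returns_fit(table, scale=config.epistasis_scale, environment=env)
        n_sig = int(table["significant"].sum())
        summary_lines.append(
            f"{env}: mean epistasis {m.mean:+.4f} (95% CI {m.ci_low:+.4f}..{m.ci_high:+.4f}, "
            f"t={m.t:.3f}, df={m.df}, p={m.p:.4g}); {n_sig} genotypes significant"
        )
        summary_lines.append(
            f"{env}: diminishing-returns r = {fit.pearson_r:+.3f} (p={fit.p_value:.4g}, "
            f"SMA slope {fit.sma_slope:+.3f}, {fit.n_genotypes} genotypes)"
        )
        if landscape.is_complete(env):
            try:
                report = paths.paths_report(landscape, env, alpha=config.alpha)
                edges = paths.step_effects(
                    landscape, env, alpha=config.alpha, correction=config.edge_correction
                )
            except (ValueError, KeyError) as exc:
                raise PipelineError("paths", f"{env}: {exc}") from exc
            _write(report, out / f"paths_{env}.csv")
            _write(edges, out / f"edges_{env}.csv")
            results["paths"][env] = report
            col = ("accessible_mean" if config.accessibility_mode == "mean"
                   else "accessible_significant")
            n_acc = int(report[col].sum())
            pk = paths.peaks(landscape, env)
            summary_lines.append(
                f"{env}: {n_acc}/{len(report)} paths accessible ({config.accessibility_mode}); "
                f"global peak {'+'.join(pk['global_maximum'])}"
            )
        summary_lines.append("")

    # -- factorial ANOVA ---------------------------------------------------
    anova_envs = config.anova_environments
    if anova_envs is None and len(envs) >= 2:
        anova_envs = tuple(envs[:2])
    if anova_envs is not None:
        obs_df = fitness_table_frame(observations)
        obs_df = obs_df[obs_df["environment"].isin(anova_envs)]
        try:
            table = gxe_anova.anova(obs_df, loci)
        except ValueError as exc:
            raise PipelineError("anova", str(exc)) from exc
        part = gxe_anova.variance_partition(table)
        _write(table.terms, out / "anova.csv")
        _write(part, out / "variance_partition.csv")
        results["anova"] = table
        results["partition"] = part
        f, dfm, dfr, p = table.overall_f()
        gxgxe = float(part.loc[part["class"] == "GxGxE", "fraction"].iloc[0])
        summary_lines.append(
            f"factorial ANOVA over {anova_envs}: F_{dfm},{dfr} = {f:.3f} (p={p:.4g}); "
            f"GxGxE explains {100 * gxgxe:.1f}% of fitness variance"
        )

    summary_text = "\n".join(summary_lines) + "\n"
    (out / "summary.txt").write_text(summary_text)
    config.to_yaml(out / "config.yaml")
    results["summary_text"] = summary_text
    return results
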