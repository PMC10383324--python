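"""End-to-end orchestration: simulate -> contrasts -> fold filter/clustering
-> network modules -> pathway activity -> behavior statistics.

Stages communicate only through files in the run directory, so every
intermediate is inspectable, and a JSON manifest written last records the
config echo, package version, per-stage output checksums and record counts,
and every RNG seed -- enough to re-derive any p-value by hand.  Identical
config + seed gives bit-identical outputs and manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior as bh
from . import diffexpr, io, netmodules, pathways as pw
from . import synthetic as syn
from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)

STAGES = ["simulate", "contrast", "diffexpr", "modules", "pathways", "behavior"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    simulate: syn.SimulationScenario | None = None
    behavior_scenario: syn.BehaviorScenario | None = None
    # external inputs (used when simulate is None)
    abundance: Path | None = None
    samples: Path | None = None
    edges: Path | None = None
    gmt: Path | None = None
    behavior_sequences: Path | None = None
    behavior_explorations: Path | None = None
    # analysis knobs
    fold: float = 1.5
    alpha: float = 0.05
    n_perm_modules: int = 1000
    n_perm_pathways: int = 1000
    null: str = "sets"
    null_signs: str = "carry"
    contrast_summary: str = "linear-mean"


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config, aggregating every violation."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []

    out_dir = raw.get("out_dir")
    if not out_dir:
        errors.append("out_dir is required")
    seed = raw.get("seed", 0)
    analysis = raw.get("analysis", {}) or {}
    fold = float(analysis.get("fold", 1.5))
    alpha = float(analysis.get("alpha", 0.05))
    n_perm_m = int(analysis.get("n_perm_modules", analysis.get("n_perm", 1000)))
    n_perm_p = int(analysis.get("n_perm_pathways", analysis.get("n_perm", 1000)))
    null = analysis.get("null", "sets")
    null_signs = analysis.get("null_signs", "carry")
    if fold <= 1:
        errors.append(f"analysis.fold must be > 1, got {fold}")
    if not 0 < alpha < 1:
        errors.append(f"analysis.alpha must be in (0, 1), got {alpha}")
    if n_perm_m < 1 or n_perm_p < 1:
        errors.append("analysis.n_perm must be >= 1")
    if null not in ("sets", "ego"):
        errors.append(f"analysis.null must be 'sets' or 'ego', got {null!r}")
    if null_signs not in ("carry", "all-positive"):
        errors.append(f"analysis.null_signs invalid: {null_signs!r}")

    sim = None
    behav = None
    inputs = raw.get("inputs", {}) or {}
    paths = {k: Path(v) for k, v in inputs.items() if v}
    if "simulate" in raw:
        sim_raw = dict(raw.get("simulate") or {})
        sim_raw.setdefault("seed", seed)
        pm = [syn.PlantedModule(**d) for d in sim_raw.pop("planted_modules", [])]
        pp = [syn.PlantedPathway(**d) for d in sim_raw.pop("planted_pathways", [])]
        beh_raw = dict(sim_raw.pop("behavior", {}) or {})
        beh_raw.setdefault("seed", seed)
        try:
            if "groups" in sim_raw:
                sim_raw["groups"] = tuple(sim_raw["groups"])
            sim = syn.SimulationScenario(
                planted_modules=tuple(pm), planted_pathways=tuple(pp), **sim_raw)
            beh_raw.setdefault("groups", sim.groups)
            if "groups" in beh_raw:
                beh_raw["groups"] = tuple(beh_raw["groups"])
            behav = syn.BehaviorScenario(**beh_raw)
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"simulate: {exc}")
    else:
        required = ["abundance", "samples", "edges", "gmt"]
        for key in required:
            if key not in paths:
                errors.append(f"inputs.{key} is required when not simulating")
            elif not paths[key].exists():
                errors.append(f"inputs.{key}: file not found: {paths[key]}")
        for key in ("behavior_sequences", "behavior_explorations"):
            if key in paths and not paths[key].exists():
                errors.append(f"inputs.{key}: file not found: {paths[key]}")

    if errors:
        raise ConfigurationError(
            "invalid run config:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        out_dir=Path(out_dir), seed=int(seed), simulate=sim,
        behavior_scenario=behav,
        abundance=paths.get("abundance"), samples=paths.get("samples"),
        edges=paths.get("edges"), gmt=paths.get("gmt"),
        behavior_sequences=paths.get("behavior_sequences"),
        behavior_explorations=paths.get("behavior_explorations"),
        fold=fold, alpha=alpha, n_perm_modules=n_perm_m,
        n_perm_pathways=n_perm_p, null=null, null_signs=null_signs,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _records(path: Path) -> int:
    if path.suffix in (".tsv", ".gmt"):
        with open(path, encoding="utf-8") as fh:
            n = sum(1 for line in fh if line.strip() and not line.startswith("#"))
        return max(0, n - 1) if path.suffix == ".tsv" else n
    return 0


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: sha}, counts}

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=str)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in dependency order; any failure aborts with the
    stage name in the error.  Returns the manifest (also written to
    ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: str(v) for k, v in dataclasses.asdict(config).items()},
        version=__version__, seed=config.seed)

    def finish(stage: str, files: list[Path]) -> None:
        manifest.stages[stage] = {
            "files": {p.name: _sha256(p) for p in files},
            "records": {p.name: _records(p) for p in files},
        }
        logger.info("stage %s: wrote %s", stage, [p.name for p in files])

    # -- simulate ----------------------------------------------------------
    try:
        if config.simulate is not None:
            scenario = config.simulate
            network = syn.generate_network(scenario)
            pathway_defs = syn.generate_pathways(network, scenario)
            matrix = syn.generate_abundances(network, scenario, pathway_defs)
            behav = syn.generate_behavior(
                config.behavior_scenario or syn.BehaviorScenario(
                    groups=scenario.groups, seed=scenario.seed))
            f_ab, f_sh = out / "abundance.tsv", out / "samples.tsv"
            f_ed, f_gmt = out / "edges.tsv", out / "pathways.gmt"
            f_bs, f_be = out / "behavior_sequences.tsv", out / "behavior_explorations.tsv"
            io.write_abundance(matrix, f_ab, f_sh)
            io.write_edge_list(network, f_ed)
            io.write_signed_gmt(pathway_defs, f_gmt)
            seqs_df, expl_df = behav.to_frames()
            io.write_behavior(seqs_df, expl_df, f_bs, f_be)
            finish("simulate", [f_ab, f_sh, f_ed, f_gmt, f_bs, f_be])
        else:
            matrix = io.read_abundance(config.abundance, config.samples)
            network = io.read_edge_list(config.edges)
            pathway_defs = io.read_signed_gmt(config.gmt)
            seqs_df = expl_df = None
            if config.behavior_sequences and config.behavior_explorations:
                seqs_df, expl_df = io.read_behavior(
                    config.behavior_sequences, config.behavior_explorations)
            finish("simulate", [])
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    # -- contrasts ---------------------------------------------------------
    try:
        case_groups = [g for g in matrix.groups if g != matrix.control_group]
        contrasts = [diffexpr.compute_contrast(matrix, g, config.contrast_summary)
                     for g in case_groups]
        f_con = out / "contrasts.tsv"
        pd.DataFrame({c.label: c.logfc for c in contrasts}).to_csv(
            f_con, sep="\t", index_label="protein_id")
        finish("contrast", [f_con])
    except Exception as exc:
        raise PipelineError(f"stage 'contrast' failed: {exc}") from exc

    # -- fold filter + clustering + set comparison -------------------------
    try:
        fold_sets = [diffexpr.fold_change_filter(c, config.fold) for c in contrasts]
        f_de = out / "de_fold.tsv"
        pd.DataFrame(
            [{"contrast": s.label, "protein_id": m}
             for s in fold_sets for m in sorted(s.members)]
        ).to_csv(f_de, sep="\t", index=False)
        files = [f_de]
        union = set().union(*(s.members for s in fold_sets))
        clusterable = sorted(
            p for p in union if all(c.valid.get(p, False) for c in contrasts))
        if len(contrasts) >= 2 and len(clusterable) >= 2:
            cl = diffexpr.cluster_expression(contrasts, clusterable)
            f_ord, f_mrg = out / "cluster_order.tsv", out / "cluster_merges.tsv"
            pd.DataFrame({"protein_id": cl.protein_order}).to_csv(
                f_ord, sep="\t", index=False)
            pd.DataFrame(cl.linkage,
                         columns=["left", "right", "distance", "size"]).to_csv(
                f_mrg, sep="\t", index=False)
            files += [f_ord, f_mrg]
        if len(fold_sets) >= 2:
            venn = diffexpr.compare_sets(fold_sets)
            f_venn = out / "venn.tsv"
            pd.DataFrame(
                [{"region": "&".join(sorted(k)), "count": v}
                 for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))]
            ).to_csv(f_venn, sep="\t", index=False)
            files.append(f_venn)
        finish("diffexpr", files)
    except Exception as exc:
        raise PipelineError(f"stage 'diffexpr' failed: {exc}") from exc

    # -- network modules ---------------------------------------------------
    try:
        selection = netmodules.select_de_proteins(
            network, contrasts, alpha=config.alpha,
            n_perm=config.n_perm_modules, seed=config.seed, null=config.null)
        f_mod, f_pair = out / "module_results.tsv", out / "module_pairs.tsv"
        selection.per_seed.to_csv(f_mod, sep="\t", index=False)
        selection.per_pair.to_csv(f_pair, sep="\t", index=False)
        f_demod = out / "de_modules.tsv"
        pd.DataFrame(
            [{"set": lbl, "criterion": s.criterion, "protein_id": m}
             for lbl, s in selection.de_sets.items() for m in sorted(s.members)]
        ).to_csv(f_demod, sep="\t", index=False)
        finish("modules", [f_mod, f_pair, f_demod])
    except Exception as exc:
        raise PipelineError(f"stage 'modules' failed: {exc}") from exc

    # -- pathway activity --------------------------------------------------
    try:
        table = pw.score_all_pathways(
            pathway_defs, contrasts, n_perm=config.n_perm_pathways,
            seed=config.seed, null_signs=config.null_signs)
        f_pw = out / "pathway_activity.tsv"
        table.to_csv(f_pw, sep="\t", index=False)
        finish("pathways", [f_pw])
    except Exception as exc:
        raise PipelineError(f"stage 'pathways' failed: {exc}") from exc

    # -- behavior ----------------------------------------------------------
    try:
        files = []
        if seqs_df is not None and expl_df is not None:
            metrics = behavior_metrics(seqs_df, expl_df)
            f_bm = out / "behavior_metrics.tsv"
            metrics.to_csv(f_bm, sep="\t", index=False)
            stats_df = behavior_group_stats(metrics)
            f_bg = out / "behavior_groupstats.tsv"
            stats_df.to_csv(f_bg, sep="\t", index=False)
            files = [f_bm, f_bg]
        finish("behavior", files)
    except Exception as exc:
        raise PipelineError(f"stage 'behavior' failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest


def behavior_metrics(seqs_df: pd.DataFrame, expl_df: pd.DataFrame) -> pd.DataFrame:
    """Per-animal alternation % and recognition indices with exclusion flags."""
    rows = []
    for _, r in seqs_df.iterrows():
        rows.append({"animal_id": r["animal_id"], "group": r["group"],
                     "metric": "alternation_pct", "phase": "",
                     "value": bh.spontaneous_alternation(tuple(r["entries"])),
                     "excluded": False})
    for _, r in expl_df.iterrows():
        res = bh.recognition_index((float(r["time_novel"]), float(r["time_familiar"])))
        rows.append({"animal_id": r["animal_id"], "group": r["group"],
                     "metric": "recognition_index", "phase": r["phase"],
                     "value": res.index, "excluded": res.excluded})
    return pd.DataFrame(rows)


def behavior_group_stats(metrics: pd.DataFrame) -> pd.DataFrame:
    """ANOVA + LSD + Levene per behavioral metric over non-excluded animals."""
    out = []
    for (metric, phase), sub in metrics.groupby(["metric", "phase"], dropna=False):
        sub = sub[~sub["excluded"] & sub["value"].notna()]
        by_group = {g: grp["value"].to_numpy(dtype=float)
                    for g, grp in sub.groupby("group")}
        by_group = {g: v for g, v in by_group.items() if v.size >= 2}
        if len(by_group) < 2:
            continue
        cmp = bh.group_compare(by_group)
        out.append({"metric": metric, "phase": phase, "anova_f": cmp.f,
                    "anova_p": cmp.p, "levene_p": cmp.levene_p,
                    "n_excluded": int(metrics[(metrics["metric"] == metric)
                                              & (metrics["phase"] == phase)]["excluded"].sum()),
                    **{f"mean_{g}": m for g, m in cmp.group_means.items()}})
    return pd.DataFrame(out)
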