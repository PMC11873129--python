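"""End-to-end workflow: simulate → preprocess → network → associate →
enrich → PRS, with stage caching and a reproducibility report.

Each stage writes its artifacts under the output directory and records a
content hash of its parameters plus the upstream stage's hash; a rerun
with unchanged configuration loads the cached artifacts instead of
recomputing. The final report (markdown + JSON) echoes the full
configuration, seed and per-stage summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from comethnet import io as cio
from comethnet.simulate import SimConfig, write_fixture_bundle
from comethnet.preprocess import (
    mad_variable_probes,
    pc_outlier_flags,
    residualize_covariates,
)
from comethnet.network import (
    ModuleAssignment,
    detect_modules,
    module_eigengenes,
    soft_threshold_scan,
    Eigengene,
)
from comethnet.association import module_trait_correlations
from comethnet.enrichment import (
    GeneSet,
    ewce_bootstrap,
    ewce_conditional,
    specificity_from_expression,
)
from comethnet import prs as cprs
from comethnet.stats import format_p_threshold
from comethnet import __version__

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

_DEFAULT_BINARY_TRAITS = (
    "dementia",
    "hallucinations",
    "depression",
    "anxiety",
    "aggression",
    "sleep_disorder",
)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; unknown keys in a YAML file are rejected."""

    outdir: str = "comethnet_run"
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    preprocess: dict[str, Any] = field(
        default_factory=lambda: {
            "covariates": ["age", "sex", "batch", "neun_prop", "pmi"],
            "n_pcs": 4,
            "sd_cut": 3.0,
            "drop_outliers": True,
        }
    )
    network: dict[str, Any] = field(
        default_factory=lambda: {
            "power": None,
            "min_size": 100,
            "max_block": 10_000,
            "merge_cut": 0.15,
        }
    )
    association: dict[str, Any] = field(
        default_factory=lambda: {
            "binary_traits": list(_DEFAULT_BINARY_TRAITS),
            "continuous_traits": ["years_disease"],
            # residualised covariates (exactly orthogonal after regression,
            # so they never falsely exclude) plus the Braak stages
            "confounds": [
                "age", "sex", "batch", "neun_prop", "pmi",
                "braak_lb", "braak_nft",
            ],
        }
    )
    enrichment: dict[str, Any] = field(
        default_factory=lambda: {"level": "subtype", "reps": 10_000, "conditional": True}
    )
    prs: dict[str, Any] = field(
        default_factory=lambda: {
            "thresholds": list(cprs.PRS_THRESHOLDS),
            "r2_max": 0.1,
            "window_kb": 1000.0,
            "flank_bp": 1_000_000,
            "gds_cut": 5,
            "min_records": 3,
            "min_event_visits": 2,
            "event_at": "first",
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in raw.items():
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                merged = {**default, **value}
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    version: str = __version__


def _hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Cache:
    def __init__(self, outdir: Path):
        self.path = outdir / "cache.json"
        self.state = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def fresh(self, stage: str, key: str, files: list[Path]) -> bool:
        return self.state.get(stage) == key and all(f.exists() for f in files)

    def store(self, stage: str, key: str) -> None:
        self.state[stage] = key
        self.path.write_text(json.dumps(self.state, indent=1))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow; every stage's outputs land in ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir)
    report = RunReport(config=config.to_dict())

    # ---- stage: simulate (or load provided inputs) -------------------------
    datadir = outdir / "data"
    sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
    if config.inputs:
        datadir = Path(config.inputs["dir"])
        report.stages["simulate"] = {"skipped": True, "inputs": str(datadir)}
    else:
        key = _hash(["simulate", dataclasses.asdict(sim_cfg)])
        datadir.mkdir(exist_ok=True)
        if not cache.fresh("simulate", key, [datadir / "manifest.json"]):
            write_fixture_bundle(sim_cfg, datadir)
            cache.store("simulate", key)
        report.stages["simulate"] = {
            "seed": config.seed,
            "manifest": str(datadir / "manifest.json"),
        }

    regions = list(sim_cfg.regions)
    betas = {
        r: cio.read_beta_tsv(datadir / f"beta_{r}.tsv") for r in regions
    }
    meta = cio.read_meta_tsv(datadir / "sample_meta.tsv")
    traits = cio.read_traits_tsv(datadir / "traits.tsv").set_index("sample")
    annotation = cio.read_annotation_tsv(datadir / "probe_annotation.tsv")

    # ---- stage: preprocess -------------------------------------------------
    pp = config.preprocess
    pp_key = _hash(["preprocess", pp, cache.state.get("simulate")])
    pp_files = [outdir / f"residualized_{r}.tsv" for r in regions]
    if cache.fresh("preprocess", pp_key, pp_files):
        residual = {r: cio.read_beta_tsv(outdir / f"residualized_{r}.tsv") for r in regions}
        n_kept = residual[regions[0]].shape[0]
        outliers = {
            r: pd.read_csv(outdir / f"outliers_{r}.tsv", sep="\t", index_col=0)
            for r in regions
            if (outdir / f"outliers_{r}.tsv").exists()
        }
    else:
        kept = mad_variable_probes(betas.values())
        n_kept = len(kept)
        residual = {}
        outliers = {}
        for r in regions:
            sub_meta = meta[meta["region"] == r]
            beta = betas[r].loc[sorted(kept)]
            res = residualize_covariates(beta, sub_meta, pp["covariates"])
            flags = pc_outlier_flags(res, pp["n_pcs"], pp["sd_cut"])
            outliers[r] = flags
            if pp.get("drop_outliers", True):
                res = res.loc[:, ~flags["outlier"]]
            residual[r] = res
            res.to_csv(outdir / f"residualized_{r}.tsv", sep="\t",
                       float_format="%.17g", index_label="probe")
            flags.to_csv(outdir / f"outliers_{r}.tsv", sep="\t",
                         float_format="%.6g", index_label="sample")
        cache.store("preprocess", pp_key)
    report.stages["preprocess"] = {
        "n_variable_probes": int(n_kept),
        "outliers_dropped": {
            r: int(f["outlier"].sum()) for r, f in outliers.items()
        },
    }

    # ---- stage: network ----------------------------------------------------
    nw = config.network
    nw_key = _hash(["network", nw, pp_key])
    assignments: dict[str, ModuleAssignment] = {}
    eigengenes: dict[str, Eigengene] = {}
    powers: dict[str, int] = {}
    nw_files = [outdir / f"modules_{r}.tsv" for r in regions] + [
        outdir / f"eigengenes_{r}.tsv" for r in regions
    ]
    if cache.fresh("network", nw_key, nw_files):
        for r in regions:
            lab = pd.read_csv(outdir / f"modules_{r}.tsv", sep="\t", index_col=0)
            assignments[r] = ModuleAssignment(lab["module"])
            eg = pd.read_csv(outdir / f"eigengenes_{r}.tsv", sep="\t", index_col=0)
            eigengenes[r] = Eigengene(eg, pd.Series(dtype=float))
            powers[r] = int(nw.get("power") or 0)
    else:
        for r in regions:
            res = residual[r]
            if nw.get("power"):
                power = int(nw["power"])
            else:
                scan = soft_threshold_scan(res)
                power = scan.selected_power
                scan.table.to_csv(
                    outdir / f"soft_threshold_{r}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
            powers[r] = power
            assign = detect_modules(
                res, power, min_size=nw["min_size"],
                max_block=nw["max_block"], merge_cut=nw["merge_cut"],
            )
            assignments[r] = assign
            me = module_eigengenes(res, assign)
            eigengenes[r] = me
            assign.labels.rename("module").to_csv(
                outdir / f"modules_{r}.tsv", sep="\t", index_label="probe"
            )
            me.scores.to_csv(
                outdir / f"eigengenes_{r}.tsv", sep="\t",
                float_format="%.17g", index_label="sample",
            )
        cache.store("network", nw_key)
    report.stages["network"] = {
        r: {
            "power": powers[r],
            "n_modules": len(assignments[r].modules),
            "bonferroni_threshold": format_p_threshold(
                0.05 / max(1, len(assignments[r].modules))
            ),
        }
        for r in regions
    }

    # ---- stage: associate --------------------------------------------------
    asc = config.association
    trait_types = {t: "binary" for t in asc["binary_traits"]}
    trait_types.update({t: "continuous" for t in asc["continuous_traits"]})
    assoc_tables = {}
    significant: list[tuple[str, str, str, float]] = []  # (region, module, trait, p)
    for r in regions:
        confounds = (
            meta[meta["region"] == r].set_index("sample")[asc["confounds"]]
        )
        for c in confounds.columns:  # categoricals as codes for screening
            if confounds[c].dtype == object:
                confounds[c] = confounds[c].astype("category").cat.codes
        result = module_trait_correlations(
            eigengenes[r], traits, trait_types, confounds
        )
        table = result.table
        table.insert(0, "region", r)
        assoc_tables[r] = table
        table.to_csv(outdir / f"module_trait_{r}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        result.excluded_modules.to_csv(
            outdir / f"confound_excluded_{r}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        for _, row in table[table["significant"]].iterrows():
            significant.append((r, row["module"], row["trait"], row["p"]))
        try:
            from comethnet.plots import module_trait_dotplot

            module_trait_dotplot(
                table, outdir / f"module_trait_{r}.svg", title=r
            )
        except Exception as exc:  # noqa: BLE001 - plotting is best-effort
            warnings.warn(f"dot plot failed for {r}: {exc}")
    significant.sort(key=lambda s: s[3])
    report.stages["associate"] = {
        "significant": [
            {"region": r, "module": m, "trait": t, "p": p}
            for r, m, t, p in significant
        ],
    }

    if not significant:
        report.stages["enrich"] = {"skipped": "no Bonferroni-significant module"}
        report.stages["prs"] = {"skipped": "no Bonferroni-significant module"}
        write_report(report, outdir)
        return report

    # focus module: the most significant association
    region, module, trait, _ = significant[0]
    module_probes = set(assignments[region].probes_in(module))

    # ---- stage: enrich -----------------------------------------------------
    en = config.enrichment
    expr = cio.read_expression(
        datadir / "expression.mtx",
        datadir / "expression_genes.tsv",
        datadir / "cell_annotation.tsv",
    )
    cells = cio.read_cell_annotation(datadir / "cell_annotation.tsv")
    spec = specificity_from_expression(expr, cells, level=en["level"])
    ann_idx = annotation.set_index("probe")["genes"]
    module_genes = GeneSet.from_symbols(
        [
            g
            for p in module_probes
            if p in ann_idx.index
            for g in str(ann_idx.loc[p]).split(";")
        ],
        provenance=f"{region}:{module}",
    )
    ewce = ewce_bootstrap(module_genes, spec, reps=en["reps"], seed=config.seed)
    ewce.to_csv(outdir / "ewce.tsv", sep="\t", index=False, float_format="%.6g")
    cond_frames = []
    if en.get("conditional", True):
        for ct in ewce.loc[ewce["q"] < 0.05, "celltype"]:
            cond_frames.append(
                ewce_conditional(
                    module_genes, spec, controlled=ct, reps=en["reps"],
                    seed=config.seed,
                )
            )
        if cond_frames:
            cond = pd.concat(cond_frames, ignore_index=True)
            cond.to_csv(outdir / "ewce_conditional.tsv", sep="\t", index=False,
                        float_format="%.6g")
    report.stages["enrich"] = {
        "module": f"{region}:{module}",
        "n_module_genes": len(module_genes),
        "significant_celltypes": ewce.loc[ewce["q"] < 0.05, "celltype"].tolist(),
        "top_sd_from_mean": float(ewce["sd_from_mean"].max()),
    }
    try:
        from comethnet.plots import ewce_barplot, conditional_heatmap

        ewce_barplot(ewce, outdir / "ewce.svg", title=f"{region}:{module}")
        if cond_frames:
            conditional_heatmap(cond, outdir / "ewce_conditional.svg")
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"enrichment plots failed: {exc}")

    # ---- stage: prs --------------------------------------------------------
    pr = config.prs
    sumstats = cio.read_sumstats(datadir / "sumstats.txt")
    dosages = cio.read_dosages(datadir / "dosages.tsv")
    pheno = cio.read_pheno_tsv(datadir / "longitudinal_pheno.tsv")
    ss, harm_report = cprs.harmonize_sumstats(sumstats)
    index_set = cprs.ld_clump(ss, dosages, pr["r2_max"], pr["window_kb"])
    windows = cprs.module_windows(module_probes, annotation, pr["flank_bp"])
    cio.write_intervals_bed(windows, outdir / "module_windows.bed")
    base = cprs.compute_prs(dosages, ss, index_set, tuple(pr["thresholds"]))
    refined = cprs.compute_prs(
        dosages, ss, index_set, tuple(pr["thresholds"]), restrict=windows
    )
    events, binary = cprs.build_event_table(
        pheno, pr["gds_cut"], pr["min_records"], pr["min_event_visits"],
        pr["event_at"],
    )
    covs = cprs.genetic_pcs(dosages).join(
        pheno.groupby("sample")["sex"].first().map({"F": 0.0, "M": 1.0}).rename("sex")
    )
    assoc = cprs.prs_trait_r2({"base": base, "refined": refined}, binary, covs)
    assoc.to_csv(outdir / "prs_association.tsv", sep="\t", index=False,
                 float_format="%.6g")
    events.to_csv(outdir / "event_table.tsv", sep="\t", index=False,
                  float_format="%.6g")

    cox_out = {}
    km_out = {}
    for name, scores in [("base", base), ("refined", refined)]:
        s = scores[0.05].dropna()
        if s.empty:
            continue
        cox = cprs.cox_time_dependent(events, s, name=f"{name}_PRS")
        cox.to_csv(outdir / f"cox_{name}.tsv", sep="\t", float_format="%.6g")
        cox_out[name] = {
            "HR_per_SD": float(cox.loc[f"{name}_PRS", "HR"]),
            "SE": float(cox.loc[f"{name}_PRS", "SE"]),
            "p": float(cox.loc[f"{name}_PRS", "p"]),
        }
        curves, hrs = cprs.km_percentile_strata(events, s)
        curves.to_csv(outdir / f"km_curves_{name}.tsv", sep="\t", index=False,
                      float_format="%.6g")
        km_out[name] = hrs.to_dict("records")
        try:
            from comethnet.plots import km_plot

            km_plot(curves, outdir / f"km_{name}.svg", title=f"{name} PRS")
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"KM plot failed: {exc}")

    sig_assoc = assoc[assoc["q"] < 0.05]
    report.stages["prs"] = {
        "harmonize": dataclasses.asdict(harm_report),
        "n_index_variants": len(index_set),
        "n_windows": len(windows),
        "n_tests_fdr": int(len(assoc)),
        "fdr_significant": sig_assoc[
            ["score_set", "threshold", "incremental_r2", "p", "q"]
        ].to_dict("records"),
        "cox": cox_out,
        "km_strata_hr": km_out,
        "n_events": int(events["event"].sum()),
    }

    write_report(report, outdir)
    return report


def write_report(run: RunReport, outdir: str | Path) -> tuple[Path, Path]:
    """Write the run report as JSON and human-readable markdown."""
    outdir = Path(outdir)
    json_path = outdir / "report.json"
    md_path = outdir / "report.md"
    payload = {
        "version": run.version,
        "config": run.config,
        "stages": run.stages,
    }
    json_path.write_text(json.dumps(payload, indent=1, default=str))

    lines = [
        "# comethnet run report",
        "",
        f"- version: {run.version}",
        f"- seed: {run.config.get('seed')}",
        "",
    ]
    if not run.stages:
        lines.append("zero stages completed")
    for stage, info in run.stages.items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(info, indent=1, default=str))
        lines.append("```")
        lines.append("")
    lines.append("## configuration (verbatim)")
    lines.append("")
    lines.append("```json")
    lines.append(json.dumps(run.config, indent=1, default=str))
    lines.append("```")
    md_path.write_text("\n".join(lines))
    return md_path, json_path
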