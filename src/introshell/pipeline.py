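"""Pipeline orchestration: configuration, stage sequencing, I/O, reporting.

A run either simulates a synthetic cohort or reads genotype/shell CSVs, then
executes QC -> introgression summaries -> depth models -> strength models ->
morphometrics, writing tidy CSV artifacts and a machine- plus human-readable
run report.  Reruns with the same config and seed are bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depthstats, introgen, morpho, syndata

__all__ = ["RunConfig", "RunReport", "read_genotype_table", "run_pipeline", "write_report"]

_ALLOWED_DOSAGE = {0.0, 0.5, 1.0}
_ALLOWED_COUNT = {0.0, 1.0, 2.0}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    outdir: str = "results/run"
    simulate: bool = True
    genotypes_path: str | None = None
    metadata_path: str | None = None
    qc_missing_threshold: float = 0.2
    efa_n_points: int = 300
    efa_n_harmonics: int = 12
    efa_power_threshold: float = 0.95
    pca_retain_threshold: float = 0.95
    run_morpho: bool = True
    design_scale: int = 1
    strength_models: dict[str, list[str]] = field(
        default_factory=lambda: {
            "additive": ["mt_af", "depth_m"],
            "interaction": ["mt_af", "depth_m", "mt_af:depth_m"],
            "mt_only": ["mt_af"],
            "depth_only": ["depth_m"],
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.qc_missing_threshold <= 1.0):
            raise ValueError("qc_missing_threshold must be in (0, 1]")
        for name in ("efa_power_threshold", "pca_retain_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    seed: int
    config_digest: str
    stages: list[dict] = field(default_factory=list)
    failed: bool = False
    failure: str | None = None

    def add(self, stage: str, n_in: int, n_out: int, **stats) -> None:
        excluded = n_in - n_out
        if n_out + excluded != n_in:
            raise AssertionError("count reconciliation failed")
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out,
             "n_excluded": excluded, **stats}
        )


def read_genotype_table(path) -> pd.DataFrame:
    """Read an individuals x loci genotype CSV into a dosage matrix.

    Header row holds locus ids, first column individual ids.  Cells are MT
    dosages {0, 0.5, 1}, allele counts {0, 1, 2} (converted by halving) or
    NA.  Unknown values and duplicated ids raise with the offending location.
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicated individual ids: {dups}")
    if df.columns.duplicated().any():
        raise ValueError("duplicated locus ids in header")
    vals = df.to_numpy(dtype=float)
    present = np.unique(vals[~np.isnan(vals)])
    as_dosage = set(present) <= _ALLOWED_DOSAGE
    as_count = set(present) <= _ALLOWED_COUNT
    if not (as_dosage or as_count):
        bad = next(
            (ind, col)
            for ind in df.index
            for col in df.columns
            if not np.isnan(df.at[ind, col])
            and df.at[ind, col] not in _ALLOWED_DOSAGE | _ALLOWED_COUNT
        )
        raise ValueError(
            f"unknown genotype value {df.at[bad]!r} at individual {bad[0]!r}, "
            f"locus {bad[1]!r}"
        )
    if not as_dosage:  # count-coded {0,1,2}: halve
        df = df / 2.0
    return df


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; returns the run report (also written)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, config_digest=config.digest())
    try:
        _run_stages(config, out, report)
    except Exception as exc:  # mark partial outputs, re-raise with context
        report.failed = True
        stage = report.stages[-1]["stage"] if report.stages else "setup"
        report.failure = f"after stage {stage}: {exc}"
        (out / "FAILED").write_text(report.failure)
        write_report(report, out)
        raise RuntimeError(report.failure) from exc
    write_report(report, out)
    return report


def _run_stages(config: RunConfig, out: Path, report: RunReport) -> None:
    # --- stage 1: inputs -------------------------------------------------
    if config.simulate:
        design = syndata.default_design(seed=config.seed)
        if config.design_scale != 1:
            design = design.scaled(config.design_scale)
        panel = syndata.default_panel(seed=config.seed)
        cohort = syndata.simulate_cohort(design, panel)
        me_calls_raw = syndata.simulate_me1516(cohort, seed=config.seed)
        genotypes = cohort.genotypes
        meta = cohort.meta
        shells = syndata.simulate_shell_traits(cohort, seed=config.seed)
        genotypes.to_csv(out / "genotypes.csv")
        meta.to_csv(out / "metadata.csv", index=False)
        shells.to_csv(out / "shells.csv", index=False)
        report.add("simulate", len(genotypes), len(genotypes),
                   n_loci=genotypes.shape[1])
    else:
        if not config.genotypes_path or not config.metadata_path:
            raise ValueError("non-simulated runs need genotypes_path and metadata_path")
        genotypes = read_genotype_table(config.genotypes_path)
        meta = pd.read_csv(config.metadata_path).set_index("individual_id", drop=False)
        shells = meta if "strength_norm" in meta.columns else None
        me_calls_raw = None
        report.add("load", len(genotypes), len(genotypes),
                   n_loci=genotypes.shape[1])

    depths = meta["depth_m"]

    # --- stage 2: QC -----------------------------------------------------
    filtered, qc_report = introgen.qc_filter(
        genotypes, missing_threshold=config.qc_missing_threshold
    )
    qc_report["loci"].to_csv(out / "qc_loci.csv")
    qc_report["individuals"].to_csv(out / "qc_individuals.csv")
    report.add("qc", len(genotypes), len(filtered),
               loci_in=genotypes.shape[1], loci_out=filtered.shape[1])

    # --- stage 3: species composition (Me15/16) --------------------------
    if me_calls_raw is not None:
        calls = [
            introgen.call_me1516(f, individual_id=i)
            for i, f in zip(me_calls_raw["individual_id"], me_calls_raw["fragments"])
        ]
        table1 = introgen.tabulate_classes(calls, depths.to_dict())
        table1.to_csv(out / "species_composition.csv", index=False)
        n_det = sum(c.species_class != "UNDETERMINED" for c in calls)
        report.add("me1516", len(calls), n_det)
    else:
        calls = None

    # --- stage 4: introgression summaries --------------------------------
    profiles = introgen.profiles_frame(filtered)
    profiles.to_csv(out / "introgression_profiles.csv", index=False)
    summary = introgen.summarize_introgression(
        profiles, depths.loc[filtered.index].to_dict()
    )
    summary.to_csv(out / "introgression_by_depth.csv", index=False)
    row_order, col_order = introgen.cluster_heatmap_order(filtered)
    heat = filtered.iloc[row_order, col_order]
    heat.to_csv(out / "heatmap_matrix.csv")
    report.add("introgression", len(filtered), len(filtered),
               pct_mt_positive=float(summary.iloc[-1]["pct_mt_positive"]))

    # --- stage 5: depth models -------------------------------------------
    per_depth = summary[summary["depth"] != "all"]
    fit = depthstats.fit_logistic_grouped(
        per_depth["mt_positive"].to_numpy(),
        per_depth["n"].to_numpy(),
        per_depth["depth"].to_numpy(dtype=float),
    )
    fit.coef_table().assign(odds_factor=lambda t: np.exp(t["estimate"])).to_csv(
        out / "depth_logistic.csv", index=False
    )
    report.add("depth_models", len(per_depth), len(per_depth),
               odds_factor_per_m=fit.odds_factor["x"])

    # --- stage 6: strength models -----------------------------------------
    if shells is not None:
        sh = shells.loc[shells.index.intersection(filtered.index)].copy()
        sh["mt_af"] = profiles["MT_AF"].reindex(sh.index)
        best, aic_table = depthstats.fit_linear(
            sh, "strength_norm", config.strength_models
        )
        aic_table.to_csv(out / "strength_aic.csv", index=False)
        best.coef_table().to_csv(out / "strength_coefficients.csv", index=False)
        flags = depthstats.weak_shell_flag(
            sh["strength_norm"], sh["SL_mm"], sh["SH_mm"]
        )
        sh.assign(weak_shell=flags).to_csv(out / "shells_flagged.csv", index=False)
        report.add("strength", len(sh), len(sh), best_model=best.model,
                   n_weak_flagged=int(np.sum(flags)))

    # --- stage 7: morphometrics -------------------------------------------
    if config.run_morpho and shells is not None:
        ratios = (sh["SL_mm"] / sh["SH_mm"]).to_numpy()
        coeffs = []
        for i, r in enumerate(ratios):
            o = syndata.simulate_outline(
                r, n_points=config.efa_n_points, noise_sd=0.02,
                seed=config.seed + i,
            )
            o = morpho.preprocess_outline(o, n_points=config.efa_n_points)
            coeffs.append(
                morpho.efa_normalize(
                    morpho.efa_decompose(o, config.efa_n_harmonics)
                )
            )
        cmat = morpho.coefficient_matrix(coeffs, ids=sh.index)
        space = morpho.shape_pca(cmat, retain_threshold=config.pca_retain_threshold)
        space.scores.to_csv(out / "shape_pc_scores.csv")
        res = morpho.manova_wilks(
            space.retained_scores(), sh["depth_m"].to_numpy()
        )
        pd.DataFrame([res.__dict__]).to_csv(out / "shape_manova.csv", index=False)
        report.add("morpho", len(sh), len(sh),
                   pc1_share=float(space.variance_shares[0]),
                   wilks_lambda=res.wilks_lambda)
    elif config.run_morpho:
        report.stages.append(
            {"stage": "morpho", "skipped": True,
             "note": "no shell records available"}
        )


def write_report(report: RunReport, outdir) -> None:
    """Write the run report as JSON and human-readable text."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2, default=str)
    lines = [
        f"run report (seed={report.seed}, config={report.config_digest})",
        "-" * 60,
    ]
    for s in report.stages:
        extra = {k: v for k, v in s.items() if k not in ("stage", "n_in", "n_out", "n_excluded")}
        if s.get("skipped"):
            lines.append(f"{s['stage']:<14} SKIPPED  {s.get('note', '')}")
        else:
            lines.append(
                f"{s['stage']:<14} in={s['n_in']:<6} out={s['n_out']:<6} "
                f"excluded={s['n_excluded']:<4} {extra}"
            )
    if report.failed:
        lines.append(f"FAILED: {report.failure}")
    (out / "run_report.txt").write_text("\n".join(lines) + "\n")
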