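"""End-to-end orchestration: curate -> collapse -> rarefy -> diversity ->
permutation tests -> hierarchical Beta model -> machine-readable report.

Every stage writes its artifacts into the output directory and logs a
digest into the run report; stage seeds are derived deterministically from
the master seed by CRC-32 of the stage name, so any stage can be re-run in
isolation and two runs with the same configuration produce identical
reports (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, diversity, io, model, multivariate, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "validate_report", "stage_seed"]

logger = logging.getLogger("streamgut")

REPORT_REQUIRED_KEYS = (
    "config",
    "software",
    "metadata_summary",
    "curation",
    "rarefaction",
    "alpha",
    "alpha_tests",
    "ordination",
    "permanova",
    "permdisp",
    "indicators",
    "model",
    "artifacts",
)


@dataclass
class PipelineConfig:
    """Settings for one full analysis run; defaults mirror the study protocol."""

    counts: str = ""
    taxonomy: str = ""
    metadata: str = ""
    counts_format: str = "tsv"
    out_dir: str = "results"
    min_reads: int = 1000
    collapse_rank: str = "family"
    rarefaction_depth: int = 1110
    rarefaction_replicates: int = 10
    group_vars: tuple[str, ...] = ("site", "order", "family", "genus", "ffg")
    permutations: int = 999
    indicator_group: str = "ffg"
    q_threshold: float = 0.05
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    fixed_factors: tuple[str, ...] = ("none", "family", "genus", "ffg", "site")
    nmds_starts: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("group_vars", "fixed_factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_vars"] = list(self.group_vars)
        d["fixed_factors"] = list(self.fixed_factors)
        return d


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC-32 of the stage name XOR master."""
    return (zlib.crc32(stage.encode()) ^ int(master)) & 0x7FFFFFFF


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _group_labels(metadata: pd.DataFrame, sample_ids, var: str) -> np.ndarray:
    meta = metadata.set_index("sample_id").loc[list(sample_ids)]
    if var == "genus":
        return np.array(
            [
                g if g is not None and pd.notna(g) else io.missing_genus_placeholder(f)
                for g, f in zip(meta["genus"], meta["family"])
            ]
        )
    return meta[var].to_numpy()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run report (also written to
    ``<out_dir>/report.json``)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}
    report: dict = {
        "config": config.to_dict(),
        "software": {"package": "streamgut", "version": "0.1.0"},
    }

    def save_table(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t")
        artifacts[name] = _digest(p)

    stage = "read"
    try:
        metadata = io.read_metadata(config.metadata)
        table = io.read_count_table(config.counts, fmt=config.counts_format)
        if config.taxonomy:
            table.taxonomy = io.read_taxonomy(config.taxonomy)
        summary = io.summarize_metadata(metadata)
        report["metadata_summary"] = {
            "n_samples": summary.n_samples,
            "distinct": summary.distinct,
            "counts": summary.counts,
            "n_missing_genus": summary.n_missing_genus,
        }

        stage = "curate"
        curated, log = community.curate_table(table, min_reads=config.min_reads)
        report["curation"] = {
            "removed_taxa": log.removed_taxa,
            "removed_samples": log.removed_samples,
            "min_reads": config.min_reads,
        }

        stage = "collapse"
        collapsed = community.collapse_to_rank(curated, rank=config.collapse_rank)
        io.write_count_table(collapsed, out / "collapsed.tsv")
        artifacts["collapsed.tsv"] = _digest(out / "collapsed.tsv")

        stage = "rarefy"
        rr = community.rarefy(
            collapsed,
            depth=config.rarefaction_depth,
            replicates=config.rarefaction_replicates,
            seed=stage_seed(config.seed, "rarefy"),
        )
        report["rarefaction"] = {
            "depth": rr.depth,
            "replicates": len(rr.replicates),
            "dropped_samples": rr.dropped_samples,
            "seed": rr.seed,
        }
        metadata_kept = metadata[
            metadata["sample_id"].isin(rr.replicates[0].sample_ids)
        ].reset_index(drop=True)

        stage = "alpha"
        alphas = [diversity.alpha_indices(rep) for rep in rr.replicates]
        alpha_mean, alpha_sd = diversity.aggregate_alpha(alphas)
        save_table(alpha_mean, "alpha_mean.tsv")
        save_table(alpha_sd, "alpha_sd.tsv")
        report["alpha"] = {"mean": alpha_mean.round(6).to_dict(orient="index")}
        group_vars = [
            v
            for v in config.group_vars
            if len(set(_group_labels(metadata_kept, alpha_mean.index, v))) >= 2
        ]
        tests = diversity.alpha_group_tests(alpha_mean, metadata_kept, group_vars)
        save_table(tests.set_index(["variable", "index"]), "alpha_tests.tsv")
        report["alpha_tests"] = tests.to_dict(orient="records")

        stage = "beta"
        dms = [diversity.bray_curtis(rep) for rep in rr.replicates]
        dm_mean, _dm_sd = diversity.aggregate_distance_matrices(dms)
        io.write_distance_matrix(dm_mean, out / "bray_curtis_mean.tsv")
        artifacts["bray_curtis_mean.tsv"] = _digest(out / "bray_curtis_mean.tsv")

        stage = "nmds"
        ord_res = multivariate.nmds(
            dm_mean, k=2, n_starts=config.nmds_starts, seed=stage_seed(config.seed, "nmds")
        )
        save_table(ord_res.coordinates, "nmds_coordinates.tsv")
        report["ordination"] = {
            "stress": ord_res.stress,
            "converged": ord_res.converged,
            "n_iterations": ord_res.n_iterations,
        }

        stage = "permanova"
        report["permanova"] = {}
        report["permdisp"] = {}
        for var in group_vars:
            labels = _group_labels(metadata_kept, dm_mean.ids, var)
            res = multivariate.permanova(
                dm_mean,
                labels,
                n_permutations=config.permutations,
                seed=stage_seed(config.seed, f"permanova:{var}"),
            )
            report["permanova"][var] = {"F": res.statistic, "p": res.p}
            _, counts = np.unique(labels, return_counts=True)
            if (counts >= 2).sum() >= 2:
                disp = multivariate.permdisp(
                    dm_mean,
                    labels,
                    n_permutations=config.permutations,
                    seed=stage_seed(config.seed, f"permdisp:{var}"),
                )
                report["permdisp"][var] = {
                    "F": None if np.isnan(disp.statistic) else disp.statistic,
                    "p": disp.p,
                    "degenerate": disp.degenerate,
                }

        stage = "indicators"
        labels = _group_labels(metadata_kept, rr.replicates[0].sample_ids, config.indicator_group)
        ind = multivariate.indicator_kw(rr.replicates[0], labels, q_threshold=config.q_threshold)
        save_table(ind.table, "indicator_tests.tsv")
        report["indicators"] = {
            "group": config.indicator_group,
            "n_significant": len(ind.significant),
            "significant": ind.significant,
        }

        stage = "model"
        obs = model.build_pair_observations(dm_mean, metadata_kept)
        obs.to_csv(out / "pair_observations.tsv", sep="\t", index=False)
        artifacts["pair_observations.tsv"] = _digest(out / "pair_observations.tsv")
        fits = []
        model_report: dict = {"fits": {}}
        for fixed in config.fixed_factors:
            spec = model.ModelSpec(fixed_factor=None if fixed == "none" else fixed)
            draws = model.sample_posterior(
                obs,
                spec,
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=stage_seed(config.seed, f"model:{fixed}"),
            )
            fits.append((spec, draws))
            summ = model.fit_summary(draws)
            core = summ.loc[[n for n in summ.index if not n.startswith(("a_", "b_"))]]
            model_report["fits"][fixed] = {
                "summary": core.replace({np.nan: None}).round(6).to_dict(orient="index"),
                "max_rhat": None
                if summ["rhat"].dropna().empty
                else float(summ["rhat"].dropna().max()),
            }
            if fixed == "none":
                model_report["variance_partition"] = model.variance_partition(draws)
                model_report["predictions"] = {
                    f: {
                        lv: model.predict_levels(draws, spec, f, lv)
                        for lv in draws.levels[f]
                    }
                    for f in model.FACTORS
                }
        comparison = model.compare_models(fits, obs)
        comparison.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
        artifacts["model_comparison.tsv"] = _digest(out / "model_comparison.tsv")
        model_report["comparison"] = comparison.round(6).to_dict(orient="records")
        report["model"] = model_report
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted at stage {stage!r}: {exc}; artifacts so far: {sorted(artifacts)}"
        ) from exc

    report["artifacts"] = artifacts
    report["timing"] = {"wall_seconds": round(time.time() - t0, 3)}
    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("pipeline finished in %.1fs, report at %s", time.time() - t0, out / "report.json")
    logger.removeHandler(handler)
    return report


def validate_report(report: dict) -> None:
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing required sections: {missing}")
    json.dumps(report)  # must be serializable


def make_fixture(scale: str = "small", seed: int = 0, out_dir: str = "fixture") -> dict[str, str]:
    """Write a complete synthetic input bundle (metadata, counts, taxonomy,
    truth) at the requested scale; ``paper-like`` mirrors the 10-site /
    41-sample study design."""
    if scale == "small":
        cfg = synthetic.GeneratorConfig.small(seed=seed)
    elif scale == "paper-like":
        cfg = synthetic.GeneratorConfig.paper_like(seed=seed)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata = synthetic.generate_metadata(cfg)
    table, truth = synthetic.generate_counts(metadata, cfg)
    io.write_metadata(metadata.drop(columns=["_true_genus"]), out / "metadata.tsv")
    io.write_count_table(table, out / "counts.tsv")
    io.write_taxonomy(table.taxonomy, out / "taxonomy.tsv")
    truth_doc = {
        "config": dataclasses.asdict(cfg),
        "effects": {
            factor: {lv: np.asarray(v).tolist() for lv, v in levels.items()}
            for factor, levels in truth.effects.items()
        },
        "depths": truth.extra.get("depths", {}),
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, sort_keys=True))
    return {
        "metadata": str(out / "metadata.tsv"),
        "counts": str(out / "counts.tsv"),
        "taxonomy": str(out / "taxonomy.tsv"),
        "truth": str(out / "truth.json"),
    }
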