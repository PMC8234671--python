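"""End-to-end orchestration: counts -> normalize -> R/G strata -> DE ->
survival -> correlations, driven by a declarative run configuration.

Every stage writes a TSV under the output directory; a JSON manifest records
the configuration hash, seed, package and library versions and the analysis
decisions in effect, so a re-run with the same configuration and seed
reproduces every output byte-identically.  Stage timings go to the log, never
into outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_tables import (
    CountTable,
    SampleMetadata,
    align_samples,
    read_count_table,
    read_sample_metadata,
    write_count_table,
    write_sample_metadata,
)
from .normalize import normalize_log, size_factors
from .rg_stratify import (
    class_fraction_table,
    profiles_to_frame,
    rg_profiles,
    stratify_cohort,
)
from .diffexpr import ma_table, nb_wald_test, significance_filter
from .survival_stats import cox_fit, forest_table, km_table, logrank_test
from .factor_corr import (
    DEFAULT_CHROMATIN_FACTORS,
    correlate_panel,
    mutation_association_table,
)
from .sim_data import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.8g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "rg_run"
    seed: int = 0
    counts_path: Optional[str] = None
    metadata_path: Optional[str] = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    pseudocount: float = 1.0
    nonzero_only: bool = False
    strata_n: int = 3
    de_base_mean_min: float = 100.0
    de_lfc_min: float = 1.0
    de_alpha: float = 0.05
    survival_covariates: list[str] = field(
        default_factory=lambda: ["stratum", "age", "gender", "cytogenetic_risk"]
    )
    reference_levels: dict[str, str] = field(
        default_factory=lambda: {"stratum": "mid", "cytogenetic_risk": "favorable"}
    )
    cox_ties: str = "efron"
    factor_list_path: Optional[str] = None
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        errs = []
        if self.pseudocount <= 0:
            errs.append("pseudocount must be positive")
        if self.strata_n < 2:
            errs.append("strata_n must be >= 2")
        if self.de_base_mean_min < 0:
            errs.append("de_base_mean_min must be >= 0")
        if self.de_lfc_min <= 0:
            errs.append("de_lfc_min must be positive")
        if not 0 < self.de_alpha < 1:
            errs.append("de_alpha must be in (0, 1)")
        if self.cox_ties not in ("efron", "breslow"):
            errs.append("cox_ties must be 'efron' or 'breslow'")
        if not self.simulate:
            if not self.counts_path or not self.metadata_path:
                errs.append(
                    "counts_path and metadata_path are required unless "
                    "simulate is true"
                )
        errs.extend(self.sim.validate())
        return errs

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        sim_data = data.pop("sim", None)
        cfg = cls(**data)
        if sim_data:
            cfg.sim = SimConfig(**sim_data)
        if "seed" in data:
            cfg.sim.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_canonical_json(self) -> str:
        """Analysis-relevant configuration as canonical JSON.

        Excludes the output location and log level, which do not affect
        results, so equal analyses hash equal.
        """
        d = asdict(self)
        d.pop("outdir", None)
        d.pop("log_level", None)
        # JSON object keys must be strings (factor tiers are keyed by float)
        d["sim"]["factor_tiers"] = {
            str(k): list(v) for k, v in d["sim"]["factor_tiers"].items()
        }
        return json.dumps(d, sort_keys=True, default=str)


def validate_config(path: str | Path) -> list[str]:
    """Load a YAML config and return its violations (empty = valid)."""
    try:
        cfg = RunConfig.from_yaml(path)
    except (OSError, ValueError, TypeError, yaml.YAMLError) as exc:
        return [f"unreadable config: {exc}"]
    return cfg.validate()


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path.name


def _meta_frame(meta: list[SampleMetadata]) -> pd.DataFrame:
    rows = []
    for m in meta:
        row = {
            "sample": m.sample, "gender": m.gender, "age": m.age,
            "cytogenetic_risk": m.cytogenetic_risk, "subtype": m.subtype,
            "time": m.survival_time, "event": m.event,
        }
        row.update(m.mutations)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every analysis stage and write outputs plus a manifest.

    Returns the run report (also serialized as ``manifest.json``).  Stages
    whose inputs are absent (no survival columns, no mutation flags, too-small
    strata for a DE contrast) are skipped with a logged warning; genuine
    failures abort with :class:`PipelineError` naming the stage.
    """
    errs = config.validate()
    if errs:
        raise PipelineError("config", "; ".join(errs))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    skipped: dict[str, str] = {}

    def _stage(name: str):
        logger.info("stage %s", name)
        return _time.monotonic()

    def _done(name: str, t0: float) -> None:
        logger.info("stage %s finished in %.2fs", name, _time.monotonic() - t0)

    # ---- inputs ---------------------------------------------------------
    t0 = _stage("input")
    factor_expr = None
    truth = None
    try:
        if config.simulate:
            config.sim.seed = config.seed
            table, meta, truth, factor_expr = simulate_cohort(config.sim)
            write_count_table(table, outdir / "counts.tsv")
            write_sample_metadata(meta, outdir / "metadata.tsv")
            truth.write_tsv(outdir / "truth.tsv")
            outputs["counts"] = "counts.tsv"
            outputs["metadata"] = "metadata.tsv"
            outputs["truth"] = "truth.tsv"
            outputs["factor_expression"] = _write(
                factor_expr, outdir / "factor_expression.tsv"
            )
        else:
            table = read_count_table(config.counts_path)
            meta = read_sample_metadata(config.metadata_path)
            table, meta = align_samples(table, meta)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    _done("input", t0)

    # ---- normalization --------------------------------------------------
    t0 = _stage("normalize")
    try:
        sf = size_factors(table)
        norm = normalize_log(table, sf, pseudocount=config.pseudocount)
        outputs["normalized_matrix"] = "normalized_matrix.tsv"
        norm.write_tsv(outdir / "normalized_matrix.tsv")
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc
    _done("normalize", t0)

    # ---- R/G ratio and stratification ------------------------------------
    t0 = _stage("stratify")
    try:
        profiles = stratify_cohort(
            rg_profiles(norm, nonzero_only=config.nonzero_only), n=config.strata_n
        )
        prof_frame = profiles_to_frame(profiles)
        outputs["rg_profiles"] = _write(prof_frame, outdir / "rg_profiles.tsv")
        fractions = class_fraction_table(table)
        outputs["class_fractions"] = _write(
            fractions, outdir / "class_fractions.tsv"
        )
    except Exception as exc:
        raise PipelineError("stratify", str(exc)) from exc
    _done("stratify", t0)
    strata = prof_frame["stratum"]
    stratum_counts = strata.value_counts().to_dict()

    # ---- differential expression -----------------------------------------
    t0 = _stage("diffexpr")
    de_summary: dict[str, Any] = {}
    for contrast, (ga, gb) in {
        "high_vs_mid": ("mid", "high"),
        "low_vs_mid": ("mid", "low"),
    }.items():
        sa = strata.index[strata == ga].tolist()
        sb = strata.index[strata == gb].tolist()
        if len(sa) < 2 or len(sb) < 2:
            skipped[f"diffexpr:{contrast}"] = (
                f"needs >=2 samples per stratum (got {len(sb)} {gb}, "
                f"{len(sa)} {ga})"
            )
            logger.warning("skipping DE contrast %s: %s",
                           contrast, skipped[f"diffexpr:{contrast}"])
            continue
        try:
            de = nb_wald_test(
                table, sf, sa, sb,
                base_mean_min=config.de_base_mean_min,
                lfc_min=config.de_lfc_min, alpha=config.de_alpha,
            )
            outputs[f"de_{contrast}"] = _write(de, outdir / f"de_{contrast}.tsv")
            hits = significance_filter(
                de, base_mean_min=config.de_base_mean_min,
                lfc_min=config.de_lfc_min, alpha=config.de_alpha,
            )
            outputs[f"significant_{contrast}"] = _write(
                hits[["log2FoldChange"]], outdir / f"significant_{contrast}.tsv"
            )
            outputs[f"ma_{contrast}"] = _write(
                ma_table(de), outdir / f"ma_{contrast}.tsv"
            )
            de_summary[contrast] = {
                "n_features": int(de.shape[0]),
                "n_significant": int(hits.shape[0]),
            }
        except Exception as exc:
            raise PipelineError(f"diffexpr:{contrast}", str(exc)) from exc
    _done("diffexpr", t0)

    # ---- survival --------------------------------------------------------
    t0 = _stage("survival")
    meta_frame = _meta_frame(meta).join(strata)
    survival_summary: dict[str, Any] = {}
    has_surv = meta_frame["time"].notna().any() and meta_frame["event"].notna().any()
    if not has_surv:
        skipped["survival"] = "no survival_time/event columns in metadata"
        logger.warning("skipping survival stage: %s", skipped["survival"])
    else:
        try:
            surv = meta_frame.dropna(subset=["time", "event"])
            km_frames = []
            for stratum, grp in surv.groupby("stratum"):
                kt = km_table(grp["time"], grp["event"].astype(int))
                kt.insert(0, "stratum", stratum)
                km_frames.append(kt)
            outputs["km_curves"] = _write(
                pd.concat(km_frames, ignore_index=True).set_index("stratum"),
                outdir / "km_curves.tsv",
            )
            lo = surv[surv["stratum"] == "low"]
            hi = surv[surv["stratum"] == "high"]
            if len(lo) and len(hi):
                chi2, p = logrank_test(
                    lo["time"], lo["event"].astype(int),
                    hi["time"], hi["event"].astype(int),
                )
                survival_summary["logrank_low_vs_high"] = {"chi2": chi2, "p": p}
                outputs["logrank"] = _write(
                    pd.DataFrame(
                        [{"contrast": "low_vs_high", "chi2": chi2, "p": p}]
                    ).set_index("contrast"),
                    outdir / "logrank.tsv",
                )
            covs = [
                c for c in config.survival_covariates
                if c in surv.columns and surv[c].notna().any()
            ]
            dropped_covs = sorted(set(config.survival_covariates) - set(covs))
            if dropped_covs:
                logger.warning("covariates unavailable, dropped: %s", dropped_covs)
            fit = cox_fit(
                surv.rename(columns={})[["time", "event", *covs]].assign(
                    event=surv["event"].astype(int)
                ),
                covs,
                reference_levels=config.reference_levels,
                ties=config.cox_ties,
            )
            outputs["cox_forest"] = _write(
                forest_table(fit), outdir / "cox_forest.tsv"
            )
            survival_summary["cox_n"] = fit.n
            survival_summary["cox_events"] = fit.n_events
        except Exception as exc:
            raise PipelineError("survival", str(exc)) from exc
    _done("survival", t0)

    # ---- chromatin-factor correlation -------------------------------------
    t0 = _stage("factor_corr")
    factor_list: list[str] = list(DEFAULT_CHROMATIN_FACTORS)
    if config.factor_list_path:
        factor_list = [
            line.strip()
            for line in Path(config.factor_list_path).read_text().splitlines()
            if line.strip()
        ]
    if factor_expr is None:
        # real-data path: factor expression comes from the normalized matrix
        nf = norm.to_frame()
        present = [f for f in factor_list if f in nf.index]
        factor_expr = nf.loc[present] if present else None
    if factor_expr is None or factor_expr.empty:
        skipped["factor_corr"] = "no panel factors found in expression matrix"
        logger.warning("skipping factor correlation: %s", skipped["factor_corr"])
    else:
        try:
            panel = correlate_panel(
                prof_frame["rg_ratio"].to_numpy(),
                factor_expr[prof_frame.index.tolist()],
                factor_list,
            )
            outputs["factor_correlations"] = _write(
                panel, outdir / "factor_correlations.tsv"
            )
        except Exception as exc:
            raise PipelineError("factor_corr", str(exc)) from exc
    _done("factor_corr", t0)

    # ---- mutation association ---------------------------------------------
    t0 = _stage("mutation")
    mutation_cols = [
        c for c in meta_frame.columns
        if c not in ("gender", "age", "cytogenetic_risk", "subtype",
                     "time", "event", "stratum")
    ]
    if not mutation_cols:
        skipped["mutation"] = "no mutation flags in metadata"
    else:
        try:
            assoc = mutation_association_table(
                prof_frame["rg_ratio"].to_numpy(),
                meta_frame.loc[prof_frame.index, mutation_cols],
            )
            if assoc.empty:
                skipped["mutation"] = "no mutation flag with both classes"
            else:
                outputs["mutation_association"] = _write(
                    assoc, outdir / "mutation_association.tsv"
                )
        except Exception as exc:
            raise PipelineError("mutation", str(exc)) from exc
    _done("mutation", t0)

    # ---- manifest ---------------------------------------------------------
    canonical = config.to_canonical_json()
    report: dict[str, Any] = {
        "package": "repeatratio",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": json.loads(canonical),
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "stratum_counts": {k: int(v) for k, v in sorted(stratum_counts.items())},
        "de": de_summary,
        "survival": survival_summary,
        "decisions": {
            "transform": norm.transform,
            "pseudocount": config.pseudocount,
            "median_rule": "even-length medians are the mean of the central pair",
            "rg_medians_nonzero_only": config.nonzero_only,
            "size_factors": "median-of-ratios over all-positive features",
            "de_model": "two-group NB Wald, pooled MoM dispersion, BH per contrast",
            "cox_ties": config.cox_ties,
            "reference_levels": config.reference_levels,
        },
        "outputs": dict(sorted(outputs.items())),
        "skipped": dict(sorted(skipped.items())),
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
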