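"""End-to-end orchestration: simulate -> scales -> twin fit -> overlap -> groups.

Every artifact is stamped with the configuration hash, the seed, and the
package version, so a report bundle is reproducible byte-for-byte from its
run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__, defaults
from .exceptions import TwinOverlapError
from .groups import fit_overlap_logit, group_counts, group_profile_table
from .overlap import reduction_table, zero_order
from .report import (render_decomposition, render_odds_ratios,
                     render_reduction_table, render_twin_correlations)
from .scales import attach_scales
from .simulate import (GeneratorConfig, SyntheticCohort, generate_cohort,
                       generate_risk_factors, read_cohort, write_cohort)
from .twin_model import (confidence_intervals, covariance_shares, fit_bivariate,
                         pairs_from_cohort, to_correlated_factors,
                         twin_correlations)

logger = logging.getLogger("twinoverlap")

__all__ = ["RunConfig", "run_pipeline"]

KEY_RISKS = [
    "low_self_control", "cognitive_ability", "early_puberty",
    "conduct_disorder", "childhood_delinquency", "childhood_substance_use",
    "total_aces", "summary_all_risks",
]


@dataclass
class RunConfig:
    """Stage toggles, paths, and stochastic-analysis settings."""

    seed: int = 0
    out_dir: str = "twinoverlap_out"
    cohort_path: str | None = None          # load instead of simulating
    simulate: bool = True
    twin_fit: bool = True
    overlap: bool = True
    groups: bool = True
    bootstrap_B: int = 200
    ci_method: str = "bootstrap"
    twin_phenotypes: tuple[str, str] = ("victim_variety", "offend_variety")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def config_hash(self) -> str:
        # hash the analytic configuration, not output locations
        skip = {"generator", "out_dir"}
        blob = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k not in skip},
             "generator": self.generator.to_yaml()},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order and write the bundle.

    Returns the in-memory report bundle; on stage failure, raises with the
    stage name, after marking partial outputs incomplete.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"meta": _stamp(config), "log": []}
    stage = "init"
    try:
        stage = "simulate"
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
            bundle["log"].append(f"loaded cohort from {config.cohort_path}")
        elif config.simulate:
            gen = replace(config.generator, seed=config.seed)
            cohort = generate_risk_factors(generate_cohort(gen), gen)
            bundle["log"].append(
                f"simulated cohort: {gen.n_pairs} pairs, seed {config.seed}")
        else:
            raise TwinOverlapError("no cohort source: enable simulate or set "
                                   "cohort_path")
        stage = "scales"
        df = attach_scales(cohort.individuals)
        cohort = SyntheticCohort(df, cohort.truth)
        write_cohort(cohort, out_dir / "cohort.csv")
        bundle["cohort"] = df
        n = len(df)
        bundle["log"].append(f"n individuals: {n}")

        if config.twin_fit:
            stage = "twin_fit"
            data = pairs_from_cohort(df, config.twin_phenotypes)
            tc = twin_correlations(data)
            params, fit_report = fit_bivariate(data, "ACE")
            sol = to_correlated_factors(params)
            shares = covariance_shares(sol)
            ci = confidence_intervals(
                data, "ACE", method=config.ci_method, B=config.bootstrap_B,
                seed=config.seed)
            bundle["twin_correlations"] = render_twin_correlations(tc)
            bundle["decomposition"] = render_decomposition(sol, shares, ci["ci"])
            bundle["fit_report"] = {
                "model": fit_report.model, "minus2ll": fit_report.minus2ll,
                "aic": fit_report.aic, "n_params": fit_report.n_params,
                "converged": fit_report.converged,
                "n_pairs": fit_report.n_pairs,
                "n_pairs_dropped": data.n_dropped,
            }
            bundle["twin_correlations"].to_csv(out_dir / "table1_twin_correlations.csv",
                                               index=False)
            bundle["decomposition"].to_csv(out_dir / "decomposition.csv", index=False)
            bundle["log"].append(
                f"twin fit converged={fit_report.converged}, "
                f"pairs dropped={data.n_dropped}")

        if config.overlap:
            stage = "overlap"
            r0, ci0 = zero_order(df, B=config.bootstrap_B, seed=config.seed)
            risks = [r for r in KEY_RISKS if r in df.columns]
            tbl = reduction_table(df, risks, B=config.bootstrap_B,
                                  seed=config.seed)
            bundle["zero_order"] = {"r": r0, "ci": ci0}
            bundle["reduction_table"] = tbl
            render_reduction_table(tbl).to_csv(
                out_dir / "table2_partial_correlations.csv", index=False)
            bundle["log"].append(f"zero-order r = {r0:.3f}")

        if config.groups:
            stage = "groups"
            continuous = ["victim_variety", "offend_variety", "low_self_control",
                          "cognitive_ability", "early_puberty",
                          "childhood_delinquency", "childhood_substance_use",
                          "total_aces", "conventional_aces", "expanded_aces",
                          "summary_all_risks"]
            binary = ["conduct_disorder"] + list(defaults.ALL_ACES)
            continuous = [c for c in continuous if c in df.columns]
            binary = [c for c in binary if c in df.columns]
            bundle["group_counts"] = group_counts(df)
            bundle["group_profiles"] = group_profile_table(df, continuous, binary)
            ors = []
            for risk in [r for r in KEY_RISKS if r in df.columns]:
                for contrast in ("victim_only", "offender_only"):
                    for model in (1, 2):
                        ors.append(fit_overlap_logit(df, risk, contrast, model))
            bundle["odds_ratios"] = render_odds_ratios(ors)
            bundle["group_profiles"].to_csv(out_dir / "table3_group_profiles.csv",
                                            index=False)
            bundle["odds_ratios"].to_csv(out_dir / "table4_odds_ratios.csv",
                                         index=False)
            bundle["log"].append(
                "group sizes: " + ", ".join(
                    f"{g}={int(c)}" for g, c in bundle["group_counts"].items()))

        meta = {**bundle["meta"], "log": bundle["log"], "complete": True}
        (out_dir / "run.json").write_text(json.dumps(meta, indent=2))
        return bundle
    except Exception as exc:
        meta = {**bundle.get("meta", {}), "complete": False, "failed_stage": stage,
                "error": str(exc)}
        (out_dir / "run.json").write_text(json.dumps(meta, indent=2))
        raise TwinOverlapError(f"pipeline failed in stage '{stage}': {exc}") from exc
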