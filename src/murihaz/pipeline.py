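"""End-to-end orchestration: simulate or ingest, then hazards, hazard-ratio
bands, survival tests, Cox and bodyweight regressions, with a manifest.

Re-running with an identical :class:`RunConfig` reproduces byte-identical
outputs (all randomness is seeded; the manifest carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version

try:
    __version__ = _pkg_version("murihaz")
except Exception:
    __version__ = "0.1.0"
from .datasets import (
    MEASUREMENT_AGES_MONTHS,
    join_weights,
    read_cohort,
    read_weights,
    write_cohort,
    write_weights,
)
from .hazard import SmootherSettings, bin_exposure, fit_smoothed_hazard
from .models import cox_fit, interaction_regression, weight_regression
from .ratio import bootstrap_hr, hr_summary
from .simulate import SimConfig, simulate_cohort
from .survival import km_curve, logrank, max_lifespan_test, median_with_ci

logger = logging.getLogger("murihaz.pipeline")

ALL_STAGES = ("simulate", "hazard", "hr", "survtest", "cox", "weightreg")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "murihaz_out"
    stages: tuple[str, ...] = ALL_STAGES
    simulate: SimConfig | None = None
    cohort_path: str | None = None
    weights_path: str | None = None
    smoother: SmootherSettings = field(default_factory=SmootherSettings)
    bootstrap_B: int = 1000
    bootstrap_seed: int = 17

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "simulate" in self.stages and self.simulate is None:
            self.simulate = SimConfig.study_like()
        if "simulate" not in self.stages and self.cohort_path is None:
            raise ValueError("either enable the simulate stage or give cohort_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "simulate" in data and data["simulate"] is not None:
            sim = data["simulate"]
            if isinstance(sim, dict):
                from .simulate import GompertzParams, HRBump, WeightModel

                for key, typ in (("female_gompertz", GompertzParams),
                                 ("hr_bump", HRBump), ("weight_model", WeightModel)):
                    if key in sim and isinstance(sim[key], dict):
                        sim[key] = typ(**sim[key])
                if "cohorts" in sim:
                    sim["cohorts"] = tuple(sim["cohorts"])
                data["simulate"] = SimConfig(**sim)
        if "smoother" in data and isinstance(data["smoother"], dict):
            data["smoother"] = SmootherSettings(**data["smoother"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        data = asdict(self)
        data.pop("outdir")  # where outputs land is not part of the analysis
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Writes every stage's tables under ``config.outdir``, a ``summary.json``
    with the headline quantities, and a ``manifest.json`` listing every
    output file with its checksum. Returns the summary dict. On a stage
    failure the pipeline halts; partial outputs are retained next to a
    ``FAILED`` marker naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.bootstrap_seed, "config_hash": config.config_hash(),
                     "version": __version__}
    outputs: list[Path] = []
    current = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        weights = None
        if "simulate" in config.stages:
            current = "simulate"
            logger.info("simulating cohort (seed=%d)", config.simulate.seed)
            sim = simulate_cohort(config.simulate)
            cohort, weights = sim.cohort, sim.weights
            write_cohort(cohort, outdir / "cohort.csv")
            write_weights(weights, outdir / "weights.csv")
            sim.truth.to_csv(outdir / "truth.csv", index=False)
            sim.truth_hazard.to_csv(outdir / "truth_hazard.csv", index=False)
            config.simulate.to_yaml(outdir / "simconfig.yaml")
            outputs += [outdir / n for n in
                        ("cohort.csv", "weights.csv", "truth.csv",
                         "truth_hazard.csv", "simconfig.yaml")]
            summary["simulate"] = {"n_animals": len(cohort),
                                   "n_weights": int(len(weights))}
        else:
            cohort = read_cohort(config.cohort_path)
            if config.weights_path:
                weights = read_weights(config.weights_path)

        tab = cohort.table

        # ---- smoothed hazards ------------------------------------------
        if "hazard" in config.stages:
            current = "hazard"
            frames = []
            for sex in ("F", "M"):
                sub = cohort.subset((tab["sex"] == sex).to_numpy())
                exp = bin_exposure(sub, bin_width_days=config.smoother.bin_width_days)
                curve = fit_smoothed_hazard(
                    exp, lam=config.smoother.lam, n_knots=config.smoother.n_knots,
                    degree=config.smoother.degree,
                    penalty_order=config.smoother.penalty_order,
                )
                frames.append(pd.DataFrame({
                    "age_days": curve.age_grid, "hazard_per_day": curve.hazard,
                    "ci_lo": curve.ci_lower, "ci_hi": curve.ci_upper, "group": sex,
                }))
                logger.info("hazard[%s]: %d events, edf=%.2f, lambda=%.3g",
                            sex, curve.n_events, curve.effective_df, curve.lam)
            pd.concat(frames).to_csv(outdir / "hazard.csv", index=False)
            outputs.append(outdir / "hazard.csv")

        # ---- hazard-ratio bands ----------------------------------------
        if "hr" in config.stages:
            current = "hr"
            hr_curve = bootstrap_hr(cohort, B=config.bootstrap_B,
                                    seed=config.bootstrap_seed,
                                    settings=config.smoother,
                                    keep_replicates=False)
            s = hr_summary(hr_curve)
            pd.DataFrame({
                "age_days": hr_curve.age_grid, "hr": hr_curve.hr,
                "band_lo": hr_curve.band_lower, "band_hi": hr_curve.band_upper,
            }).to_csv(outdir / "hr.csv", index=False)
            outputs.append(outdir / "hr.csv")
            summary["hazard_ratio"] = {
                "peak_age_days": s.peak_age_days, "peak_hr": s.peak_hr,
                "convergence_age_days": s.convergence_age_days,
                "no_distinct_peak": s.no_distinct_peak,
                "n_bootstrap": hr_curve.n_bootstrap,
            }

        # ---- classical survival comparisons ----------------------------
        if "survtest" in config.stages:
            current = "survtest"
            medians = {}
            for sex in ("F", "M"):
                sub = tab[tab["sex"] == sex]
                est = median_with_ci(km_curve(sub["age_days"], sub["status"]))
                medians[sex] = {"median_days": est.median_days,
                                "ci": [est.ci_lower_days, est.ci_upper_days]}
            f, m = tab[tab["sex"] == "F"], tab[tab["sex"] == "M"]
            chi2, p = logrank(f["age_days"], f["status"], m["age_days"], m["status"])
            ml = max_lifespan_test(cohort)
            summary["survival"] = {
                "median": medians,
                "logrank": {"chi_square": chi2, "p": p},
                "max_lifespan": {
                    "threshold_age_days": ml.threshold_age_days,
                    "proportion_alive": ml.proportions,
                    "fisher_p": ml.fisher_p,
                },
            }

        # ---- Cox sex x site --------------------------------------------
        if "cox" in config.stages:
            current = "cox"
            cox = cox_fit(cohort, include_interaction=True)
            summary["cox"] = {
                "terms": [{"name": t.name, "coef": t.coef, "se": t.se,
                           "hazard_ratio": t.hazard_ratio, "p": t.p}
                          for t in cox.terms],
                "lrt": {"statistic": cox.lrt_statistic, "df": cox.lrt_df,
                        "p": cox.lrt_p},
            }

        # ---- bodyweight regressions ------------------------------------
        if "weightreg" in config.stages and weights is not None:
            current = "weightreg"
            joined, report = join_weights(cohort, weights)
            report.write(outdir / "weight_exclusions.csv")
            outputs.append(outdir / "weight_exclusions.csv")
            rows = []
            for months in MEASUREMENT_AGES_MONTHS:
                if not (joined["age_months"] == months).any():
                    continue
                for res in (weight_regression(joined, months, stratify_by_sex=False)
                            + weight_regression(joined, months, stratify_by_sex=True)):
                    rows.append({
                        "age_months": res.age_months, "stratum": res.stratum,
                        "coefficient": res.coefficient, "se": res.se, "p": res.p,
                        "r_squared": res.r_squared,
                        "standardized_coefficient": res.standardized_coefficient,
                        "n": res.n,
                    })
            pd.DataFrame(rows).to_csv(outdir / "weight_regression.csv", index=False)
            outputs.append(outdir / "weight_regression.csv")
            inter = interaction_regression(joined, 6, moderator="sex")
            summary["weight_regression"] = {
                "table": rows,
                "sex_weight_interaction": {
                    "age_months": 6, "F": inter.interaction_f,
                    "p": inter.interaction_p,
                },
                "exclusions": {f"{r}|{s}": n for (r, s), n in report.counts.items()},
            }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise

    _write_json(outdir / "summary.json", summary)
    outputs.append(outdir / "summary.json")
    manifest = {
        "version": __version__,
        "config_hash": summary["config_hash"],
        "seed": config.bootstrap_seed,
        "files": {p.name: _sha256(p) for p in outputs},
    }
    _write_json(outdir / "manifest.json", manifest)
    return summary
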