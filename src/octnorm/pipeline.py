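"""End-to-end study orchestration.

``run_full_study`` reproduces the whole reference-database comparison on
synthetic (or user-supplied) cohorts: generate the small and large reference
databases and the two test sets, fit the 50th/5th/1st percentile QRLs under
both databases, fit the Gaussian null, flag both test cohorts under both
databases, tabulate flag transitions and sensitivity/specificity deltas, run
the Monte Carlo subsampling study, and check the small database's
coefficients against the subsampling intervals.  Every stage's output is
serialized under the output directory and a manifest records seeds.

All randomness flows from one master seed: per-stage seeds are drawn, in a
fixed documented order, from ``numpy.random.default_rng(master_seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohorts as ch
from .compare import accuracy_of_flagging, delta_confusion, transition_table
from .flags import CutoffSet, flag_cohort
from .gaussian import fit_gaussian_model, qrl_gaussian_divergence
from .io import read_cohort_csv, write_cohort_csv
from .quantile import fit_qrl
from .registry import GLOBAL_METRICS, METRICS
from .resampling import MCConfig, membership_check, run_subsample_study

__all__ = ["RunConfig", "run_full_study", "StageError"]

TAUS = (0.50, 0.05, 0.01)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    outdir: str = "results/study"
    seed: int = 0
    metrics: tuple[str, ...] = GLOBAL_METRICS
    mc_m: int = 398
    mc_iterations: int = 1000
    n_reference_large: int = 4830
    n_reference_small: int = 398
    n_healthy_test: int = 175
    n_disease_test: int = 183
    run_mc: bool = True
    # optional paths to pre-existing cohort CSVs; None -> generate
    path_reference_large: str | None = None
    path_reference_small: str | None = None
    path_healthy_test: str | None = None
    path_disease_test: str | None = None

    def validate(self) -> None:
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unregistered metric {m!r}")


def _stage_seeds(master: int, names: tuple[str, ...]) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {name: int(rng.integers(0, 2**31 - 1)) for name in names}


def run_full_study(config: RunConfig, log=print) -> dict:
    """Run every stage; returns the study report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.seed,
        ("reference_large", "reference_small", "healthy_test", "disease_test", "mc"),
    )
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "metrics": list(config.metrics)}
    t_start = time.perf_counter()

    def stage(name):
        log(f"[{time.perf_counter() - t_start:7.1f}s] stage: {name}")

    # --- cohorts ---------------------------------------------------------
    stage("cohorts")
    try:
        data = {}
        if config.path_reference_large:
            data["reference_large"] = read_cohort_csv(config.path_reference_large)
        else:
            data["reference_large"] = ch.generate_healthy_cohort(
                ch.default_rw_rdb_config(config.n_reference_large, seed=seeds["reference_large"])
            )
        if config.path_reference_small:
            data["reference_small"] = read_cohort_csv(config.path_reference_small)
        else:
            data["reference_small"] = ch.generate_healthy_cohort(
                ch.default_c_rdb_config(config.n_reference_small, seed=seeds["reference_small"])
            )
        if config.path_healthy_test:
            data["healthy_test"] = read_cohort_csv(config.path_healthy_test)
        else:
            data["healthy_test"] = ch.generate_healthy_cohort(
                ch.default_healthy_test_config(config.n_healthy_test, seed=seeds["healthy_test"])
            )
        if config.path_disease_test:
            data["disease_test"] = read_cohort_csv(config.path_disease_test)
        else:
            base, disease = ch.default_ong_configs(
                config.n_disease_test, seed=seeds["disease_test"]
            )
            data["disease_test"] = ch.generate_disease_cohort(base, disease)
        for name, df in data.items():
            write_cohort_csv(df, outdir / f"cohort_{name}.csv")
    except Exception as e:  # noqa: BLE001 - abort with stage context
        raise StageError("cohorts", e) from e

    # --- QRL and Gaussian fits ------------------------------------------
    stage("fits")
    try:
        fits: dict[str, dict[str, dict[float, object]]] = {}
        gaussians: dict[str, dict[str, object]] = {}
        for rdb in ("reference_small", "reference_large"):
            fits[rdb] = {}
            gaussians[rdb] = {}
            for metric in config.metrics:
                spec = METRICS[metric]
                fits[rdb][metric] = {
                    tau: fit_qrl(data[rdb], spec, tau) for tau in TAUS
                }
                gaussians[rdb][metric] = fit_gaussian_model(data[rdb], spec)
        fit_dump = [
            {**fit.to_dict(), "rdb": rdb}
            for rdb, by_metric in fits.items()
            for fit_by_tau in by_metric.values()
            for fit in fit_by_tau.values()
        ] + [
            {**g.to_dict(), "rdb": rdb}
            for rdb, by_metric in gaussians.items()
            for g in by_metric.values()
        ]
        (outdir / "fits.json").write_text(json.dumps(fit_dump, indent=1))
    except Exception as e:
        raise StageError("fits", e) from e

    # --- Gaussian-null divergence ---------------------------------------
    stage("gaussian_divergence")
    try:
        age_grid = np.linspace(20.0, 80.0, 61)
        divergence = {}
        for rdb in fits:
            divergence[rdb] = {}
            for metric in config.metrics:
                qr = {t: f for t, f in fits[rdb][metric].items() if t in (0.05, 0.01)}
                div = qrl_gaussian_divergence(qr, gaussians[rdb][metric], age_grid)
                divergence[rdb][metric] = {str(t): d for t, d in div.items()}
        (outdir / "gaussian_divergence.json").write_text(json.dumps(divergence, indent=1))
        report["gaussian_divergence"] = divergence
    except Exception as e:
        raise StageError("gaussian_divergence", e) from e

    # --- flagging --------------------------------------------------------
    stage("flagging")
    try:
        crossings: list[dict] = []
        flags: dict[str, dict[str, dict[str, pd.DataFrame]]] = {}
        for cohort in ("healthy_test", "disease_test"):
            flags[cohort] = {}
            for metric in config.metrics:
                flags[cohort][metric] = {}
                for rdb in ("reference_small", "reference_large"):
                    cs = CutoffSet(
                        metric=metric, method="quantile",
                        fits=fits[rdb][metric], rdb=rdb,
                    )
                    table, counts = flag_cohort(data[cohort], cs, on_crossing="log")
                    if "crossed_eyes" in counts:
                        crossings.append(
                            {
                                "cohort": cohort, "metric": metric, "rdb": rdb,
                                "eyes": counts["crossed_eyes"],
                            }
                        )
                        log(
                            f"  quantile crossing: {metric} under {rdb} at "
                            f"{len(counts['crossed_eyes'])} {cohort} eye(s)"
                        )
                    flags[cohort][metric][rdb] = table
                    table.to_csv(
                        outdir / f"flags_{cohort}_{metric}_{rdb}.csv", index=False
                    )
        report["quantile_crossings"] = crossings
    except Exception as e:
        raise StageError("flagging", e) from e

    # --- transitions and deltas -----------------------------------------
    stage("comparison")
    try:
        comparison = {}
        for metric in config.metrics:
            tabH = transition_table(
                flags["healthy_test"][metric]["reference_small"],
                flags["healthy_test"][metric]["reference_large"],
            )
            tabD = transition_table(
                flags["disease_test"][metric]["reference_small"],
                flags["disease_test"][metric]["reference_large"],
            )
            deltas = {
                lvl: delta_confusion(tabH, tabD, lvl).to_dict() for lvl in ("5%", "1%")
            }
            truth = pd.concat(
                [
                    pd.Series(
                        "healthy",
                        index=flags["healthy_test"][metric]["reference_small"]["eye_id"],
                    ),
                    pd.Series(
                        "disease",
                        index=flags["disease_test"][metric]["reference_small"]["eye_id"],
                    ),
                ]
            )
            all_small = pd.concat(
                [
                    flags["healthy_test"][metric]["reference_small"],
                    flags["disease_test"][metric]["reference_small"],
                ]
            )
            all_large = pd.concat(
                [
                    flags["healthy_test"][metric]["reference_large"],
                    flags["disease_test"][metric]["reference_large"],
                ]
            )
            discordance = accuracy_of_flagging(all_small, all_large, truth)
            comparison[metric] = {
                "healthy_transitions": tabH.paper_rows(),
                "healthy_total_changed": tabH.n_changed(),
                "healthy_percent_changed": tabH.percent_changed(),
                "disease_transitions": tabD.paper_rows(),
                "disease_total_changed": tabD.n_changed(),
                "disease_percent_changed": tabD.percent_changed(),
                "deltas": deltas,
                "discordance": discordance,
            }
        (outdir / "comparison.json").write_text(json.dumps(comparison, indent=1))
        report["comparison"] = comparison
    except Exception as e:
        raise StageError("comparison", e) from e

    # --- Monte Carlo subsampling ----------------------------------------
    if config.run_mc:
        stage("monte_carlo")
        try:
            mc_report = {}
            for metric in config.metrics:
                spec = METRICS[metric]
                mc = MCConfig(
                    m=config.mc_m, iterations=config.mc_iterations, seed=seeds["mc"],
                )
                dist = run_subsample_study(data["reference_large"], spec, mc)
                dist.to_frame().to_csv(outdir / f"mc_{metric}.csv", index=False)
                small_fits = {
                    t: fits["reference_small"][metric][t] for t in (0.05, 0.01)
                }
                table, counts = membership_check(small_fits, dist)
                table.to_csv(outdir / f"mc_membership_{metric}.csv", index=False)
                mc_report[metric] = {
                    "ci": {
                        str(tau): {
                            coef: list(dist.ci(tau, coef))
                            for coef in dist.estimates[tau]
                        }
                        for tau in dist.estimates
                    },
                    "membership": counts,
                    "redraws": dist.redraws,
                }
            (outdir / "mc_summary.json").write_text(json.dumps(mc_report, indent=1))
            report["monte_carlo"] = mc_report
        except Exception as e:
            raise StageError("monte_carlo", e) from e

    # --- manifest --------------------------------------------------------
    report["runtime_s"] = time.perf_counter() - t_start
    manifest = {
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": seeds,
        "taus": list(TAUS),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    stage("done")
    return report
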