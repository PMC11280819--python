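"""End-to-end orchestration of the drinking-water-source analysis.

Stage order: simulate (optional) -> wqi -> ei -> hra -> geodetect ->
associate.  Each stage reads ``measurements.csv`` (and ``covariates.csv``
where relevant), writes its own CSV outputs under one output directory,
and contributes headline quantities to ``report.json``.  One global seed
fans out to fixed per-stage child seeds, so disabling a stage never
perturbs another stage's random stream.  On any stage failure the files
already written by this run are removed before the error propagates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, exposure_risk, geodetector, synthetic_data, trophic_state, wq_index
from .configio import (
    load_class3_limits,
    load_exposure_model,
    load_geodetector_config,
    load_toxicity,
    load_trophic_config,
    load_wqi_config,
)
from .synthetic_data import METALS, PARAMETERS, SEASONS

log = logging.getLogger("aquarisk")

REQUIRED_MEASUREMENT_COLUMNS = ("site_id", "season") + PARAMETERS

# fixed seed-splitting offsets; adding a stage must not renumber others
_STAGE_STREAMS = {"sites": 11, "covariates": 12, "measurements": 13, "hra": 21}

#: Responses screened by the geodetector stage.
GEODETECTOR_RESPONSES = METALS + ("TN", "TP")


@dataclass
class RunConfig:
    """Inputs, toggles and seeds for one pipeline run."""

    outdir: Path
    seed: int = 0
    simulate: bool = True
    n_sites: int = 59
    measurements_path: Path | None = None
    covariates_path: Path | None = None
    wqi_config_path: Path | None = None
    trophic_config_path: Path | None = None
    exposure_path: Path | None = None
    toxicity_path: Path | None = None
    geodetector_path: Path | None = None
    n_iter: int = 10_000
    keep_draws: bool = False
    stages: tuple[str, ...] = ("wqi", "ei", "hra", "geodetect", "associate")

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        self.outdir = Path(self.outdir)
        if not self.simulate:
            if self.measurements_path is None:
                raise ValueError("measurements_path is required when simulate is off")
            if not Path(self.measurements_path).exists():
                raise FileNotFoundError(f"measurements file not found: {self.measurements_path}")


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, _STAGE_STREAMS[stage]]).generate_state(1)[0] % (2**31)
    )


def validate_inputs(
    measurements: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> list[dict]:
    """Report-only input validation: required columns, positive
    concentrations, legal season labels, site-id consistency."""
    issues: list[dict] = []
    for col in REQUIRED_MEASUREMENT_COLUMNS:
        if col not in measurements.columns:
            issues.append({"table": "measurements", "column": col, "issue": "missing column"})
    if "season" in measurements.columns:
        bad = set(measurements["season"].unique()) - set(SEASONS)
        if bad:
            issues.append(
                {"table": "measurements", "column": "season",
                 "issue": f"unknown season label(s) {sorted(bad)}"}
            )
    for col in PARAMETERS:
        if col not in measurements.columns:
            continue
        vals = measurements[col]
        bad_rows = measurements.index[(vals <= 0) | vals.isna()].tolist()
        for row in bad_rows:
            issues.append(
                {"table": "measurements", "column": col, "row": int(row),
                 "issue": "non-positive or missing concentration"}
            )
    if covariates is not None and "site_id" in measurements.columns:
        m_sites = set(measurements["site_id"])
        c_sites = set(covariates["site_id"]) if "site_id" in covariates.columns else set()
        for s in sorted(c_sites - m_sites):
            issues.append(
                {"table": "covariates", "column": "site_id",
                 "issue": f"site {s!r} absent from measurements"}
            )
        for s in sorted(m_sites - c_sites):
            issues.append(
                {"table": "measurements", "column": "site_id",
                 "issue": f"site {s!r} absent from covariates"}
            )
    return issues


class _OutputTracker:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []

    def write_csv(self, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        p = self.outdir / name
        df.to_csv(p, index=index)
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def _season_mean(measurements: pd.DataFrame, columns) -> pd.DataFrame:
    return measurements.groupby("site_id", sort=True)[list(columns)].mean()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all outputs plus report.json.

    Returns the report dictionary.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    out = _OutputTracker(config.outdir)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    t0 = time.perf_counter()
    try:
        covariates = None
        if config.simulate:
            log.info("stage simulate: %d sites", config.n_sites)
            sites = synthetic_data.generate_sites(
                config.n_sites, seed=_stage_seed(config.seed, "sites")
            )
            covariates = synthetic_data.generate_covariates(
                sites, seed=_stage_seed(config.seed, "covariates")
            )
            measurements = synthetic_data.generate_measurements(
                sites, covariates, seed=_stage_seed(config.seed, "measurements")
            )
            out.write_csv("sites.csv", sites)
            out.write_csv("covariates.csv", covariates)
            out.write_csv("measurements.csv", measurements)
        else:
            measurements = pd.read_csv(config.measurements_path)
            if config.covariates_path is not None:
                covariates = pd.read_csv(config.covariates_path)
        missing = [c for c in REQUIRED_MEASUREMENT_COLUMNS if c not in measurements.columns]
        if missing:
            raise ValueError(f"measurements table lacks required column(s): {missing}")
        report["n_sites"] = int(measurements["site_id"].nunique())
        report["n_records"] = int(len(measurements))
        report["validation_issues"] = len(validate_inputs(measurements, covariates))

        if "wqi" in config.stages:
            log.info("stage wqi")
            wcfg = load_wqi_config(config.wqi_config_path)
            limits = load_class3_limits(config.wqi_config_path)
            wtab = wq_index.wqi_table(measurements, wcfg)
            out.write_csv("wqi_results.csv", wtab)
            exc = wq_index.exceedance_summary(measurements, limits)
            out.write_csv("exceedance.csv", exc, index=True)
            counts = wtab["wqi_class"].value_counts().to_dict()
            report["wqi"] = {
                "mean": float(wtab["WQI"].mean()),
                "class_counts": {k: int(v) for k, v in sorted(counts.items())},
                "exceedance_pct": {
                    p: float(exc.loc[p, "exceedance_pct"]) for p in exc.index
                },
            }

        if "ei" in config.stages:
            log.info("stage ei")
            tcfg = load_trophic_config(config.trophic_config_path)
            etab = trophic_state.ei_table(measurements, tcfg)
            out.write_csv("ei_results.csv", etab)
            per_site = _season_mean(measurements, PARAMETERS)
            rho = trophic_state.ei_correlates(
                etab.set_index("site_id")["EI"].loc[per_site.index], per_site
            )
            out.write_csv(
                "ei_correlations.csv",
                rho.rename_axis("parameter").reset_index(), index=False,
            )
            shares = (
                etab["grade_label"].value_counts(normalize=True).mul(100.0).to_dict()
            )
            report["trophic"] = {
                "overall_EI": float(etab["EI"].mean()),
                "grade_shares_pct": {k: float(v) for k, v in sorted(shares.items())},
            }

        if "hra" in config.stages:
            log.info("stage hra: %d iterations", config.n_iter)
            emodel = load_exposure_model(config.exposure_path)
            tox = load_toxicity(config.toxicity_path)
            conc_specs = {
                m: exposure_risk.fit_concentration(measurements[m]) for m in METALS
            }
            summary, draws = exposure_risk.monte_carlo_risk(
                conc_specs, emodel, tox,
                n_iter=config.n_iter,
                seed=_stage_seed(config.seed, "hra"),
                keep_draws=True,
            )
            out.write_csv("risk_summary.csv", summary, index=True)
            curves = []
            for (metal, pop), d in draws.items():
                for kind in ("CR", "HQ"):
                    if d[kind] is None:
                        continue
                    c = exposure_risk.cumulative_frequency(d[kind])
                    c.insert(0, "metal", metal)
                    c.insert(1, "population", pop)
                    c.insert(2, "quantity", kind)
                    curves.append(c)
            out.write_csv("cumulative_frequency.csv", pd.concat(curves, ignore_index=True))
            if config.keep_draws:
                flat = {
                    f"{m}_{p}_{k}": d[k]
                    for (m, p), d in draws.items()
                    for k in ("CR", "HQ")
                    if d[k] is not None
                }
                out.write_csv("risk_draws.csv", pd.DataFrame(flat))
            ranking = exposure_risk.risk_ranking(summary)
            report["hra"] = {
                "n_iter": config.n_iter,
                "ranking": ranking,
                "P_CR_gt_1e6": {
                    f"{m}|{p}": float(v)
                    for (m, p), v in summary["P_CR_gt_1e6"].dropna().items()
                },
                "P_HQ_gt_1": {
                    f"{m}|{p}": float(v) for (m, p), v in summary["P_HQ_gt_1"].items()
                },
            }

        if "geodetect" in config.stages:
            if covariates is None:
                raise ValueError("geodetect stage requires a covariates table")
            log.info("stage geodetect")
            gcfg = load_geodetector_config(config.geodetector_path)
            responses = _season_mean(measurements, GEODETECTOR_RESPONSES)
            cov = covariates.set_index("site_id").loc[responses.index].reset_index()
            factors = cov[list(synthetic_data.FACTOR_NAMES)]
            qmat = geodetector.factor_screen(
                responses, factors, method=gcfg["method"], n_classes=gcfg["n_classes"]
            )
            out.write_csv("q_factors.csv", qmat, index=True)
            inter = geodetector.interaction_screen(
                responses, factors,
                method=gcfg["method"], n_classes=gcfg["n_classes"],
                tolerance=gcfg["tolerance"],
            )
            out.write_csv("q_interactions.csv", inter)
            top_factors = {
                r: qmat.loc[r].sort_values(ascending=False).head(3).to_dict()
                for r in qmat.index
            }
            top_inter = {}
            for r, grp in inter.groupby("response"):
                top = grp.sort_values("q12", ascending=False).head(3)
                top_inter[r] = [
                    {"pair": f"{a}x{b}", "q12": float(v)}
                    for a, b, v in zip(top["factor_a"], top["factor_b"], top["q12"])
                ]
            report["geodetector"] = {
                "top_factors": top_factors, "top_interactions": top_inter
            }

        if "associate" in config.stages:
            log.info("stage associate")
            metals_site = _season_mean(measurements, METALS)
            corr = association.correlation_matrix(metals_site)
            out.write_csv("correlations.csv", corr, index=True)
            pca = association.pca_rotated(metals_site, n_components=2)
            out.write_csv("pca_loadings.csv", pca.loadings, index=True)
            report["association"] = {
                "explained_pct": [float(v) for v in pca.explained_pct],
                "cumulative_pct": float(pca.cumulative_pct),
                "rotation": pca.rotation,
            }

        # timing is logged, not reported: report.json must be byte-identical
        # across runs with the same seed
        report_path = config.outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        out.written.append(report_path)
        log.info("pipeline done in %.1fs", time.perf_counter() - t0)
        return report
    except Exception:
        out.cleanup()
        raise
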