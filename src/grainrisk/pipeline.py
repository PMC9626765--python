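"""End-to-end orchestration: data -> indices -> risk -> surfaces -> stats.

``run_pipeline`` executes the whole analysis on a sample table (read from
disk or synthesized) and writes every artifact into one output directory:
concentration summary tables, the pollution-index table, mean-level and
per-sample risk tables, IDW concentration and exceedance rasters,
regression and population-comparison tables, and a machine-readable JSON
report of the headline numbers.  ``reference_comparison`` (re-exported
from :mod:`grainrisk.reference`) recomputes the published risk indicators
from the published mean concentrations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from .errors import ConfigError
from .io_config import (
    CROPS,
    ParameterSet,
    default_parameters,
    read_samples,
    subset,
    summarize,
    write_samples,
)
from .pollution_index import (
    bin_cd_categories,
    bin_f_categories,
    exceedance_ratio,
    pi_for_crop,
)
from .reference import reference_comparison
from .risk import mean_risk, per_sample_risk
from .spatial_idw import (
    GridSpec,
    exceedance_surface,
    interpolate_surface,
    write_ascii_grid,
)
from .stats_inference import annotate_significance, fit_regression, mann_whitney
from .synthetic_data import STUDY_BBOX, generate_survey

logger = logging.getLogger("grainrisk")

__all__ = ["RunConfig", "run_pipeline", "reference_comparison"]


def round_sig(x: float, digits: int = 6) -> float:
    """Round to significant digits (byte-stable JSON serialization)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class RunConfig:
    """One pipeline invocation: exactly one of input_path / synth."""

    outdir: str | Path
    input_path: str | Path | None = None
    synth: bool = False
    seed: int = 1
    params: ParameterSet | None = None
    grid: tuple[int, int] = (200, 150)  # n_cols, n_rows
    power: float = 2.0
    neighbors: int = 12

    def __post_init__(self) -> None:
        if (self.input_path is None) == (not self.synth):
            raise ConfigError("specify exactly one of input_path or synth")


def _risk_rows(results, mean_level: bool) -> list[dict]:
    rows = []
    for res in results:
        for element in ("F", "Cd"):
            rows.append({
                **({"sample_id": res.sample_id} if not mean_level else {}),
                "crop": res.crop,
                "population": res.population,
                "element": element,
                "adi": res.adi[element],
                "thq": res.thq[element],
                "hi": res.hi,
                "r": res.r_cd if element == "Cd" else "",
                "r_band": res.r_band if element == "Cd" else "",
                "hi_flag": res.hi_flag,
            })
    return rows


def _bin_rows(binning, exceed_pct: float | None) -> list[dict]:
    rows = []
    for i, b in enumerate(binning.per_category, start=1):
        rows.append({
            "crop": binning.crop,
            "element": binning.element,
            "category": i,
            "n": b.n,
            "obs_min": b.obs_min if b.obs_min is not None else "",
            "obs_max": b.obs_max if b.obs_max is not None else "",
            "median": b.median if b.median is not None else "",
            "mean": b.mean if b.mean is not None else "",
            "exceeding_ratio_pct": exceed_pct if (i == 1 and exceed_pct is not None) else "",
        })
    return rows


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the JSON report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg.params or default_parameters()

    if cfg.synth:
        logger.info("stage synth: generating survey (seed=%d)", cfg.seed)
        records = generate_survey(cfg.seed)
        write_samples(records, outdir / "samples.csv")
    else:
        logger.info("stage read: %s", cfg.input_path)
        records = read_samples(cfg.input_path)

    crops = [c for c in CROPS if subset(records, c)]
    report: dict = {
        "version": 1,
        "seed": cfg.seed if cfg.synth else None,
        "n_samples": len(records),
        "crops": {},
    }

    # -- stage: summaries, pollution index, category binning
    logger.info("stage indices: Pi, grades, exceedance, binning")
    table1_rows: list[dict] = []
    table2_rows: list[dict] = []
    for crop in crops:
        si = params.element("Cd").si_for(crop)
        exceed = exceedance_ratio(records, crop, si)
        table1_rows += _bin_rows(bin_f_categories(records, crop), None)
        table1_rows += _bin_rows(bin_cd_categories(records, crop, si), exceed)
        pi_res = pi_for_crop(records, crop, si)
        summ = summarize(records, crop, "Cd")
        table2_rows.append({
            "crop": crop, "n": summ["n"],
            "cd_min": summ["min"], "cd_max": summ["max"],
            "cd_mean": summ["mean"], "limit": si,
            "pi": pi_res.pi, "grade": pi_res.grade,
        })
        report["crops"][crop] = {
            "n": summ["n"],
            "mean_f_mgkg": round_sig(summarize(records, crop, "F")["mean"]),
            "mean_cd_mgkg": round_sig(summ["mean"]),
            "pi": round_sig(pi_res.pi),
            "grade": pi_res.grade,
            "cd_exceedance_pct": round_sig(exceed),
        }
    pd.DataFrame(table1_rows).to_csv(outdir / "table1.csv", index=False)
    pd.DataFrame(table2_rows).to_csv(outdir / "table2.csv", index=False)

    # -- stage: risk (mean-level and per-sample)
    logger.info("stage risk: ADI/THQ/HI/R for adult and child")
    mean_results = []
    sample_results = {}
    for population in ("adult", "child"):
        sample_results[population] = per_sample_risk(records, params, population)
        for crop in crops:
            res = mean_risk(records, crop, params, population)
            mean_results.append(res)
            report["crops"][crop][population] = {
                "thq_f": round_sig(res.thq["F"]),
                "thq_cd": round_sig(res.thq["Cd"]),
                "hi": round_sig(res.hi),
                "r_cd": round_sig(res.r_cd),
                "r_band": res.r_band,
                "hi_flag": res.hi_flag,
            }
    pd.DataFrame(_risk_rows(mean_results, mean_level=True)).to_csv(
        outdir / "risk_summary.csv", index=False)
    all_sample_rows = _risk_rows(sample_results["adult"], mean_level=False) + \
        _risk_rows(sample_results["child"], mean_level=False)
    pd.DataFrame(all_sample_rows).to_csv(
        outdir / "per_sample_risk.csv", index=False)

    # -- stage: IDW surfaces
    n_cols, n_rows = cfg.grid
    spec = GridSpec.square(STUDY_BBOX[0], STUDY_BBOX[1], STUDY_BBOX[2],
                           n_cols=n_cols, n_rows=n_rows)
    logger.info("stage spatial: IDW %dx%d grid, power=%g, k=%d",
                n_cols, n_rows, cfg.power, cfg.neighbors)
    for crop in crops:
        group = subset(records, crop)
        for element in ("F", "Cd"):
            surf = interpolate_surface(group, element, spec,
                                       power=cfg.power, k=cfg.neighbors,
                                       crop=crop)
            write_ascii_grid(surf, outdir / f"{crop}_{element}.asc")
            if element == "Cd":
                si = params.element("Cd").si_for(crop)
                write_ascii_grid(exceedance_surface(surf, si),
                                 outdir / f"{crop}_Cd_exceedance.asc")

    # -- stage: statistics
    logger.info("stage stats: regression and population comparisons")
    reg_rows = []
    test_rows = []
    report["regression"] = {}
    report["comparisons"] = {}
    for crop in crops:
        group = subset(records, crop)
        fit = fit_regression([r.cd_mgkg for r in group],
                             [r.f_mgkg for r in group])
        reg_rows.append({"crop": crop, "slope": fit.slope,
                         "intercept": fit.intercept, "r": fit.r,
                         "p_value": fit.p_value, "n": fit.n})
        report["regression"][crop] = {
            "slope": round_sig(fit.slope), "intercept": round_sig(fit.intercept),
            "r": round_sig(fit.r), "p_value": round_sig(fit.p_value),
        }
        report["comparisons"][crop] = {}
        adult = sample_results["adult"]
        child = sample_results["child"]
        metrics = {
            "thq_F": lambda res: res.thq["F"],
            "thq_Cd": lambda res: res.thq["Cd"],
            "hi": lambda res: res.hi,
            "r_cd": lambda res: res.r_cd,
        }
        for metric, getter in metrics.items():
            a = [getter(r) for r in adult if r.crop == crop]
            c = [getter(r) for r in child if r.crop == crop]
            t = mann_whitney(a, c)
            test_rows.append({
                "crop": crop, "metric": metric, "u": t.statistic,
                "p_value": t.p_value, "method": t.method,
                "significance": annotate_significance(t.p_value),
            })
            report["comparisons"][crop][metric] = {
                "p_value": round_sig(t.p_value),
                "significance": annotate_significance(t.p_value),
            }
    pd.DataFrame(reg_rows).to_csv(outdir / "regression.csv", index=False)
    pd.DataFrame(test_rows).to_csv(outdir / "population_tests.csv", index=False)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", outdir)
    return report


def reproduce_reference(outdir: str | Path | None = None) -> pd.DataFrame:
    """Recompute published risk indicators from the published means.

    Optionally writes the computed-vs-published comparison to
    ``<outdir>/reference_comparison.csv``.
    """
    frame = reference_comparison()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / "reference_comparison.csv", index=False)
    return frame
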