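"""End-to-end orchestration: dataset -> metrics -> fits -> scores -> bias.

Glue shared by the command-line interface, the test suite and scripts.
Replicates are averaged pointwise before any scoring, matching the
per-condition curves the analysis is defined on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay_io import AnalysisConfig, PlateDataset, aggregate_replicates
from .bias import (
    BiasPoint,
    RobustnessResult,
    bias_profile,
    classify_drug,
    ks_compare,
    lumped_bias_distance,
)
from .errors import InsufficientDataError
from .kinetics import ClosureDeathMetrics, closure_death_metrics
from .landscape import (
    DoseScores,
    LandscapeFit,
    LumpedScores,
    fit_landscape,
    lumped_scores,
    phenotype_scores,
)

FLOAT_FORMAT = "%.9g"


@dataclass
class SeriesResult:
    """Scored dose series of one drug in one stratum."""

    cell_line: str
    drug: str
    density: int
    mmc: bool
    metrics: list[ClosureDeathMetrics]
    fit: LandscapeFit
    scores: list[DoseScores]
    lumped: LumpedScores
    bias_points: list[BiasPoint]
    classification: str

    @property
    def lumped_bias(self) -> float:
        return self.lumped.bias

    @property
    def lumped_distance(self) -> float:
        return lumped_bias_distance(self.lumped)


@dataclass
class ScreenResult:
    """All per-condition metrics and per-series scores of one dataset."""

    config: AnalysisConfig
    metrics: list[ClosureDeathMetrics]
    series: list[SeriesResult]


def score_dataset(dataset: PlateDataset, config: AnalysisConfig) -> ScreenResult:
    """Run the full scoring pipeline on a validated dataset."""
    dataset.validate()
    agg = aggregate_replicates(dataset)

    all_metrics: list[ClosureDeathMetrics] = []
    series_results: list[SeriesResult] = []
    for (cell_line, density, mmc), wells in sorted(agg.strata().items()):
        mets = closure_death_metrics(wells, config)
        all_metrics.extend(mets)
        by_drug: dict[str, list[ClosureDeathMetrics]] = {}
        for m in mets:
            if m.condition.is_control:
                continue
            by_drug.setdefault(m.condition.drug, []).append(m)
        for drug in sorted(by_drug):
            ms = sorted(by_drug[drug], key=lambda m: m.condition.concentration)
            fit = fit_landscape(ms, config.r2_threshold)
            scores = phenotype_scores(fit, ms)
            lumped = lumped_scores(scores)
            series_results.append(
                SeriesResult(
                    cell_line=cell_line,
                    drug=drug,
                    density=density,
                    mmc=mmc,
                    metrics=ms,
                    fit=fit,
                    scores=scores,
                    lumped=lumped,
                    bias_points=bias_profile(scores),
                    classification=classify_drug(
                        lumped, config.activity_floor, config.bias_floor
                    ),
                )
            )
    return ScreenResult(config=config, metrics=all_metrics, series=series_results)


def metrics_frame(result: ScreenResult) -> pd.DataFrame:
    """One row per condition with all closure/death metrics."""
    rows = []
    for m in result.metrics:
        c = m.condition
        rows.append(
            {
                "cell_line": c.cell_line,
                "drug": c.drug,
                "conc_uM": c.concentration,
                "density": c.density,
                "mmc": int(c.mmc),
                "endpoint_method": result.config.endpoint_method,
                "window_end": m.window_end,
                "auc_rwd": m.auc_rwd,
                "wc": m.wc,
                "wc_ind": m.wc_ind,
                "auc_death": m.auc_death,
                "dc": m.dc,
                "dc_raw": m.dc_raw,
            }
        )
    return pd.DataFrame(rows)


def scores_frame(result: ScreenResult) -> pd.DataFrame:
    """Per-dose score rows plus one lumped summary row per series."""
    rows = []
    for s in result.series:
        common = {
            "cell_line": s.cell_line,
            "drug": s.drug,
            "density": s.density,
            "mmc": int(s.mmc),
            "endpoint_method": result.config.endpoint_method,
            "model": s.fit.model,
            "r2": s.fit.r2,
        }
        for m, d in zip(s.metrics, s.scores):
            rows.append(
                {
                    **common,
                    "row_type": "dose",
                    "conc_uM": d.concentration,
                    "wc": m.wc,
                    "dc": m.dc,
                    "theta_rad": d.theta,
                    "migration": d.migration,
                    "death": d.death,
                    "flag": d.flag or "",
                }
            )
        rows.append(
            {
                **common,
                "row_type": "lumped",
                "conc_uM": np.nan,
                "wc": np.nan,
                "dc": np.nan,
                "theta_rad": np.nan,
                "migration": s.lumped.migration_lumped,
                "death": s.lumped.death_lumped,
                "flag": "",
            }
        )
    return pd.DataFrame(rows)


def bias_frame(result: ScreenResult) -> pd.DataFrame:
    """Per-dose bias rows plus one lumped row per series with classification."""
    rows = []
    for s in result.series:
        common = {
            "cell_line": s.cell_line,
            "drug": s.drug,
            "density": s.density,
            "mmc": int(s.mmc),
            "endpoint_method": result.config.endpoint_method,
        }
        for p in s.bias_points:
            rows.append(
                {
                    **common,
                    "row_type": "dose",
                    "conc_uM": p.concentration,
                    "bias": p.bias,
                    "distance": p.distance,
                    "angle_rad": p.angle,
                    "classification": "",
                }
            )
        rows.append(
            {
                **common,
                "row_type": "lumped",
                "conc_uM": np.nan,
                "bias": s.lumped_bias,
                "distance": s.lumped_distance,
                "angle_rad": (
                    0.0
                    if s.lumped.migration_lumped == 0 and s.lumped.death_lumped == 0
                    else math.atan2(s.lumped.death_lumped, s.lumped.migration_lumped)
                    - math.pi / 4
                ),
                "classification": s.classification,
            }
        )
    return pd.DataFrame(rows)


def robustness_frame(bias_rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise density KS comparisons from per-dose bias rows.

    ``bias_rows`` follows the :func:`bias_frame` layout (possibly
    concatenated over several runs).  For each (cell line, drug, MMC,
    endpoint method) observed at >= 2 densities, every density pair is
    compared on its per-dose bias sample.
    """
    dose_rows = bias_rows[bias_rows["row_type"] == "dose"]
    if dose_rows.empty:
        raise InsufficientDataError("no per-dose bias rows to compare")
    out = []
    group_cols = ["cell_line", "drug", "mmc", "endpoint_method"]
    for key, grp in dose_rows.groupby(group_cols, sort=True):
        densities = sorted(grp["density"].unique())
        if len(densities) < 2:
            continue
        samples = {
            d: grp[grp["density"] == d].sort_values("conc_uM")["bias"].to_numpy()
            for d in densities
        }
        for da, db in itertools.combinations(densities, 2):
            res: RobustnessResult = ks_compare(samples[da], samples[db], alpha, (da, db))
            out.append(
                dict(
                    zip(group_cols, key),
                    density_a=da,
                    density_b=db,
                    n_a=len(samples[da]),
                    n_b=len(samples[db]),
                    ks_distance=res.ks_distance,
                    p_value=res.p_value,
                    significant=int(res.significant),
                )
            )
    if not out:
        raise InsufficientDataError(
            "robustness comparison needs >= 2 seeding densities per series"
        )
    return pd.DataFrame(out)


def write_frame(df: pd.DataFrame, path) -> None:
    """Write a result table with platform-stable 9-significant-digit floats."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
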