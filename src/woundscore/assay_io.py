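"""Typed containers and file I/O for scratch-assay time-series exports.

A live-imaging instrument (IncuCyte-style) exports, per well, a sampled
trace of relative wound density (RWD, in percent) and integrated
caspase-3/7 signal (arbitrary units).  A separate plate map annotates each
well with its experimental condition: cell line, drug, concentration,
seeding density, Mitomycin-C pre-treatment flag, and replicate id.  This
module reads both files into a validated :class:`PlateDataset` and provides
replicate averaging plus the analysis configuration.

RWD is stored internally as a fraction in [0, 1]; conversion from percent
happens only at the file boundary so that every downstream threshold lives
in fractional units.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    EmptyInputError,
    FormatError,
    RangeError,
    SequencingError,
    StratumError,
)

VEHICLE = "DMSO"

# Instrument RWD occasionally overshoots 100% by a few percent; values in
# (100, 105]% are clamped to 100% on read, anything larger is an error.
RWD_CLAMP_LIMIT_PCT = 105.0

TIMESERIES_COLUMNS = ("well", "time_h", "rwd_pct", "caspase_au")
PLATE_MAP_COLUMNS = ("well", "cell_line", "drug", "conc_uM", "density", "mmc", "replicate")


@dataclass(frozen=True, order=True)
class Condition:
    """Experimental annotation of one well.

    ``drug == "DMSO"`` is reserved for the vehicle control and must carry
    concentration 0; conversely any zero-concentration well must be DMSO.
    """

    cell_line: str
    drug: str
    concentration: float
    density: int
    mmc: bool
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise RangeError(f"negative concentration {self.concentration} for {self}")
        if (self.drug == VEHICLE) != (self.concentration == 0):
            raise FormatError(
                f"vehicle invariant violated: drug={self.drug!r} "
                f"concentration={self.concentration} (DMSO <=> 0 uM)"
            )
        if self.density <= 0:
            raise RangeError(f"non-positive density {self.density}")
        if self.replicate < 1:
            raise RangeError(f"replicate id must be >= 1, got {self.replicate}")

    @property
    def is_control(self) -> bool:
        return self.drug == VEHICLE

    @property
    def stratum_key(self) -> tuple[str, int, bool]:
        """Wells sharing (cell line, density, MMC) are scored against one control."""
        return (self.cell_line, self.density, self.mmc)

    @property
    def series_key(self) -> tuple[str, str, int, bool]:
        """One dose series: (cell line, drug, density, MMC)."""
        return (self.cell_line, self.drug, self.density, self.mmc)

    def without_replicate(self) -> "Condition":
        return dataclasses.replace(self, replicate=1)


@dataclass
class WellTimeSeries:
    """One well's sampled (time, RWD, caspase) trace.

    times are hours, strictly increasing, starting at 0; rwd is a fraction
    in [0, 1]; caspase is a non-negative integrated intensity in arbitrary
    units.  All three arrays have equal length >= 3.
    """

    condition: Condition
    times: np.ndarray
    rwd: np.ndarray
    caspase: np.ndarray
    well_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rwd = np.asarray(self.rwd, dtype=float)
        self.caspase = np.asarray(self.caspase, dtype=float)
        n = self.times.size
        label = self.well_id or str(self.condition)
        if not (n == self.rwd.size == self.caspase.size):
            raise SequencingError(f"well {label}: times/rwd/caspase lengths differ")
        if n < 3:
            raise SequencingError(f"well {label}: need >= 3 time points, got {n}")
        if self.times[0] != 0:
            raise SequencingError(f"well {label}: times must start at 0, got {self.times[0]}")
        if not np.all(np.diff(self.times) > 0):
            raise SequencingError(f"well {label}: times not strictly increasing")
        if not np.all(np.isfinite(self.times) & np.isfinite(self.rwd) & np.isfinite(self.caspase)):
            raise RangeError(f"well {label}: non-finite values in trace")
        if np.any(self.rwd < -1e-12) or np.any(self.rwd > 1 + 1e-12):
            raise RangeError(f"well {label}: RWD fraction outside [0, 1]")
        if np.any(self.caspase < 0):
            raise RangeError(f"well {label}: negative caspase signal")


@dataclass
class PlateDataset:
    """A collection of wells plus free-form metadata.

    Invariants enforced by :meth:`validate`: condition keys are unique;
    every stratum containing a treated well also contains at least one
    vehicle-control well (scores are control-normalized); all wells of a
    stratum share one exact time grid (no silent resampling).
    """

    wells: list[WellTimeSeries]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "PlateDataset":
        seen: set[tuple] = set()
        for w in self.wells:
            c = w.condition
            key = (c.cell_line, c.drug, c.concentration, c.density, c.mmc, c.replicate)
            if key in seen:
                raise FormatError(f"duplicate condition {key}")
            seen.add(key)
        for skey, wells in self.strata().items():
            if not any(w.condition.is_control for w in wells):
                if any(not w.condition.is_control for w in wells):
                    raise StratumError(
                        f"stratum {skey} has treated wells but no {VEHICLE} control"
                    )
            ref = wells[0].times
            for w in wells[1:]:
                if w.times.shape != ref.shape or not np.array_equal(w.times, ref):
                    raise SequencingError(
                        f"stratum {skey}: wells do not share a common time grid"
                    )
        return self

    def strata(self) -> dict[tuple[str, int, bool], list[WellTimeSeries]]:
        out: dict[tuple[str, int, bool], list[WellTimeSeries]] = defaultdict(list)
        for w in self.wells:
            out[w.condition.stratum_key].append(w)
        return dict(out)

    def __len__(self) -> int:
        return len(self.wells)


@dataclass
class AnalysisConfig:
    """Analysis-window and scoring configuration.

    endpoint_method: 'A' fixed experiment endpoint; 'B' time at which the
    vehicle-control closure rate declines below ``slope_threshold``
    (fraction RWD per hour); 'C' per-condition time to reach ``rwd_target``.
    """

    endpoint_method: str = "B"
    fixed_endpoint: float = 72.0
    slope_threshold: float = 0.02
    rwd_target: float = 0.5
    r2_threshold: float = 0.6
    ks_alpha: float = 0.05
    slope_smooth_window: int = 3
    slope_guard: float = 0.25
    activity_floor: float = 0.05
    bias_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.endpoint_method not in ("A", "B", "C"):
            raise FormatError(f"endpoint_method must be A, B or C, got {self.endpoint_method!r}")
        if self.fixed_endpoint <= 0 or self.slope_threshold <= 0:
            raise RangeError("fixed_endpoint and slope_threshold must be positive")
        if not (0 < self.rwd_target < 1):
            raise RangeError(f"rwd_target must lie in (0, 1), got {self.rwd_target}")
        if not (0 < self.r2_threshold < 1):
            raise RangeError(f"r2_threshold must lie in (0, 1), got {self.r2_threshold}")
        if not (0 < self.ks_alpha < 1):
            raise RangeError(f"ks_alpha must lie in (0, 1), got {self.ks_alpha}")
        if self.slope_smooth_window < 1 or self.slope_smooth_window % 2 == 0:
            raise RangeError("slope_smooth_window must be a positive odd integer")
        if not (0 <= self.slope_guard < 1):
            raise RangeError("slope_guard must lie in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def read_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML or JSON; all keys optional."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise FormatError(f"config file {path} must contain a mapping")
    return AnalysisConfig.from_mapping(data)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_timeseries(path: str | Path, plate_map_path: str | Path) -> PlateDataset:
    """Read a time-series CSV and its plate map into a validated PlateDataset.

    Time-series columns: well, time_h, rwd_pct, caspase_au (one row per
    well x time point).  Plate-map columns: well, cell_line, drug, conc_uM,
    density, mmc, replicate.  RWD percent is divided by 100; percent values
    in (100, 105] are clamped to 100, larger values are a range error.
    """
    # round_trip parsing: the default float parser may be off by one ulp,
    # which would break bit-exact write/read round-trips
    ts = pd.read_csv(path, float_precision="round_trip")
    pm = pd.read_csv(plate_map_path, float_precision="round_trip")
    _require_columns(ts, TIMESERIES_COLUMNS, path)
    _require_columns(pm, PLATE_MAP_COLUMNS, plate_map_path)

    if pm["well"].duplicated().any():
        dups = pm.loc[pm["well"].duplicated(), "well"].tolist()
        raise FormatError(f"{plate_map_path}: duplicate well id(s) {dups}")

    ts_wells = set(ts["well"].astype(str))
    pm_wells = set(pm["well"].astype(str))
    only_ts = sorted(ts_wells - pm_wells)
    only_pm = sorted(pm_wells - ts_wells)
    if only_ts or only_pm:
        raise FormatError(
            f"wells present in only one file: time-series-only={only_ts}, "
            f"plate-map-only={only_pm}"
        )

    conditions: dict[str, Condition] = {}
    for row in pm.itertuples(index=False):
        mmc_raw = int(row.mmc)
        if mmc_raw not in (0, 1):
            raise FormatError(f"{plate_map_path}: well {row.well}: mmc must be 0 or 1")
        conditions[str(row.well)] = Condition(
            cell_line=str(row.cell_line),
            drug=str(row.drug),
            concentration=float(row.conc_uM),
            density=int(row.density),
            mmc=bool(mmc_raw),
            replicate=int(row.replicate),
        )

    wells: list[WellTimeSeries] = []
    for well_id, grp in ts.groupby("well", sort=False):
        pct = grp["rwd_pct"].to_numpy(dtype=float)
        if np.any(pct < -1e-9) or np.any(pct > RWD_CLAMP_LIMIT_PCT):
            bad = pct[(pct < -1e-9) | (pct > RWD_CLAMP_LIMIT_PCT)][0]
            raise RangeError(
                f"well {well_id}: rwd_pct {bad} outside [0, {RWD_CLAMP_LIMIT_PCT}]%"
            )
        pct = np.clip(pct, 0.0, 100.0)
        times = grp["time_h"].to_numpy(dtype=float)
        if not np.all(np.diff(times) > 0):
            raise SequencingError(f"well {well_id}: time_h not strictly increasing")
        wells.append(
            WellTimeSeries(
                condition=conditions[str(well_id)],
                times=times,
                rwd=pct / 100.0,
                caspase=grp["caspase_au"].to_numpy(dtype=float),
                well_id=str(well_id),
            )
        )
    return PlateDataset(wells=wells).validate()


def _percent_repr(frac: float) -> str:
    """Shortest percent string whose parse-and-divide reproduces ``frac``.

    (x*100)/100 is not bit-exact for every double, so search a few ulps
    around fl(100*x) for an exactly invertible representation; fractions
    that were themselves read from a percent column always have one.
    """
    p = frac * 100.0
    candidates = [p]
    up = down = p
    for _ in range(3):
        up = np.nextafter(up, np.inf)
        down = np.nextafter(down, -np.inf)
        candidates += [up, down]
    for cand in candidates:
        if float(cand) / 100.0 == frac:
            return repr(float(cand))
    return repr(float(p))


def quantize_rwd(rwd: np.ndarray) -> np.ndarray:
    """Snap RWD fractions onto the percent-representable grid.

    Applying fl(fl(100*x)/100) makes a trace survive the percent round-trip
    through :func:`write_timeseries` / :func:`read_timeseries` bit-exactly.
    """
    return (np.asarray(rwd, dtype=float) * 100.0) / 100.0


def _assign_well_ids(dataset: PlateDataset) -> list[str]:
    ids = []
    for i, w in enumerate(dataset.wells):
        ids.append(w.well_id if w.well_id is not None else f"W{i + 1:03d}")
    if len(set(ids)) != len(ids):
        raise FormatError("well ids are not unique")
    return ids


def write_timeseries(dataset: PlateDataset, path: str | Path) -> None:
    """Write the time-series CSV (well, time_h, rwd_pct, caspase_au)."""
    ids = _assign_well_ids(dataset)
    lines = [",".join(TIMESERIES_COLUMNS)]
    for well_id, w in zip(ids, dataset.wells):
        for t, r, c in zip(w.times, w.rwd, w.caspase):
            lines.append(f"{well_id},{float(t)!r},{_percent_repr(float(r))},{float(c)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_plate_map(dataset: PlateDataset, path: str | Path) -> None:
    """Write the plate-map CSV (well, cell_line, drug, conc_uM, density, mmc, replicate)."""
    ids = _assign_well_ids(dataset)
    lines = [",".join(PLATE_MAP_COLUMNS)]
    for well_id, w in zip(ids, dataset.wells):
        c = w.condition
        lines.append(
            f"{well_id},{c.cell_line},{c.drug},{c.concentration!r},"
            f"{c.density},{int(c.mmc)},{c.replicate}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def aggregate_replicates(dataset: PlateDataset) -> PlateDataset:
    """Average replicate wells pointwise into one well per condition.

    Wells sharing a Condition up to replicate id are replaced by a single
    well whose RWD and caspase traces are pointwise means.  Replicate
    counts are recorded in the returned metadata; the operation is
    idempotent (a single replicate passes through unchanged).
    """
    if not dataset.wells:
        raise EmptyInputError("aggregate_replicates: dataset has no wells")
    groups: dict[Condition, list[WellTimeSeries]] = defaultdict(list)
    order: list[Condition] = []
    for w in dataset.wells:
        key = w.condition.without_replicate()
        if key not in groups:
            order.append(key)
        groups[key].append(w)

    wells: list[WellTimeSeries] = []
    counts: dict[str, int] = {}
    for key in order:
        members = groups[key]
        ref = members[0].times
        for m in members[1:]:
            if m.times.shape != ref.shape or not np.array_equal(m.times, ref):
                raise SequencingError(
                    f"replicates of {key} are sampled on different time grids"
                )
        if len(members) == 1:
            w = members[0]
            wells.append(WellTimeSeries(key, w.times, w.rwd, w.caspase, w.well_id))
        else:
            rwd = np.mean([m.rwd for m in members], axis=0)
            casp = np.mean([m.caspase for m in members], axis=0)
            wells.append(WellTimeSeries(key, ref.copy(), rwd, casp))
        counts[str(key)] = len(members)

    metadata = dict(dataset.metadata)
    metadata["replicate_counts"] = counts
    return PlateDataset(wells=wells, metadata=metadata).validate()


def config_to_dict(config: AnalysisConfig) -> dict:
    return dataclasses.asdict(config)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2) + "\n")
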