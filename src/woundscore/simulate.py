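"""Mechanistic synthetic scratch-assay generator with known ground truth.

The simulator emulates the phenomenology the scoring pipeline must
disentangle: saturating wound closure, drug-dependent motility inhibition
and death induction, a cumulative caspase-3/7 signal, density-dependent
closure speed, and multiplicative observation noise.

Model.  With front speed v and death rate delta,

    v     = v0 * (density / density_ref)^density_exponent
               * (1 - emax_mig * H_mig(d))
    delta = delta0 + dmax * H_death(d),        H(d) = d^h / (ec50^h + d^h)

the surviving motile fraction is S(t) = exp(-delta t) and the relative
wound density follows

    RWD(t)     = 1 - exp(-v * (1 - exp(-delta t)) / delta)
    caspase(t) = baseline + gain * (1 - exp(-delta t))

(with the delta -> 0 limit RWD = 1 - exp(-v t)).  Death therefore both
slows closure and caps its plateau below 1 - the key confound by which
cytotoxicity mimics migration inhibition in the raw closure readout.

Each well's noise stream is seeded from a hash of (seed, condition), so any
subset of a screen is reproducible independently of generation order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .assay_io import Condition, PlateDataset, WellTimeSeries, quantize_rwd
from .errors import FormatError, RangeError

SCENARIOS = ("pure_migrastatic", "pure_cytotoxic", "mixed", "null")

_SCENARIO_DRUGS = {
    "pure_migrastatic": "MIGSIM-1",
    "pure_cytotoxic": "TOXSIM-1",
    "mixed": "MIXSIM-1",
    "null": "NULLSIM-1",
}


@dataclass(frozen=True)
class HillEffect:
    """Saturating dose-effect: emax * d^hill / (ec50^hill + d^hill).

    For motility inhibition emax is a fraction in [0, 1]; for death
    induction it is the maximal added death rate in 1/h.
    """

    emax: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if self.emax < 0 or self.ec50 <= 0 or self.hill <= 0:
            raise RangeError(f"invalid Hill parameters {self}")

    def __call__(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        ratio = (dose / self.ec50) ** self.hill
        return self.emax * ratio / (1.0 + ratio)


@dataclass(frozen=True)
class SimParams:
    """Simulator settings; defaults mirror a 72 h, 2-h-interval screen.

    v0 is the closure rate (1/h) of an untreated well at the reference
    density (median 50%-closure time near 12 h, an intermediate-motility
    line); density_exponent > 0 makes denser wells close faster.  The
    death-effect EC50 sits above the motility EC50 so the mixed scenario is
    low-dose migrastatic and high-dose cytotoxic.
    """

    v0: float = 0.06
    density_ref: int = 30_000
    density_exponent: float = 0.5
    delta0: float = 0.002
    drug_mig: HillEffect = HillEffect(emax=0.9, ec50=1.0, hill=1.5)
    drug_death: HillEffect = HillEffect(emax=0.08, ec50=2.5, hill=1.5)
    caspase_gain: float = 5_000.0
    caspase_baseline: float = 100.0
    noise_sd: float = 0.02
    seed: int = 0
    sample_interval: float = 2.0
    duration: float = 72.0

    def __post_init__(self) -> None:
        if min(self.v0, self.delta0, self.caspase_gain, self.caspase_baseline) < 0:
            raise RangeError("rates and caspase parameters must be >= 0")
        if self.drug_mig.emax > 1:
            raise RangeError("motility inhibition emax must be <= 1")
        if self.noise_sd < 0:
            raise RangeError("noise_sd must be >= 0")
        if self.sample_interval <= 0 or self.duration < 3 * self.sample_interval:
            raise RangeError("need a positive interval and >= 3 samples")
        if self.density_ref <= 0:
            raise RangeError("density_ref must be positive")


def twofold_series(top: float = 10.0, n: int = 8) -> list[float]:
    """Ascending n-point two-fold serial dilution series ending at ``top`` uM."""
    return [top / 2**i for i in reversed(range(n))]


def _well_rng(seed: int, condition: Condition) -> np.random.Generator:
    """Generator seeded from a stable hash of (seed, condition)."""
    key = (
        f"{seed}|{condition.cell_line}|{condition.drug}|{condition.concentration!r}"
        f"|{condition.density}|{int(condition.mmc)}|{condition.replicate}"
    )
    digest = hashlib.sha256(key.encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *words.tolist()]))


def well_rates(params: SimParams, condition: Condition) -> tuple[float, float]:
    """Ground-truth (front speed v, death rate delta) for a condition."""
    d = condition.concentration
    v = (
        params.v0
        * (condition.density / params.density_ref) ** params.density_exponent
        * (1.0 - params.drug_mig(d))
    )
    delta = params.delta0 + params.drug_death(d)
    return v, delta


def simulate_well(params: SimParams, condition: Condition) -> WellTimeSeries:
    """Simulate one well's RWD and caspase trace."""
    v, delta = well_rates(params, condition)
    n = int(round(params.duration / params.sample_interval)) + 1
    t = np.arange(n, dtype=float) * params.sample_interval
    if delta == 0:
        effective_time = t
    else:
        effective_time = -np.expm1(-delta * t) / delta
    rwd = -np.expm1(-v * effective_time)
    dead_fraction = -np.expm1(-delta * t)
    caspase = params.caspase_baseline + params.caspase_gain * dead_fraction

    if params.noise_sd > 0:
        rng = _well_rng(params.seed, condition)
        rwd = rwd * np.exp(rng.normal(0.0, params.noise_sd, size=n))
        caspase = caspase * np.exp(rng.normal(0.0, params.noise_sd, size=n))

    rwd = quantize_rwd(np.clip(rwd, 0.0, 1.0))
    caspase = np.maximum(caspase, 0.0)
    return WellTimeSeries(condition=condition, times=t, rwd=rwd, caspase=caspase)


def scenario_params(params: SimParams, scenario: str) -> SimParams:
    """Specialize drug-effect parameters for a named screen scenario."""
    if scenario not in SCENARIOS:
        raise FormatError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    mig, death = params.drug_mig, params.drug_death
    if scenario == "pure_migrastatic":
        death = dataclasses.replace(death, emax=0.0)
    elif scenario == "pure_cytotoxic":
        mig = dataclasses.replace(mig, emax=0.0)
    elif scenario == "null":
        mig = dataclasses.replace(mig, emax=0.0)
        death = dataclasses.replace(death, emax=0.0)
    else:  # mixed: low-dose migrastatic, high-dose cytotoxic
        if death.ec50 <= mig.ec50:
            raise RangeError(
                "mixed scenario requires ec50_death > ec50_mig "
                f"(got {death.ec50} <= {mig.ec50})"
            )
    return dataclasses.replace(params, drug_mig=mig, drug_death=death)


def simulate_screen(
    params: SimParams,
    scenario: str,
    densities: Sequence[int] = (20_000, 30_000, 40_000),
    doses: Sequence[float] | None = None,
    replicates: int = 2,
    cell_line: str = "SIMCL-1",
    drug: str | None = None,
) -> PlateDataset:
    """Simulate a full screen: vehicle plus a dose series per stratum.

    Each (cell line, density) stratum gets ``replicates`` vehicle wells and
    ``replicates`` wells per dose.  Ground-truth rates per condition are
    stored in the dataset metadata.
    """
    sp = scenario_params(params, scenario)
    if doses is None:
        doses = twofold_series()
    doses = sorted(float(d) for d in doses)
    if any(d <= 0 for d in doses):
        raise RangeError("doses must be positive")
    if replicates < 1:
        raise RangeError("replicates must be >= 1")
    drug_name = drug or _SCENARIO_DRUGS[scenario]

    wells: list[WellTimeSeries] = []
    truth: dict[str, dict] = {}
    for density in densities:
        for rep in range(1, replicates + 1):
            conditions = [Condition(cell_line, "DMSO", 0.0, int(density), True, rep)]
            conditions += [
                Condition(cell_line, drug_name, dose, int(density), True, rep)
                for dose in doses
            ]
            for cond in conditions:
                wells.append(simulate_well(sp, cond))
                v, delta = well_rates(sp, cond)
                key = f"{cond.cell_line}|{cond.drug}|{cond.concentration:g}|{cond.density}|{cond.replicate}"
                truth[key] = {"v_per_h": v, "delta_per_h": delta}

    metadata = {
        "scenario": scenario,
        "cell_line": cell_line,
        "drug": drug_name,
        "seed": params.seed,
        "sim_params": dataclasses.asdict(sp),
        "ground_truth": truth,
    }
    return PlateDataset(wells=wells, metadata=metadata).validate()


def write_ground_truth(dataset: PlateDataset, path: str | Path) -> None:
    """Write the scenario, parameters and per-condition true rates as JSON."""
    payload = {
        k: dataset.metadata.get(k)
        for k in ("scenario", "cell_line", "drug", "seed", "sim_params", "ground_truth")
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
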