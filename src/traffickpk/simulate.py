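"""Synthetic trafficking studies with the measurement structure of the assay.

The generator emulates what the gamma counter would see in a real labeled-
lymphocyte study:

* blood levels follow a mono-exponential decline, linear on the log10 scale:
  log10 %Inj/ml(t) = intercept - (log10 2 / half_time) * t, with an infinite
  half-time producing the flat (steady-state) profile of a non-clearing
  host;
* tissue uptake is at steady state, parameterized by a tissue/RBC base
  ratio (ul/g) modulated multiplicatively by cell-source, host and
  interaction fold-factors — fold changes are the natural scale for
  positive biological rates;
* mouse-to-mouse biological variability is lognormal with a configurable
  coefficient of variation (mean-one deviates);
* counting noise is Poisson on every recorded cpm.

Every simulated mouse yields an injection check, a blood sample, and one
sample per configured tissue, emitted in the tidy study-CSV schema of
:mod:`traffickpk.measures`; the generating scenario travels with the
records so recovery tests can compare estimates with truth.  All draws go
through one :class:`numpy.random.Generator`, so a scenario plus a seed
reproduces the records exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import measures
from .measures import REQUIRED_COLUMNS, CapillaryDepletionSample

__all__ = [
    "TraffickingScenario",
    "SimulatedStudy",
    "simulate_clearance_series",
    "simulate_2x2_study",
    "simulate_time_course",
    "simulate_capillary_depletion",
]

LOG10_2 = math.log10(2.0)

#: Typical wet weights (g) used for simulated organs.
DEFAULT_TISSUE_WEIGHTS_G = {
    "brain": 0.45,
    "spleen": 0.123,
    "cervical_node": 0.0052,
    "axillary_node": 0.0052,
}

#: Steady-state tissue/RBC base ratios (ul/g).  Brain sits near 10 ul/g; the
#: spleen ratio is anchored so that at a blood level of ~2 %Inj/ml its uptake
#: lands in the 15-20 %Inj/g range; nodes are high but below spleen.
DEFAULT_BASE_RATIOS = {
    "brain": 10.0,
    "spleen": 7500.0,
    "cervical_node": 1500.0,
    "axillary_node": 1500.0,
}

_SCALAR_FIELDS = {
    "injected_cpm": (int, float),
    "specific_activity_cpm_per_cell": (int, float),
    "biological_cv": (int, float),
    "counting_noise": bool,
    "n_per_group": int,
    "seed": int,
}


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Lognormal deviates with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class TraffickingScenario:
    """Generative parameters of a synthetic trafficking study.

    Fold-factor dictionaries map tissue name to the multiplier applied when
    the observation belongs to the *second* level of the corresponding
    factor (``cells_levels[1]``, ``host_levels[1]``); the interaction factor
    applies only when both are at their second level.  A factor of 1 means
    no effect.
    """

    injected_cpm: float = 150_000.0
    specific_activity_cpm_per_cell: float = 53.3
    cells_levels: Tuple[str, str] = ("CD1", "SJL")
    host_levels: Tuple[str, str] = ("CD1", "SJL")
    half_time_min: Mapping[str, float] = field(
        default_factory=lambda: {"CD1": 171.0, "SJL": math.inf}
    )
    intercept_log10: Mapping[str, float] = field(
        default_factory=lambda: {"CD1": 0.5, "SJL": 0.5}
    )
    tissue_base_ratio: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATIOS)
    )
    tissue_weight_g: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_WEIGHTS_G)
    )
    cells_factor: Mapping[str, float] = field(default_factory=dict)
    mouse_factor: Mapping[str, float] = field(default_factory=dict)
    interaction_factor: Mapping[str, float] = field(default_factory=dict)
    biological_cv: float = 0.25
    counting_noise: bool = True
    time_points: Tuple[float, ...] = (5.0, 15.0, 30.0, 90.0, 150.0)
    n_per_group: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.injected_cpm > 0:
            raise ValueError("injected_cpm must be > 0")
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be >= 0")
        if len(self.time_points) == 0:
            raise ValueError("time_points must be nonempty")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for name in ("cells_factor", "mouse_factor", "interaction_factor"):
            for tissue, f in getattr(self, name).items():
                if not f > 0:
                    raise ValueError(f"{name}[{tissue!r}] must be > 0, got {f}")
        for level in self.host_levels:
            if level not in self.half_time_min or level not in self.intercept_log10:
                raise ValueError(f"missing clearance parameters for host level {level!r}")
        for tissue in self.tissue_base_ratio:
            if tissue not in self.tissue_weight_g:
                raise ValueError(f"no tissue_weight_g for tissue {tissue!r}")

    # -- derived expectations ------------------------------------------------

    @property
    def tissues(self) -> List[str]:
        return list(self.tissue_base_ratio)

    def expected_pct_inj_per_ml(self, host_level: str, time_min: float) -> float:
        """Noise-free blood level (%Inj/ml) for a host at a given time."""
        ht = self.half_time_min[host_level]
        slope = 0.0 if math.isinf(ht) else -LOG10_2 / ht
        return 10.0 ** (self.intercept_log10[host_level] + slope * time_min)

    def expected_ratio(self, tissue: str, cells_level: str, host_level: str) -> float:
        """Noise-free tissue/RBC ratio (ul/g) for one design cell."""
        r = self.tissue_base_ratio[tissue]
        second_cells = cells_level == self.cells_levels[1]
        second_host = host_level == self.host_levels[1]
        if second_cells:
            r *= self.cells_factor.get(tissue, 1.0)
        if second_host:
            r *= self.mouse_factor.get(tissue, 1.0)
        if second_cells and second_host:
            r *= self.interaction_factor.get(tissue, 1.0)
        return r

    # -- JSON config ---------------------------------------------------------

    def to_json(self, path=None) -> str:
        d = asdict(self)
        for key in ("cells_levels", "host_levels", "time_points"):
            d[key] = list(d[key])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TraffickingScenario":
        """Load and validate a scenario from a JSON file path or string."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            raw = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        for key, types in _SCALAR_FIELDS.items():
            if key in raw and not isinstance(raw[key], types):
                raise ValueError(f"scenario key {key!r} has wrong type: {raw[key]!r}")
        for key in ("cells_levels", "host_levels", "time_points"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("half_time_min", "intercept_log10"):
            if key in raw:
                raw[key] = {
                    k: (math.inf if v in (None, "inf", "Infinity") else float(v))
                    for k, v in raw[key].items()
                }
        return cls(**raw)

    def replace(self, **kwargs) -> "TraffickingScenario":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulatedStudy:
    """Generated records (tidy study-CSV schema) plus the generating truth."""

    records: pd.DataFrame
    truth: TraffickingScenario

    def to_csv(self, path) -> None:
        """Write the records deterministically (fixed column order/format)."""
        self.records.to_csv(
            path, index=False, float_format="%.10g", lineterminator="\n"
        )

    def derived(self) -> pd.DataFrame:
        """Per-mouse derived measures (see :func:`measures.derive_measures`)."""
        return measures.derive_measures(self.records)

    def clearance_points(self, host_level: str) -> Tuple[np.ndarray, np.ndarray]:
        """(time, measured %Inj/ml) pairs for one host level."""
        d = self.derived()
        blood = d[(d["tissue_name"] == "blood") & (d["group_mouse"] == host_level)]
        return blood["time_min"].to_numpy(), blood["pct_inj_per_ml"].to_numpy()


# ---------------------------------------------------------------------------
# Record generation
# ---------------------------------------------------------------------------


def _blank_row(mouse_id, cells, host, time_min, sample_type):
    return {
        "mouse_id": mouse_id,
        "group_cells": cells,
        "group_mouse": host,
        "time_min": time_min,
        "sample_type": sample_type,
        "tissue_name": "",
        "cpm": np.nan,
        "weight_g": np.nan,
        "volume_ul": np.nan,
        "cells_injected": np.nan,
    }


def _simulate_mouse(
    rng: np.random.Generator,
    scenario: TraffickingScenario,
    mouse_id: str,
    cells_level: str,
    host_level: str,
    time_min: float,
    tissues: Sequence[str],
) -> List[dict]:
    noise = scenario.counting_noise
    inj = scenario.injected_cpm

    def count(expected: float) -> float:
        return float(rng.poisson(expected)) if noise else expected

    rows = []
    check = _blank_row(mouse_id, cells_level, host_level, 0.0, "injection_check")
    check["cpm"] = count(inj)
    check["volume_ul"] = 200.0
    check["cells_injected"] = round(inj / scenario.specific_activity_cpm_per_cell)
    rows.append(check)

    # blood: per-mouse lognormal deviation around the clearance curve
    pct = scenario.expected_pct_inj_per_ml(host_level, time_min)
    pct *= _mean_one_lognormal(rng, scenario.biological_cv)
    pellet_conc = pct / 100.0 * inj / 1000.0  # cpm per ul of RBC pellet
    # pellet volumes are not observed quantities of interest; only the
    # concentration matters downstream, so any realistic volume will do
    pellet_vol = rng.uniform(15.0, 25.0)
    blood = _blank_row(mouse_id, cells_level, host_level, time_min, "blood")
    blood["cpm"] = count(pellet_conc * pellet_vol)
    blood["volume_ul"] = pellet_vol
    rows.append(blood)

    for tissue in tissues:
        ratio = scenario.expected_ratio(tissue, cells_level, host_level)
        ratio *= _mean_one_lognormal(rng, scenario.biological_cv)
        weight = scenario.tissue_weight_g[tissue]
        row = _blank_row(mouse_id, cells_level, host_level, time_min, "tissue")
        row["tissue_name"] = tissue
        row["cpm"] = count(ratio * pellet_conc * weight)
        row["weight_g"] = weight
        rows.append(row)
    return rows


def _finish(rows: List[dict], scenario: TraffickingScenario) -> SimulatedStudy:
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    return SimulatedStudy(records=df, truth=scenario)


def simulate_clearance_series(
    scenario: TraffickingScenario,
    host_level: str,
    n_per_time: Union[int, Sequence[int], None] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedStudy:
    """Blood-only study for a clearance fit: mice at each configured time.

    ``n_per_time`` may be a single count or one count per time point (e.g.
    ``[4, 4, 4, 4, 3]`` for 19 mice over 5 times); default is
    ``scenario.n_per_group`` at every time.  Cells are autologous (same
    level as the host).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    times = scenario.time_points
    if n_per_time is None:
        counts = [scenario.n_per_group] * len(times)
    elif isinstance(n_per_time, int):
        counts = [n_per_time] * len(times)
    else:
        counts = list(n_per_time)
        if len(counts) != len(times):
            raise ValueError("n_per_time must match the number of time points")
    rows: List[dict] = []
    for t, n in zip(times, counts):
        for i in range(n):
            mid = f"{host_level}_t{t:g}_m{i}"
            rows.extend(
                _simulate_mouse(rng, scenario, mid, host_level, host_level, t, ())
            )
    return _finish(rows, scenario)


def simulate_2x2_study(
    scenario: TraffickingScenario,
    sample_time: float = 30.0,
    n_per_group: Union[int, Mapping[Tuple[str, str], int], None] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedStudy:
    """Factorial study: all four Cells x Mouse groups at one sample time.

    ``n_per_group`` may be a single count or a mapping
    ``(cells_level, host_level) -> n`` for unbalanced designs; default is
    ``scenario.n_per_group`` everywhere.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    rows: List[dict] = []
    for cells in scenario.cells_levels:
        for host in scenario.host_levels:
            if n_per_group is None:
                n = scenario.n_per_group
            elif isinstance(n_per_group, int):
                n = n_per_group
            else:
                n = n_per_group[(cells, host)]
            for i in range(n):
                mid = f"{cells}to{host}_m{i}"
                rows.extend(
                    _simulate_mouse(
                        rng, scenario, mid, cells, host, sample_time, scenario.tissues
                    )
                )
    return _finish(rows, scenario)


def simulate_time_course(
    scenario: TraffickingScenario,
    host_levels: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedStudy:
    """Time-course study: independent mice per host level and time point.

    Cells are autologous (same level as the host), matching a two-strain
    time-course comparison; tissue ratios are at steady state while blood
    levels follow each host's clearance curve.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if host_levels is None:
        host_levels = scenario.host_levels
    rows: List[dict] = []
    for host in host_levels:
        for t in scenario.time_points:
            for i in range(scenario.n_per_group):
                mid = f"{host}_t{t:g}_m{i}"
                rows.extend(
                    _simulate_mouse(rng, scenario, mid, host, host, t, scenario.tissues)
                )
    return _finish(rows, scenario)


def simulate_capillary_depletion(
    parenchyma_ratio_true: float,
    capillary_ratio_true: float,
    biological_cv: float = 0.0,
    n: int = 1,
    counting_noise: bool = False,
    cortex_weight_g: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> List[CapillaryDepletionSample]:
    """Generate capillary-depletion samples consistent with given ratios.

    Each sample draws an RBC-pellet concentration and produces parenchyma
    and capillary cpm such that the fraction/pellet ratios equal the true
    values times an optional lognormal deviate; with both noise layers off
    the true ratios are recovered exactly.
    """
    if parenchyma_ratio_true < 0 or capillary_ratio_true < 0:
        raise ValueError("true ratios must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        pellet_conc = rng.uniform(400.0, 600.0)  # cpm/ul
        p_ratio = parenchyma_ratio_true * _mean_one_lognormal(rng, biological_cv)
        c_ratio = capillary_ratio_true * _mean_one_lognormal(rng, biological_cv)
        p_cpm = p_ratio * cortex_weight_g * pellet_conc
        c_cpm = c_ratio * cortex_weight_g * pellet_conc
        if counting_noise:
            p_cpm = float(rng.poisson(p_cpm))
            c_cpm = float(rng.poisson(c_cpm))
        samples.append(
            CapillaryDepletionSample(
                cortex_weight_g=cortex_weight_g,
                parenchyma_cpm=p_cpm,
                capillary_cpm=c_cpm,
                rbc_pellet_concentration=pellet_conc,
            )
        )
    return samples
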