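"""Raw gamma-counter measurement types and the per-mouse derived quantities.

The core currency of a radiolabeled-lymphocyte trafficking study is a set of
counts-per-minute (cpm) measurements made per mouse: an injection check (the
total dose), a blood red-blood-cell (RBC) pellet, and one or more tissues.
From these, three families of derived measures are computed:

* dose fractions — ``%Inj/ml`` (percent of injected dose per ml of RBC
  pellet) and ``%Inj/g`` (percent of injected dose per gram of tissue);
* distribution-volume-like uptake ratios — tissue cpm/g divided by RBC
  pellet cpm/ul, in ul/g, which are insensitive to clearance from blood;
* back-calculated cell numbers — lymphocytes per gram of tissue and per
  organ, from blood lymphocyte concentration, hematocrit and the ratio.

Units are handled in one canonical convention: cpm concentrations are stored
per microliter; the per-ml concentration needed by ``%Inj/ml`` is obtained by
multiplying by 1000.  ``%Inj/ml`` is defined per ml of RBC *pellet*, not per
ml of whole blood; the two differ by the hematocrit factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InjectionCheck",
    "BloodSample",
    "TissueSample",
    "CapillaryDepletionSample",
    "LabelingBatch",
    "CellNumberInputs",
    "LabelingQC",
    "pct_inj_per_ml",
    "pct_inj_per_gram",
    "tissue_rbc_ratio",
    "pct_inj_per_gram_from_ratio",
    "organ_sequestration_pct",
    "fraction_over_pellet",
    "parenchymal_fraction_pct",
    "lymphocytes_per_gram",
    "lymphocytes_per_organ",
    "cells_per_injected",
    "labeling_qc",
    "corrected_cpm",
    "REQUIRED_COLUMNS",
    "SAMPLE_TYPES",
    "read_study_csv",
    "derive_measures",
]

# ---------------------------------------------------------------------------
# Measurement record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InjectionCheck:
    """The injection check: an aliquot equal to the injected dose.

    Parameters
    ----------
    injected_cpm
        Total radioactivity injected i.v. per mouse (cpm).
    injected_cells
        Number of labeled lymphocytes injected (0 if not recorded).
    injectate_volume_ml
        Volume of the injectate, default 0.2 ml.
    """

    injected_cpm: float
    injected_cells: float = 0.0
    injectate_volume_ml: float = 0.2

    def __post_init__(self) -> None:
        if not self.injected_cpm > 0:
            raise ValueError("injected_cpm must be > 0")
        if self.injected_cells < 0:
            raise ValueError("injected_cells must be >= 0")
        if not self.injectate_volume_ml > 0:
            raise ValueError("injectate_volume_ml must be > 0")


@dataclass(frozen=True)
class BloodSample:
    """Radioactivity of the RBC pellet of an arterial blood sample.

    The pellet carries the labeled cells; serum activity, where measured,
    is stored upstream but enters no derived quantity.
    """

    mouse_id: str
    time_post_injection_min: float
    pellet_cpm: float
    pellet_volume_ul: float

    def __post_init__(self) -> None:
        if self.pellet_cpm < 0:
            raise ValueError("pellet_cpm must be >= 0")
        if not self.pellet_volume_ul > 0:
            raise ValueError("pellet_volume_ul must be > 0")
        if self.time_post_injection_min < 0:
            raise ValueError("time_post_injection_min must be >= 0")

    @property
    def pellet_concentration(self) -> float:
        """Pellet radioactivity concentration in cpm per microliter."""
        return self.pellet_cpm / self.pellet_volume_ul


@dataclass(frozen=True)
class TissueSample:
    """Total radioactivity and wet weight of one dissected tissue."""

    mouse_id: str
    tissue_name: str
    time_post_injection_min: float
    wet_weight_g: float
    total_cpm: float
    node_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.wet_weight_g > 0:
            raise ValueError("wet_weight_g must be > 0")
        if self.total_cpm < 0:
            raise ValueError("total_cpm must be >= 0")

    @property
    def weight_per_node_g(self) -> Optional[float]:
        if self.node_count is None or self.node_count == 0:
            return None
        return self.wet_weight_g / self.node_count


@dataclass(frozen=True)
class CapillaryDepletionSample:
    """Parenchyma (supernatant) and capillary (pellet) fractions of cortex.

    Density-gradient fractionation of a cortical homogenate separates the
    brain vasculature (pellet) from the parenchyma (supernatant); each
    fraction's cpm is normalized by cortex weight and the RBC pellet
    concentration of the same animal.
    """

    cortex_weight_g: float
    parenchyma_cpm: float
    capillary_cpm: float
    rbc_pellet_concentration: float  # cpm per ul

    def __post_init__(self) -> None:
        if not self.cortex_weight_g > 0:
            raise ValueError("cortex_weight_g must be > 0")
        if self.parenchyma_cpm < 0 or self.capillary_cpm < 0:
            raise ValueError("fraction cpm must be >= 0")
        if not self.rbc_pellet_concentration > 0:
            raise ValueError("rbc_pellet_concentration must be > 0")


@dataclass(frozen=True)
class LabelingBatch:
    """QC measurements of one lymphocyte iodination batch."""

    total_cpm: float
    cell_count: float
    qc_pellet_cpm: float
    qc_supernatant_cpm: float

    def __post_init__(self) -> None:
        if not self.cell_count > 0:
            raise ValueError("cell_count must be > 0")
        for name in ("total_cpm", "qc_pellet_cpm", "qc_supernatant_cpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CellNumberInputs:
    """Inputs for back-calculating lymphocyte numbers in a tissue.

    ``tissue_rbc_ratio_ul_per_g`` is the distribution-volume-like uptake
    ratio; ``blood_lymphocytes_per_ul`` is per microliter of *whole blood*.
    Because labeled cells sediment with the RBC fraction, cells per ul of
    pellet = cells per ul of whole blood / hematocrit.
    """

    blood_lymphocytes_per_ul: float
    hematocrit: float
    tissue_rbc_ratio_ul_per_g: float
    organ_weight_g: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in (0, 1)")
        if self.blood_lymphocytes_per_ul < 0:
            raise ValueError("blood_lymphocytes_per_ul must be >= 0")
        if self.tissue_rbc_ratio_ul_per_g < 0:
            raise ValueError("tissue_rbc_ratio_ul_per_g must be >= 0")
        if self.organ_weight_g < 0:
            raise ValueError("organ_weight_g must be >= 0")


@dataclass(frozen=True)
class LabelingQC:
    """Result of :func:`labeling_qc`."""

    specific_activity_cpm_per_cell: float
    incorporation: float
    incorporation_threshold: float
    passed: bool


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def corrected_cpm(cpm: float, background_cpm: float = 0.0) -> float:
    """Subtract an optional per-batch background, clamping at zero.

    No background correction is applied by default; near background, counting
    data can go negative after subtraction, so the result is clamped at 0
    with a warning rather than raising.
    """
    value = cpm - background_cpm
    if value < 0:
        logger.warning(
            "cpm %.3g below background %.3g; clamping to 0", cpm, background_cpm
        )
        return 0.0
    return value


def pct_inj_per_ml(blood: BloodSample, check: InjectionCheck) -> float:
    """Percent of injected dose per ml of RBC pellet: 100 * Cp / Inj.

    Cp is the pellet concentration in cpm/ml (pellet cpm / pellet volume,
    scaled from per-ul to per-ml); Inj is the total injected cpm.
    """
    cp_per_ml = blood.pellet_concentration * 1000.0
    return 100.0 * cp_per_ml / check.injected_cpm


def pct_inj_per_gram(tissue: TissueSample, check: InjectionCheck) -> float:
    """Percent of injected dose taken up per gram of tissue.

    %Inj/g = (tissue cpm / Inj / tissue weight) * 100.
    """
    return 100.0 * tissue.total_cpm / check.injected_cpm / tissue.wet_weight_g


def tissue_rbc_ratio(
    tissue: TissueSample,
    blood: BloodSample,
    *,
    allow_cross_mouse: bool = False,
) -> float:
    """Tissue/RBC uptake ratio in ul/g.

    (tissue cpm per g) / (RBC pellet cpm per ul).  A within-animal quantity:
    the two samples must share a ``mouse_id`` unless ``allow_cross_mouse``.
    """
    if tissue.mouse_id != blood.mouse_id and not allow_cross_mouse:
        raise ValueError(
            f"tissue sample from mouse {tissue.mouse_id!r} but blood from "
            f"{blood.mouse_id!r}; pass allow_cross_mouse=True to override"
        )
    conc = blood.pellet_concentration
    if conc == 0:
        raise ValueError("RBC pellet concentration is zero; ratio undefined")
    return (tissue.total_cpm / tissue.wet_weight_g) / conc


def pct_inj_per_gram_from_ratio(ratio_ul_per_g: float, pct_inj_per_ml_blood: float) -> float:
    """%Inj/g from the tissue/RBC ratio and the blood level.

    Multiplying the tissue/RBC ratio (ul/g) by %Inj/ml and dividing by 1000
    yields %Inj/g; this is an exact algebraic identity with
    :func:`pct_inj_per_gram` when both are computed from the same records.
    """
    if ratio_ul_per_g < 0 or pct_inj_per_ml_blood < 0:
        raise ValueError("ratio and blood level must be >= 0")
    return ratio_ul_per_g * pct_inj_per_ml_blood / 1000.0


def organ_sequestration_pct(pct_per_gram: float, organ_weight_g: float) -> float:
    """Percent of injected dose contained in a whole organ.

    %Inj/g times organ weight (g).
    """
    if pct_per_gram < 0 or organ_weight_g < 0:
        raise ValueError("inputs must be >= 0")
    return pct_per_gram * organ_weight_g


def fraction_over_pellet(sample: CapillaryDepletionSample, which: str) -> float:
    """Fraction/pellet ratio (ul/g) for the parenchyma or capillary fraction.

    (fraction cpm / cortex weight) / (RBC pellet cpm per ul).
    """
    if which == "parenchyma":
        cpm = sample.parenchyma_cpm
    elif which == "capillary":
        cpm = sample.capillary_cpm
    else:
        raise ValueError(f"which must be 'parenchyma' or 'capillary', got {which!r}")
    return (cpm / sample.cortex_weight_g) / sample.rbc_pellet_concentration


def parenchymal_fraction_pct(parenchyma_ratio: float, capillary_ratio: float) -> float:
    """Percent of brain-associated label in the parenchymal fraction.

    100 * P / (P + C) where P and C are the parenchyma/pellet and
    capillary/pellet ratios.  The parenchymal and capillary percentages are
    complementary: swapping the arguments gives 100 minus the result.
    """
    if parenchyma_ratio < 0 or capillary_ratio < 0:
        raise ValueError("ratios must be >= 0")
    total = parenchyma_ratio + capillary_ratio
    if total == 0:
        raise ValueError("both ratios are zero; fraction undefined")
    return 100.0 * parenchyma_ratio / total


def lymphocytes_per_gram(inputs: CellNumberInputs) -> float:
    """Estimated lymphocytes per gram of tissue.

    Labeled cells sediment with the RBC pellet, so cells per ul of pellet
    equals (cells per ul whole blood) / hematocrit; multiplying by the
    tissue/RBC ratio (ul of pellet-equivalent per g) gives cells per gram.
    """
    cells_per_ul_pellet = inputs.blood_lymphocytes_per_ul / inputs.hematocrit
    return cells_per_ul_pellet * inputs.tissue_rbc_ratio_ul_per_g


def lymphocytes_per_organ(inputs: CellNumberInputs) -> float:
    """Estimated lymphocytes in a whole organ (per-gram estimate x weight)."""
    return lymphocytes_per_gram(inputs) * inputs.organ_weight_g


def cells_per_injected(pct_per_gram: float) -> float:
    """Injected cells per cell taken up per gram of tissue: 100 / (%Inj/g)."""
    if not pct_per_gram > 0:
        raise ValueError("pct_per_gram must be > 0")
    return 100.0 / pct_per_gram


def labeling_qc(batch: LabelingBatch, incorporation_threshold: float = 0.90) -> LabelingQC:
    """Specific activity and iodine incorporation for a labeling batch.

    Specific activity is total cpm / cell count; incorporation is the
    cell-pellet fraction of the QC spin, pellet / (pellet + supernatant),
    flagged against ``incorporation_threshold`` (default 0.90).
    """
    denom = batch.qc_pellet_cpm + batch.qc_supernatant_cpm
    if denom == 0:
        raise ValueError("qc pellet + supernatant cpm is zero; incorporation undefined")
    incorporation = batch.qc_pellet_cpm / denom
    specific_activity = batch.total_cpm / batch.cell_count
    return LabelingQC(
        specific_activity_cpm_per_cell=specific_activity,
        incorporation=incorporation,
        incorporation_threshold=incorporation_threshold,
        passed=incorporation >= incorporation_threshold,
    )


# ---------------------------------------------------------------------------
# Tidy CSV interface
# ---------------------------------------------------------------------------

#: Required columns of the tidy study CSV, one row per measurement.
REQUIRED_COLUMNS = [
    "mouse_id",
    "group_cells",
    "group_mouse",
    "time_min",
    "sample_type",
    "tissue_name",
    "cpm",
    "weight_g",
    "volume_ul",
    "cells_injected",
]

SAMPLE_TYPES = frozenset(
    {"injection_check", "blood", "tissue", "capillary_parenchyma", "capillary_pellet"}
)

#: Columns of the derived per-mouse measure table.
DERIVED_COLUMNS = [
    "mouse_id",
    "group_cells",
    "group_mouse",
    "tissue_name",
    "time_min",
    "pct_inj_per_ml",
    "pct_inj_per_g",
    "tissue_rbc_ratio_ul_per_g",
]


def read_study_csv(path) -> pd.DataFrame:
    """Read and validate a tidy study CSV (one row per measurement)."""
    df = pd.read_csv(path, comment="#")
    return validate_study_frame(df)


def validate_study_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table missing required columns: {missing}")
    bad = set(df["sample_type"].unique()) - SAMPLE_TYPES
    if bad:
        rows = df.index[df["sample_type"].isin(bad)].tolist()[:5]
        raise ValueError(
            f"unknown sample_type values {sorted(bad)} (first rows: {rows}); "
            f"expected one of {sorted(SAMPLE_TYPES)}"
        )
    return df


def derive_measures(df: pd.DataFrame) -> pd.DataFrame:
    """Compute the per-mouse derived measures from a tidy study table.

    Returns one row per blood sample (``tissue_name == "blood"``, carrying
    %Inj/ml) and one row per tissue or capillary-depletion fraction
    (carrying %Inj/g and the tissue/RBC ratio alongside the mouse's
    %Inj/ml).  Mice missing their injection check or blood sample are
    excluded with a logged warning.
    """
    df = validate_study_frame(df)

    checks = df[df["sample_type"] == "injection_check"]
    checks = checks.drop_duplicates("mouse_id").set_index("mouse_id")
    blood = df[df["sample_type"] == "blood"].drop_duplicates("mouse_id")

    mice = df["mouse_id"].unique()
    have_check = set(checks.index)
    have_blood = set(blood["mouse_id"])
    dropped = [m for m in mice if m not in have_check or m not in have_blood]
    if dropped:
        logger.warning(
            "excluding %d mouse/mice missing an injection check or blood sample: %s",
            len(dropped),
            dropped,
        )

    blood = blood[blood["mouse_id"].isin(have_check)].copy()
    blood["inj_cpm"] = checks["cpm"].reindex(blood["mouse_id"]).to_numpy()
    blood["pellet_conc"] = blood["cpm"] / blood["volume_ul"]  # cpm/ul
    blood["pct_inj_per_ml"] = 100.0 * blood["pellet_conc"] * 1000.0 / blood["inj_cpm"]

    rows = blood[["mouse_id", "group_cells", "group_mouse", "time_min", "pct_inj_per_ml"]].copy()
    rows["tissue_name"] = "blood"
    rows["pct_inj_per_g"] = np.nan
    rows["tissue_rbc_ratio_ul_per_g"] = np.nan
    out = [rows]

    per_mouse = blood.set_index("mouse_id")[["inj_cpm", "pellet_conc", "pct_inj_per_ml"]]
    tissue_like = df[
        df["sample_type"].isin(["tissue", "capillary_parenchyma", "capillary_pellet"])
    ]
    tissue_like = tissue_like[tissue_like["mouse_id"].isin(per_mouse.index)].copy()
    if len(tissue_like):
        tissue_like["tissue_name"] = tissue_like["tissue_name"].where(
            tissue_like["sample_type"] == "tissue", tissue_like["sample_type"]
        )
        idx = tissue_like["mouse_id"]
        inj = per_mouse["inj_cpm"].reindex(idx).to_numpy()
        conc = per_mouse["pellet_conc"].reindex(idx).to_numpy()
        tissue_like["pct_inj_per_ml"] = per_mouse["pct_inj_per_ml"].reindex(idx).to_numpy()
        tissue_like["pct_inj_per_g"] = (
            100.0 * tissue_like["cpm"] / inj / tissue_like["weight_g"]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            tissue_like["tissue_rbc_ratio_ul_per_g"] = (
                tissue_like["cpm"] / tissue_like["weight_g"]
            ) / conc
        out.append(tissue_like[DERIVED_COLUMNS])

    result = pd.concat(out, ignore_index=True)[DERIVED_COLUMNS]
    return result.sort_values(["mouse_id", "tissue_name"], kind="stable").reset_index(
        drop=True
    )
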