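"""End-to-end study analysis: derived measures, clearance fits, ANOVAs.

``run_study_analysis`` ingests a tidy study CSV (or DataFrame), computes the
per-mouse derived measures, fits a blood-clearance model per host group
where the design permits (at least two distinct sampling times with
positive blood levels), and analyzes each tissue:

* single-time factorial designs get the 2x2 Cells-by-Mouse ANOVA with
  percent-variance attribution plus a one-way ANOVA and Newman-Keuls
  post-test over the four groups;
* multi-time designs get a host-by-time ANOVA per tissue with
  Bonferroni-adjusted per-time comparisons.

Every output embeds a hash of the analysis configuration so numbers are
traceable to the exact settings that produced them; re-running on identical
input and configuration yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from . import measures
from .clearance import ClearanceFit, fit_clearance
from .variance import (
    AnovaTable,
    FactorialDataset,
    PostTestResult,
    bonferroni_by_time,
    newman_keuls,
    one_way_anova,
    pct_variance,
    two_way_anova,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CONFIG",
    "validate_config",
    "config_hash",
    "StudyReport",
    "run_study_analysis",
    "report_to_tables",
    "load_report",
]

DEFAULT_CONFIG: Dict = {
    "alpha": 0.05,
    "ss_type": 3,
    "response": "ratio",  # ratio | pct_inj_per_g | pct_inj_per_ml
    "window": None,  # [t_min, t_max] for clearance fits
    "drop_first_point": False,
    "tissues": None,  # None -> every tissue present in the data
    "posttest": "newman_keuls",  # newman_keuls | bonferroni (time courses)
}

_RESPONSE_COLUMNS = {
    "ratio": "tissue_rbc_ratio_ul_per_g",
    "pct_inj_per_g": "pct_inj_per_g",
    "pct_inj_per_ml": "pct_inj_per_ml",
}


def validate_config(config: Optional[Dict]) -> Dict:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    if cfg["ss_type"] not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    if not (0 < cfg["alpha"] < 1):
        raise ValueError("alpha must be in (0, 1)")
    if cfg["response"] not in _RESPONSE_COLUMNS:
        raise ValueError(f"response must be one of {sorted(_RESPONSE_COLUMNS)}")
    if cfg["window"] is not None:
        lo, hi = cfg["window"]
        if not lo < hi:
            raise ValueError("window must be [t_min, t_max] with t_min < t_max")
        cfg["window"] = [float(lo), float(hi)]
    return cfg


def config_hash(cfg: Dict) -> str:
    """Stable short hash of a configuration dictionary."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All analysis results for one study, with provenance."""

    derived: pd.DataFrame
    clearance_fits: Dict[str, dict]  # host level -> fit dict (or reason)
    factorial: Dict[str, dict]  # tissue -> {anova, pct_variance, newman_keuls}
    time_course: Dict[str, dict]  # tissue -> {anova, bonferroni}
    provenance: Dict

    def to_dict(self) -> dict:
        return {
            "derived": self.derived.to_dict(orient="records"),
            "clearance_fits": self.clearance_fits,
            "factorial": self.factorial,
            "time_course": self.time_course,
            "provenance": self.provenance,
        }


def _group_label(cells: str, host: str) -> str:
    return f"{cells}->{host}"


def run_study_analysis(
    study: Union[str, os.PathLike, pd.DataFrame],
    config: Optional[Dict] = None,
) -> StudyReport:
    """Run the full analysis pipeline on a tidy study table.

    Raises a stage-tagged error if any stage fails; records dropped for
    missing companions (injection check or blood sample) are logged.
    """
    cfg = validate_config(config)
    if isinstance(study, pd.DataFrame):
        raw = measures.validate_study_frame(study)
    else:
        raw = measures.read_study_csv(study)

    try:
        derived = measures.derive_measures(raw)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"[measures] derivation failed: {exc}") from exc
    if derived.empty:
        raise ValueError("[measures] no derivable records in input")

    blood = derived[derived["tissue_name"] == "blood"]
    window = tuple(cfg["window"]) if cfg["window"] else None
    clearance_fits: Dict[str, dict] = {}
    for host in sorted(blood["group_mouse"].unique()):
        sub = blood[blood["group_mouse"] == host]
        t = sub["time_min"].to_numpy(dtype=float)
        y = sub["pct_inj_per_ml"].to_numpy(dtype=float)
        if window is not None:
            keep = (t >= window[0]) & (t <= window[1])
            n_times = np.unique(t[keep]).size
        else:
            n_times = np.unique(t).size
        if n_times < 2:
            logger.info("host %s: single sampling time; clearance fit skipped", host)
            clearance_fits[host] = {
                "fit": None,
                "reason": "insufficient_time_points",
                "n_points": int(len(sub)),
            }
            continue
        try:
            fit = fit_clearance(
                t,
                y,
                window=window,
                drop_first_point=cfg["drop_first_point"],
                alpha=cfg["alpha"],
            )
        except ValueError as exc:
            raise RuntimeError(f"[clearance] host {host}: {exc}") from exc
        clearance_fits[host] = {"fit": fit.to_dict(), "reason": None, "n_points": fit.n_points}

    response_col = _RESPONSE_COLUMNS[cfg["response"]]
    tissue_rows = derived[derived["tissue_name"] != "blood"]
    tissues = cfg["tissues"] or sorted(tissue_rows["tissue_name"].unique())
    multi_time = tissue_rows["time_min"].nunique() > 1

    factorial: Dict[str, dict] = {}
    time_course: Dict[str, dict] = {}
    for tissue in tissues:
        sub = tissue_rows[tissue_rows["tissue_name"] == tissue]
        if sub.empty:
            raise ValueError(f"[variance_model] no records for tissue {tissue!r}")
        y = sub[response_col].to_numpy(dtype=float)
        cells = sub["group_cells"].to_numpy()
        hosts = sub["group_mouse"].to_numpy()
        try:
            if multi_time:
                t = sub["time_min"].to_numpy(dtype=float)
                table = two_way_anova(
                    FactorialDataset(y, hosts, t),
                    ss_type=cfg["ss_type"],
                    effect_names=("Mouse", "Time"),
                )
                bonf = bonferroni_by_time(y, hosts, t, alpha=cfg["alpha"])
                time_course[tissue] = {
                    "anova": table.to_dict(),
                    "bonferroni": [r.to_dict() for r in bonf],
                }
            else:
                data = FactorialDataset(y, cells, hosts)
                table = two_way_anova(data, ss_type=cfg["ss_type"])
                shares = pct_variance(table)
                labels = sorted(set(_group_label(c, h) for c, h in zip(cells, hosts)))
                groups = [
                    y[(np.char.add(np.char.add(cells.astype(str), "->"), hosts.astype(str)) == lab)]
                    for lab in labels
                ]
                nk = newman_keuls(groups, alpha=cfg["alpha"], labels=labels)
                factorial[tissue] = {
                    "anova": table.to_dict(),
                    "pct_variance": shares,
                    "newman_keuls": [r.to_dict() for r in nk],
                }
        except ValueError as exc:
            raise RuntimeError(f"[variance_model] tissue {tissue}: {exc}") from exc

    provenance = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "n_input_records": int(len(raw)),
        "n_derived_records": int(len(derived)),
        "n_mice": int(derived["mouse_id"].nunique()),
    }
    return StudyReport(
        derived=derived,
        clearance_fits=clearance_fits,
        factorial=factorial,
        time_course=time_course,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_POSTTEST_COLUMNS = [
    "comparison_a",
    "comparison_b",
    "time",
    "statistic",
    "critical_value",
    "adjusted_p",
    "significant",
    "alpha",
    "span",
]


def _write_csv(df: pd.DataFrame, path: str, chash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _posttest_frame(results: List[dict]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "comparison_a": r["comparison"][0],
                "comparison_b": r["comparison"][1],
                "time": r.get("time"),
                "statistic": r["statistic"],
                "critical_value": r.get("critical_value"),
                "adjusted_p": r.get("adjusted_p"),
                "significant": r["significant"],
                "alpha": r["alpha"],
                "span": r.get("span"),
            }
        )
    return pd.DataFrame(rows, columns=_POSTTEST_COLUMNS)


def report_to_tables(report: StudyReport, outdir: Union[str, os.PathLike]) -> List[str]:
    """Write the report as a deterministic set of CSV/JSON files.

    Produces ``derived_measures.csv``, ``clearance.json``, one
    ``anova_<tissue>.csv`` and ``posttests_<tissue>.csv`` per analyzed
    tissue, and the full-precision ``report.json``.  Returns the paths.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    chash = report.provenance["config_hash"]
    paths: List[str] = []

    p = os.path.join(outdir, "derived_measures.csv")
    _write_csv(report.derived, p, chash)
    paths.append(p)

    p = os.path.join(outdir, "clearance.json")
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(
            {"config_hash": chash, "fits": report.clearance_fits},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    paths.append(p)

    analyses = {**{t: d for t, d in report.factorial.items()}, **report.time_course}
    for tissue in sorted(analyses):
        entry = analyses[tissue]
        anova_df = pd.DataFrame(entry["anova"]["rows"])
        p = os.path.join(outdir, f"anova_{tissue}.csv")
        _write_csv(anova_df, p, chash)
        paths.append(p)
        posts = entry.get("newman_keuls") or entry.get("bonferroni") or []
        p = os.path.join(outdir, f"posttests_{tissue}.csv")
        _write_csv(_posttest_frame(posts), p, chash)
        paths.append(p)

    p = os.path.join(outdir, "report.json")
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(p)
    return paths


def load_report(path: Union[str, os.PathLike]) -> dict:
    """Load a ``report.json`` back into its dictionary form."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
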