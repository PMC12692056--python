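"""Chip-level quality control for probe-intensity tables.

Works on a plain probe-level table (one hybridized sample per table) rather
than vendor binaries.  The metric suite mirrors standard Affymetrix QC
practice: overall intensity level, negative/saturated values, poly-A
sample-preparation and cRNA hybridization spike-in concentration order,
GAPDH and ACTB 3'/5' ratios, spatial centering of the negative controls
(Cmoff), positive-vs-negative border controls, and an RNA degradation slope
over the 5'->3' probe positions of each probeset.

The literature gives the parameter list but not numeric cutoffs; defaults
here follow community conventions and are fully configurable via
:class:`QCThresholds`.  Criteria can be waived per dataset with a mandatory
audited reason, mirroring the practice of retaining an otherwise valuable
dataset that fails a single spatial criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SATURATION_LIMIT = 65535  # 16-bit scanner ceiling

CONTROL_CLASSES = (
    "none",
    "polyA_lys", "polyA_phe", "polyA_thr", "polyA_dap",
    "hyb_bioB", "hyb_bioC", "hyb_bioD", "hyb_cre",
    "border_pos", "border_neg", "negative_ctrl",
    "gapdh_5", "gapdh_m", "gapdh_3",
    "actb_5", "actb_m", "actb_3",
)

POLYA_ORDER = ("polyA_lys", "polyA_phe", "polyA_thr", "polyA_dap")
HYB_ORDER = ("hyb_bioB", "hyb_bioC", "hyb_bioD", "hyb_cre")

#: evaluation order of the QC criteria
CRITERIA = (
    "mean_intensity",
    "negative_values",
    "saturation",
    "polya_order",
    "hyb_order",
    "gapdh_35_ratio",
    "actb_35_ratio",
    "cmoff",
    "border_controls",
    "rna_degradation",
)

PROBE_COLUMNS = (
    "probe_id", "probeset_id", "x", "y", "position", "intensity", "control_class"
)


@dataclass
class ProbeTable:
    """Probe-level intensities of one hybridized sample."""

    sample_id: str
    probes: pd.DataFrame  # columns per PROBE_COLUMNS
    chip_dims: tuple[int, int]  # (n_columns, n_rows), 0-based coordinates
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        missing = set(PROBE_COLUMNS) - set(self.probes.columns)
        if missing:
            raise FormatError(f"probe table missing columns {sorted(missing)}")
        if len(self.probes) == 0:
            raise ValidationError("empty probe table")
        nx, ny = self.chip_dims
        x = self.probes["x"].to_numpy()
        y = self.probes["y"].to_numpy()
        if (x < 0).any() or (x >= nx).any() or (y < 0).any() or (y >= ny).any():
            raise ValidationError("probe coordinates outside chip dimensions")
        if (self.probes["position"].to_numpy() < 1).any():
            raise ValidationError("probe position must be >= 1")
        bad = set(self.probes["control_class"]) - set(CONTROL_CLASSES)
        if bad:
            raise FormatError(f"unknown control classes: {sorted(bad)}")

    def class_intensities(self, control_class: str) -> np.ndarray:
        sel = self.probes["control_class"] == control_class
        return self.probes.loc[sel, "intensity"].to_numpy(float)


@dataclass(frozen=True)
class QCThresholds:
    """Numeric cutoffs for every criterion (defaults are package conventions)."""

    mean_intensity_min: float = 50.0
    mean_intensity_max: float = 20000.0
    gapdh_35_max: float = 1.25
    actb_35_max: float = 3.0
    cmoff_max: float = 0.15
    border_neg_sd_factor: float = 3.0
    rna_deg_slope_max: float = 5.0  # single-sample absolute cap
    rna_deg_mad_factor: float = 3.0  # cohort mode


@dataclass
class QCReport:
    """Per-sample metric values and pass/fail/waived status per criterion."""

    sample_id: str
    metrics: dict
    criteria: dict  # criterion -> "pass" | "fail" | "waived"
    waiver_reasons: dict = field(default_factory=dict)
    dataset_id: str | None = None

    @property
    def overall_pass(self) -> bool:
        return all(v in ("pass", "waived") for v in self.criteria.values())

    @property
    def failed_criteria(self) -> list[str]:
        return [k for k, v in self.criteria.items() if v == "fail"]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "dataset_id": self.dataset_id,
            "overall_pass": self.overall_pass,
            "metrics": {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.metrics.items()
            },
            "criteria": dict(self.criteria),
            "waiver_reasons": dict(self.waiver_reasons),
        }


def read_probe_table(path, sample_id: str, chip_dims: tuple[int, int],
                     dataset_id: str | None = None) -> ProbeTable:
    probes = pd.read_csv(path, sep="\t")
    return ProbeTable(sample_id, probes, chip_dims, dataset_id)


def write_probe_table(table: ProbeTable, path) -> None:
    table.probes.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def three_five_ratio(table: ProbeTable, gene: str) -> float:
    """3'/5' probe-intensity ratio of a housekeeping control (gapdh or actb).

    Elevated ratios indicate RNA degradation (5' ends under-represented).
    Returns NaN when either control class is absent.
    """
    if gene not in ("gapdh", "actb"):
        raise ValidationError(f"three_five_ratio supports gapdh/actb, got {gene!r}")
    five = table.class_intensities(f"{gene}_5")
    three = table.class_intensities(f"{gene}_3")
    if len(five) == 0 or len(three) == 0:
        logger.warning("%s: missing %s 3'/5' control probes", table.sample_id, gene)
        return float("nan")
    return float(three.mean() / five.mean())


def rna_degradation_slope(table: ProbeTable) -> float:
    """OLS slope of mean probe intensity against 5'->3' position.

    Positions are averaged across all non-control probesets; a strongly
    positive slope marks 5' signal loss from degraded RNA.  Invariant to
    adding a constant to all intensities; scales linearly with intensity.
    """
    regular = table.probes[table.probes["control_class"] == "none"]
    if len(regular) == 0:
        raise ValidationError("no non-control probes for degradation slope")
    means = regular.groupby("position")["intensity"].mean()
    if len(means) < 2:
        raise ValidationError("need >= 2 distinct probe positions for a slope")
    slope = np.polyfit(means.index.to_numpy(float), means.to_numpy(float), 1)[0]
    return float(slope)


def center_of_intensity_offset(
    table: ProbeTable, chip_dims: tuple[int, int] | None = None
) -> float:
    """Normalized offset of the negative-control intensity centroid.

    The intensity-weighted centroid of the negative-control probes should sit
    at the chip center when background is spatially uniform.  Returns the
    Euclidean distance from the center divided by half the chip diagonal,
    giving a value in [0, 1].
    """
    nx, ny = chip_dims or table.chip_dims
    neg = table.probes[table.probes["control_class"] == "negative_ctrl"]
    if len(neg) == 0:
        raise ValidationError("no negative-control probes for Cmoff")
    w = neg["intensity"].to_numpy(float)
    total = w.sum()
    if total <= 0:
        raise ValidationError("zero total negative-control intensity")
    cx = float((neg["x"].to_numpy(float) * w).sum() / total)
    cy = float((neg["y"].to_numpy(float) * w).sum() / total)
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    half_diag = np.hypot(nx - 1, ny - 1) / 2.0
    return float(np.hypot(cx - center[0], cy - center[1]) / half_diag)


def spike_in_order_check(table: ProbeTable, family: str) -> dict:
    """Check that spike-in class mean intensities rise in concentration order.

    ``family`` is ``"polyA"`` (sample-preparation spike-ins lys<phe<thr<dap)
    or ``"hyb"`` (hybridization spike-ins bioB<bioC<bioD<cre).  The order
    must be strictly increasing; ties fail.
    """
    order = {"polyA": POLYA_ORDER, "hyb": HYB_ORDER}.get(family)
    if order is None:
        raise ValidationError(f"unknown spike-in family {family!r}")
    means = []
    for cls in order:
        vals = table.class_intensities(cls)
        if len(vals) == 0:
            return {"ok": False, "observed": {}, "missing_class": cls}
        means.append(float(vals.mean()))
    ok = all(means[i] < means[i + 1] for i in range(len(means) - 1))
    return {"ok": ok, "observed": dict(zip(order, means)), "missing_class": None}


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def run_qc(table: ProbeTable, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Compute all QC metrics and evaluate every criterion.

    The RNA degradation criterion uses the absolute single-sample cap;
    cohort-relative flagging is available via :func:`cohort_rna_deg_flags`.
    """
    intens = table.probes["intensity"].to_numpy(float)
    polya = spike_in_order_check(table, "polyA")
    hyb = spike_in_order_check(table, "hyb")
    gapdh = three_five_ratio(table, "gapdh")
    actb = three_five_ratio(table, "actb")
    cmoff = center_of_intensity_offset(table)
    slope = rna_degradation_slope(table)
    border_pos = table.class_intensities("border_pos")
    border_neg = table.class_intensities("border_neg")
    bp_mean = float(border_pos.mean()) if len(border_pos) else float("nan")
    bn_mean = float(border_neg.mean()) if len(border_neg) else float("nan")
    bn_sd = float(border_neg.std(ddof=1)) if len(border_neg) > 1 else float("nan")
    metrics = {
        "mean_intensity": float(intens.mean()),
        "n_negative": int((intens < 0).sum()),
        "n_saturated": int((intens > SATURATION_LIMIT).sum()),
        "polyA_order_ok": bool(polya["ok"]),
        "hyb_order_ok": bool(hyb["ok"]),
        "gapdh_35_ratio": gapdh,
        "actb_35_ratio": actb,
        "cmoff": cmoff,
        "border_pos_mean": bp_mean,
        "border_neg_mean": bn_mean,
        "rna_deg_slope": slope,
    }
    t = thresholds
    border_ok = (
        np.isfinite(bp_mean) and np.isfinite(bn_mean) and np.isfinite(bn_sd)
        and bp_mean > bn_mean + t.border_neg_sd_factor * bn_sd
    )
    checks = {
        "mean_intensity": t.mean_intensity_min
        <= metrics["mean_intensity"]
        <= t.mean_intensity_max,
        "negative_values": metrics["n_negative"] == 0,
        "saturation": metrics["n_saturated"] == 0,
        "polya_order": metrics["polyA_order_ok"],
        "hyb_order": metrics["hyb_order_ok"],
        "gapdh_35_ratio": np.isfinite(gapdh) and gapdh <= t.gapdh_35_max,
        "actb_35_ratio": np.isfinite(actb) and actb <= t.actb_35_max,
        "cmoff": cmoff <= t.cmoff_max,
        "border_controls": bool(border_ok),
        "rna_degradation": abs(slope) <= t.rna_deg_slope_max,
    }
    criteria = {k: ("pass" if checks[k] else "fail") for k in CRITERIA}
    return QCReport(
        sample_id=table.sample_id,
        metrics=metrics,
        criteria=criteria,
        dataset_id=table.dataset_id,
    )


def cohort_rna_deg_flags(
    slopes: pd.Series, mad_factor: float = 3.0
) -> pd.Series:
    """Flag samples whose degradation slope sits > ``mad_factor`` MADs from
    the cohort median (cohort-relative alternative to the absolute cap)."""
    med = slopes.median()
    mad = float((slopes - med).abs().median())
    if mad == 0:
        return pd.Series(False, index=slopes.index)
    return (slopes - med).abs() / mad > mad_factor


def apply_waivers(
    report: QCReport,
    waivers: dict,
    reason: str,
) -> QCReport:
    """Flip listed failing criteria to ``waived`` with an audited reason.

    ``waivers`` maps dataset id to the list of waivable criteria; the
    report's own dataset id selects the applicable entry.  Passing criteria
    are untouched (idempotent) and an empty reason is rejected.
    """
    if not reason or not reason.strip():
        raise ValidationError("a waiver requires a non-empty reason")
    applicable = waivers.get(report.dataset_id, [])
    unknown = set(applicable) - set(CRITERIA)
    if unknown:
        raise ValidationError(f"unknown criteria in waiver: {sorted(unknown)}")
    criteria = dict(report.criteria)
    reasons = dict(report.waiver_reasons)
    for crit in applicable:
        if criteria.get(crit) == "fail":
            criteria[crit] = "waived"
            reasons[crit] = reason
            logger.info(
                "waived criterion %s for sample %s (dataset %s): %s",
                crit, report.sample_id, report.dataset_id, reason,
            )
    return replace(report, criteria=criteria, waiver_reasons=reasons)
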