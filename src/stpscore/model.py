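"""Bayesian-network pathway-activity scoring.

The model is a two-layer Bayesian network: one hidden binary node for the
pathway's transcription-complex state (active/inactive) and, conditionally
independent given that state, one hidden binary node per transcription-factor
target gene ("target up" / "target not up").  Measured log2 expression of a
target enters as soft (virtual) evidence on its gene node through a logistic
transform; exact inference then reduces to a weighted sum of per-gene
log-likelihood ratios, i.e. weighted naive-Bayes log-odds:

    p_g = sigma(d_g * (e_g - theta_g) / s_g)
    L   = prior + sum_g w_g * log2[ (p_g a_g + (1-p_g)(1-a_g))
                                  / (p_g b_g + (1-p_g)(1-b_g)) ]

where ``a_g = P(target up | pathway active)`` and ``b_g = P(target up |
pathway inactive)``.  The log-odds ``L`` is mapped to a 0-100 activity score
against the model's analytically attainable extremes ``L_min``/``L_max``, so
0 and 100 are reachable and dataset-independent.

Models are calibrated on ground-truth samples (known active/inactive
pathway state) with Laplace-smoothed conditional probabilities.

FOXO transcription-factor activity serves as an inverse readout of PI3K
signalling: active PI3K suppresses FOXO.  Oxidative stress activates FOXO
independently of PI3K, so elevated SOD2 (an oxidative-stress response gene)
marks samples whose FOXO score cannot be read as PI3K activity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError, ValidationError
from .io import ExpressionMatrix, PathwayDefinition

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: gene symbols copied into ActivityTable covariates when present
KI67_GENE = "MKI67"
SOD2_GENE = "SOD2"

#: floor on the fuzzification scale, log2 units
MIN_SCALE = 0.05


@dataclass
class TargetParams:
    """Calibrated per-target-gene parameters.

    ``direction`` is the literature-derived regulation sense (+1: induced by
    the active pathway, -1: repressed).  ``midpoint``/``scale`` place the
    logistic soft-evidence transform on the log2 expression axis.
    ``p_active``/``p_inactive`` are the conditional probabilities that the
    target is in its "up" state given the pathway state.  Targets whose
    calibration yields ``p_active <= p_inactive`` are flagged
    non-informative and contribute exactly zero.
    """

    gene_id: str
    direction: int
    weight: float
    midpoint: float
    scale: float
    p_active: float
    p_inactive: float
    informative: bool = True

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ParameterError(f"{self.gene_id}: direction must be +1/-1")
        if not self.weight >= 0:
            raise ParameterError(f"{self.gene_id}: weight must be >= 0")
        if not self.scale > 0:
            raise ParameterError(f"{self.gene_id}: scale must be > 0")
        for name in ("p_active", "p_inactive"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{self.gene_id}: {name}={v} outside (0,1)")
        if self.informative and not self.p_active > self.p_inactive:
            raise ParameterError(
                f"{self.gene_id}: informative target requires p_active > p_inactive"
            )


@dataclass
class CalibratedPathwayModel:
    """A pathway model ready for scoring, with its normalization anchors."""

    pathway_name: str
    targets: list[TargetParams]
    prior_logodds: float = 0.0

    @property
    def informative_targets(self) -> list[TargetParams]:
        return [t for t in self.targets if t.informative and t.weight > 0]

    @property
    def l_max(self) -> float:
        """Log2-odds when every informative target's evidence saturates at 1."""
        return self.prior_logodds + sum(
            t.weight * math.log2(t.p_active / t.p_inactive)
            for t in self.informative_targets
        )

    @property
    def l_min(self) -> float:
        """Log2-odds when every informative target's evidence is 0."""
        return self.prior_logodds + sum(
            t.weight * math.log2((1 - t.p_active) / (1 - t.p_inactive))
            for t in self.informative_targets
        )


class PI3KInterpretation(str, Enum):
    """Per-sample reading of PI3K state from FOXO activity and SOD2."""

    PI3K_ACTIVE = "PI3K_ACTIVE"
    PI3K_INACTIVE = "PI3K_INACTIVE"
    UNINTERPRETABLE_OXIDATIVE_STRESS = "UNINTERPRETABLE_OXIDATIVE_STRESS"


@dataclass
class ActivityTable:
    """Samples-by-pathways normalized activity scores plus named covariates."""

    scores: pd.DataFrame  # samples x pathways, each value in [0, 100]
    covariates: pd.DataFrame  # samples x {ki67, sod2}; NaN when absent
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    pi3k_interpretation: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.scores.index)
        arr = self.scores.to_numpy()
        if arr.size and ((arr < -1e-9) | (arr > 100 + 1e-9)).any():
            raise ValidationError("activity scores outside [0, 100]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path) -> None:
        out = self.scores.round(4).copy()
        for col in self.covariates.columns:
            out[col] = self.covariates[col].round(4)
        if self.pi3k_interpretation is not None:
            out["pi3k_interpretation"] = [
                v.value if isinstance(v, PI3KInterpretation) else v
                for v in self.pi3k_interpretation
            ]
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def fuzzify_expression(e: float, t: TargetParams) -> float:
    """Soft evidence that target ``t`` is in its "up" state given expression.

    Logistic in direction-adjusted distance from the midpoint:
    ``sigma(d * (e - theta) / s)``; returns 0.5 exactly at the midpoint.
    """
    if not np.all(np.isfinite(e)):
        raise ValidationError(f"{t.gene_id}: non-finite expression value")
    return float(expit(t.direction * (e - t.midpoint) / t.scale))


def gene_evidence_logodds(p_evidence: float, t: TargetParams) -> float:
    """Weighted log2 likelihood-ratio contribution of one target gene.

    Marginalizes the binary gene node against soft evidence ``p_evidence``:
    ``w * log2[(p a + (1-p)(1-a)) / (p b + (1-p)(1-b))]``.  Non-informative
    targets contribute exactly 0.
    """
    if not t.informative:
        return 0.0
    a, b = t.p_active, t.p_inactive
    num = p_evidence * a + (1.0 - p_evidence) * (1.0 - a)
    den = p_evidence * b + (1.0 - p_evidence) * (1.0 - b)
    return t.weight * math.log2(num / den)


def sample_logodds(
    expr,
    model: CalibratedPathwayModel,
    missing_policy: str = "skip",
) -> float:
    """Pathway log2-odds for one sample.

    ``expr`` maps gene id to log2 expression (dict or pandas Series).
    Missing target genes are skipped with a logged count
    (``missing_policy="skip"``) or raise (``missing_policy="error"``).
    """
    if missing_policy not in ("skip", "error"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    total = model.prior_logodds
    n_missing = 0
    for t in model.targets:
        if t.gene_id not in expr:
            n_missing += 1
            continue
        total += gene_evidence_logodds(fuzzify_expression(expr[t.gene_id], t), t)
    if n_missing:
        if missing_policy == "error" or n_missing == len(model.targets):
            raise ValidationError(
                f"{model.pathway_name}: {n_missing}/{len(model.targets)} "
                "target genes missing from expression input"
            )
        logger.debug(
            "%s: skipped %d/%d missing targets",
            model.pathway_name, n_missing, len(model.targets),
        )
    return float(total)


def normalize_logodds(L: float, model: CalibratedPathwayModel) -> float:
    """Map log2-odds onto the 0-100 activity scale via the model anchors."""
    lmin, lmax = model.l_min, model.l_max
    if not lmax > lmin:
        raise ParameterError(
            f"{model.pathway_name}: no informative targets, score undefined"
        )
    if not np.isfinite(L):
        raise ValidationError(f"{model.pathway_name}: non-finite log-odds")
    return float(np.clip(100.0 * (L - lmin) / (lmax - lmin), 0.0, 100.0))


def score_sample(expr, model: CalibratedPathwayModel,
                 missing_policy: str = "skip") -> float:
    """Convenience: log-odds then normalization for one sample."""
    return normalize_logodds(sample_logodds(expr, model, missing_policy), model)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_pathway(
    training: ExpressionMatrix,
    labels,
    definition: PathwayDefinition,
    pseudocount: float = 1.0,
    prior_logodds: float = 0.0,
) -> CalibratedPathwayModel:
    """Calibrate a pathway model on ground-truth samples.

    ``labels`` maps each training sample id to ``"active"`` or
    ``"inactive"``.  Per gene, the fuzzification midpoint is the midpoint of
    the two class means, the scale is half the pooled within-class SD
    (floored at 0.05 log2 units), and the conditional probabilities are
    Laplace-smoothed counts of samples falling on the active side of the
    midpoint.  Genes whose calibrated ``a <= b`` are kept but neutralized
    (non-informative) rather than direction-flipped.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(training.sample_ids)
    if labels.isna().any():
        raise ValidationError("every training sample needs a class label")
    classes = set(labels)
    if classes != {"active", "inactive"}:
        raise ValidationError(
            f"labels must contain both 'active' and 'inactive' (got {sorted(classes)})"
        )
    active_ids = labels.index[labels == "active"]
    inactive_ids = labels.index[labels == "inactive"]
    n_a, n_i = len(active_ids), len(inactive_ids)
    if n_a < 2 or n_i < 2:
        raise ValidationError(
            f"need >= 2 samples per class (got {n_a} active, {n_i} inactive)"
        )
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")

    targets: list[TargetParams] = []
    n_dropped = 0
    for tdef in definition.targets:
        if tdef.gene_id not in training.values.index:
            n_dropped += 1
            continue
        row = training.values.loc[tdef.gene_id]
        ea = row[active_ids].to_numpy(float)
        ei = row[inactive_ids].to_numpy(float)
        theta = (ea.mean() + ei.mean()) / 2.0
        pooled_var = (
            (n_a - 1) * ea.var(ddof=1) + (n_i - 1) * ei.var(ddof=1)
        ) / (n_a + n_i - 2)
        s = max(math.sqrt(pooled_var) / 2.0, MIN_SCALE)
        d = tdef.direction
        k_a = int(np.sum(d * (ea - theta) > 0))
        k_i = int(np.sum(d * (ei - theta) > 0))
        a = (k_a + pseudocount) / (n_a + 2 * pseudocount)
        b = (k_i + pseudocount) / (n_i + 2 * pseudocount)
        targets.append(
            TargetParams(
                gene_id=tdef.gene_id,
                direction=d,
                weight=tdef.weight,
                midpoint=float(theta),
                scale=float(s),
                p_active=float(a),
                p_inactive=float(b),
                informative=a > b,
            )
        )
    if n_dropped:
        logger.warning(
            "%s: %d/%d definition genes missing from training matrix",
            definition.pathway_name, n_dropped, len(definition.targets),
        )
    if not targets:
        raise ValidationError(
            f"{definition.pathway_name}: no definition genes present in training data"
        )
    return CalibratedPathwayModel(
        pathway_name=definition.pathway_name,
        targets=targets,
        prior_logodds=prior_logodds,
    )


# ---------------------------------------------------------------------------
# matrix scoring and PI3K interpretation
# ---------------------------------------------------------------------------

def score_matrix(
    matrix: ExpressionMatrix,
    models: list[CalibratedPathwayModel],
    missing_policy: str = "skip",
) -> ActivityTable:
    """Score every sample against every calibrated model.

    MKI67 and SOD2 expression rows, when present, are copied into the
    covariate columns ``ki67`` and ``sod2``.
    """
    samples = matrix.sample_ids
    scores = pd.DataFrame(index=pd.Index(samples, name="sample_id"),
                          columns=[m.pathway_name for m in models], dtype=float)
    for model in models:
        genes = [t.gene_id for t in model.targets if t.gene_id in matrix.values.index]
        sub = matrix.values.loc[genes] if genes else matrix.values.iloc[:0]
        for sid in samples:
            scores.loc[sid, model.pathway_name] = score_sample(
                sub[sid], model, missing_policy
            )
    covariates = pd.DataFrame(index=scores.index, columns=["ki67", "sod2"],
                              dtype=float)
    for gene, col in ((KI67_GENE, "ki67"), (SOD2_GENE, "sod2")):
        if gene in matrix.values.index:
            covariates[col] = matrix.values.loc[gene].to_numpy(float)
        else:
            logger.info("covariate gene %s absent from matrix", gene)
    return ActivityTable(scores, covariates, matrix.annotations.copy())


def interpret_pi3k(
    foxo_scores: pd.Series,
    sod2_expr: pd.Series,
    reference: dict,
    tau_foxo: float = 5.0,
    tau_sod2: float = 0.5,
) -> pd.Series:
    """Classify each sample's PI3K state from FOXO activity and SOD2.

    ``reference`` carries the control-group medians
    (``{"foxo_median": ..., "sod2_median": ...}``).  FOXO counts as high
    when the score exceeds the control median by more than ``tau_foxo``
    score units; SOD2 when expression exceeds its control median by more
    than ``tau_sod2`` log2 units.  High FOXO with high SOD2 is attributed
    to oxidative stress and PI3K is declared uninterpretable; high FOXO
    with low SOD2 reads as inactive PI3K; low FOXO as active PI3K.
    """
    missing = {"foxo_median", "sod2_median"} - set(reference)
    if missing:
        raise ValidationError(f"reference medians missing: {sorted(missing)}")
    foxo_high = foxo_scores > reference["foxo_median"] + tau_foxo
    sod2_high = sod2_expr.reindex(foxo_scores.index) > (
        reference["sod2_median"] + tau_sod2
    )
    out = pd.Series(index=foxo_scores.index, dtype=object)
    out[~foxo_high] = PI3KInterpretation.PI3K_ACTIVE
    out[foxo_high & ~sod2_high] = PI3KInterpretation.PI3K_INACTIVE
    out[foxo_high & sod2_high] = (
        PI3KInterpretation.UNINTERPRETABLE_OXIDATIVE_STRESS
    )
    return out


def control_reference(
    foxo_scores: pd.Series,
    sod2_expr: pd.Series,
    groups: pd.Series,
) -> dict:
    """Control-group medians used as the PI3K interpretation reference."""
    control_ids = groups.index[groups == "control"]
    if len(control_ids) == 0:
        raise ValidationError("no control samples to build the PI3K reference")
    return {
        "foxo_median": float(foxo_scores.loc[control_ids].median()),
        "sod2_median": float(sod2_expr.loc[control_ids].median()),
    }


def read_activity_table(path, annotations: pd.DataFrame | None = None) -> ActivityTable:
    """Read an activity TSV written by :meth:`ActivityTable.to_tsv`.

    ``annotations`` (indexed by sample id, columns ``group``/``pair_id``...)
    restores the sample metadata the TSV does not carry.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index(
        "sample_id"
    )
    interp = None
    if "pi3k_interpretation" in frame.columns:
        interp = frame.pop("pi3k_interpretation").map(
            lambda v: PI3KInterpretation(v) if isinstance(v, str) else v
        )
    covariate_cols = [c for c in ("ki67", "sod2") if c in frame.columns]
    covariates = frame[covariate_cols].astype(float) if covariate_cols else \
        pd.DataFrame(index=frame.index, columns=["ki67", "sod2"], dtype=float)
    scores = frame.drop(columns=covariate_cols).astype(float)
    if annotations is not None:
        annotations = annotations.reindex(frame.index)
    return ActivityTable(scores, covariates, annotations, interp)


# ---------------------------------------------------------------------------
# serialization (bit-exact round trip via JSON shortest-repr floats)
# ---------------------------------------------------------------------------

def save_models(models: list[CalibratedPathwayModel], path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "models": [
            {
                "pathway_name": m.pathway_name,
                "prior_logodds": m.prior_logodds,
                "l_min": m.l_min,
                "l_max": m.l_max,
                "targets": [asdict(t) for t in m.targets],
            }
            for m in models
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_models(path) -> list[CalibratedPathwayModel]:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model file format_version {version!r}"
        )
    models = []
    for rec in payload["models"]:
        model = CalibratedPathwayModel(
            pathway_name=rec["pathway_name"],
            targets=[TargetParams(**t) for t in rec["targets"]],
            prior_logodds=rec["prior_logodds"],
        )
        models.append(model)
    return models
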