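"""Cell-type composition from bulk expression by signature-matrix regression.

Bulk mRNA mixes additively on the linear intensity scale, so a bulk profile
``b`` over lineage-specific marker genes is modelled as ``b = S f`` with
``S`` the marker-by-cell-type signature matrix and ``f`` the non-negative
cell fractions.  Fractions are estimated by non-negative least squares on a
system augmented with a sum-to-one penalty row,

    min_f ||S f - b||^2 + lambda^2 (1' f - 1)^2   s.t.  f >= 0,

then renormalized to sum exactly to one.  A second stage distributes the
top-level immune fraction over immune subsets with a subset signature.

Top-level lineages default to {epithelial, fibroblast, immune}; immune
subsets to {granulocyte, monocyte_macrophage, T_cell, B_cell, NK}.  Both
are configurable through the signature matrices themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ValidationError

#: default multiplier on the mean signature column norm for the
#: sum-to-one penalty weight
DEFAULT_SUM_WEIGHT_FACTOR = 100.0

#: condition numbers above this are flagged as ill-conditioned
CONDITION_NUMBER_FLAG = 1e4


@dataclass
class SignatureMatrix:
    """Marker-gene by cell-type matrix of expected linear-scale expression."""

    values: pd.DataFrame  # marker genes x cell types, linear scale
    level: str = "top"  # "top" or "immune_subset"

    def __post_init__(self) -> None:
        if self.level not in ("top", "immune_subset"):
            raise ValidationError(f"unknown signature level {self.level!r}")
        if self.values.shape[0] < self.values.shape[1]:
            raise ValidationError("signature needs at least one marker per type")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("signature values must be non-negative")
        if self.values.columns.has_duplicates or self.values.index.has_duplicates:
            raise ValidationError("duplicate marker or cell-type ids in signature")

    @property
    def marker_genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellFractions:
    """Estimated composition of one bulk sample."""

    sample_id: str
    fractions: pd.Series  # per top-level type, >= 0, sums to 1
    residual_norm: float
    subset_fractions: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy(float)
        if (f < -1e-12).any():
            raise ValidationError("negative cell fraction")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {f.sum()}, expected 1")


def validate_signature(signature: SignatureMatrix) -> dict:
    """Rank/conditioning diagnostics for a signature matrix.

    Returns ``{"rank", "n_types", "condition_number", "markers_per_type",
    "full_rank", "ill_conditioned", "collinear_types"}``.
    """
    S = signature.values.to_numpy(float)
    rank = int(np.linalg.matrix_rank(S))
    n_types = S.shape[1]
    cond = float(np.linalg.cond(S)) if rank == n_types else float("inf")
    markers_per_type = {
        ct: int((signature.values[ct] > 0).sum()) for ct in signature.cell_types
    }
    collinear: list[str] = []
    if rank < n_types:
        # name the columns whose removal restores full row-space coverage
        for j, ct in enumerate(signature.cell_types):
            reduced = np.delete(S, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(ct)
    return {
        "rank": rank,
        "n_types": n_types,
        "condition_number": cond,
        "markers_per_type": markers_per_type,
        "full_rank": rank == n_types,
        "ill_conditioned": cond > CONDITION_NUMBER_FLAG,
        "collinear_types": collinear,
    }


def estimate_fractions(
    bulk: pd.Series,
    signature: SignatureMatrix,
    sum_weight: float | None = None,
    sample_id: str = "",
) -> CellFractions:
    """Estimate cell-type fractions of one linear-scale bulk profile.

    ``bulk`` must cover the signature's marker genes and be non-negative.
    ``sum_weight`` is the penalty weight lambda on the sum-to-one row;
    by default 100x the mean column norm of the signature, which makes the
    constraint effectively hard while keeping the system well scaled.
    The residual norm is reported on the unaugmented system.
    """
    diag = validate_signature(signature)
    if not diag["full_rank"]:
        raise ValidationError(
            "rank-deficient signature; collinear cell types: "
            f"{diag['collinear_types']}"
        )
    missing = [g for g in signature.marker_genes if g not in bulk.index]
    if missing:
        raise ValidationError(
            f"bulk profile lacks {len(missing)} signature marker genes "
            f"(e.g. {missing[:5]})"
        )
    b = bulk.reindex(signature.marker_genes).to_numpy(float)
    if (b < 0).any():
        raise ValidationError("bulk profile has negative entries (linear scale)")
    S = signature.values.to_numpy(float)
    if sum_weight is None:
        sum_weight = DEFAULT_SUM_WEIGHT_FACTOR * float(
            np.mean(np.linalg.norm(S, axis=0))
        )
    # pre-normalize the bulk by its unconstrained NNLS mass so the penalty
    # acts on a unit-scale problem; this makes the estimate exactly
    # invariant to positive rescaling of the bulk profile
    f0, _ = nnls(S, b)
    mass = f0.sum()
    if mass <= 0:
        raise ValidationError("deconvolution produced an all-zero solution")
    b_unit = b / mass
    S_aug = np.vstack([S, sum_weight * np.ones((1, S.shape[1]))])
    b_aug = np.concatenate([b_unit, [sum_weight]])
    f, _ = nnls(S_aug, b_aug)
    f[f < 1e-12 * max(f.max(), 1.0)] = 0.0  # snap NNLS dust to exact zero
    total = f.sum()
    if total <= 0:
        raise ValidationError("deconvolution produced an all-zero solution")
    f = f / total
    residual = float(np.linalg.norm(S @ (mass * f) - b))
    return CellFractions(
        sample_id=sample_id,
        fractions=pd.Series(f, index=signature.cell_types),
        residual_norm=residual,
    )


def estimate_immune_subsets(
    bulk: pd.Series,
    immune_signature: SignatureMatrix,
    top: CellFractions,
    immune_type: str = "immune",
    sum_weight: float | None = None,
) -> CellFractions:
    """Distribute the top-level immune fraction over immune subsets.

    Subset proportions are estimated with :func:`estimate_fractions` on the
    subset marker genes and scaled by the top-level immune fraction, so the
    subset vector sums to the immune fraction.  An immune fraction of zero
    yields all-zero subsets without touching the markers.
    """
    if immune_signature.level != "immune_subset":
        raise ValidationError("immune signature must have level='immune_subset'")
    if immune_type not in top.fractions.index:
        raise ValidationError(f"top-level fractions lack type {immune_type!r}")
    immune_fraction = float(top.fractions[immune_type])
    if immune_fraction == 0.0:
        subsets = pd.Series(0.0, index=immune_signature.cell_types)
    else:
        inner = estimate_fractions(
            bulk, immune_signature, sum_weight=sum_weight, sample_id=top.sample_id
        )
        subsets = inner.fractions * immune_fraction
    return CellFractions(
        sample_id=top.sample_id,
        fractions=top.fractions.copy(),
        residual_norm=top.residual_norm,
        subset_fractions=subsets,
    )


def deconvolve_matrix(
    linear_values: pd.DataFrame,
    signature: SignatureMatrix,
    immune_signature: SignatureMatrix | None = None,
    sum_weight: float | None = None,
) -> pd.DataFrame:
    """Per-sample deconvolution of a linear-scale genes-by-samples matrix.

    Returns a samples-by-types DataFrame; when ``immune_signature`` is given,
    subset columns (scaled by the immune fraction) and the residual norm are
    appended.
    """
    rows = []
    for sid in linear_values.columns:
        bulk = linear_values[sid]
        top = estimate_fractions(bulk, signature, sum_weight, sample_id=str(sid))
        rec = dict(top.fractions)
        if immune_signature is not None:
            full = estimate_immune_subsets(bulk, immune_signature, top)
            rec.update(dict(full.subset_fractions))
        rec["residual_norm"] = top.residual_norm
        rows.append(pd.Series(rec, name=sid))
    out = pd.DataFrame(rows)
    out.index.name = "sample_id"
    return out


def linear_from_log2(log2_values: pd.DataFrame) -> pd.DataFrame:
    """Undo the log2(x+1) transform; deconvolution operates on linear scale."""
    return np.exp2(log2_values) - 1.0
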