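"""Rank-based group comparison and correlation statistics.

The comparison layer mirrors a tumor-vs-control microarray study design:
two-sided Mann-Whitney U tests for unpaired cohorts, two-sided Wilcoxon
signed-rank tests for paired tumor/adjacent designs, Spearman/Pearson
correlations for covariate coupling, a per-pathway comparison table with a
flat alpha = 0.01 significance rule (0.05 annotation level, optional Holm
adjustment), a reference-pathway check for cross-dataset comparability, and
a ranked paired-sample output table.

Both rank tests compute exact conditional permutation p-values (ties handled
with midranks) whenever the enumeration budget permits -- via generating-
function counts over integer-doubled midranks, which equals full enumeration
-- and fall back to the tie- and continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .model import ActivityTable

logger = logging.getLogger(__name__)

#: largest C(n+m, n) for which the Mann-Whitney p-value is computed exactly
EXACT_MW_BUDGET = 2_000_000
#: largest number of informative pairs for exact signed-rank enumeration
EXACT_WILCOXON_MAX_N = 25

ALPHA_SIGNIFICANT = 0.01
ALPHA_ANNOTATE = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided rank test."""

    statistic: float  # U (Mann-Whitney) or min(W+, W-) (signed-rank)
    n: tuple
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    tie_corrected: bool
    w_plus: float | None = None
    w_minus: float | None = None
    n_zero_dropped: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValidationError(f"p-value {self.p_two_sided} outside [0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _doubled_int_ranks(ranks: np.ndarray) -> np.ndarray:
    doubled = np.rint(ranks * 2).astype(np.int64)
    assert np.allclose(doubled, ranks * 2), "midranks must be multiples of 0.5"
    return doubled


def _rank_sum_counts(doubled: np.ndarray, k: int) -> dict[int, int]:
    """Number of size-k subsets of ``doubled`` per subset sum.

    Equivalent to enumerating all C(n, k) subsets; implemented as a
    generating-function dynamic program so it stays cheap inside the
    enumeration budget.
    """
    counts: list[dict[int, int]] = [dict() for _ in range(k + 1)]
    counts[0][0] = 1
    for r in doubled:
        for size in range(min(k, 1_000_000) - 1, -1, -1):
            layer = counts[size]
            nxt = counts[size + 1]
            for s, c in layer.items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    return counts[k]


def _two_sided_from_counts(counts: dict[int, int], observed: int) -> Fraction:
    total = sum(counts.values())
    le = sum(c for s, c in counts.items() if s <= observed)
    ge = sum(c for s, c in counts.items() if s >= observed)
    p = 2 * Fraction(min(le, ge), total)
    return min(p, Fraction(1))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The U statistic is counted for ``x`` (0.5 per tie across groups).  The
    p-value is the exact conditional permutation probability whenever
    ``C(|x|+|y|, |x|)`` is within the enumeration budget, and otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n_x, n_y = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    rank_sum_x = float(ranks[:n_x].sum())
    u_x = rank_sum_x - n_x * (n_x + 1) / 2.0
    has_ties = len(np.unique(combined)) < combined.size
    if comb(n_x + n_y, n_x) <= EXACT_MW_BUDGET:
        doubled = _doubled_int_ranks(ranks)
        counts = _rank_sum_counts(doubled, n_x)
        observed = int(np.rint(rank_sum_x * 2))
        p = float(_two_sided_from_counts(counts, observed))
        method = "exact"
    else:
        mu = n_x * n_y / 2.0
        tie_counts = np.array(list(Counter(combined.tolist()).values()))
        n = n_x + n_y
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_x - mu) - 0.5) / sqrt(var)
            p = float(2 * sps.norm.sf(max(z, 0.0)))
        p = min(p, 1.0)
        method = "normal_approx"
    return TestResult(
        statistic=float(u_x),
        n=(n_x, n_y),
        p_two_sided=p,
        method=method,
        tie_corrected=has_ties,
    )


def wilcoxon_signed_rank(pairs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on (control, tumor) pairs.

    Differences are tumor minus control; zero differences are dropped with
    a logged count; tied absolute differences receive midranks.  Exact
    two-sided p by enumeration over the 2^n sign patterns (via a
    generating-function count) for n <= 25, otherwise the tie- and
    continuity-corrected normal approximation.  The reported statistic is
    ``min(W+, W-)``.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array of (control, tumor)")
    diffs = arr[:, 1] - arr[:, 0]
    nonzero = diffs[diffs != 0]
    n_dropped = int(diffs.size - nonzero.size)
    if n_dropped:
        logger.info("wilcoxon_signed_rank: dropped %d zero differences", n_dropped)
    if nonzero.size == 0:
        raise ValidationError("all paired differences are zero")
    n = nonzero.size
    ranks = _midranks(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    has_ties = len(np.unique(np.abs(nonzero))) < n
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = _doubled_int_ranks(ranks)
        # distribution of doubled W+ over all 2^n sign assignments
        counts: dict[int, int] = {0: 1}
        for r in doubled:
            nxt: dict[int, int] = {}
            for s, c in counts.items():
                nxt[s] = nxt.get(s, 0) + c
                nxt[s + int(r)] = nxt.get(s + int(r), 0) + c
            counts = nxt
        observed = int(np.rint(w_plus * 2))
        p = float(_two_sided_from_counts(counts, observed))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.array(list(Counter(np.abs(nonzero).tolist()).values()))
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            (tie_counts**3 - tie_counts).sum()
        ) / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w_plus - mu) - 0.5) / sqrt(var)
            p = float(2 * sps.norm.sf(max(z, 0.0)))
        p = min(p, 1.0)
        method = "normal_approx"
    return TestResult(
        statistic=float(min(w_plus, w_minus)),
        n=(n,),
        p_two_sided=p,
        method=method,
        tie_corrected=has_ties,
        w_plus=w_plus,
        w_minus=w_minus,
        n_zero_dropped=n_dropped,
    )


def correlate(x, y, method: str = "spearman") -> dict:
    """Spearman or Pearson correlation with its two-sided p-value.

    Spearman is Pearson on midranks; p-values use the t approximation.
    Zero variance in either input is an error (coefficient undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("correlate needs equal-length inputs, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return {"coefficient": float(rho), "p": float(p), "n": int(x.size)}


# ---------------------------------------------------------------------------
# pathway comparison tables
# ---------------------------------------------------------------------------

def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def compare_pathway_activity(
    activity: ActivityTable,
    paired: bool,
    alpha_significant: float = ALPHA_SIGNIFICANT,
    alpha_annotate: float = ALPHA_ANNOTATE,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-pathway tumor-vs-control comparison table.

    Paired designs use the signed-rank test on (control, tumor) pairs
    matched by ``pair_id``; unpaired designs use the Mann-Whitney U test.
    ``significant`` flags p <= ``alpha_significant`` (0.01) and ``annotate``
    p <= ``alpha_annotate`` (0.05); no multiple-testing correction is
    applied across pathways unless ``holm=True``.
    """
    if alpha_significant > alpha_annotate:
        raise ValidationError("alpha_significant must be <= alpha_annotate")
    ann = activity.annotations
    groups = ann["group"] if "group" in ann.columns else pd.Series(dtype=object)
    tumor_ids = [s for s in activity.sample_ids if groups.get(s) == "tumor"]
    control_ids = [s for s in activity.sample_ids if groups.get(s) == "control"]
    if not tumor_ids or not control_ids:
        raise ValidationError(
            f"need both groups (got {len(tumor_ids)} tumor, "
            f"{len(control_ids)} control)"
        )
    pair_rows = None
    if paired:
        if "pair_id" not in ann.columns:
            raise ValidationError("paired comparison requires pair_id annotations")
        pairs = ann.loc[tumor_ids + control_ids, "pair_id"]
        broken = [s for s in pairs.index if pd.isna(pairs[s])]
        if broken:
            raise ValidationError(f"samples without pair_id: {broken[:5]}")
        by_pair = {}
        for sid in tumor_ids + control_ids:
            by_pair.setdefault(pairs[sid], {})[groups[sid]] = sid
        bad = [pid for pid, d in by_pair.items() if set(d) != {"tumor", "control"}]
        if bad:
            raise ValidationError(f"incomplete pairs: {sorted(map(str, bad))[:5]}")
        pair_rows = [
            (d["control"], d["tumor"]) for _, d in sorted(by_pair.items())
        ]
    rows = []
    for pathway in activity.pathways:
        col = activity.scores[pathway]
        tumor_vals = col.loc[tumor_ids].to_numpy(float)
        control_vals = col.loc[control_ids].to_numpy(float)
        if paired:
            res = wilcoxon_signed_rank(
                [(col[c], col[t]) for c, t in pair_rows]
            )
        else:
            res = mann_whitney(tumor_vals, control_vals)
        rows.append(
            {
                "pathway": pathway,
                "median_tumor": float(np.median(tumor_vals)),
                "median_control": float(np.median(control_vals)),
                "delta": float(np.median(tumor_vals) - np.median(control_vals)),
                "statistic": res.statistic,
                "n_tumor": len(tumor_ids),
                "n_control": len(control_ids),
                "method": res.method,
                "p": res.p_two_sided,
            }
        )
    table = pd.DataFrame(rows)
    pcol = "p_holm" if holm else "p"
    if holm:
        table["p_holm"] = _holm(table["p"].tolist())
    table["significant"] = table[pcol] <= alpha_significant
    table["annotate"] = table[pcol] <= alpha_annotate
    assert (table["annotate"] | ~table["significant"]).all()
    return table


def check_reference_comparability(
    scores_a: pd.Series,
    scores_b: pd.Series,
    p_floor: float = 0.05,
    max_median_delta: float = 5.0,
) -> dict:
    """Judge cross-dataset comparability from a reference pathway.

    A pathway whose activity is unaltered by disease (estrogen receptor, by
    default, in this package's pipeline) should score similarly in two
    comparable datasets: comparable iff the Mann-Whitney p exceeds
    ``p_floor`` and the absolute median difference is below
    ``max_median_delta`` score units.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    res = mann_whitney(a, b)
    median_delta = float(np.median(a) - np.median(b))
    comparable = res.p_two_sided > p_floor and abs(median_delta) < max_median_delta
    return {
        "comparable": bool(comparable),
        "p": res.p_two_sided,
        "median_delta": median_delta,
    }


def ranked_paired_table(
    activity: ActivityTable,
    rank_pathway: str,
    report_pathways: list[str] | None = None,
) -> pd.DataFrame:
    """Per-pair score table sorted by descending tumor activity.

    One row per tumor/adjacent pair carrying adjacent and tumor scores for
    each reported pathway, ordered by the tumor score of ``rank_pathway``
    (ties broken stably by pair id).
    """
    if report_pathways is None:
        report_pathways = activity.pathways
    if rank_pathway not in activity.pathways:
        raise ValidationError(f"rank pathway {rank_pathway!r} not scored")
    ann = activity.annotations
    if "pair_id" not in ann.columns or ann["pair_id"].isna().all():
        raise ValidationError("ranked paired table requires pair annotations")
    by_pair: dict = {}
    for sid in activity.sample_ids:
        pid = ann.loc[sid, "pair_id"]
        group = ann.loc[sid, "group"]
        if pd.isna(pid):
            raise ValidationError(f"sample {sid!r} lacks a pair_id")
        by_pair.setdefault(pid, {})[group] = sid
    rows = []
    for pid in sorted(by_pair, key=str):
        members = by_pair[pid]
        if set(members) != {"tumor", "control"}:
            raise ValidationError(f"incomplete pair {pid!r}")
        rec = {"pair_id": pid}
        for pw in report_pathways:
            rec[f"{pw}_adjacent"] = float(activity.scores.loc[members["control"], pw])
            rec[f"{pw}_tumor"] = float(activity.scores.loc[members["tumor"], pw])
        rows.append(rec)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        f"{rank_pathway}_tumor", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return table
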