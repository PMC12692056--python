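"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the Bayesian-network
oracle enumerates every hidden-state configuration of the two-layer network,
and the rank-test oracles enumerate every group assignment / sign pattern.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata


def enumeration_logodds(model, expr: dict) -> float:
    """Exact posterior log2-odds of the pathway node by joint enumeration.

    Sums the joint probability over all 2^(G+1) configurations of the
    pathway node and the binary target-gene nodes, with the observed
    expression entering as virtual evidence P(obs | gene up) = p,
    P(obs | gene down) = 1 - p.  Requires unit evidence weights.
    """
    targets = [t for t in model.targets if t.gene_id in expr]
    assert all(t.weight == 1.0 for t in targets)
    prior_active = 2.0**model.prior_logodds / (1.0 + 2.0**model.prior_logodds)
    post = {True: 0.0, False: 0.0}
    for active in (True, False):
        p_state = prior_active if active else 1.0 - prior_active
        for genes_up in itertools.product([True, False], repeat=len(targets)):
            joint = p_state
            for t, up in zip(targets, genes_up):
                p_evidence = float(
                    expit(t.direction * (expr[t.gene_id] - t.midpoint) / t.scale)
                )
                if not t.informative:
                    p_up = 0.5  # a = b: the gene node carries no information
                else:
                    p_up = t.p_active if active else t.p_inactive
                joint *= (p_up if up else 1.0 - p_up) * (
                    p_evidence if up else 1.0 - p_evidence
                )
            post[active] += joint
    return math.log2(post[True] / post[False])


def mann_whitney_exact_oracle(x, y) -> Fraction:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    n = len(x)
    observed = ranks[:n].sum()
    sums = [sum(ranks[list(idx)])
            for idx in itertools.combinations(range(len(combined)), n)]
    le = sum(1 for s in sums if s <= observed + 1e-9)
    ge = sum(1 for s in sums if s >= observed - 1e-9)
    p = 2 * Fraction(min(le, ge), len(sums))
    return min(p, Fraction(1))


def wilcoxon_exact_oracle(pairs) -> Fraction:
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    arr = np.asarray(pairs, float)
    diffs = arr[:, 1] - arr[:, 0]
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    observed = ranks[diffs > 0].sum()
    n = len(diffs)
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([True, False], repeat=n)
    ]
    le = sum(1 for s in sums if s <= observed + 1e-9)
    ge = sum(1 for s in sums if s >= observed - 1e-9)
    p = 2 * Fraction(min(le, ge), len(sums))
    return min(p, Fraction(1))


def rank_auc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve via the rank-sum identity."""
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))
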