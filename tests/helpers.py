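"""Shared test helpers that are not fixtures."""

import numpy as np

from stpscore.model import CalibratedPathwayModel, TargetParams


def random_model(rng, n_targets, weights_one=True) -> CalibratedPathwayModel:
    """A random calibrated model for oracle-equivalence checks."""
    targets = []
    for i in range(n_targets):
        b = rng.uniform(0.05, 0.45)
        a = rng.uniform(b + 0.05, 0.95)
        targets.append(
            TargetParams(
                gene_id=f"G{i}",
                direction=int(rng.choice([1, -1])),
                weight=1.0 if weights_one else float(rng.uniform(0.5, 2.0)),
                midpoint=float(rng.normal(7, 1)),
                scale=float(rng.uniform(0.1, 1.0)),
                p_active=float(a),
                p_inactive=float(b),
            )
        )
    return CalibratedPathwayModel(
        pathway_name="RND", targets=targets,
        prior_logodds=float(rng.normal(0, 1)),
    )
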