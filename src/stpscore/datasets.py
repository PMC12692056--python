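"""Bundled worked-example fixtures.

Two small TSVs ship with the package: a 16-pair table of MAPK and TGFb
activity scores from a paired tumor/adjacent-pancreas cohort (the package's
worked example for the paired statistics), and the six-dataset study design
registry that the paired-sample bookkeeping is checked against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import StudyRegistry, build_study_registry
from .model import ActivityTable


def _data_path(name: str):
    return resources.files("stpscore.data").joinpath(name)


def load_paired_example_table() -> pd.DataFrame:
    """The raw 16-pair MAPK/TGFb score table (one row per pair)."""
    with resources.as_file(_data_path("paired_mapk_tgfb_scores.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"pair_id": str})


def load_paired_example_activity() -> ActivityTable:
    """The worked example as an :class:`ActivityTable` of 32 samples.

    Pair ``k`` expands into samples ``A<k>`` (adjacent normal, group
    ``control``) and ``T<k>`` (tumor), both annotated with ``pair_id = k``.
    """
    table = load_paired_example_table()
    records = []
    for _, row in table.iterrows():
        pid = row["pair_id"]
        records.append(
            (f"A{pid}", "control", pid, row["MAPK_adjacent"], row["TGFB_adjacent"])
        )
        records.append((f"T{pid}", "tumor", pid, row["MAPK_tumor"], row["TGFB_tumor"]))
    frame = pd.DataFrame(
        records, columns=["sample_id", "group", "pair_id", "MAPK", "TGFB"]
    ).set_index("sample_id")
    scores = frame[["MAPK", "TGFB"]].astype(float)
    annotations = frame[["group", "pair_id"]].copy()
    annotations["dataset_id"] = "GSE16515"
    annotations["origin"] = None
    covariates = pd.DataFrame(index=scores.index, columns=["ki67", "sod2"],
                              dtype=float)
    return ActivityTable(scores, covariates, annotations)


def load_study_registry() -> StudyRegistry:
    """The six-dataset study design registry."""
    with resources.as_file(_data_path("study_design.tsv")) as p:
        return build_study_registry(p)
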