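"""End-to-end orchestration: read -> QC -> calibrate/score -> interpret ->
deconvolve -> compare/correlate -> report.

A single flat YAML config drives the run (unknown keys are errors).  All
outputs land in one bundle directory, written to a temporary sibling and
moved into place atomically so a failed run leaves no partial bundle.
Samples that fail QC without a waiver are excluded from scoring, with the
exclusion list recorded in ``summary.json``.  Re-running with an identical
config reproduces byte-identical bundle files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .io import read_expression_matrix, read_pathway_definitions
from .model import (
    ActivityTable,
    calibrate_pathway,
    control_reference,
    interpret_pi3k,
    load_models,
    save_models,
    score_matrix,
)
from .deconvolution import SignatureMatrix, deconvolve_matrix, linear_from_log2
from .qc import apply_waivers, read_probe_table, run_qc
from .stats import (
    check_reference_comparability,
    compare_pathway_activity,
    correlate,
    ranked_paired_table,
)

logger = logging.getLogger(__name__)

#: the correlation pairs reported by the pipeline (pathway-vs-pathway or
#: pathway-vs-covariate), evaluated on tumor samples
CORRELATION_SET = (
    ("MAPK", "ki67"),
    ("FOXO", "sod2"),
    ("MAPK", "TGFB"),
    ("MAPK", "WNT"),
    ("MAPK", "NOTCH"),
    ("MAPK", "HH"),
    ("WNT", "NOTCH"),
)

_CONFIG_KEYS = {
    "matrix": None,
    "dialect": "series_matrix_like",
    "input_scale": "log2",
    "model": None,
    "pathway_definitions": None,
    "calibration_matrix": None,
    "calibration_labels": None,
    "signature": None,
    "immune_signature": None,
    "probe_dir": None,
    "chip_dims": "100x100",
    "qc_waivers": None,
    "qc_waiver_reason": "",
    "alpha_significant": 0.01,
    "alpha_annotate": 0.05,
    "reference_pathway": "ER",
    "rank_pathway": "MAPK",
    "tau_foxo": 5.0,
    "tau_sod2": 0.5,
    "seed": 0,
    "output_dir": None,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_CONFIG_KEYS`` for keys)."""

    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.options) - set(_CONFIG_KEYS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_CONFIG_KEYS, **self.options}
        if merged["matrix"] is None:
            raise ValidationError("config requires 'matrix'")
        if merged["output_dir"] is None:
            raise ValidationError("config requires 'output_dir'")
        if merged["model"] is None and merged["pathway_definitions"] is None:
            raise ValidationError(
                "config requires either 'model' or 'pathway_definitions' "
                "with calibration inputs"
            )
        if merged["pathway_definitions"] is not None and merged["model"] is None:
            for key in ("calibration_matrix", "calibration_labels"):
                if merged[key] is None:
                    raise ValidationError(f"calibration requires '{key}'")
        if merged["alpha_significant"] > merged["alpha_annotate"]:
            raise ValidationError("alpha_significant must be <= alpha_annotate")
        if merged["qc_waivers"] and not str(merged["qc_waiver_reason"]).strip():
            raise ValidationError("qc_waivers requires a qc_waiver_reason")
        self.options = merged

    def __getitem__(self, key: str):
        return self.options[key]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a key-value mapping")
        return cls(raw)

    def canonical_json(self) -> str:
        return json.dumps(self.options, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class ReportBundle:
    """Paths and summary of one pipeline run."""

    output_dir: Path
    files: dict
    summary: dict


def _parse_chip_dims(text: str) -> tuple[int, int]:
    try:
        nx, ny = (int(v) for v in str(text).lower().split("x"))
    except Exception as exc:
        raise ValidationError(f"chip_dims must look like '100x100', got {text!r}") \
            from exc
    return nx, ny


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _qc_stage(config: PipelineConfig, outdir: Path, log: list[str]):
    """Run QC over every probe table in ``probe_dir``; return excluded ids."""
    probe_dir = config["probe_dir"]
    excluded: list[str] = []
    if probe_dir is None:
        log.append("qc: skipped (no probe_dir configured)")
        return excluded
    chip_dims = _parse_chip_dims(config["chip_dims"])
    waivers = config["qc_waivers"] or {}
    reports = []
    for path in sorted(Path(probe_dir).glob("*.tsv")):
        sample_id = path.stem
        table = read_probe_table(path, sample_id, chip_dims)
        # the dataset id, when encoded as <dataset>__<sample>.tsv, selects waivers
        if "__" in sample_id:
            table.dataset_id, table.sample_id = sample_id.split("__", 1)
        report = run_qc(table)
        if waivers:
            report = apply_waivers(report, waivers, config["qc_waiver_reason"])
        reports.append(report)
        if not report.overall_pass:
            excluded.append(report.sample_id)
    if reports:
        rows = []
        for r in reports:
            rec = {"sample_id": r.sample_id, "dataset_id": r.dataset_id,
                   "overall_pass": r.overall_pass}
            rec.update({f"metric_{k}": v for k, v in r.metrics.items()})
            rec.update({f"criterion_{k}": v for k, v in r.criteria.items()})
            rows.append(rec)
        pd.DataFrame(rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.append(
            f"qc: {len(reports)} samples, {len(excluded)} excluded "
            f"({sorted(excluded)})"
        )
    return excluded


def _get_models(config: PipelineConfig, outdir: Path, log: list[str]):
    if config["model"] is not None:
        models = load_models(config["model"])
        log.append(f"models: loaded {len(models)} calibrated models")
    else:
        definitions = read_pathway_definitions(config["pathway_definitions"])
        training = read_expression_matrix(
            config["calibration_matrix"], dialect="plain_tsv"
        )
        labels = pd.read_csv(config["calibration_labels"], sep="\t", dtype=str)
        required = {"sample_id", "pathway", "label"}
        if not required <= set(labels.columns):
            raise ValidationError(
                f"calibration labels need columns {sorted(required)}"
            )
        models = []
        for definition in definitions:
            block = labels[labels["pathway"] == definition.pathway_name]
            if block.empty:
                raise ValidationError(
                    f"no calibration labels for pathway {definition.pathway_name!r}"
                )
            sub = training.subset_samples(block["sample_id"].tolist())
            models.append(
                calibrate_pathway(
                    sub,
                    pd.Series(block["label"].values, index=block["sample_id"]),
                    definition,
                )
            )
        log.append(f"models: calibrated {len(models)} pathways")
    save_models(models, outdir / "models.json")
    return models


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    out = Path(config["output_dir"])
    tmp = out.parent / (out.name + ".tmp")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    log: list[str] = [f"stpscore {__version__} pipeline"]
    try:
        excluded = _qc_stage(config, tmp, log)
        matrix = read_expression_matrix(
            config["matrix"], dialect=config["dialect"],
            input_scale=config["input_scale"],
        )
        kept = [s for s in matrix.sample_ids if s not in set(excluded)]
        if not kept:
            raise ValidationError("all samples excluded by QC")
        if len(kept) < matrix.n_samples:
            matrix = matrix.subset_samples(kept)
        log.append(f"matrix: {matrix.n_genes} genes x {matrix.n_samples} samples")

        models = _get_models(config, tmp, log)
        activity = score_matrix(matrix, models)

        groups = activity.annotations["group"]
        if "FOXO" in activity.pathways and activity.covariates["sod2"].notna().all() \
                and (groups == "control").any():
            reference = control_reference(
                activity.scores["FOXO"], activity.covariates["sod2"], groups
            )
            activity.pi3k_interpretation = interpret_pi3k(
                activity.scores["FOXO"], activity.covariates["sod2"], reference,
                tau_foxo=config["tau_foxo"], tau_sod2=config["tau_sod2"],
            )
            log.append("pi3k: interpretation computed from FOXO/SOD2")
        activity.to_tsv(tmp / "activity_scores.tsv")

        if config["signature"] is not None:
            sig_values = pd.read_csv(config["signature"], sep="\t", index_col=0)
            signature = SignatureMatrix(sig_values, level="top")
            immune_sig = None
            if config["immune_signature"] is not None:
                immune_sig = SignatureMatrix(
                    pd.read_csv(config["immune_signature"], sep="\t", index_col=0),
                    level="immune_subset",
                )
            linear = linear_from_log2(matrix.values).clip(lower=0.0)
            marker_rows = [g for g in signature.marker_genes
                           if g in linear.index]
            if len(marker_rows) < len(signature.marker_genes):
                raise ValidationError("matrix lacks signature marker genes")
            fractions = deconvolve_matrix(linear, signature, immune_sig)
            fractions.round(6).to_csv(tmp / "fractions.tsv", sep="\t")
            log.append(f"deconvolution: {len(fractions)} samples")

        # per-dataset tumor-vs-control comparisons
        comparisons = []
        datasets = activity.annotations["dataset_id"].fillna("all")
        for ds in sorted(datasets.unique()):
            ids = datasets.index[datasets == ds].tolist()
            sub = ActivityTable(
                activity.scores.loc[ids],
                activity.covariates.loc[ids],
                activity.annotations.loc[ids],
            )
            g = sub.annotations["group"]
            if not ((g == "tumor").any() and (g == "control").any()):
                continue
            paired = sub.annotations.loc[g == "tumor", "pair_id"].notna().all() \
                and sub.annotations.loc[g == "control", "pair_id"].notna().all()
            table = compare_pathway_activity(
                sub, paired=bool(paired),
                alpha_significant=config["alpha_significant"],
                alpha_annotate=config["alpha_annotate"],
            )
            table.insert(0, "dataset_id", ds)
            comparisons.append(table)
            if paired and config["rank_pathway"] in sub.pathways:
                ranked = ranked_paired_table(sub, config["rank_pathway"])
                ranked.round(4).to_csv(
                    tmp / f"paired_ranked_{config['rank_pathway']}_{ds}.tsv",
                    sep="\t", index=False,
                )
        if comparisons:
            pd.concat(comparisons, ignore_index=True).round(6).to_csv(
                tmp / "comparisons.tsv", sep="\t", index=False
            )
            log.append(f"comparisons: {sum(len(t) for t in comparisons)} rows")

        # correlations on tumor samples
        tumor_ids = groups.index[groups == "tumor"].tolist()
        corr_rows = []
        for a, b in CORRELATION_SET:
            xa = activity.scores[a] if a in activity.pathways else \
                activity.covariates.get(a)
            xb = activity.scores[b] if b in activity.pathways else \
                activity.covariates.get(b)
            if xa is None or xb is None or len(tumor_ids) < 3:
                continue
            va = xa.loc[tumor_ids]
            vb = xb.loc[tumor_ids]
            if va.isna().any() or vb.isna().any():
                continue
            try:
                res = correlate(va, vb, method="spearman")
            except ValidationError:
                continue
            corr_rows.append({"x": a, "y": b, **res})
        if corr_rows:
            pd.DataFrame(corr_rows).round(6).to_csv(
                tmp / "correlations.tsv", sep="\t", index=False
            )
            log.append(f"correlations: {len(corr_rows)} pairs")

        # reference-pathway comparability between datasets (report note only)
        comparability_rows = []
        ref = config["reference_pathway"]
        ds_names = sorted(datasets.unique())
        if ref in activity.pathways:
            for i, ds_a in enumerate(ds_names):
                for ds_b in ds_names[i + 1:]:
                    ids_a = datasets.index[(datasets == ds_a)
                                           & (groups == "control")]
                    ids_b = datasets.index[(datasets == ds_b)
                                           & (groups == "control")]
                    if len(ids_a) == 0 or len(ids_b) == 0:
                        continue
                    res = check_reference_comparability(
                        activity.scores.loc[ids_a, ref],
                        activity.scores.loc[ids_b, ref],
                    )
                    comparability_rows.append(
                        {"dataset_a": ds_a, "dataset_b": ds_b,
                         "reference_pathway": ref, **res}
                    )
        if comparability_rows:
            pd.DataFrame(comparability_rows).round(6).to_csv(
                tmp / "comparability.tsv", sep="\t", index=False
            )

        (tmp / "run.log").write_text("\n".join(log) + "\n")
        files = {
            p.name: p for p in sorted(tmp.iterdir()) if p.name != "summary.json"
        }
        summary = {
            "package_version": __version__,
            "config_hash": config.config_hash,
            "seed": config["seed"],
            "qc_excluded_samples": sorted(excluded),
            "n_samples_scored": int(activity.scores.shape[0]),
            "pathways": activity.pathways,
            "outputs": {name: _sha256(path) for name, path in files.items()},
        }
        with open(tmp / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if out.exists():
        shutil.rmtree(out)
    os.replace(tmp, out)
    files = {name: out / name for name in
             list(summary["outputs"]) + ["summary.json"]}
    logger.info("pipeline bundle written to %s", out)
    return ReportBundle(out, files, summary)
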