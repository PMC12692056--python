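"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of bulk Affymetrix cohorts from a
tumor-vs-normal pancreatic study: ground-truth calibration sets with known
pathway state, mixed-composition tumor/adjacent-control cohorts (epithelial
/ fibroblast / immune compartments drawn from Dirichlet priors), pure
epithelial cell-line panels, lineage marker signatures, and probe-level
chips with spike-ins, border/negative controls and 5'->3' degradation.
Every output is a pure function of its configuration, including the seed,
and ships with a truth table for parameter-recovery tests.

Generative model, in brief: each cell type has a fixed log2 expression
profile -- pathway target genes sit at a common baseline and are shifted by
``delta`` log2 units (in the target's direction) in cell types where that
pathway is active; lineage markers are expressed ``marker_fold``-fold above
their off-type baseline.  A bulk sample is the composition-weighted linear
mixture of its compartment profiles, log2(x+1)-transformed, plus i.i.d.
Gaussian log2 noise.  Proliferation (MKI67) couples to the tumor-epithelial
MAPK signal; a latent per-sample oxidative-stress state jointly raises the
FOXO target genes and SOD2, reproducing the confound that makes FOXO an
ambiguous PI3K readout in tissue.

The per-cell-type active-pathway sets are model assumptions chosen to echo
qualitative descriptions of pancreatic tumor biology (MAPK/STAT3/Wnt/Notch/
TGFb-active tumor epithelium, TGFb/HH/NFkB-active fibroblasts, NFkB- and
interferon-active immune cells); they are not measured facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, PathwayDefinition, PathwayTarget
from .deconvolution import SignatureMatrix
from .qc import ProbeTable

#: the twelve scored pathways plus the FOXO readout model
DEFAULT_PATHWAYS = (
    "AR", "ER", "PI3K", "MAPK", "TGFB", "NOTCH", "HH", "WNT", "NFKB",
    "STAT12_IFN1", "STAT12_IFN2", "STAT3",
)
FOXO_PATHWAY = "FOXO"

#: which pathways are transcriptionally active in each compartment
ACTIVE_PATHWAYS_BY_TYPE = {
    "tumor_epithelial": frozenset({"MAPK", "STAT3", "WNT", "NOTCH", "TGFB"}),
    "normal_epithelial": frozenset(),
    "fibroblast": frozenset({"TGFB", "HH", "NFKB"}),
    "immune": frozenset({"NFKB", "STAT12_IFN1", "STAT12_IFN2"}),
}

TOP_TYPES = ("epithelial", "fibroblast", "immune")
IMMUNE_SUBSETS = ("granulocyte", "monocyte_macrophage", "T_cell", "B_cell", "NK")

BASELINE_LOG2 = 7.0  # common log2 baseline of non-marker genes
MARKER_BASELINE_LOG2 = 4.0  # off-type expression of lineage markers


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator (defaults are the study conditions)."""

    seed: int = 0
    n_genes: int = 1000  # background genes
    n_targets_per_pathway: int = 25  # within the 20-30 per-pathway convention
    delta: float = 1.0  # active-pathway target shift, log2 units
    noise_sigma: float = 0.3  # i.i.d. log2 noise
    markers_per_type: int = 30
    marker_fold: float = 8.0  # linear on/off contrast of lineage markers
    markers_per_subset: int = 10
    n_pairs: int = 16  # tumor/adjacent pairs when paired
    paired: bool = True
    n_tumor: int = 16  # unpaired design sizes
    n_control: int = 16
    n_cell_lines: int = 0
    tumor_alpha: tuple = (4.0, 5.0, 1.0)  # Dirichlet over (epi, fib, immune)
    control_alpha: tuple = (4.0, 5.0, 1.0)
    subset_alpha: tuple = (6.0, 2.0, 2.0, 1.0, 1.0)  # granulocyte-dominant
    kappa_ki67: float = 0.8  # MAPK->MKI67 coupling, log2 units per unit signal
    oxidative_stress_p: float = 0.3  # tissue samples; 0 in cell lines
    sod2_shift: float = 1.5  # log2 SOD2 shift under oxidative stress
    foxo_stress_shift: float = 1.0  # log2 shift of FOXO targets under stress
    dataset_id: str = "SIM1"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        for name in ("tumor_alpha", "control_alpha", "subset_alpha"):
            if any(a <= 0 for a in getattr(self, name)):
                raise ValidationError(f"{name} entries must be > 0")
        if not 0 <= self.oxidative_stress_p <= 1:
            raise ValidationError("oxidative_stress_p must be in [0, 1]")
        if self.n_targets_per_pathway < 1:
            raise ValidationError("n_targets_per_pathway must be >= 1")


@dataclass
class CohortData:
    """A generated cohort with its signatures, definitions and ground truth."""

    matrix: ExpressionMatrix
    signature: SignatureMatrix
    immune_signature: SignatureMatrix
    definitions: list[PathwayDefinition]
    truth: pd.DataFrame  # per-sample composition, stress flag, group
    config: GeneratorConfig = field(repr=False, default=None)  # type: ignore


def default_pathway_definitions(
    n_targets: int = 25, pathways: tuple = DEFAULT_PATHWAYS, include_foxo: bool = True
) -> list[PathwayDefinition]:
    """Synthetic target-gene catalogues: ``<PW>_Tnn`` genes, every fifth
    target repressed (direction -1), unit evidence weights."""
    names = list(pathways) + ([FOXO_PATHWAY] if include_foxo else [])
    defs = []
    for pw in names:
        targets = [
            PathwayTarget(
                gene_id=f"{pw}_T{i:02d}",
                direction=-1 if i % 5 == 0 else 1,
                weight=1.0,
            )
            for i in range(1, n_targets + 1)
        ]
        defs.append(PathwayDefinition(pw, targets))
    return defs


def generate_calibration_set(
    definition: PathwayDefinition,
    n_active: int = 50,
    n_inactive: int = 50,
    delta: float = 1.0,
    sigma: float = 0.3,
    seed: int = 0,
    n_background: int = 100,
):
    """Ground-truth samples with known pathway state.

    Target genes sit at ``baseline + direction * delta`` in active samples
    and at baseline in inactive ones; background genes are state-independent.
    Returns ``(ExpressionMatrix, labels)`` with labels "active"/"inactive".
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    if n_active < 2 or n_inactive < 2:
        raise ValidationError("need >= 2 samples per class")
    rng = np.random.default_rng(seed)
    genes = definition.gene_ids + [f"BG{i:04d}" for i in range(1, n_background + 1)]
    n = n_active + n_inactive
    state = np.array([1] * n_active + [0] * n_inactive)
    values = np.empty((len(genes), n))
    for gi, t in enumerate(definition.targets):
        mu = BASELINE_LOG2 + t.direction * delta * state
        values[gi] = rng.normal(mu, sigma)
    for gi in range(len(definition.targets), len(genes)):
        values[gi] = rng.normal(BASELINE_LOG2, sigma, size=n)
    sample_ids = [f"CAL_A{i:03d}" for i in range(n_active)] + [
        f"CAL_I{i:03d}" for i in range(n_inactive)
    ]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    labels = pd.Series(
        ["active"] * n_active + ["inactive"] * n_inactive, index=sample_ids
    )
    return matrix, labels


def generate_calibration_suite(
    definitions: list[PathwayDefinition],
    n_active: int = 50,
    n_inactive: int = 50,
    delta: float = 1.0,
    sigma: float = 0.3,
    seed: int = 0,
    n_background: int = 100,
):
    """One combined ground-truth matrix covering several pathways.

    Each pathway gets its own block of ``CAL_<pw>_*`` samples whose state
    shifts only that pathway's targets; all other genes stay at baseline.
    Returns ``(ExpressionMatrix, labels)`` where ``labels`` is a DataFrame
    with columns ``sample_id, pathway, label`` suitable for per-pathway
    calibration.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [g for d in definitions for g in d.gene_ids] + [
        f"BG{i:04d}" for i in range(1, n_background + 1)
    ]
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_ids: list[str] = []
    label_rows: list[dict] = []
    columns: list[np.ndarray] = []
    for d in definitions:
        for label, count in (("active", n_active), ("inactive", n_inactive)):
            for i in range(count):
                sid = f"CAL_{d.pathway_name}_{label[0].upper()}{i:03d}"
                col = rng.normal(BASELINE_LOG2, sigma, size=len(genes))
                if label == "active":
                    for t in d.targets:
                        col[gene_index[t.gene_id]] += t.direction * delta
                sample_ids.append(sid)
                columns.append(col)
                label_rows.append(
                    {"sample_id": sid, "pathway": d.pathway_name, "label": label}
                )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    )
    return matrix, pd.DataFrame(label_rows)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def _marker_gene_ids(config: GeneratorConfig) -> dict[str, list[str]]:
    prefix = {"epithelial": "EPI", "fibroblast": "FIB", "immune": "IMM"}
    return {
        t: [f"{prefix[t]}_M{i:02d}" for i in range(1, config.markers_per_type + 1)]
        for t in TOP_TYPES
    }


def _subset_marker_ids(config: GeneratorConfig) -> dict[str, list[str]]:
    prefix = {
        "granulocyte": "GRA", "monocyte_macrophage": "MONO",
        "T_cell": "TC", "B_cell": "BC", "NK": "NK",
    }
    return {
        s: [f"{prefix[s]}_M{i:02d}" for i in range(1, config.markers_per_subset + 1)]
        for s in IMMUNE_SUBSETS
    }


def build_signatures(config: GeneratorConfig):
    """Top-level and immune-subset signature matrices (linear scale)."""
    on = 2.0 ** MARKER_BASELINE_LOG2 * config.marker_fold
    off = 2.0 ** MARKER_BASELINE_LOG2
    markers = _marker_gene_ids(config)
    genes = [g for t in TOP_TYPES for g in markers[t]]
    top = pd.DataFrame(off, index=genes, columns=list(TOP_TYPES))
    for t in TOP_TYPES:
        top.loc[markers[t], t] = on
    subset_markers = _subset_marker_ids(config)
    sgenes = [g for s in IMMUNE_SUBSETS for g in subset_markers[s]]
    sub = pd.DataFrame(off, index=sgenes, columns=list(IMMUNE_SUBSETS))
    for s in IMMUNE_SUBSETS:
        sub.loc[subset_markers[s], s] = on
    return (
        SignatureMatrix(top, level="top"),
        SignatureMatrix(sub, level="immune_subset"),
    )


def _type_profiles_linear(
    config: GeneratorConfig,
    definitions: list[PathwayDefinition],
    background_baseline: pd.Series,
) -> pd.DataFrame:
    """Linear expression profile per compartment (genes x compartments)."""
    markers = _marker_gene_ids(config)
    subset_markers = _subset_marker_ids(config)
    gene_ids = (
        list(background_baseline.index)
        + [g for d in definitions for g in d.gene_ids]
        + [g for t in TOP_TYPES for g in markers[t]]
        + [g for s in IMMUNE_SUBSETS for g in subset_markers[s]]
        + ["MKI67", "SOD2"]
    )
    compartments = list(ACTIVE_PATHWAYS_BY_TYPE)
    log2p = pd.DataFrame(BASELINE_LOG2, index=gene_ids, columns=compartments)
    log2p.loc[background_baseline.index, :] = np.tile(
        background_baseline.to_numpy()[:, None], (1, len(compartments))
    )
    for d in definitions:
        if d.pathway_name == FOXO_PATHWAY:
            continue  # FOXO targets shift with the sample-level stress state
        for t in d.targets:
            for comp, active in ACTIVE_PATHWAYS_BY_TYPE.items():
                if d.pathway_name in active:
                    log2p.loc[t.gene_id, comp] += t.direction * config.delta
    linear = 2.0 ** log2p
    # lineage markers: marker_fold contrast, absent outside their lineage
    marker_on = 2.0 ** MARKER_BASELINE_LOG2 * config.marker_fold
    marker_off = 2.0 ** MARKER_BASELINE_LOG2
    type_of = {
        "tumor_epithelial": "epithelial",
        "normal_epithelial": "epithelial",
        "fibroblast": "fibroblast",
        "immune": "immune",
    }
    for t in TOP_TYPES:
        for comp in compartments:
            linear.loc[markers[t], comp] = (
                marker_on if type_of[comp] == t else marker_off
            )
    # subset markers are expressed only within the immune compartment;
    # the immune column is filled per sample from its subset mix
    for s in IMMUNE_SUBSETS:
        linear.loc[subset_markers[s], :] = 0.0
    return linear


def generate_cohort(config: GeneratorConfig) -> CohortData:
    """Generate a mixed-composition tumor/control (or cell-line) cohort.

    Paired designs emit ``n_pairs`` tumor/adjacent pairs with correlated
    compositions sharing a ``pair_id``; unpaired designs emit independent
    ``n_tumor``/``n_control`` groups; ``n_cell_lines`` adds pure tumor-
    epithelial samples.  Returns the expression matrix (log2 scale), both
    signatures, the pathway definitions and a per-sample truth table.
    """
    rng = np.random.default_rng(config.seed)
    definitions = default_pathway_definitions(config.n_targets_per_pathway)
    background = pd.Series(
        rng.normal(BASELINE_LOG2, 1.0, size=config.n_genes),
        index=[f"BG{i:04d}" for i in range(1, config.n_genes + 1)],
    )
    profiles = _type_profiles_linear(config, definitions, background)
    subset_markers = _subset_marker_ids(config)
    marker_on = 2.0 ** MARKER_BASELINE_LOG2 * config.marker_fold
    marker_off = 2.0 ** MARKER_BASELINE_LOG2
    top_sig, sub_sig = build_signatures(config)

    samples: list[dict] = []
    if config.paired:
        for i in range(1, config.n_pairs + 1):
            base = rng.dirichlet(config.control_alpha)
            tumor_f = 0.5 * base + 0.5 * rng.dirichlet(config.tumor_alpha)
            samples.append(
                {"sample_id": f"N{i:02d}", "group": "control",
                 "pair_id": f"P{i:02d}", "composition": base}
            )
            samples.append(
                {"sample_id": f"T{i:02d}", "group": "tumor",
                 "pair_id": f"P{i:02d}", "composition": tumor_f}
            )
    else:
        for i in range(1, config.n_control + 1):
            samples.append(
                {"sample_id": f"N{i:02d}", "group": "control",
                 "pair_id": None, "composition": rng.dirichlet(config.control_alpha)}
            )
        for i in range(1, config.n_tumor + 1):
            samples.append(
                {"sample_id": f"T{i:02d}", "group": "tumor",
                 "pair_id": None, "composition": rng.dirichlet(config.tumor_alpha)}
            )
    for i in range(1, config.n_cell_lines + 1):
        samples.append(
            {"sample_id": f"CL{i:02d}", "group": "cell_line",
             "pair_id": None, "composition": np.array([1.0, 0.0, 0.0])}
        )

    gene_ids = list(profiles.index)
    n_genes = len(gene_ids)
    values = np.empty((n_genes, len(samples)))
    truth_rows = []
    foxo_genes = [g for d in definitions if d.pathway_name == FOXO_PATHWAY
                  for g in d.gene_ids]
    foxo_dirs = np.array(
        [t.direction for d in definitions if d.pathway_name == FOXO_PATHWAY
         for t in d.targets], float,
    )
    foxo_idx = [gene_ids.index(g) for g in foxo_genes]
    ki67_idx = gene_ids.index("MKI67")
    sod2_idx = gene_ids.index("SOD2")

    for si, spec in enumerate(samples):
        f_epi, f_fib, f_imm = spec["composition"]
        tissue = spec["group"] != "cell_line"
        epi_comp = "tumor_epithelial" if spec["group"] in ("tumor", "cell_line") \
            else "normal_epithelial"
        subset_p = rng.dirichlet(config.subset_alpha)
        stress = bool(
            tissue and rng.random() < config.oxidative_stress_p
        )
        bulk = (
            f_epi * profiles[epi_comp].to_numpy()
            + f_fib * profiles["fibroblast"].to_numpy()
            + f_imm * profiles["immune"].to_numpy()
        )
        # immune-subset markers: expressed by the immune compartment only,
        # with the sample's subset mix setting the on/off pattern
        for sj, subset in enumerate(IMMUNE_SUBSETS):
            rows = [gene_ids.index(g) for g in subset_markers[subset]]
            level = subset_p[sj] * marker_on + (1 - subset_p[sj]) * marker_off
            bulk[rows] = f_imm * level
        log2bulk = np.log2(bulk + 1.0)
        if stress:
            log2bulk[foxo_idx] += config.foxo_stress_shift * foxo_dirs
            log2bulk[sod2_idx] += config.sod2_shift
        mapk_signal = config.delta * f_epi if epi_comp == "tumor_epithelial" else 0.0
        log2bulk[ki67_idx] += config.kappa_ki67 * mapk_signal
        log2bulk += rng.normal(0.0, config.noise_sigma, size=n_genes)
        values[:, si] = log2bulk
        truth_rows.append(
            {
                "sample_id": spec["sample_id"],
                "group": spec["group"],
                "pair_id": spec["pair_id"],
                "f_epithelial": f_epi,
                "f_fibroblast": f_fib,
                "f_immune": f_imm,
                **{f"p_{s}": subset_p[j] for j, s in enumerate(IMMUNE_SUBSETS)},
                "oxidative_stress": stress,
                "mapk_signal": mapk_signal,
            }
        )

    sample_ids = [s["sample_id"] for s in samples]
    annotations = pd.DataFrame(
        {
            "group": [s["group"] for s in samples],
            "pair_id": [s["pair_id"] for s in samples],
            "dataset_id": config.dataset_id,
            "origin": None,
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), annotations
    )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return CohortData(matrix, top_sig, sub_sig, definitions, truth, config)


def generate_cell_line_panel(config: GeneratorConfig, n_lines: int = 10) -> CohortData:
    """Pure tumor-epithelial samples (composition exactly (1, 0, 0))."""
    cfg = replace(
        config, paired=False, n_tumor=0, n_control=0, n_cell_lines=n_lines
    )
    return generate_cohort(cfg)


# ---------------------------------------------------------------------------
# probe-level chip generator
# ---------------------------------------------------------------------------

PROBES_PER_SET = 11
FAULT_INJECTORS = (
    "negative_value", "saturation", "spikein_inversion",
    "corner_negative_controls", "steep_decay",
)


def generate_probe_level(
    sample_id: str = "chip01",
    chip_dims: tuple[int, int] = (100, 100),
    decay_lambda: float = 0.01,
    fault_injections: tuple = (),
    seed: int = 0,
    n_probesets: int = 300,
    dataset_id: str | None = None,
) -> ProbeTable:
    """Synthetic probe-level chip for the QC suite.

    Regular probes follow ``intensity = E_j * exp(-lambda * (P - position))
    * noise`` with ``P = 11`` probes per probeset (position 1 is 5');
    spike-in families step up 1.5x per class; housekeeping (GAPDH/ACTB)
    5'/middle/3' probes carry the same decay; negative controls are placed
    in centrally symmetric pairs so their intensity centroid sits at the
    chip center.  Each fault injector corrupts exactly one QC criterion:

    - ``negative_value``: one mid-position probe set to -3
    - ``saturation``: one mid-position probe above the 16-bit ceiling
    - ``spikein_inversion``: swaps the bioC/bioD hybridization classes
    - ``corner_negative_controls``: piles the negative controls at (0, 0)
    - ``steep_decay``: lambda = 0.15 on regular probes only
    """
    unknown = set(fault_injections) - set(FAULT_INJECTORS)
    if unknown:
        raise ValidationError(f"unknown fault injectors: {sorted(unknown)}")
    nx, ny = chip_dims
    if nx < 4 or ny < 4:
        raise ValidationError("chip dimensions too small")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def interior_xy(n: int) -> np.ndarray:
        return np.column_stack(
            [rng.integers(1, nx - 1, size=n), rng.integers(1, ny - 1, size=n)]
        )

    lam = 0.15 if "steep_decay" in fault_injections else decay_lambda
    base_expr = rng.lognormal(mean=np.log(200.0), sigma=0.8, size=n_probesets)
    for j in range(n_probesets):
        xy = interior_xy(PROBES_PER_SET)
        for pos in range(1, PROBES_PER_SET + 1):
            intensity = (
                base_expr[j]
                * np.exp(-lam * (PROBES_PER_SET - pos))
                * rng.lognormal(0.0, 0.1)
            )
            rows.append(
                {"probe_id": f"PS{j:04d}_{pos:02d}", "probeset_id": f"PS{j:04d}",
                 "x": int(xy[pos - 1, 0]), "y": int(xy[pos - 1, 1]),
                 "position": pos, "intensity": float(intensity),
                 "control_class": "none"}
            )
    # targeted single-probe faults at the middle position so the
    # degradation slope is untouched
    mid = PROBES_PER_SET // 2 + 1
    if "negative_value" in fault_injections:
        idx = mid - 1  # probeset 0, middle position
        rows[idx]["intensity"] = -3.0
    if "saturation" in fault_injections:
        idx = PROBES_PER_SET + mid - 1  # probeset 1, middle position
        rows[idx]["intensity"] = 70000.0

    spike_families = {
        "polyA": (("polyA_lys", "polyA_phe", "polyA_thr", "polyA_dap"), 100.0),
        "hyb": (("hyb_bioB", "hyb_bioC", "hyb_bioD", "hyb_cre"), 200.0),
    }
    for family, (classes, base) in spike_families.items():
        levels = {cls: base * 1.5**k for k, cls in enumerate(classes)}
        if family == "hyb" and "spikein_inversion" in fault_injections:
            levels["hyb_bioC"], levels["hyb_bioD"] = (
                levels["hyb_bioD"], levels["hyb_bioC"],
            )
        for cls in classes:
            xy = interior_xy(20)
            for k in range(20):
                rows.append(
                    {"probe_id": f"{cls}_{k:02d}", "probeset_id": cls,
                     "x": int(xy[k, 0]), "y": int(xy[k, 1]), "position": 1,
                     "intensity": float(levels[cls] * rng.lognormal(0.0, 0.1)),
                     "control_class": cls}
                )
    # housekeeping 3'/5' controls share the regular decay profile
    for gene, level in (("gapdh", 1000.0), ("actb", 1200.0)):
        for cls_suffix, pos in (("_5", 1), ("_m", mid), ("_3", PROBES_PER_SET)):
            xy = interior_xy(10)
            for k in range(10):
                val = (
                    level
                    * np.exp(-decay_lambda * (PROBES_PER_SET - pos))
                    * rng.lognormal(0.0, 0.05)
                )
                rows.append(
                    {"probe_id": f"{gene}{cls_suffix}_{k:02d}",
                     "probeset_id": f"{gene}_ctrl",
                     "x": int(xy[k, 0]), "y": int(xy[k, 1]), "position": pos,
                     "intensity": float(val),
                     "control_class": f"{gene}{cls_suffix}"}
                )
    # border controls: positive and negative alternating along the top edge
    for k in range(40):
        rows.append(
            {"probe_id": f"border_pos_{k:02d}", "probeset_id": "border",
             "x": int(k % nx), "y": 0, "position": 1,
             "intensity": float(500.0 * rng.lognormal(0.0, 0.1)),
             "control_class": "border_pos"}
        )
        rows.append(
            {"probe_id": f"border_neg_{k:02d}", "probeset_id": "border",
             "x": int(k % nx), "y": int(ny - 1), "position": 1,
             "intensity": float(30.0 * rng.lognormal(0.0, 0.1)),
             "control_class": "border_neg"}
        )
    # negative controls in centrally symmetric pairs -> centroid at center
    n_neg_pairs = 50
    xy = interior_xy(n_neg_pairs)
    for k in range(n_neg_pairs):
        inten = float(40.0 * rng.lognormal(0.0, 0.1))
        for tag, (px, py) in (
            ("a", (int(xy[k, 0]), int(xy[k, 1]))),
            ("b", (int(nx - 1 - xy[k, 0]), int(ny - 1 - xy[k, 1]))),
        ):
            rows.append(
                {"probe_id": f"neg_{k:02d}{tag}", "probeset_id": "neg",
                 "x": px, "y": py, "position": 1, "intensity": inten,
                 "control_class": "negative_ctrl"}
            )
    if "corner_negative_controls" in fault_injections:
        for r in rows:
            if r["control_class"] == "negative_ctrl":
                r["x"], r["y"] = 0, 0
    probes = pd.DataFrame(rows)
    return ProbeTable(sample_id, probes, chip_dims, dataset_id)
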