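"""Expression-matrix, pathway-definition and study-design I/O.

Two tab-separated matrix dialects are supported:

``plain_tsv``
    Row 1 is ``feature_id`` followed by sample ids; every following row is a
    feature id and one decimal value per sample.

``series_matrix_like``
    The same table preceded by optional ``!``-prefixed annotation lines in
    the style of GEO series-matrix headers.  Recognized lines are
    ``!Sample_group``, ``!Sample_pair``, ``!Sample_dataset`` and
    ``!Sample_origin``; unrecognized ``!`` lines are skipped, never fatal.

Expression values are log2-scale by convention; ``input_scale="linear"``
applies a ``log2(x + 1)`` transform on read.  Identifiers are case-sensitive
gene symbols; probeset-level matrices can be collapsed to gene level with
:func:`collapse_probesets`.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

VALID_GROUPS = ("tumor", "control", "cell_line")
VALID_ORIGINS = ("primary", "metastasis", "none")

#: annotation columns written/read in the series_matrix_like dialect
_ANNOTATION_TAGS = {
    "!Sample_group": "group",
    "!Sample_pair": "pair_id",
    "!Sample_dataset": "dataset_id",
    "!Sample_origin": "origin",
}
_ANNOTATION_COLUMNS = ["group", "pair_id", "dataset_id", "origin"]


@dataclass
class ExpressionMatrix:
    """Genes-by-samples log2 expression with per-sample annotations.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``annotations`` is indexed by sample id with columns ``group``,
    ``pair_id``, ``dataset_id`` and ``origin`` (missing entries are NaN).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                index=self.values.columns, columns=_ANNOTATION_COLUMNS, dtype=object
            )
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self, require_groups: bool = False) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate gene ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        if not self.annotations.index.equals(cols):
            raise ValidationError("annotation index does not match sample ids")
        groups = self.annotations["group"]
        known = groups.dropna()
        bad_groups = set(known) - set(VALID_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown sample groups: {sorted(bad_groups)}")
        if require_groups and groups.isna().any():
            missing = list(groups[groups.isna()].index[:5])
            raise ValidationError(f"samples without a group annotation: {missing}")
        # a pair id, when present, names exactly one tumor and one control
        pairs = self.annotations["pair_id"].dropna()
        for pid, members in self.annotations.loc[pairs.index].groupby("pair_id"):
            if len(members) != 2 or set(members["group"]) != {"tumor", "control"}:
                raise ValidationError(
                    f"pair {pid!r} must contain exactly one tumor and one control "
                    f"sample (got groups {list(members['group'])})"
                )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.annotations.loc[sample_ids].copy()
        )


def _parse_numeric_block(lines: list[str], path: str) -> pd.DataFrame:
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: header row has no sample ids")
    text = "".join(lines)
    try:
        frame = pd.read_csv(
            _io.StringIO(text), sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (frame != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at row "
            f"{frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: empty cell at row {frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    return numeric.astype(float)


def read_expression_matrix(
    path,
    dialect: str = "plain_tsv",
    input_scale: str = "log2",
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV file.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"plain_tsv", "series_matrix_like"}
        ``series_matrix_like`` consumes leading ``!`` annotation lines.
    input_scale : {"log2", "linear"}
        ``linear`` applies ``log2(x + 1)`` on read.
    """
    if dialect not in ("plain_tsv", "series_matrix_like"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    if input_scale not in ("log2", "linear"):
        raise ValidationError(f"unknown input_scale {input_scale!r}")
    with open(path) as fh:
        lines = fh.readlines()
    ann_lines: dict[str, list[str]] = {}
    start = 0
    if dialect == "series_matrix_like":
        for start, line in enumerate(lines):
            if not line.startswith("!"):
                break
            tag, *fields = line.rstrip("\n").split("\t")
            col = _ANNOTATION_TAGS.get(tag)
            if col is None:
                logger.debug("skipping unrecognized annotation line %r", tag)
                continue
            ann_lines[col] = fields
    if start >= len(lines) or not lines[start:]:
        raise FormatError(f"{path}: no matrix block found")
    values = _parse_numeric_block(lines[start:], str(path))
    values.index.name = None
    values.columns.name = None
    if input_scale == "linear":
        if (values.to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative values with input_scale=linear")
        values = np.log2(values + 1.0)
    annotations = pd.DataFrame(
        index=values.columns, columns=_ANNOTATION_COLUMNS, dtype=object
    )
    for col, fields in ann_lines.items():
        if len(fields) != values.shape[1]:
            raise FormatError(
                f"{path}: annotation line for {col!r} has {len(fields)} fields, "
                f"expected {values.shape[1]}"
            )
        annotations[col] = [None if f == "" else f for f in fields]
    return ExpressionMatrix(values, annotations)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path,
    dialect: str = "plain_tsv",
    precision: int = 6,
) -> None:
    """Write a matrix in the given dialect with fixed decimal precision."""
    if dialect not in ("plain_tsv", "series_matrix_like"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "series_matrix_like":
            for tag, col in _ANNOTATION_TAGS.items():
                series = matrix.annotations[col]
                if series.notna().any():
                    fields = ["" if pd.isna(v) else str(v) for v in series]
                    fh.write(tag + "\t" + "\t".join(fields) + "\n")
        fh.write("feature_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        fmt = f"%.{precision}f"
        for gene, row in matrix.values.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(fmt % v for v in row) + "\n")


def collapse_probesets(
    matrix: ExpressionMatrix,
    mapping: dict[str, str] | pd.Series,
    method: str = "max_mean",
) -> ExpressionMatrix:
    """Collapse a probeset-level matrix to gene level.

    ``max_mean`` keeps, per gene, the probeset with the highest row mean
    (the convention for Affymetrix arrays with several probesets per gene);
    ``mean`` averages all probesets of a gene.  Probesets absent from
    ``mapping`` are dropped with a logged count.
    """
    if method not in ("max_mean", "mean"):
        raise ValidationError(f"unknown collapse method {method!r}")
    mapping = dict(mapping)
    present = [p for p in matrix.gene_ids if p in mapping]
    dropped = matrix.n_genes - len(present)
    if not present:
        raise ValidationError("probeset mapping covers none of the matrix rows")
    if dropped:
        logger.info("collapse_probesets: dropped %d unmapped probesets", dropped)
    sub = matrix.values.loc[present]
    genes = pd.Series({p: mapping[p] for p in present}, name="gene")
    if method == "mean":
        collapsed = sub.groupby(genes).mean()
    else:
        row_means = sub.mean(axis=1)
        best = row_means.groupby(genes).idxmax()
        collapsed = sub.loc[best.values]
        collapsed.index = best.index
    collapsed = collapsed.sort_index()
    collapsed.index.name = None
    return ExpressionMatrix(collapsed, matrix.annotations.copy())


# ---------------------------------------------------------------------------
# pathway definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayTarget:
    """One transcription-factor target gene of a pathway."""

    gene_id: str
    direction: int = 1  # +1 up-regulated by the active pathway, -1 down
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValidationError(
                f"target {self.gene_id!r}: direction must be +1 or -1, "
                f"got {self.direction}"
            )
        if not self.weight > 0:
            raise ValidationError(
                f"target {self.gene_id!r}: weight must be positive, got {self.weight}"
            )


@dataclass
class PathwayDefinition:
    """A pathway's target-gene list with directions and evidence weights."""

    pathway_name: str
    targets: list[PathwayTarget]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"pathway {self.pathway_name!r} has no targets")
        seen = [t.gene_id for t in self.targets]
        if len(set(seen)) != len(seen):
            dupes = sorted({g for g in seen if seen.count(g) > 1})
            raise ValidationError(
                f"pathway {self.pathway_name!r} lists duplicate genes: {dupes}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.targets]


def read_pathway_definitions(path) -> list[PathwayDefinition]:
    """Read pathway definitions from a TSV with columns
    ``pathway, gene, direction, weight`` (direction and weight optional,
    defaulting to +1 and 1.0)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pathway", "gene"}
    if not required <= set(table.columns):
        raise FormatError(
            f"{path}: pathway definition file needs columns {sorted(required)}"
        )
    defs: list[PathwayDefinition] = []
    for name, block in table.groupby("pathway", sort=False):
        targets = []
        for _, row in block.iterrows():
            d = int(float(row["direction"])) if row.get("direction", "") != "" else 1
            w = float(row["weight"]) if row.get("weight", "") != "" else 1.0
            targets.append(PathwayTarget(row["gene"], d, w))
        defs.append(PathwayDefinition(str(name), targets))
    names = [d.pathway_name for d in defs]
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate pathway names")
    return defs


def write_pathway_definitions(definitions: list[PathwayDefinition], path) -> None:
    rows = [
        {"pathway": d.pathway_name, "gene": t.gene_id,
         "direction": t.direction, "weight": t.weight}
        for d in definitions
        for t in d.targets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study design registry
# ---------------------------------------------------------------------------

VALID_CONTROL_KINDS = ("tumor_adjacent", "normal_pancreas", "none")


@dataclass(frozen=True)
class DatasetDesign:
    dataset_id: str
    n_tumor: int
    n_control: int
    control_kind: str
    paired: bool
    selection: str = ""

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_control < 0:
            raise ValidationError(f"{self.dataset_id}: negative sample count")
        if self.control_kind not in VALID_CONTROL_KINDS:
            raise ValidationError(
                f"{self.dataset_id}: control_kind {self.control_kind!r} not in "
                f"{VALID_CONTROL_KINDS}"
            )
        if self.paired and self.n_tumor != self.n_control:
            raise ValidationError(
                f"{self.dataset_id}: paired design requires n_tumor == n_control "
                f"(got {self.n_tumor} vs {self.n_control})"
            )


@dataclass
class StudyRegistry:
    """The study's dataset inventory with derived sample totals."""

    datasets: list[DatasetDesign]

    @property
    def total_paired_samples(self) -> int:
        """Number of tumor/adjacent pairs summed over the paired datasets.

        Each pair contributes one tumor and one matched control sample; the
        paired-sample count equals the number of tumor samples in the
        paired datasets.
        """
        return sum(d.n_tumor for d in self.datasets if d.paired)

    @property
    def total_paired_arrays(self) -> int:
        """Hybridized arrays (tumor plus control) in the paired datasets."""
        return sum(d.n_tumor + d.n_control for d in self.datasets if d.paired)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def get(self, dataset_id: str) -> DatasetDesign:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)


def build_study_registry(design_table) -> StudyRegistry:
    """Build a :class:`StudyRegistry` from a design TSV with columns
    ``dataset_id, n_tumor, n_control, control_kind, paired, selection``."""
    table = pd.read_csv(design_table, sep="\t", dtype=str, keep_default_na=False)
    required = {"dataset_id", "n_tumor", "n_control", "control_kind", "paired"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{design_table}: missing columns {sorted(missing)}")
    datasets = []
    for _, row in table.iterrows():
        datasets.append(
            DatasetDesign(
                dataset_id=row["dataset_id"],
                n_tumor=int(row["n_tumor"]),
                n_control=int(row["n_control"]),
                control_kind=row["control_kind"],
                paired=str(row["paired"]).strip().lower() in ("true", "1", "yes"),
                selection=row.get("selection", ""),
            )
        )
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{design_table}: duplicate dataset ids")
    return StudyRegistry(datasets)
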