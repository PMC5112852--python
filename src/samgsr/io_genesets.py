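"""Expression-matrix, label and GMT gene-set I/O.

Containers for two-class log2-scale expression data (genes x samples) and
named gene-set collections (MSigDB-style GMT), plus the standard
pre-analysis steps: collapsing probe-level rows to gene level by largest
fold change, and restricting a collection to the measured gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DISEASED = 1
CONTROL = -1

_LABEL_VALUES = frozenset({DISEASED, CONTROL})


class ParseError(ValueError):
    """A file could not be parsed (malformed line, non-numeric cell, ...)."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (duplicate ids, missing values, ...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples matrix of log2-scale expression with binary labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``labels`` is a Series over the same sample ids with values +1
    (diseased) / -1 (control).
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        if not self.values.columns.equals(self.labels.index):
            lab = self.labels.reindex(self.values.columns)
            if lab.isna().any():
                missing = list(self.values.columns[lab.isna()])
                raise ValidationError(f"samples without a label: {missing[:5]}")
            object.__setattr__(self, "labels", lab)
        bad = set(self.labels.unique()) - _LABEL_VALUES
        if bad:
            raise ValidationError(f"labels must be in {{+1, -1}}, got {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValidationError("missing expression values are not supported")

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

    @property
    def y(self) -> np.ndarray:
        """Label vector aligned with ``sample_ids`` (+1 diseased, -1 control)."""
        return self.labels.to_numpy()

    def require_two_groups(self, min_per_class: int = 2) -> None:
        n_d = int((self.y == DISEASED).sum())
        n_c = int((self.y == CONTROL).sum())
        if n_d < min_per_class or n_c < min_per_class:
            raise ValidationError(
                f"need >= {min_per_class} samples per class, got {n_d} diseased / {n_c} control"
            )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from dataset: {missing[:5]}")
        return ExpressionDataset(self.values.loc[gene_ids], self.labels)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: ``sets`` maps set id -> ordered member gene ids."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) != len(set(members)):
                raise ValidationError(f"duplicate members in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def set_ids(self) -> list[str]:
        return list(self.sets)

    def members(self, set_id: str) -> list[str]:
        return list(self.sets[set_id])

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g)
        return list(seen)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate member ids within a line are deduplicated preserving the first
    occurrence; a duplicate set name across lines is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped: dict[str, None] = {}
            for g in members:
                if g:
                    deduped.setdefault(g)
            sets[name] = list(deduped)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# expression / labels


def read_expression(path, labels: pd.Series, orientation: str = "genes_in_rows",
                    sep: str | None = None) -> ExpressionDataset:
    """Read a rectangular numeric TSV/CSV into an ExpressionDataset.

    ``orientation`` declares whether rows are genes or samples; the result is
    always genes x samples. Non-numeric cells (including NA) are a hard error.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    try:
        numeric = table.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric cell in expression table ({exc})") from exc
    if numeric.isna().any().any():
        raise ParseError(f"{path}: missing value in expression table")
    if orientation == "samples_in_rows":
        numeric = numeric.T
    if numeric.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample id")
    return ExpressionDataset(numeric.astype(float), labels)


def read_labels(path, diseased: str = "1", control: str = "-1",
                sep: str | None = None) -> pd.Series:
    """Read a two-column ``sample_id, label`` file into a +1/-1 Series.

    ``diseased`` / ``control`` give the class names used in the file
    (defaults accept a numeric +1/-1 coding directly).
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                        keep_default_na=False)
    if table.shape[1] != 2:
        raise ParseError(f"{path}: labels file must have exactly two columns")
    sample_ids = table.iloc[:, 0]
    if sample_ids.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample id in labels file")
    mapping = {diseased: DISEASED, control: CONTROL}
    try:
        values = [mapping[v] for v in table.iloc[:, 1]]
    except KeyError as exc:
        raise ParseError(
            f"{path}: unknown class label {exc.args[0]!r} "
            f"(expected {diseased!r} or {control!r})"
        ) from exc
    return pd.Series(values, index=list(sample_ids), name="label")


def write_expression(ds: ExpressionDataset, path, sep: str = "\t") -> None:
    ds.values.to_csv(path, sep=sep)


def write_labels(ds: ExpressionDataset, path, sep: str = "\t") -> None:
    ds.labels.to_csv(path, sep=sep, header=False)


# ---------------------------------------------------------------------------
# probe collapse and collection restriction


def collapse_probes(values: pd.DataFrame, probe_to_gene: dict[str, str],
                    labels: pd.Series) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene by largest fold change.

    For a gene measured by several probes, the probe whose absolute
    between-group difference of means (log-scale fold change) is largest is
    kept; ties go to the lexicographically smallest probe id. Probes not in
    the mapping are dropped; a gene with no mapped probe is simply absent.
    """
    if not probe_to_gene:
        raise ValidationError("empty probe-to-gene mapping")
    lab = labels.reindex(values.columns)
    if lab.isna().any():
        raise ValidationError("every sample needs a label for fold-change collapse")
    y = lab.to_numpy()
    mat = values.to_numpy(dtype=float)
    mean_d = mat[:, y == DISEASED].mean(axis=1)
    mean_c = mat[:, y == CONTROL].mean(axis=1)
    fold = np.abs(mean_d - mean_c)

    best: dict[str, tuple[float, str]] = {}  # gene -> (fold, probe)
    for probe, fc in zip(values.index, fold):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        # larger fold change wins; on an exact tie the smaller probe id wins
        if cur is None or fc > cur[0] or (fc == cur[0] and probe < cur[1]):
            best[gene] = (fc, probe)

    genes = sorted(best)
    probes = [best[g][1] for g in genes]
    collapsed = values.loc[probes].copy()
    collapsed.index = pd.Index(genes, name="gene_id")
    return ExpressionDataset(collapsed, labels)


def restrict_collection(coll: GeneSetCollection, ds: ExpressionDataset,
                        min_size: int = 2) -> GeneSetCollection:
    """Intersect each set with the dataset's genes; drop sets below ``min_size``.

    A 1-gene set degenerates the set statistic to a single squared SAM
    statistic, hence the default floor of 2. The input collection is
    unmodified.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = set(ds.values.index)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name, members in coll.sets.items():
        surviving = [g for g in members if g in universe]
        if len(surviving) >= min_size:
            sets[name] = surviving
            descriptions[name] = coll.descriptions.get(name, "")
    return replace(coll, sets=sets, descriptions=descriptions)
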