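"""Data model and I/O for expression matrices and sample/group annotations.

The pipeline operates on a genes x samples matrix of normalized log2
expression intensities (RMA scale) together with an annotation that maps
each sample to a group and assigns each group a role in the analysis:

* ``subtype`` -- a tumor subtype; differential-expression testing and the
  differentiation ranking are restricted to these groups.
* ``root_outgroup`` -- a primitive cell type (e.g. embryonic or
  tissue-specific stem cells) used to root the tree.
* ``differentiated_reference`` -- a fully mature tissue profile defining
  the far end of the differentiation path.
* ``auxiliary`` -- any other group carried along as a tree leaf (e.g.
  progenitor populations of known maturity).

The tool performs no normalization: input is assumed to be already on the
log2 scale, and missing values are rejected rather than imputed, since
silent imputation would change the distances downstream.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "AnnotationError",
    "ExpressionMatrix",
    "GroupAnnotation",
    "GroupMeanMatrix",
    "TableFormatError",
    "compute_group_means",
    "read_annotation",
    "read_expression_table",
]

SUBTYPE = "subtype"
ROOT_OUTGROUP = "root_outgroup"
DIFFERENTIATED_REFERENCE = "differentiated_reference"
AUXILIARY = "auxiliary"
ROLES = frozenset({SUBTYPE, ROOT_OUTGROUP, DIFFERENTIATED_REFERENCE, AUXILIARY})


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


class AnnotationError(ValueError):
    """Raised when the sample/group annotation is inconsistent."""


def _check_unique(ids, kind: str) -> None:
    seen = Counter(ids)
    dups = [k for k, c in seen.items() if c > 1]
    if dups:
        raise TableFormatError(f"duplicate {kind} id(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities.

    Wraps a :class:`pandas.DataFrame` (index = gene ids, columns = sample
    ids) and enforces uniqueness of identifiers and finiteness of all
    values.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "gene")
        _check_unique(self.frame.columns, "sample")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise TableFormatError(
                f"non-finite value at gene {self.frame.index[r]!r}, "
                f"sample {self.frame.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.frame.index]
        if missing:
            raise KeyError(f"unknown gene id(s): {', '.join(map(str, missing[:5]))}")
        return ExpressionMatrix(self.frame.loc[list(genes)])

    def write(self, path) -> None:
        """Write as tab-delimited text (full float precision, round-trips exactly)."""
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_table(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples TSV: first row sample ids, first column gene ids.

    Raises :class:`TableFormatError` naming the offending identifier or cell
    on duplicate ids and non-numeric/empty cells.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    samples = header[1:]
    if not samples:
        raise TableFormatError(f"{path}: no sample columns found")
    _check_unique(samples, "sample")
    raw = pd.read_csv(path, sep=sep, skiprows=1, header=None, index_col=0, dtype=str)
    if raw.shape[1] != len(samples):
        raise TableFormatError(
            f"{path}: {raw.shape[1]} data columns but {len(samples)} sample ids"
        )
    raw.columns = samples
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "gene")
    try:
        # numpy's str->float conversion is correctly rounded (exact round-trip)
        numeric = raw.astype(float)
    except (ValueError, TypeError):
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna().to_numpy()
        r, c = np.argwhere(bad)[0]
        cell = raw.iat[r, c]
        shown = "empty cell" if pd.isna(cell) else f"value {cell!r}"
        raise TableFormatError(
            f"non-numeric {shown} at gene {raw.index[r]!r}, sample {samples[c]!r} "
            f"(row {r + 2}, column {c + 2})"
        ) from None
    if numeric.isna().to_numpy().any():
        bad = numeric.isna().to_numpy()
        r, c = np.argwhere(bad)[0]
        raise TableFormatError(
            f"non-numeric empty cell at gene {raw.index[r]!r}, sample "
            f"{samples[c]!r} (row {r + 2}, column {c + 2})"
        )
    return ExpressionMatrix(numeric)


@dataclass
class GroupAnnotation:
    """Sample -> group map plus a role for every group.

    ``groups`` follow first-appearance order of the samples, which fixes the
    column order of all downstream outputs.
    """

    sample_to_group: dict[str, str]
    group_role: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self._appearance_order():
            self.group_role.setdefault(g, SUBTYPE)
        unknown = set(self.group_role.values()) - ROLES
        if unknown:
            raise AnnotationError(
                f"unknown role(s) {sorted(unknown)}; valid roles: {sorted(ROLES)}"
            )

    def _appearance_order(self) -> list[str]:
        return list(dict.fromkeys(self.sample_to_group.values()))

    @property
    def groups(self) -> list[str]:
        return self._appearance_order()

    @property
    def subtypes(self) -> list[str]:
        return [g for g in self.groups if self.group_role[g] == SUBTYPE]

    @property
    def group_sizes(self) -> dict[str, int]:
        return dict(Counter(self.sample_to_group.values()))

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    def _unique_role(self, role: str) -> str | None:
        labels = [g for g in self.groups if self.group_role[g] == role]
        if len(labels) > 1:
            raise AnnotationError(
                f"at most one group may have role {role!r}; got {labels}"
            )
        return labels[0] if labels else None

    @property
    def root_outgroup(self) -> str | None:
        return self._unique_role(ROOT_OUTGROUP)

    @property
    def differentiated_reference(self) -> str | None:
        return self._unique_role(DIFFERENTIATED_REFERENCE)

    def validate_against(self, x: ExpressionMatrix) -> None:
        """Check that every annotated sample exists in the expression matrix."""
        known = set(x.sample_ids)
        missing = [s for s in self.sample_to_group if s not in known]
        if missing:
            raise AnnotationError(
                f"annotated sample(s) absent from matrix: {', '.join(missing[:5])}"
            )

    def require_subtypes(self, minimum: int = 2) -> list[str]:
        st = self.subtypes
        if len(st) < minimum:
            raise AnnotationError(
                f"need at least {minimum} subtype groups, got {len(st)}"
            )
        return st

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for s, g in self.sample_to_group.items():
                fh.write(f"{s}\t{g}\t{self.group_role[g]}\n")


def read_annotation(path, sep: str = "\t") -> GroupAnnotation:
    """Read a headerless TSV of ``sample_id<TAB>group[<TAB>role]`` rows.

    The role column is optional and defaults to ``subtype``.
    """
    sample_to_group: dict[str, str] = {}
    group_role: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) not in (2, 3):
                raise AnnotationError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            sample, group = parts[0].strip(), parts[1].strip()
            role = parts[2].strip() if len(parts) == 3 and parts[2].strip() else SUBTYPE
            if role not in ROLES:
                raise AnnotationError(
                    f"{path}:{lineno}: unknown role {role!r}; valid: {sorted(ROLES)}"
                )
            if sample in sample_to_group and sample_to_group[sample] != group:
                raise AnnotationError(
                    f"{path}:{lineno}: sample {sample!r} annotated with both "
                    f"{sample_to_group[sample]!r} and {group!r}"
                )
            if group in group_role and group_role[group] != role:
                raise AnnotationError(
                    f"{path}:{lineno}: group {group!r} annotated with both roles "
                    f"{group_role[group]!r} and {role!r}"
                )
            sample_to_group[sample] = group
            group_role[group] = role
    return GroupAnnotation(sample_to_group, group_role)


@dataclass
class GroupMeanMatrix:
    """Per-gene arithmetic mean of log2 intensity within each group."""

    frame: pd.DataFrame  # genes x groups

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def group_column_order(a: GroupAnnotation) -> list[str]:
    """Deterministic group order: subtypes first (annotation order), then the rest."""
    subtypes = a.subtypes
    rest = [g for g in a.groups if g not in subtypes]
    return subtypes + rest


def compute_group_means(
    x: ExpressionMatrix,
    a: GroupAnnotation,
    genes=None,
) -> GroupMeanMatrix:
    """Average each gene's expression across the samples of each group.

    ``genes`` optionally restricts the rows (order preserved as given).
    Groups whose samples are absent from the matrix raise ``AnnotationError``.
    """
    a.validate_against(x)
    frame = x.frame if genes is None else x.subset_genes(genes).frame
    cols = {}
    for group in group_column_order(a):
        samples = a.samples_of(group)
        if not samples:
            raise AnnotationError(f"group {group!r} has no samples")
        cols[group] = frame[samples].to_numpy().mean(axis=1)
    out = pd.DataFrame(cols, index=frame.index)
    if out.empty:
        warnings.warn("group mean matrix is empty (no genes selected)")
    return GroupMeanMatrix(out)
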