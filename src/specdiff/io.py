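"""Reading and writing of on-disk artifacts.

All tabular artifacts are UTF-8, tab-delimited, with "." as the decimal
separator.  Count matrices are stored proteins-as-rows, samples-as-columns.
A missing protein in a sample is encoded as count 0; there is no distinct
"NA" state because spectral counting conflates "absent" and "undetected".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "StudyDesign",
    "AnnotationCollection",
    "DataFormatError",
    "IdentifierError",
    "DesignError",
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_differential_table",
    "read_differential_table",
    "write_signature",
    "read_signature",
    "write_enrichment_table",
    "save_model",
    "load_model",
]


class DataFormatError(ValueError):
    """Malformed on-disk artifact (ragged rows, bad header, empty file)."""


class IdentifierError(ValueError):
    """Duplicate or empty identifiers on either axis."""


class DesignError(ValueError):
    """Invalid sample-to-group assignment."""


@dataclass(frozen=True)
class CountMatrix:
    """Protein x sample matrix of non-negative integer spectral counts."""

    protein_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise DataFormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        for axis_name, ids in (("protein", self.protein_ids), ("sample", self.sample_ids)):
            if any(not i for i in ids):
                raise IdentifierError(f"empty {axis_name} identifier")
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if list(ids).count(i) > 1})
                raise IdentifierError(f"duplicate {axis_name} identifiers: {dupes}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or not np.all(counts == np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))
                raise ValueError(f"non-integer cell at (row, col) {bad[0].tolist()}")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at protein {self.protein_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.protein_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(
            protein_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )

    def subset_proteins(self, keep: np.ndarray | list) -> "CountMatrix":
        """Return a new matrix restricted to the given protein rows.

        ``keep`` is either a boolean mask or a list of protein identifiers;
        original row order is preserved.
        """
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([p in wanted for p in self.protein_ids])
        return CountMatrix(
            protein_ids=tuple(p for p, m in zip(self.protein_ids, mask) if m),
            sample_ids=self.sample_ids,
            counts=self.counts[mask],
        )


@dataclass(frozen=True)
class StudyDesign:
    """Sample-to-group assignment for a two-group comparison."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        sizes = self.group_sizes()
        if not sizes:
            raise DesignError("design contains no samples")
        small = {g: n for g, n in sizes.items() if n < 2}
        if small:
            raise DesignError(f"every group needs >= 2 samples; too small: {small}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return tuple(seen)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.assignments.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def require_two_groups(self) -> tuple[str, str]:
        groups = self.groups
        if len(groups) != 2:
            raise DesignError(f"exactly two groups required, found {len(groups)}: {groups}")
        return groups  # type: ignore[return-value]

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignments.items() if g == group)

    def mask(self, group: str, sample_ids: tuple[str, ...]) -> np.ndarray:
        """Boolean mask over ``sample_ids`` of membership in ``group``."""
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")
        return np.array([self.assignments[s] == group for s in sample_ids])

    def check_matches(self, matrix: CountMatrix) -> None:
        """Raise if the design does not cover the matrix samples exactly."""
        design_set = set(self.assignments)
        matrix_set = set(matrix.sample_ids)
        if design_set != matrix_set:
            missing = sorted(matrix_set - design_set)
            extra = sorted(design_set - matrix_set)
            raise DesignError(
                f"design/matrix sample mismatch: missing {missing}, extra {extra}"
            )


@dataclass(frozen=True)
class AnnotationCollection:
    """Named protein categories (GMT-style annotation sets)."""

    categories: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = {str(k): frozenset(v) for k, v in self.categories.items()}
        empty = [k for k, v in cats.items() if not v]
        if empty:
            raise ValueError(f"empty category member sets: {empty}")
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "descriptions", dict(self.descriptions))

    def __len__(self) -> int:
        return len(self.categories)

    def restrict(self, universe: set[str]) -> "AnnotationCollection":
        """Intersect every category with ``universe``; drop emptied ones."""
        kept = {
            name: members & universe
            for name, members in self.categories.items()
            if members & universe
        }
        return AnnotationCollection(
            categories=kept,
            descriptions={k: v for k, v in self.descriptions.items() if k in kept},
        )


def read_count_matrix(path: str | Path, sep: str = "\t") -> CountMatrix:
    """Read a TSV count matrix (header row of sample ids, first column protein ids)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    if frame.shape[1] == 0:
        raise DataFormatError(f"{path}: no sample columns")
    if frame.isna().any().any():
        row, col = next(zip(*np.where(frame.isna().to_numpy())))
        raise ValueError(
            f"{path}: missing/ragged cell at protein {frame.index[row]!r}, "
            f"sample {frame.columns[col]!r}"
        )
    try:
        counts = frame.astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer cell: {exc}") from exc
    if np.any(counts < 0):
        r, c = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"{path}: negative count at protein {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    matrix = CountMatrix(
        protein_ids=tuple(str(i) for i in frame.index),
        sample_ids=tuple(str(c) for c in frame.columns),
        counts=counts,
    )
    logger.info("read count matrix %s: %d proteins x %d samples", path, *matrix.shape)
    return matrix


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="protein")


def read_design(path: str | Path) -> StudyDesign:
    """Read a two-column (sample_id, group) TSV, with or without a header."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    if frame.shape[1] != 2:
        raise DataFormatError(f"{path}: expected 2 columns, found {frame.shape[1]}")
    if list(frame.iloc[0]) == ["sample", "group"]:
        frame = frame.iloc[1:]
    samples = frame.iloc[:, 0].tolist()
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise DesignError(f"{path}: duplicate sample ids: {dupes}")
    design = StudyDesign(assignments=dict(zip(samples, frame.iloc[:, 1])))
    logger.info("read design %s: group sizes %s", path, design.group_sizes())
    return design


def write_design(design: StudyDesign, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.assignments.items():
            fh.write(f"{sample}\t{group}\n")


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: one category per line, name TAB description TAB members..."""
    path = Path(path)
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: skipping category with no members", path, lineno)
                continue
            name, description = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                logger.warning("%s:%d: skipping empty category %r", path, lineno, name)
                continue
            if name in categories:
                raise IdentifierError(f"{path}:{lineno}: duplicate category {name!r}")
            categories[name] = members
            descriptions[name] = description
    if not categories:
        raise DataFormatError(f"{path}: no usable categories")
    return AnnotationCollection(categories=categories, descriptions=descriptions)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in collection.categories.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


_DIFF_COLUMNS = [
    "protein", "si", "r_A", "r_B", "f_A", "f_B", "p", "significant", "direction",
]


def write_differential_table(result, path: str | Path) -> None:
    """Write per-protein differential records (full float precision)."""
    frame = result.to_frame()
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.17g")


def read_differential_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = [c for c in _DIFF_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    return frame


def write_signature(signature, path: str | Path) -> None:
    payload = {
        "proteins": list(signature.proteins),
        "scores": [float(s) for s in signature.scores],
        "directions": [int(d) for d in signature.directions],
        "positive_label": signature.positive_label,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_signature(path: str | Path):
    from .classifier import Signature  # local import: avoid cycle

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return Signature(
        proteins=tuple(payload["proteins"]),
        scores=tuple(payload["scores"]),
        directions=tuple(payload["directions"]),
        positive_label=payload["positive_label"],
    )


def write_enrichment_table(records, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "category": r.category,
                "overlap": r.overlap,
                "category_size": r.category_size,
                "list_size": r.list_size,
                "background_size": r.background_size,
                "p": r.p_empirical,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in records
        ]
    )
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.17g")


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted shrunken-centroid model to JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n", encoding="utf-8")


def load_model(path: str | Path):
    from .classifier import ShrunkenCentroidModel  # local import: avoid cycle

    return ShrunkenCentroidModel.from_dict(
        json.loads(Path(path).read_text(encoding="utf-8"))
    )
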