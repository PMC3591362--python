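"""Presence filtering and spectral-index differential expression.

The spectral index (SI) for a protein compares two groups A and B:

    m_A = mean count in A, m_B = mean count in B
    r_A = m_A / (m_A + m_B), r_B = 1 - r_A       (0 if both means are 0)
    f_A = fraction of A samples with count > 0, f_B likewise
    SI  = r_A * f_A - r_B * f_B

SI lies in [-1, +1]: +1 exactly when detection is universal in A and absent
from B, -1 in the mirrored case, and 0 for identical balanced counts.
Group means (not sums) are used so unequal group sizes do not bias SI.
No per-sample depth normalization is applied by default.

Significance comes from a label-permutation null (default 10,000
permutations, 95% confidence).  The default "global" mode pools all permuted
SI values into a single null distribution and derives one two-sided
empirical-quantile band for the whole comparison; "per_protein" keeps one
null (and one band) per protein.  Empirical p-values use the add-one
estimator; quantiles use linear (type-7) interpolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .io import CountMatrix, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "SIRecord",
    "DifferentialResult",
    "apply_presence_filter",
    "compute_spectral_index",
    "spectral_index_matrix",
    "build_permutation_null",
    "call_differential",
]

Direction = Literal["up_in_A", "up_in_B", "none"]
Mode = Literal["global", "per_protein"]


@dataclass(frozen=True)
class SIRecord:
    protein_id: str
    si: float
    r_A: float
    r_B: float
    f_A: float
    f_B: float
    p_empirical: float
    significant: bool
    direction: Direction


@dataclass(frozen=True)
class DifferentialResult:
    """Per-protein SI records plus the permutation-null provenance."""

    records: tuple[SIRecord, ...]
    null_band: tuple[float, float]
    n_permutations: int
    confidence: float
    mode: Mode
    seed: int | None
    group_A: str
    group_B: str
    exhaustive: bool = False
    per_protein_bands: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.records)

    def significant_proteins(self) -> tuple[str, ...]:
        return tuple(r.protein_id for r in self.records if r.significant)

    def direction_counts(self) -> dict[str, int]:
        counts = {"up_in_A": 0, "up_in_B": 0}
        for r in self.records:
            if r.direction in counts:
                counts[r.direction] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [r.protein_id for r in self.records],
                "si": [r.si for r in self.records],
                "r_A": [r.r_A for r in self.records],
                "r_B": [r.r_B for r in self.records],
                "f_A": [r.f_A for r in self.records],
                "f_B": [r.f_B for r in self.records],
                "p": [r.p_empirical for r in self.records],
                "significant": [r.significant for r in self.records],
                "direction": [r.direction for r in self.records],
            }
        )


def apply_presence_filter(matrix: CountMatrix, design: StudyDesign) -> CountMatrix:
    """Retain proteins detected in at least half the subjects of one group.

    "At least half" with odd group sizes means ceil(n/2).  Protein order is
    preserved.  An empty result is returned (with a warning), not raised.
    """
    design.check_matches(matrix)
    detected = matrix.counts > 0
    keep = np.zeros(matrix.shape[0], dtype=bool)
    for group in design.groups:
        mask = design.mask(group, matrix.sample_ids)
        threshold = math.ceil(int(mask.sum()) / 2)
        keep |= detected[:, mask].sum(axis=1) >= threshold
    filtered = matrix.subset_proteins(keep)
    logger.info(
        "presence filter: %d of %d proteins retained", filtered.shape[0], matrix.shape[0]
    )
    if filtered.shape[0] == 0:
        logger.warning("presence filter removed every protein")
    return filtered


def compute_spectral_index(
    counts_A: np.ndarray | list, counts_B: np.ndarray | list
) -> tuple[float, float, float, float, float]:
    """Spectral index for one protein; returns (si, r_A, r_B, f_A, f_B)."""
    a = np.asarray(counts_A, dtype=float)
    b = np.asarray(counts_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both count vectors must be non-empty")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative counts are not allowed")
    m_a, m_b = a.mean(), b.mean()
    total = m_a + m_b
    if total == 0:
        r_a = r_b = 0.0
    else:
        r_a = m_a / total
        r_b = 1.0 - r_a
    f_a = float(np.count_nonzero(a)) / a.size
    f_b = float(np.count_nonzero(b)) / b.size
    si = r_a * f_a - r_b * f_b
    return float(si), float(r_a), float(r_b), float(f_a), float(f_b)


def spectral_index_matrix(
    counts: np.ndarray, mask_A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized SI over all rows of ``counts`` for one A/B column split."""
    a = counts[:, mask_A]
    b = counts[:, ~mask_A]
    m_a = a.mean(axis=1)
    m_b = b.mean(axis=1)
    total = m_a + m_b
    with np.errstate(invalid="ignore", divide="ignore"):
        r_a = np.where(total > 0, m_a / np.where(total > 0, total, 1.0), 0.0)
    r_b = np.where(total > 0, 1.0 - r_a, 0.0)
    f_a = (a > 0).mean(axis=1)
    f_b = (b > 0).mean(axis=1)
    return r_a * f_a - r_b * f_b, r_a, r_b, f_a, f_b


def _iter_label_masks(
    n_samples: int, n_A: int, n_perm: int, rng: np.random.Generator
) -> tuple[Iterator[np.ndarray], int, bool]:
    """Permuted group-A masks; exhaustive when the assignment space is small."""
    n_assignments = math.comb(n_samples, n_A)
    if n_perm >= n_assignments:
        logger.info(
            "n_perm=%d >= %d distinct assignments: using exhaustive enumeration",
            n_perm,
            n_assignments,
        )

        def exhaustive() -> Iterator[np.ndarray]:
            for combo in combinations(range(n_samples), n_A):
                mask = np.zeros(n_samples, dtype=bool)
                mask[list(combo)] = True
                yield mask

        return exhaustive(), n_assignments, True

    def sampled() -> Iterator[np.ndarray]:
        for _ in range(n_perm):
            mask = np.zeros(n_samples, dtype=bool)
            mask[rng.choice(n_samples, size=n_A, replace=False)] = True
            yield mask

    return sampled(), n_perm, False


def build_permutation_null(
    matrix: CountMatrix,
    design: StudyDesign,
    n_perm: int = 10_000,
    confidence: float = 0.95,
    mode: Mode = "global",
    seed: int | None = None,
) -> DifferentialResult:
    """Permutation null for the SI statistic over an already-filtered matrix.

    Labels are reassigned uniformly at random preserving group sizes; SI is
    recomputed for every protein in every permutation.  If ``n_perm`` is at
    least the number of distinct label assignments the null is enumerated
    exhaustively instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < confidence <= 1.0:
        raise ValueError("confidence must be in (0, 1]")
    if mode not in ("global", "per_protein"):
        raise ValueError(f"unknown mode {mode!r}")
    design.check_matches(matrix)
    group_A, group_B = design.require_two_groups()
    mask_A = design.mask(group_A, matrix.sample_ids)
    n_A = int(mask_A.sum())

    counts = matrix.counts.astype(float)
    si, r_a, r_b, f_a, f_b = spectral_index_matrix(counts, mask_A)

    rng = np.random.default_rng(seed)
    masks, n_used, exhaustive = _iter_label_masks(
        len(matrix.sample_ids), n_A, n_perm, rng
    )
    null = np.empty((n_used, matrix.shape[0]))
    for i, perm_mask in enumerate(masks):
        null[i] = spectral_index_matrix(counts, perm_mask)[0]

    alpha = 1.0 - confidence
    pooled = null.ravel()
    global_band = (
        float(np.quantile(pooled, alpha / 2)),
        float(np.quantile(pooled, 1.0 - alpha / 2)),
    )
    per_protein_bands: np.ndarray | None = None
    if mode == "global":
        significant = (si < global_band[0]) | (si > global_band[1])
        abs_null_sorted = np.sort(np.abs(pooled))
        n_null = abs_null_sorted.size
        # tolerance so ties are counted despite float roundoff in SI
        exceed = n_null - np.searchsorted(
            abs_null_sorted, np.abs(si) - 1e-12, side="left"
        )
        p = (1.0 + exceed) / (n_null + 1.0)
    else:
        lower = np.quantile(null, alpha / 2, axis=0)
        upper = np.quantile(null, 1.0 - alpha / 2, axis=0)
        per_protein_bands = np.column_stack([lower, upper])
        significant = (si < lower) | (si > upper)
        abs_null = np.sort(np.abs(null), axis=0)
        exceed = null.shape[0] - np.array(
            [
                np.searchsorted(abs_null[:, j], abs(si[j]) - 1e-12, side="left")
                for j in range(null.shape[1])
            ]
        )
        p = (1.0 + exceed) / (null.shape[0] + 1.0)

    direction = np.where(
        significant & (si > 0), "up_in_A", np.where(significant & (si < 0), "up_in_B", "none")
    )
    records = tuple(
        SIRecord(
            protein_id=pid,
            si=float(si[j]),
            r_A=float(r_a[j]),
            r_B=float(r_b[j]),
            f_A=float(f_a[j]),
            f_B=float(f_b[j]),
            p_empirical=float(p[j]),
            significant=bool(significant[j]),
            direction=str(direction[j]),  # type: ignore[arg-type]
        )
        for j, pid in enumerate(matrix.protein_ids)
    )
    return DifferentialResult(
        records=records,
        null_band=global_band,
        n_permutations=n_used,
        confidence=confidence,
        mode=mode,
        seed=seed,
        group_A=group_A,
        group_B=group_B,
        exhaustive=exhaustive,
        per_protein_bands=per_protein_bands,
    )


def call_differential(
    matrix: CountMatrix,
    design: StudyDesign,
    n_perm: int = 10_000,
    confidence: float = 0.95,
    mode: Mode = "global",
    seed: int | None = None,
) -> DifferentialResult:
    """Full differential call on a presence-filtered matrix.

    Records are sorted by |SI| descending; summary counts are logged.
    """
    result = build_permutation_null(
        matrix, design, n_perm=n_perm, confidence=confidence, mode=mode, seed=seed
    )
    order = sorted(
        range(len(result.records)),
        key=lambda j: (-abs(result.records[j].si), result.records[j].protein_id),
    )
    ordered = tuple(result.records[j] for j in order)
    bands = result.per_protein_bands
    if bands is not None:
        bands = bands[order]
    result = DifferentialResult(
        records=ordered,
        null_band=result.null_band,
        n_permutations=result.n_permutations,
        confidence=result.confidence,
        mode=result.mode,
        seed=result.seed,
        group_A=result.group_A,
        group_B=result.group_B,
        exhaustive=result.exhaustive,
        per_protein_bands=bands,
    )
    tallies = result.direction_counts()
    logger.info(
        "differential: %d tested, %d significant (up in %s: %d, up in %s: %d)",
        len(result.records),
        result.n_significant,
        result.group_A,
        tallies["up_in_A"],
        result.group_B,
        tallies["up_in_B"],
    )
    return result
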