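"""Over-representation analysis with a permutation-based FDR.

Each category's observed overlap with the hit list is compared against a
null built by repeatedly drawing |hits| proteins from the background
without replacement.  Empirical p-values use the add-one estimator and are
converted to FDR by Benjamini-Hochberg; a category is significant when it
overlaps the hits in at least 3 members and its FDR is below 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import AnnotationCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "test_enrichment"]

MIN_MEMBERS = 3
FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentRecord:
    category: str
    overlap: int
    category_size: int
    list_size: int
    background_size: int
    p_empirical: float
    fdr: float
    significant: bool


def test_enrichment(
    hits: set[str],
    background: set[str],
    annotations: AnnotationCollection,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[EnrichmentRecord]:
    """Permutation over-representation test of ``hits`` against ``annotations``.

    ``hits`` must be a subset of ``background``; categories are intersected
    with the background before testing.  Records are returned sorted by
    ascending p-value then category name.
    """
    hits = set(hits)
    background = set(background)
    stray = hits - background
    if stray:
        raise ValueError(f"hits not contained in background: {sorted(stray)[:5]}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    restricted = annotations.restrict(background)
    if not restricted.categories:
        logger.warning("no annotation category overlaps the background")
        return []

    bg_list = sorted(background)
    bg_index = {p: i for i, p in enumerate(bg_list)}
    n_bg = len(bg_list)
    n_hits = len(hits)

    names = sorted(restricted.categories)
    membership = np.zeros((len(names), n_bg), dtype=bool)
    for row, name in enumerate(names):
        for member in restricted.categories[name]:
            membership[row, bg_index[member]] = True

    hit_mask = np.zeros(n_bg, dtype=bool)
    for h in hits:
        hit_mask[bg_index[h]] = True
    observed = membership[:, hit_mask].sum(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=np.int64)
    for _ in range(n_perm):
        draw = rng.choice(n_bg, size=n_hits, replace=False)
        exceed += membership[:, draw].sum(axis=1) >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    records = [
        EnrichmentRecord(
            category=name,
            overlap=int(observed[i]),
            category_size=len(restricted.categories[name]),
            list_size=n_hits,
            background_size=n_bg,
            p_empirical=float(p[i]),
            fdr=float(fdr[i]),
            significant=bool(observed[i] >= MIN_MEMBERS and fdr[i] < FDR_THRESHOLD),
        )
        for i, name in enumerate(names)
    ]
    records.sort(key=lambda r: (r.p_empirical, r.category))
    n_sig = sum(r.significant for r in records)
    logger.info("enrichment: %d of %d categories significant", n_sig, len(records))
    return records


test_enrichment.__test__ = False  # type: ignore[attr-defined]  # not a pytest item
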