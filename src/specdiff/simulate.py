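"""Synthetic spectral-count datasets with known ground truth.

Counts are generated as overdispersed (negative-binomial) draws around
protein baselines and per-sample depth factors, with independent dropout
zeroing so presence/absence structure can be planted alongside abundance
shifts.  Differential proteins come in two archetypes:

* ``abundance``: the up group's mean is multiplied by 2^(lfc/2) and the
  down group's by 2^(-lfc/2), so the group mean ratio is 2^lfc.
* ``presence``: the up group's mean is multiplied by 2^(lfc/2); the down
  group keeps the baseline mean per detected cell but each of its cells is
  structurally zeroed with probability 1 - 2^(-lfc/2), so the group mean
  ratio is again 2^lfc while the detection fraction drops.

Defaults mirror a two-group cohort of 14 + 16 samples with 394 proteins of
which 60 are up in group A and 15 up in group B.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, StudyDesign

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_counts", "generate_null_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 394
    n_group_A: int = 14
    n_group_B: int = 16
    group_labels: tuple[str, str] = ("A", "B")
    n_up_A: int = 60
    n_up_B: int = 15
    log2_fold_change: float = 2.0
    presence_fraction: float = 0.5  # fraction of differential proteins of the presence archetype
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    dispersion: float = 1.0  # negative-binomial size; var = m + m^2/size
    dropout: float = 0.05  # independent per-cell zeroing probability
    depth_log2_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_group_A < 2 or self.n_group_B < 2:
            raise ValueError("each group needs >= 2 samples")
        if self.n_up_A < 0 or self.n_up_B < 0:
            raise ValueError("differential counts must be non-negative")
        if self.n_up_A + self.n_up_B > self.n_proteins:
            raise ValueError("n_up_A + n_up_B exceeds n_proteins")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if not 0.0 <= self.presence_fraction <= 1.0:
            raise ValueError("presence_fraction must be in [0, 1]")
        if self.log2_fold_change < 0:
            raise ValueError("log2_fold_change must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_log2_sd < 0 or self.depth_log2_sd < 0:
            raise ValueError("SD parameters must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-protein ground truth for a generated dataset."""

    protein_ids: tuple[str, ...]
    is_differential: np.ndarray  # bool
    direction: tuple[str, ...]  # up_in_A / up_in_B / none
    log2_fold_change: np.ndarray
    archetype: tuple[str, ...] = field(default=())  # abundance / presence / none

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": list(self.protein_ids),
                "is_differential": self.is_differential,
                "direction": list(self.direction),
                "log2_fold_change": self.log2_fold_change,
                "archetype": list(self.archetype),
            }
        )


def generate_counts(
    config: SyntheticConfig,
) -> tuple[CountMatrix, StudyDesign, SyntheticTruth]:
    """Generate a (CountMatrix, StudyDesign, SyntheticTruth) triple.

    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_p = config.n_proteins
    n_a, n_b = config.n_group_A, config.n_group_B
    n = n_a + n_b
    label_a, label_b = config.group_labels

    protein_ids = tuple(f"P{i + 1:04d}" for i in range(n_p))
    sample_ids = tuple(
        [f"{label_a}{i + 1:02d}" for i in range(n_a)]
        + [f"{label_b}{i + 1:02d}" for i in range(n_b)]
    )
    design = StudyDesign(
        assignments={
            **{s: label_a for s in sample_ids[:n_a]},
            **{s: label_b for s in sample_ids[n_a:]},
        }
    )

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_p)
    depth = 2.0 ** rng.normal(0.0, config.depth_log2_sd, n)

    direction = ["none"] * n_p
    archetype = ["none"] * n_p
    lfc = np.zeros(n_p)
    diff_idx = rng.choice(n_p, size=config.n_up_A + config.n_up_B, replace=False)
    up_a_idx = diff_idx[: config.n_up_A]
    up_b_idx = diff_idx[config.n_up_A :]
    n_diff = diff_idx.size
    n_presence = int(round(config.presence_fraction * n_diff))
    presence_flags = np.zeros(n_diff, dtype=bool)
    if n_diff:
        presence_flags[rng.choice(n_diff, size=n_presence, replace=False)] = True
    for pos, idx in enumerate(diff_idx):
        direction[idx] = "up_in_A" if pos < config.n_up_A else "up_in_B"
        archetype[idx] = "presence" if presence_flags[pos] else "abundance"
        lfc[idx] = config.log2_fold_change

    half_fc = 2.0 ** (config.log2_fold_change / 2.0)
    mask_a = np.array([design.assignments[s] == label_a for s in sample_ids])
    effect = np.ones((n_p, n))  # multiplicative group effect on the mean
    structural_keep = np.ones((n_p, n), dtype=bool)
    for idx in up_a_idx:
        effect[idx, mask_a] *= half_fc
        if archetype[idx] == "presence":
            structural_keep[idx, ~mask_a] = rng.random(n_b) < 1.0 / half_fc
        else:
            effect[idx, ~mask_a] /= half_fc
    for idx in up_b_idx:
        effect[idx, ~mask_a] *= half_fc
        if archetype[idx] == "presence":
            structural_keep[idx, mask_a] = rng.random(n_a) < 1.0 / half_fc
        else:
            effect[idx, mask_a] /= half_fc

    mean = baseline[:, None] * depth[None, :] * effect
    size = config.dispersion
    prob = size / (size + mean)
    counts = rng.negative_binomial(size, prob)
    counts = np.where(structural_keep, counts, 0)
    if config.dropout > 0:
        counts = np.where(rng.random(counts.shape) < config.dropout, 0, counts)

    matrix = CountMatrix(protein_ids=protein_ids, sample_ids=sample_ids, counts=counts)
    truth = SyntheticTruth(
        protein_ids=protein_ids,
        is_differential=np.array([d != "none" for d in direction]),
        direction=tuple(direction),
        log2_fold_change=lfc,
        archetype=tuple(archetype),
    )
    return matrix, design, truth


def generate_null_dataset(
    config: SyntheticConfig,
) -> tuple[CountMatrix, StudyDesign, SyntheticTruth]:
    """Same generator with no differential proteins (exchangeable samples)."""
    return generate_counts(replace(config, n_up_A=0, n_up_B=0))
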