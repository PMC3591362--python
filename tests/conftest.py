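import numpy as np
import pytest

from specdiff import CountMatrix, StudyDesign, SyntheticConfig, generate_counts


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    return CountMatrix(
        protein_ids=("P1", "P2", "P3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        counts=np.array([[5, 3, 0, 0], [0, 0, 4, 6], [2, 2, 2, 2]]),
    )


@pytest.fixture
def tiny_design() -> StudyDesign:
    return StudyDesign(assignments={"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture
def study_scale_dataset():
    """394 proteins, 14 vs 16 samples, 75 planted differential proteins."""
    return generate_counts(SyntheticConfig(seed=42))


def plant_strong_panel(
    n_moderate: int = 10, seed: int = 0
) -> tuple[CountMatrix, StudyDesign, tuple[str, str, str]]:
    """Synthetic dataset with 3 overwhelming marker proteins.

    The three planted markers are abundant and universally detected in group
    A and absent from group B; ``n_moderate`` additional proteins carry a
    moderate planted shift.  Returns (matrix, design, marker ids).
    """
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(
        n_proteins=100, n_up_A=n_moderate, n_up_B=0, log2_fold_change=1.5,
        seed=int(rng.integers(2**31)),
    )
    matrix, design, truth = generate_counts(config)
    counts = matrix.counts.copy()
    mask_a = design.mask("A", matrix.sample_ids)
    null_rows = [i for i, d in enumerate(truth.direction) if d == "none"]
    markers = tuple(matrix.protein_ids[i] for i in null_rows[:3])
    for i in null_rows[:3]:
        counts[i, mask_a] = rng.integers(40, 80, size=int(mask_a.sum()))
        counts[i, ~mask_a] = 0
    return (
        CountMatrix(matrix.protein_ids, matrix.sample_ids, counts),
        design,
        markers,
    )
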