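import numpy as np
import pandas as pd
import pytest

from haplogic.cohort import PhasedCohort, Variant
from haplogic.windows import GeneWindow


def make_cohort(haps, phenotype, cohort_labels=None, start_pos=1000,
                spacing=1000):
    """Build a cohort from a (2N, M) allele matrix and per-subject phenotype."""
    haps = np.asarray(haps, dtype=np.int8)
    n = haps.shape[0] // 2
    variants = [Variant(f"rs{j}", "1", start_pos + j * spacing)
                for j in range(haps.shape[1])]
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "phenotype": np.asarray(phenotype, dtype=int),
    })
    if cohort_labels is not None:
        subjects["cohort"] = cohort_labels
    return PhasedCohort(variants, haps, subjects)


def full_window(cohort, window_id="w"):
    """A window spanning every variant of a cohort, already 'pruned'."""
    idx = np.arange(cohort.n_variants)
    return GeneWindow(window_id=window_id, gene_ids=[window_id],
                      chrom=cohort.variants[0].chrom, start=1,
                      end=cohort.variants[-1].pos + 1,
                      snp_indices_all=idx, snp_indices_pruned=idx.copy())


def random_cohort(rng, n_subjects=100, n_snps=6, maf=(0.1, 0.5),
                  case_fraction=0.5):
    """A null cohort: independent haplotypes, phenotype independent of them."""
    mafs = rng.uniform(*maf, size=n_snps)
    haps = (rng.random((2 * n_subjects, n_snps)) < mafs).astype(np.int8)
    y = (rng.random(n_subjects) < case_fraction).astype(int)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n_subjects:
        y[0] = 0
    return make_cohort(haps, y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
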