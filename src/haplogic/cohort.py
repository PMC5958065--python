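"""Core data containers for phased case-control cohorts and variant/sample QC.

A :class:`PhasedCohort` stores biallelic variants, a chromosome-by-variant
allele matrix (two rows per subject: rows ``2i`` and ``2i+1`` belong to
subject ``i``), and a subject table with case/control phenotype and a cohort
label (``discovery`` / ``replication``).  Alleles are coded 0 (reference),
1 (alternative), with -1 for missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

DISCOVERY = "discovery"
REPLICATION = "replication"
COMBINED = "combined"


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with a 1-based genomic position."""

    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")


class PhasedCohort:
    """Phased haplotypes plus phenotypes for a case-control study.

    Parameters
    ----------
    variants : list of Variant
        Ordered variant metadata (columns of ``haps``).
    haps : ndarray of int8, shape (2 * n_subjects, n_variants)
        Phased alleles per chromosome copy; entries in {0, 1, -1}.
    subjects : pandas.DataFrame
        Columns ``subject_id``, ``phenotype`` (0 control / 1 case) and
        ``cohort`` (free label, conventionally discovery/replication).
    """

    def __init__(self, variants: list[Variant], haps: np.ndarray,
                 subjects: pd.DataFrame):
        haps = np.asarray(haps, dtype=np.int8)
        if haps.ndim != 2:
            raise ValueError("haps must be 2-D (chromosomes x variants)")
        if haps.shape[0] != 2 * len(subjects):
            raise ValueError(
                f"{haps.shape[0]} chromosome rows for {len(subjects)} subjects "
                "(expected 2 per subject)")
        if haps.shape[1] != len(variants):
            raise ValueError("variant list length does not match haps columns")
        bad = ~np.isin(haps, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele matrix entries must be 0, 1 or -1 (missing)")
        subjects = subjects.reset_index(drop=True)
        for col in ("subject_id", "phenotype"):
            if col not in subjects.columns:
                raise ValueError(f"subjects table lacks column {col!r}")
        if "cohort" not in subjects.columns:
            subjects = subjects.assign(cohort=DISCOVERY)
        phen = subjects["phenotype"].to_numpy()
        if not np.isin(phen, (0, 1)).all():
            raise ValueError("phenotype must be 0 (control) or 1 (case)")
        self.variants = list(variants)
        self.haps = haps
        self.subjects = subjects

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def phenotype(self) -> np.ndarray:
        """Per-subject 0/1 phenotype vector."""
        return self.subjects["phenotype"].to_numpy(dtype=np.int8)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def genotypes(self) -> np.ndarray:
        """Subject-level allele dosages (0/1/2, -1 where either copy missing)."""
        a = self.haps[0::2]
        b = self.haps[1::2]
        g = (a + b).astype(np.int8)
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g

    def with_phenotype(self, phenotype: np.ndarray) -> "PhasedCohort":
        """Return a view-like copy with phenotypes replaced (e.g. permuted)."""
        subj = self.subjects.assign(phenotype=np.asarray(phenotype, dtype=int))
        return PhasedCohort(self.variants, self.haps, subj)

    def take_subjects(self, idx: np.ndarray) -> "PhasedCohort":
        idx = np.asarray(idx)
        rows = np.empty(2 * len(idx), dtype=np.intp)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return PhasedCohort(self.variants, self.haps[rows],
                            self.subjects.iloc[idx])

    def take_variants(self, idx: np.ndarray) -> "PhasedCohort":
        idx = np.asarray(idx)
        return PhasedCohort([self.variants[i] for i in idx],
                            self.haps[:, idx], self.subjects)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PhasedCohort {self.n_subjects} subjects x "
                f"{self.n_variants} variants>")


def split_cohort(cohort: PhasedCohort, label: str) -> PhasedCohort:
    """Subset to subjects with the given cohort label.

    ``label="combined"`` returns all subjects; unknown labels raise.
    """
    if label == COMBINED:
        return cohort
    mask = (cohort.subjects["cohort"] == label).to_numpy()
    if not mask.any():
        raise ValueError(f"no subjects with cohort label {label!r}")
    return cohort.take_subjects(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (plain, not mid-p).

    Enumerates all heterozygote counts compatible with the observed allele
    counts, conditional on allele totals, and sums the probabilities of
    configurations no more likely than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_alt + n_het
    if n_rare > n:  # orient to the rarer allele
        n_rare = 2 * n - n_rare
    het_vals = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het | n_rare, n) up to a constant: product form of the
    # conditional distribution; computed via log-gammas for stability.
    lg = math.lgamma
    logp = np.array([
        h * math.log(2) - (lg(h + 1) + lg((n_rare - h) // 2 + 1)
                           + lg(n - (n_rare + h) // 2 + 1))
        for h in het_vals
    ])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.searchsorted(het_vals, n_het)]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Bookkeeping for variant/sample QC (in = out + removals per filter)."""

    n_variants_in: int = 0
    n_variants_out: int = 0
    n_subjects_in: int = 0
    n_subjects_out: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_sample_call: int = 0
    dropped_variant_ids: list = field(default_factory=list)
    dropped_subject_ids: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"QC: variants {self.n_variants_in} -> {self.n_variants_out} "
                f"(call rate {self.removed_call_rate}, MAF {self.removed_maf}, "
                f"HWE {self.removed_hwe}); subjects {self.n_subjects_in} -> "
                f"{self.n_subjects_out} (sample call {self.removed_sample_call})")


def qc_filter(cohort: PhasedCohort, min_call: float = 0.95,
              min_maf: float = 0.05, min_hwe_p: float = 0.001,
              min_sample_call: float = 0.97) -> tuple[PhasedCohort, QcReport]:
    """Apply variant then sample QC filters.

    Variant filters run in order: call rate >= ``min_call``, MAF >=
    ``min_maf``, Hardy-Weinberg exact p >= ``min_hwe_p`` computed in
    controls from subject-level genotypes.  Samples with call rate below
    ``min_sample_call`` among retained variants are then excluded.
    """
    rep = QcReport(n_variants_in=cohort.n_variants,
                   n_subjects_in=cohort.n_subjects)
    haps = cohort.haps
    obs = haps != MISSING
    call = obs.mean(axis=0)
    keep = call >= min_call
    rep.removed_call_rate = int((~keep).sum())

    with np.errstate(invalid="ignore"):
        alt_freq = np.where(obs & keep, haps == 1, 0).sum(axis=0) / np.maximum(
            obs.sum(axis=0), 1)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    fail_maf = keep & (maf < min_maf)
    rep.removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    controls = np.flatnonzero(cohort.phenotype == 0)
    if len(controls) == 0:
        raise ValueError("HWE filter needs at least one control subject")
    gctl = cohort.take_subjects(controls).genotypes()
    fail_hwe = np.zeros_like(keep)
    for j in np.flatnonzero(keep):
        gj = gctl[:, j]
        gj = gj[gj != MISSING]
        counts = np.bincount(gj, minlength=3)
        if hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2])) < min_hwe_p:
            fail_hwe[j] = True
    rep.removed_hwe = int(fail_hwe.sum())
    keep &= ~fail_hwe

    rep.dropped_variant_ids = [v.id for v, k in zip(cohort.variants, keep) if not k]
    if not keep.any():
        rep.n_variants_out = 0
        rep.n_subjects_out = cohort.n_subjects
        raise ValueError(f"all variants removed by QC ({rep})")
    out = cohort.take_variants(np.flatnonzero(keep))
    rep.n_variants_out = out.n_variants

    # sample call rate among retained variants (chromosome entries)
    sobs = (out.haps != MISSING).reshape(out.n_subjects, 2, -1)
    scall = sobs.mean(axis=(1, 2))
    skeep = scall >= min_sample_call
    rep.removed_sample_call = int((~skeep).sum())
    rep.dropped_subject_ids = list(
        out.subjects.loc[~skeep, "subject_id"])
    out = out.take_subjects(np.flatnonzero(skeep))
    rep.n_subjects_out = out.n_subjects
    return out, rep
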