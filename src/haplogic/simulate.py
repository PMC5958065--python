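"""Synthetic phased case-control cohorts with an embedded haplotype risk tree.

The generator draws independent haplotypes SNP by SNP: each SNP's
alternative-allele frequency is uniform in a configured MAF range, and
adjacent-SNP LD is induced by a first-order copying chain — with
probability ``rho`` the allele is copied from the previous SNP on the same
haplotype, otherwise drawn fresh.  A subject is two independent haplotypes.
Disease status is generated at the subject level from the additive model

    logit P(case) = beta0 + beta1 * L,

where L in {0, 1, 2} counts the subject's haplotypes satisfying the causal
Boolean tree (L = 0 for all subjects when no causal tree is configured).
This exactly matches the inference model, so parameter recovery is a clean
check; no population-genetic realism (recombination maps, demography) is
attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DISCOVERY, REPLICATION, PhasedCohort, Variant
from .enrich import AnnotationTrack
from .tree import LogicTree
from .windows import GeneRecord


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort generator."""

    n_subjects: int = 2000
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_override: dict[int, float] | None = None  # pin selected SNPs' MAF
    rho: float = 0.2  # adjacent-SNP haplotype-copying probability
    causal_tree: LogicTree | None = None
    beta0: float = 0.0
    beta1: float = 0.0
    discovery_fraction: float = 2 / 3  # a-priori cohort split
    chrom: str = "1"
    spacing: int = 5000  # bp between adjacent SNPs
    start_pos: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.causal_tree is not None:
            if max(self.causal_tree.snps) >= self.n_snps:
                raise ValueError("causal tree SNP index out of range")


@dataclass
class TruthRecord:
    """Ground truth recorded at generation time, before any analysis."""

    causal_tree: LogicTree | None
    beta0: float
    beta1: float
    tree_frequency: float  # fraction of haplotypes satisfying the tree
    case_fraction: float
    maf: np.ndarray = field(repr=False, default=None)
    monomorphic_warning: bool = False


def simulate_phased_cohort(config: SimConfig
                           ) -> tuple[PhasedCohort, TruthRecord]:
    """Draw a phased cohort and its ground truth under ``config``."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    if config.maf_override:
        for j, f in config.maf_override.items():
            maf[j] = f
    haps = np.empty((2 * n, m), dtype=np.int8)
    haps[:, 0] = rng.random(2 * n) < maf[0]
    for j in range(1, m):
        fresh = rng.random(2 * n) < maf[j]
        copy = rng.random(2 * n) < config.rho
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)

    if config.causal_tree is not None:
        L = config.causal_tree.copy_counts(haps)
        sat = float(L.astype(float).sum()) / (2 * n)
    else:
        L = np.zeros(n, dtype=np.int8)
        sat = 0.0
    logit = config.beta0 + config.beta1 * L.astype(float)
    p = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random(n) < p).astype(int)

    n_disc = int(round(config.discovery_fraction * n))
    cohorts = np.array([DISCOVERY] * n_disc + [REPLICATION] * (n - n_disc))
    subjects = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "phenotype": y,
        "cohort": cohorts,
    })
    variants = [Variant(f"snp{j:04d}", config.chrom,
                        config.start_pos + j * config.spacing, "A", "G")
                for j in range(m)]
    cohort = PhasedCohort(variants, haps, subjects)

    mono = config.causal_tree is not None and sat in (0.0, 1.0)
    if mono:
        warnings.warn("causal tree is monomorphic in the simulated haplotypes")
    truth = TruthRecord(causal_tree=config.causal_tree, beta0=config.beta0,
                        beta1=config.beta1, tree_frequency=float(sat),
                        case_fraction=float(y.mean()), maf=maf,
                        monomorphic_warning=mono)
    return cohort, truth


def simulate_gene_table(n_genes: int, chrom_length: int,
                        gene_length_range: tuple[int, int] = (5000, 50000),
                        seed: int = 0, chrom: str = "1") -> list[GeneRecord]:
    """Random non-nested gene spans sorted by start position."""
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    if hi > chrom_length:
        raise ValueError("gene length exceeds chromosome length")
    if n_genes * lo > chrom_length:
        raise ValueError(f"cannot pack {n_genes} genes of >= {lo} bp into "
                         f"{chrom_length} bp")
    # partition the chromosome into n_genes slots; one gene per slot
    bounds = np.linspace(1, chrom_length + 1, n_genes + 1).astype(int)
    genes = []
    for i in range(n_genes):
        slot_lo, slot_hi = bounds[i], bounds[i + 1] - 1
        max_len = min(hi, slot_hi - slot_lo)
        if max_len < lo:
            raise ValueError("infeasible packing for gene length range")
        length = int(rng.integers(lo, max_len + 1))
        start = int(rng.integers(slot_lo, slot_hi - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(gene_id=f"G{i:04d}", chrom=chrom,
                                tx_start=start, tx_end=start + length - 1,
                                strand=strand))
    return genes


def simulate_tracks(snps: list[Variant], cover_set: list[Variant],
                    padding: int = 100, seed: int = 0,
                    track_id: str = "sim_track") -> AnnotationTrack:
    """A track with one padded interval per covered SNP."""
    ids = {v.id for v in snps}
    for v in cover_set:
        if v.id not in ids:
            raise ValueError(f"cover SNP {v.id} not among provided SNPs")
    intervals = [(v.chrom, max(0, v.pos - 1 - padding), v.pos + padding)
                 for v in cover_set]
    return AnnotationTrack(track_id, intervals)


def write_truth_json(truth: TruthRecord, path: str, variants=None) -> None:
    payload = {
        "causal_tree": (truth.causal_tree.describe(variants)
                        if truth.causal_tree else None),
        "beta0": truth.beta0,
        "beta1": truth.beta1,
        "tree_frequency": truth.tree_frequency,
        "case_fraction": truth.case_fraction,
        "monomorphic_warning": truth.monomorphic_warning,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
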