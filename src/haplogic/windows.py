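"""Gene analytic windows: gene span +/- flank, SNP mapping, LD tag pruning.

A *gene analytic window* is a gene's merged transcript span extended by a
flank (500 kb by default) on each side; SNPs whose positions fall inside the
span (inclusive, 1-based) belong to the window.  Within each window SNPs are
thinned to tags by a greedy sweep in ascending position so that no retained
pair has haplotypic r-squared above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import MISSING, PhasedCohort

DEFAULT_FLANK = 500_000
DEFAULT_R2_MAX = 0.8
MIN_WINDOW_SNPS = 2


@dataclass(frozen=True)
class GeneRecord:
    """One gene's transcribed span (1-based inclusive)."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")


@dataclass
class GeneWindow:
    """A gene-centered analytic window with its mapped / pruned SNP indices."""

    window_id: str
    gene_ids: list[str]
    chrom: str
    start: int
    end: int
    snp_indices_all: np.ndarray = field(default_factory=lambda: np.array([], int))
    snp_indices_pruned: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices_all)

    @property
    def n_pruned(self) -> int:
        return len(self.snp_indices_pruned)


def build_windows(genes: list[GeneRecord], variants, flank: int = DEFAULT_FLANK,
                  min_snps: int = MIN_WINDOW_SNPS) -> list[GeneWindow]:
    """Build one window per gene (transcripts merged per gene id).

    Window span is ``[max(1, tx_start - flank), tx_end + flank]``; a SNP maps
    to the window iff it lies inside the span on the same chromosome.
    Windows with fewer than ``min_snps`` mapped SNPs are dropped.
    ``gene_ids`` lists every gene whose merged span is contained in the
    window (overlapping windows are expected and kept).
    """
    if not genes or len(variants) == 0:
        warnings.warn("no genes or no variants; returning no windows")
        return []
    # merge transcripts of the same gene id into one span
    merged: dict[tuple[str, str], GeneRecord] = {}
    for g in genes:
        key = (g.chrom, g.gene_id)
        if key in merged:
            m = merged[key]
            merged[key] = replace(m, tx_start=min(m.tx_start, g.tx_start),
                                  tx_end=max(m.tx_end, g.tx_end))
        else:
            merged[key] = g
    spans = sorted(merged.values(), key=lambda g: (g.chrom, g.tx_start, g.gene_id))

    pos = np.asarray([v.pos for v in variants], dtype=np.int64)
    chrom = np.asarray([v.chrom for v in variants])
    order = np.lexsort((pos, chrom))
    windows: list[GeneWindow] = []
    for g in spans:
        start = max(1, g.tx_start - flank)
        end = g.tx_end + flank
        on_chrom = order[chrom[order] == g.chrom]
        p = pos[on_chrom]
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="right")
        idx = on_chrom[lo:hi]
        if len(idx) < min_snps:
            continue
        covered = [h.gene_id for h in spans
                   if h.chrom == g.chrom and h.tx_start >= start
                   and h.tx_end <= end]
        windows.append(GeneWindow(window_id=g.gene_id, gene_ids=covered,
                                  chrom=g.chrom, start=start, end=end,
                                  snp_indices_all=idx,
                                  snp_indices_pruned=idx.copy()))
    return windows


def ld_r2(alleles_a: np.ndarray, alleles_b: np.ndarray) -> float:
    """Haplotypic LD r-squared between two phased 0/1 allele vectors.

    Chromosomes missing at either site are removed first.  Raises on
    monomorphic input (r-squared undefined).
    """
    a = np.asarray(alleles_a)
    b = np.asarray(alleles_b)
    if a.shape != b.shape:
        raise ValueError("allele vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) < 2:
        raise ValueError("fewer than two jointly observed chromosomes")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("undefined r^2 for monomorphic site")
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def prune_window(cohort: PhasedCohort, window: GeneWindow,
                 r2_max: float = DEFAULT_R2_MAX,
                 min_snps: int = MIN_WINDOW_SNPS) -> GeneWindow | None:
    """Greedy LD pruning in ascending position.

    A SNP is kept iff its r-squared with every already-kept SNP is
    <= ``r2_max``.  Monomorphic SNPs (r-squared undefined) are dropped.
    Returns ``None`` when fewer than ``min_snps`` SNPs survive.
    """
    idx = np.asarray(window.snp_indices_all)
    pos = cohort.positions[idx]
    idx = idx[np.argsort(pos, kind="stable")]
    kept: list[int] = []
    for j in idx:
        col = cohort.haps[:, j]
        obs = col[col != MISSING]
        if len(obs) == 0 or obs.min() == obs.max():
            continue
        try:
            if all(ld_r2(cohort.haps[:, k], col) <= r2_max for k in kept):
                kept.append(int(j))
        except ValueError:
            continue
    if len(kept) < min_snps:
        return None
    out = replace(window)
    out.snp_indices_pruned = np.asarray(kept, dtype=np.int64)
    return out
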