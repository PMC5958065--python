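"""Fisher-exact enrichment of haplotype SNPs over annotation tracks.

Compares the SNPs contributing to replicated haplotype trees against a
comparison SNP set (in practice: window-mapped SNPs with nominal single-SNP
associations) for overlap with interval tracks (e.g. histone-mark or DNase
peaks per cell type) or for per-SNP significant-eQTL indicators, using
two-sided Fisher's exact tests with a Bonferroni threshold per track family.

Intervals are 0-based half-open as on disk (BED); SNP positions are 1-based,
so position p overlaps interval [start, end) iff start < p <= end, i.e.
start <= p - 1 < end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .cohort import Variant


@dataclass
class AnnotationTrack:
    """Named interval set; intervals are (chrom, start, end), half-open."""

    track_id: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for c, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"{self.track_id}: degenerate interval "
                                 f"{c}:{s}-{e}")


def overlap_count(snps: list[Variant], track: AnnotationTrack) -> int:
    """Number of SNPs whose position falls in at least one interval."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in track.intervals:
        by_chrom.setdefault(c, []).append((s, e))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[c] = (np.asarray(starts), np.asarray(ends))
    n = 0
    for v in snps:
        if v.chrom not in merged:
            continue
        starts, ends = merged[v.chrom]
        p0 = v.pos - 1  # 0-based coordinate of the SNP
        i = np.searchsorted(starts, p0, side="right") - 1
        if i >= 0 and p0 < ends[i]:
            n += 1
    return n


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p (probability-mass criterion)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(fisher_exact(t, alternative="two-sided")[1])


@dataclass
class EnrichmentResult:
    track_id: str
    table: np.ndarray  # rows: (overlap, non-overlap); cols: (hap, comparison)
    pvalue: float
    threshold: float
    significant: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        (a, b), (c, d) = self.table
        flag = "*" if self.significant else ""
        return (f"{self.track_id}: hap {a}/{a + c} vs comp {b}/{b + d}, "
                f"p={self.pvalue:.3g} (thr {self.threshold:.3g}){flag}")


def _check_disjoint(hap_snps, comparison_snps) -> None:
    hap_ids = {v.id for v in hap_snps}
    comp_ids = {v.id for v in comparison_snps}
    common = hap_ids & comp_ids
    if common:
        raise ValueError(f"haplotype and comparison SNP sets overlap: "
                         f"{sorted(common)[:5]}")


def enrichment_scan(hap_snps: list[Variant], comparison_snps: list[Variant],
                    tracks: list[AnnotationTrack],
                    alpha: float = 0.05) -> list[EnrichmentResult]:
    """One two-sided Fisher test per track.

    The per-track threshold is ``alpha`` divided by the number of tracks in
    the scan (the assay family).  The two SNP sets must be disjoint.
    """
    _check_disjoint(hap_snps, comparison_snps)
    thr = alpha / len(tracks) if tracks else alpha
    out = []
    for tr in tracks:
        a = overlap_count(hap_snps, tr)
        b = overlap_count(comparison_snps, tr)
        table = np.array([[a, b],
                          [len(hap_snps) - a, len(comparison_snps) - b]])
        p = fisher_two_sided(table)
        out.append(EnrichmentResult(track_id=tr.track_id, table=table,
                                    pvalue=p, threshold=thr,
                                    significant=p < thr))
    return out


def eqtl_enrichment(hap_snps: list[Variant], comparison_snps: list[Variant],
                    eqtl_table: pd.DataFrame, tissue: str | None = None,
                    per_snp: bool = False, alpha: float = 0.05
                    ) -> EnrichmentResult:
    """Enrichment of significant cis-eQTLs among haplotype SNPs.

    ``eqtl_table`` has columns ``snp_id``, optionally ``tissue`` and
    ``gene_id``, and ``significant`` (0/1).  The default counting unit is
    the SNP-gene pair; with ``per_snp`` each SNP counts once if it has any
    significant eQTL.
    """
    _check_disjoint(hap_snps, comparison_snps)
    df = eqtl_table
    if tissue is not None and "tissue" in df.columns:
        df = df[df["tissue"] == tissue]
    sig = df[df["significant"].astype(bool)]

    def count(snps):
        ids = {v.id for v in snps}
        hit = sig[sig["snp_id"].isin(ids)]
        if per_snp:
            return hit["snp_id"].nunique(), len(ids)
        return len(hit), len(ids)

    a, na = count(hap_snps)
    b, nb = count(comparison_snps)
    if per_snp:
        table = np.array([[a, b], [na - a, nb - b]])
    else:
        # pair-level: non-events are SNPs' non-significant pairs
        all_pairs = df
        ta = len(all_pairs[all_pairs["snp_id"].isin({v.id for v in hap_snps})])
        tb = len(all_pairs[all_pairs["snp_id"].isin(
            {v.id for v in comparison_snps})])
        table = np.array([[a, b], [max(ta - a, 0), max(tb - b, 0)]])
    p = fisher_two_sided(table)
    label = f"eQTL[{tissue}]" if tissue else "eQTL"
    return EnrichmentResult(track_id=label, table=table, pvalue=p,
                            threshold=alpha, significant=p < alpha)
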