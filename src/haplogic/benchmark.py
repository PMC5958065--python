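"""Benchmark method: EM haplotype frequencies and a global haplotype score test.

This mirrors the classical sliding-window approach for unphased genotypes:
haplotype frequencies within a small window (k = 3 SNPs) are estimated by
expectation-maximization under random mating, and a global score test of
haplotype-phenotype association is computed with the most common haplotype
as reference (h - 1 degrees of freedom for h scorable haplotypes).

Score test construction (phenotype y, subject posterior expected haplotype
dosages x_i = E[z_i | genotype, f]):

    U  = sum_i (y_i - ybar) x_i
    V  = ybar (1 - ybar) sum_i (x_i - xbar)(x_i - xbar)^T

i.e. V is the permutation variance of U given the observed dosages: the
empirical covariance of the posterior expected dosages.  Phase uncertainty
shrinks the x_i toward their mean, and V shrinks with them, which keeps the
test calibrated under the null however ambiguous the phase is.  For fully
homozygous subjects (phase known, x_i = 2 e_h) the statistic reduces
exactly to the Pearson contingency score statistic on the subject-level
haplotype-class x phenotype table.  The statistic is U' V^- U with a
Moore-Penrose generalized inverse; df = rank(V).

Haplotypes with estimated counts (2N x frequency) below ``min_count``
(default 20) are excluded from scoring; optionally they can be pooled into
a single remainder category instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import chi2

from .assoc import bonferroni_threshold
from .cohort import PhasedCohort
from .windows import GeneWindow

RANK_TOL = 1e-10


@dataclass
class HaploFreqs:
    """EM output: haplotypes (allele tuples), frequencies, posteriors."""

    haplotypes: list[tuple[int, ...]]
    frequencies: np.ndarray
    log_likelihood: float
    log_likelihood_path: np.ndarray
    converged: bool
    n_subjects: int
    # per complete-genotype subject: expected dosage of each haplotype
    expected_dosage: np.ndarray = field(repr=False, default=None)
    subject_index: np.ndarray = field(repr=False, default=None)

    def estimated_counts(self) -> np.ndarray:
        return 2 * self.n_subjects * self.frequencies


def _compatible_pairs(geno: tuple[int, ...], haps: list[tuple[int, ...]],
                      index: dict) -> list[tuple[int, int]]:
    """Unordered haplotype pairs (i <= j) consistent with a genotype."""
    het = [s for s, g in enumerate(geno) if g == 1]
    base = [g // 2 for g in geno]  # 0->0, 1->0 (placeholder), 2->1
    pairs = []
    if not het:
        h = tuple(g // 2 for g in geno)
        if h in index:
            pairs.append((index[h], index[h]))
        return pairs
    for bits in product((0, 1), repeat=len(het) - 1):
        bits = (0,) + bits  # fix first het site to break pair symmetry
        h1 = list(base)
        h2 = list(base)
        for s, b in zip(het, bits):
            h1[s] = b
            h2[s] = 1 - b
        t1, t2 = tuple(h1), tuple(h2)
        if t1 in index and t2 in index:
            i, j = index[t1], index[t2]
            pairs.append((min(i, j), max(i, j)))
    return pairs


def em_hap_freqs(genotypes: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 500) -> HaploFreqs:
    """EM haplotype-frequency estimation from unphased genotypes.

    ``genotypes``: (n_subjects, k) allele-count matrix in {0, 1, 2}, with
    negative entries marking missing calls; subjects with any missing call
    in the window are dropped.  Starts from uniform frequencies over
    haplotypes compatible with at least one observed genotype; the observed
    log-likelihood is non-decreasing across iterations.
    """
    g = np.asarray(genotypes)
    complete = (g >= 0).all(axis=1)
    subject_index = np.flatnonzero(complete)
    g = g[complete]
    if len(g) == 0:
        raise ValueError("no subjects with complete genotypes in window")
    k = g.shape[1]

    patterns, inverse, counts = np.unique(g, axis=0, return_inverse=True,
                                          return_counts=True)
    # haplotypes compatible with >= 1 observed genotype
    hap_set: set[tuple[int, ...]] = set()
    for pat in patterns:
        het = [s for s, v in enumerate(pat) if v == 1]
        base = [v // 2 for v in pat]
        for bits in product((0, 1), repeat=len(het)):
            h = list(base)
            for s, b in zip(het, bits):
                h[s] = b
            hap_set.add(tuple(h))
    haps = sorted(hap_set)
    index = {h: i for i, h in enumerate(haps)}
    H = len(haps)
    pair_lists = [_compatible_pairs(tuple(pat), haps, index)
                  for pat in patterns]

    f = np.full(H, 1.0 / H)
    ll_path = []
    converged = False
    n = len(g)
    for _ in range(max_iter):
        # E step: posterior over compatible pairs per pattern
        expected = np.zeros(H)
        ll = 0.0
        post_by_pattern = []
        for pairs, cnt in zip(pair_lists, counts):
            w = np.array([(2.0 if i != j else 1.0) * f[i] * f[j]
                          for i, j in pairs])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(w), 1.0 / len(w))
                tot = 1.0
                post = w
            else:
                post = w / tot
                ll += cnt * np.log(tot)
            post_by_pattern.append(post)
            for (i, j), p in zip(pairs, post):
                expected[i] += cnt * p
                expected[j] += cnt * p
        ll_path.append(ll)
        f_new = expected / (2 * n)
        if len(ll_path) > 1 and abs(ll_path[-1] - ll_path[-2]) < tol:
            f = f_new
            converged = True
            break
        f = f_new

    # final per-subject expected dosages under the last f
    dosage_pat = np.zeros((len(patterns), H))
    for pi, (pairs, _) in enumerate(zip(pair_lists, counts)):
        w = np.array([(2.0 if i != j else 1.0) * f[i] * f[j]
                      for i, j in pairs])
        tot = w.sum()
        post = (w / tot) if tot > 0 else np.full(len(w), 1.0 / len(w))
        for (i, j), p in zip(pairs, post):
            dosage_pat[pi, i] += p
            dosage_pat[pi, j] += p
    dosage = dosage_pat[inverse]
    return HaploFreqs(haplotypes=haps, frequencies=f,
                      log_likelihood=ll_path[-1],
                      log_likelihood_path=np.asarray(ll_path),
                      converged=converged, n_subjects=n,
                      expected_dosage=dosage, subject_index=subject_index)


@dataclass
class ScoreTestResults:
    """Global haplotype score test for one SNP window."""

    statistic: float
    df: int
    pvalue: float
    h: int  # scorable haplotypes (including reference)
    reference: tuple[int, ...]
    freqs: HaploFreqs
    untestable: bool = False
    reason: str = ""

    def summary(self) -> str:
        if self.untestable:
            return f"score test untestable: {self.reason}"
        return (f"global haplotype score test: chi2 = {self.statistic:.4f}, "
                f"df = {self.df}, p = {self.pvalue:.3g} "
                f"({self.h} haplotypes, ref {self.reference})")


def global_score_test(genotypes: np.ndarray, phenotype: np.ndarray,
                      min_count: float = 20.0,
                      pool_rare: bool = False) -> ScoreTestResults:
    """Global score test of haplotype association within one window.

    Haplotypes with estimated counts below ``min_count`` are excluded from
    scoring (or pooled into one remainder category with ``pool_rare``);
    the most common scorable haplotype is the reference.
    """
    y_all = np.asarray(phenotype, dtype=float)
    freqs = em_hap_freqs(genotypes)
    y = y_all[freqs.subject_index]
    if len(np.unique(y)) < 2:
        return ScoreTestResults(np.nan, 0, np.nan, 0, (), freqs,
                                untestable=True,
                                reason="single phenotype class")
    n = freqs.n_subjects
    est = freqs.estimated_counts()
    keep = est >= min_count
    X = freqs.expected_dosage[:, keep]
    labels = [h for h, k in zip(freqs.haplotypes, keep) if k]
    if pool_rare and (~keep).any():
        X = np.column_stack([X, freqs.expected_dosage[:, ~keep].sum(axis=1)])
        labels.append(("pooled",))
    if X.shape[1] < 2:
        return ScoreTestResults(np.nan, 0, np.nan, X.shape[1], (), freqs,
                                untestable=True,
                                reason="fewer than 2 scorable haplotypes")
    c = X.sum(axis=0)
    ref = int(np.argmax(c))
    ybar = y.mean()
    U = (y - ybar) @ X
    Xc = X - X.mean(axis=0)
    V = ybar * (1 - ybar) * (Xc.T @ Xc)
    sel = np.arange(X.shape[1]) != ref
    U = U[sel]
    V = V[np.ix_(sel, sel)]
    Vinv = np.linalg.pinv(V, rcond=RANK_TOL, hermitian=True)
    stat = float(U @ Vinv @ U)
    df = int(np.linalg.matrix_rank(V, tol=RANK_TOL * np.abs(V).max(),
                                   hermitian=True))
    p = float(chi2.sf(stat, df)) if df > 0 else np.nan
    return ScoreTestResults(statistic=max(stat, 0.0), df=df, pvalue=p,
                            h=X.shape[1], reference=tuple(labels[ref]),
                            freqs=freqs)


class HaplotypeScoreTest:
    """Model-style wrapper around :func:`global_score_test`."""

    def __init__(self, genotypes, phenotype, min_count: float = 20.0,
                 pool_rare: bool = False):
        self.genotypes = np.asarray(genotypes)
        self.phenotype = np.asarray(phenotype)
        self.min_count = min_count
        self.pool_rare = pool_rare

    def fit(self) -> ScoreTestResults:
        return global_score_test(self.genotypes, self.phenotype,
                                 self.min_count, self.pool_rare)


def sliding_windows(snp_indices, size: int = 3, skip: int = 1) -> list[tuple]:
    """Contiguous index triples (i, i+1, i+2) along an ordered SNP list."""
    idx = list(snp_indices)
    return [tuple(idx[i:i + size]) for i in range(0, len(idx) - size + 1, skip)]


@dataclass
class BenchmarkScan:
    results: list  # (window_id, snp_triple, ScoreTestResults)
    n_tests: int
    threshold: float
    best_per_window: dict

    def significant(self):
        return [(w, t, r) for w, t, r in self.results
                if not r.untestable and r.pvalue < self.threshold]


def window_overlap_fraction(flagged_windows, reference_windows) -> float:
    """Fraction of reference windows also flagged by the benchmark scan."""
    ref = set(reference_windows)
    if not ref:
        return float("nan")
    return len(set(flagged_windows) & ref) / len(ref)


def benchmark_scan(cohort: PhasedCohort, windows: list[GeneWindow],
                   alpha: float = 0.05, min_count: float = 20.0,
                   use_pruned: bool = False) -> BenchmarkScan:
    """Exhaustive 3-SNP sliding-window score tests over gene windows.

    Genotypes are derived by collapsing the phased input (the benchmark
    operates on unphased data).  Every window triple counts as one test;
    the Bonferroni threshold divides ``alpha`` by the total test count.
    """
    geno = cohort.genotypes()
    y = cohort.phenotype
    results = []
    best: dict[str, tuple] = {}
    n_tests = 0
    for w in windows:
        idx = w.snp_indices_pruned if use_pruned else w.snp_indices_all
        for triple in sliding_windows(idx, 3, 1):
            n_tests += 1
            res = global_score_test(geno[:, list(triple)], y,
                                    min_count=min_count)
            results.append((w.window_id, triple, res))
            if not res.untestable:
                cur = best.get(w.window_id)
                if cur is None or res.pvalue < cur[1].pvalue:
                    best[w.window_id] = (triple, res)
    thr = bonferroni_threshold(alpha, max(n_tests, 1))
    return BenchmarkScan(results=results, n_tests=n_tests, threshold=thr,
                         best_per_window=best)
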