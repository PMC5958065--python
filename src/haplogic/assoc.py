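"""Subject-level additive haplotype association model.

The inference model is an ordinary logistic regression of case status on the
haplotype copy count L in {0, 1, 2}:

    logit P(case) = beta0 + beta1 * L

with each subject a single independent observation (unlike the
chromosome-level search score).  ``exp(beta1)`` is the per-copy odds ratio.
Fits accept per-subject data or grouped counts per copy number (the two are
likelihood-identical); grouped-count fitting also supports reconstructing
integer case counts from published group sizes and one-decimal case
percentages.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import PhasedCohort
from .tree import LogicTree


@dataclass
class GroupedCounts:
    """Subject counts per copy number: totals and case counts aligned to L."""

    levels: np.ndarray  # copy numbers with n_total > 0
    n_total: np.ndarray
    n_cases: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=int)
        self.n_cases = np.asarray(self.n_cases, dtype=int)
        if ((self.n_cases < 0) | (self.n_cases > self.n_total)).any():
            raise ValueError("need 0 <= n_cases <= n_total in every group")

    @classmethod
    def from_subject_data(cls, copy_count, phenotype) -> "GroupedCounts":
        L = np.asarray(copy_count, dtype=float)
        y = np.asarray(phenotype)
        ok = ~np.isnan(L) & (L >= 0)
        L, y = L[ok], y[ok]
        levels = np.unique(L)
        tot = np.array([(L == v).sum() for v in levels])
        cas = np.array([y[L == v].sum() for v in levels])
        return cls(levels, tot, cas)


class AdditiveHaplotypeResults:
    """Estimates, uncertainties and a summary for the additive model."""

    def __init__(self, params, bse, n_subjects, deviance, null_deviance,
                 separation=False):
        self.params = np.asarray(params, dtype=float)  # (beta0, beta1)
        self.bse = np.asarray(bse, dtype=float)
        self.n_subjects = int(n_subjects)
        self.deviance = float(deviance)
        self.null_deviance = float(null_deviance)
        self.separation = bool(separation)

    @property
    def beta0(self) -> float:
        return self.params[0]

    @property
    def beta1(self) -> float:
        return self.params[1]

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta1))

    @property
    def direction(self) -> int:
        return int(np.sign(self.beta1))

    @property
    def pvalue(self) -> float:
        """Two-sided Wald p for beta1 (nan when separation is flagged)."""
        if self.separation:
            return math.nan
        from scipy.stats import norm
        z = self.beta1 / self.bse[1]
        return float(2 * norm.sf(abs(z)))

    @property
    def pvalue_lrt(self) -> float:
        """Likelihood-ratio p for beta1 (1 df); optional alternative to Wald."""
        from scipy.stats import chi2
        return float(chi2.sf(max(self.null_deviance - self.deviance, 0.0), 1))

    def conf_int(self, alpha: float = 0.05):
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def summary(self) -> str:
        lines = [
            "Additive haplotype logistic model",
            f"  subjects: {self.n_subjects}",
            f"  beta0 = {self.beta0:+.4f} (SE {self.bse[0]:.4f})",
            f"  beta1 = {self.beta1:+.4f} (SE {self.bse[1]:.4f})",
            f"  OR per copy = {self.odds_ratio:.3f}",
            f"  Wald p = {self.pvalue:.3g}",
            f"  deviance = {self.deviance:.3f} "
            f"(null {self.null_deviance:.3f})",
        ]
        if self.separation:
            lines.append("  WARNING: separation detected; p omitted")
        return "\n".join(lines)


class AdditiveHaplotypeModel:
    """Logistic model of phenotype on haplotype copy count.

    Construct from per-subject copy counts (+ phenotypes), grouped counts, or
    a tree on a phased cohort; ``fit()`` returns
    :class:`AdditiveHaplotypeResults`.
    """

    def __init__(self, grouped: GroupedCounts):
        self.grouped = grouped

    @classmethod
    def from_subject_data(cls, copy_count, phenotype):
        return cls(GroupedCounts.from_subject_data(copy_count, phenotype))

    @classmethod
    def from_tree(cls, tree: LogicTree, cohort: PhasedCohort):
        L = tree.copy_counts(cohort.haps).astype(float)
        L[L < 0] = np.nan
        return cls.from_subject_data(L, cohort.phenotype)

    def fit(self) -> AdditiveHaplotypeResults:
        g = self.grouped
        use = g.n_total > 0
        levels, tot, cas = g.levels[use], g.n_total[use], g.n_cases[use]
        if len(levels) < 2:
            raise ValueError("no haplotype variation: a single copy-number "
                             "group carries no slope information")
        if cas.sum() == 0 or cas.sum() == tot.sum():
            raise ValueError("both outcome classes must be present")
        endog = np.column_stack([cas, tot - cas]).astype(float)
        exog = sm.add_constant(levels.astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        sep = _is_separated(levels, tot, cas)
        return AdditiveHaplotypeResults(
            params=res.params, bse=res.bse, n_subjects=int(tot.sum()),
            deviance=res.deviance, null_deviance=res.null_deviance,
            separation=sep)


def _is_separated(levels, tot, cas) -> bool:
    """Complete separation: case status is a step function of L."""
    frac = cas / tot
    order = np.argsort(levels)
    f = frac[order]
    pure = np.isin(f, (0.0, 1.0)).all()
    return bool(pure and len(set(f)) > 1 and (np.diff(f) >= 0).all()
                or pure and len(set(f)) > 1 and (np.diff(f) <= 0).all())


def fit_additive(copy_count=None, phenotype=None,
                 grouped: GroupedCounts | None = None) -> AdditiveHaplotypeResults:
    """Functional front door: fit from subject data or grouped counts."""
    if grouped is not None:
        return AdditiveHaplotypeModel(grouped).fit()
    return AdditiveHaplotypeModel.from_subject_data(copy_count, phenotype).fit()


# ---------------------------------------------------------------------------
# grouped-count reconstruction from printed percentages
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int = 1) -> float:
    f = 10 ** decimals
    return math.floor(x * f + 0.5) / f


def reconstruct_group_counts(group_sizes, pct_cases, total_cases: int
                             ) -> GroupedCounts:
    """Invert a printed "N (x.y% cases)" display into integer case counts.

    For each group, admissible case counts are the integers whose exact
    percentage rounds (half-up, one decimal) to the printed value; the
    unique combination summing to ``total_cases`` is returned.  Raises if
    zero or multiple combinations are consistent.
    """
    sizes = [int(n) for n in group_sizes]
    cands: list[list[int]] = []
    for n, pct in zip(sizes, pct_cases):
        ok = [c for c in range(n + 1)
              if abs(_round_half_up(100.0 * c / n) - pct) < 1e-9] if n else [0]
        if not ok:
            raise ValueError(f"no consistent solution: no case count in "
                             f"0..{n} rounds to {pct}%")
        cands.append(ok)
    sols = [c for c in itertools.product(*cands) if sum(c) == total_cases]
    if len(sols) != 1:
        raise ValueError(
            f"{'no' if not sols else len(sols)} consistent case-count "
            f"combinations for total {total_cases}: {sols[:10]}")
    return GroupedCounts(levels=np.arange(len(sizes), dtype=float),
                         n_total=np.array(sizes),
                         n_cases=np.array(sols[0]))


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# replication protocol
# ---------------------------------------------------------------------------

@dataclass
class ReplicationVerdict:
    tree: LogicTree
    discovery: AdditiveHaplotypeResults | None
    replication: AdditiveHaplotypeResults | None
    combined: AdditiveHaplotypeResults | None
    threshold: float
    replicated: bool
    untestable: bool = False
    reason: str = ""


def replicate_candidates(candidates, discovery: PhasedCohort,
                         replication: PhasedCohort,
                         combined: PhasedCohort | None = None,
                         alpha: float = 0.05) -> list[ReplicationVerdict]:
    """Refit each candidate tree in the replication cohort.

    A candidate replicates iff its replication Wald p is strictly below the
    Bonferroni per-test threshold ``alpha / n_candidates`` AND the
    replication odds ratio lies on the same side of 1 as in discovery.
    Trees that cannot be fitted in replication (no haplotype variation, one
    outcome class, SNPs absent) are reported untestable.
    """
    if not candidates:
        raise ValueError("no candidates to replicate")
    thr = bonferroni_threshold(alpha, len(candidates))
    out = []
    for cand in candidates:
        tree = cand.fit.tree if hasattr(cand, "fit") else cand
        disc = _try_fit(tree, discovery)
        rep = _try_fit(tree, replication)
        comb = _try_fit(tree, combined) if combined is not None else None
        if disc is None or rep is None:
            out.append(ReplicationVerdict(
                tree=tree, discovery=disc, replication=rep, combined=comb,
                threshold=thr, replicated=False, untestable=True,
                reason="model not estimable in one cohort"))
            continue
        same_dir = rep.direction == disc.direction and disc.direction != 0
        ok = (not math.isnan(rep.pvalue)) and rep.pvalue < thr and same_dir
        out.append(ReplicationVerdict(
            tree=tree, discovery=disc, replication=rep, combined=comb,
            threshold=thr, replicated=bool(ok)))
    return out


def _try_fit(tree: LogicTree, cohort: PhasedCohort):
    try:
        return AdditiveHaplotypeModel.from_tree(tree, cohort).fit()
    except (ValueError, IndexError):
        return None
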