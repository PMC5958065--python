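"""Permutation-based evaluation statistic and top-percentile candidate selection.

For each window the best observed deviance ``D_obs`` is compared with the
best deviances found after permuting case/control labels (both chromosomes
of a subject move together).  With 20 permutation deviances ``D_1..D_20``:

* deviations ``d_i = D_i - median(D_{-i})`` (leave-one-out medians),
* ``D_med`` = median of all 20 permutation deviances,
* ``MAD`` = median absolute deviation of the ``d_i`` (scaled by 1.4826 for
  normal consistency by default; raw MAD available),
* statistic = ``(D_obs - D_med) / MAD``.

More negative values mean the observed fit is farther below its permutation
null.  Candidates are deduplicated across windows by canonical tree identity
(best statistic retained) and the most negative ``ceil(fraction * n_unique)``
are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import PhasedCohort
from .search import FitResult, SearchConfig, _search_eval, _WindowEval
from .windows import GeneWindow

DEGENERATE = "degenerate"


@dataclass
class PermStat:
    d_obs: float
    perm_deviances: np.ndarray
    deviations: np.ndarray = field(default=None)
    d_med: float = math.nan
    mad: float = math.nan
    statistic: float | None = None  # None => degenerate (MAD = 0)

    @property
    def degenerate(self) -> bool:
        return self.statistic is None


def permutation_deviances(cohort: PhasedCohort, window: GeneWindow,
                          config: SearchConfig, n_perm: int = 20,
                          seed: int = 0,
                          perm_config: SearchConfig | None = None) -> np.ndarray:
    """Best deviance under each of ``n_perm`` phenotype permutations.

    Each permutation shuffles subject phenotypes (keeping the case count)
    and re-runs the full multi-restart search.  ``perm_config`` may reduce
    the restart/iteration budget for the permuted searches.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    pcfg = perm_config or config
    snps = np.asarray(window.snp_indices_pruned)
    ev = _WindowEval.from_cohort(cohort, snps)
    mapping = {i: int(s) for i, s in enumerate(snps)}
    rng = np.random.default_rng(seed)
    y = cohort.phenotype
    out = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(y)
        pev = ev.with_phenotype(perm)
        res = _search_eval(pev, f"{window.window_id}#perm{p}", pcfg, mapping)
        out[p] = res.deviance
    return out


def evaluation_statistic(d_obs: float, perm_deviances: np.ndarray,
                         scale_mad: bool = True) -> PermStat:
    """The permutation-based evaluation statistic (D_obs - D_med) / MAD."""
    perms = np.asarray(perm_deviances, dtype=float)
    n = len(perms)
    if n < 2:
        raise ValueError("need at least 2 permutation deviances")
    dev = np.empty(n)
    for i in range(n):
        dev[i] = perms[i] - np.median(np.delete(perms, i))
    d_med = float(np.median(perms))
    mad = float(np.median(np.abs(dev - np.median(dev))))
    if scale_mad:
        mad *= 1.4826
    stat = None if mad == 0 else (d_obs - d_med) / mad
    return PermStat(d_obs=float(d_obs), perm_deviances=perms,
                    deviations=dev, d_med=d_med, mad=mad, statistic=stat)


@dataclass
class Candidate:
    """A unique tree with its best window's fit and evaluation statistic."""

    fit: FitResult
    stat: PermStat
    window_ids: list[str]

    @property
    def statistic(self) -> float:
        return self.stat.statistic


def select_candidates(results: list[tuple[GeneWindow, FitResult, PermStat]],
                      fraction: float = 0.01
                      ) -> tuple[list[Candidate], float | None]:
    """Deduplicate trees across windows and keep the top fraction.

    Returns (selected candidates sorted by statistic ascending, realized
    cutoff = statistic of the last selected candidate).  Degenerate
    statistics (MAD = 0) and windows without a qualifying tree are excluded
    from ranking.
    """
    unique: dict[str, Candidate] = {}
    for window, fit, stat in results:
        if fit.tree is None or stat.degenerate:
            continue
        key = fit.tree.key
        cur = unique.get(key)
        if cur is None:
            unique[key] = Candidate(fit=fit, stat=stat,
                                    window_ids=[window.window_id])
        else:
            cur.window_ids.append(window.window_id)
            if stat.statistic < cur.stat.statistic:
                cur.fit, cur.stat = fit, stat
    if not unique:
        return [], None
    ranked = sorted(unique.values(),
                    key=lambda c: (c.statistic, c.fit.tree.key))
    n_sel = math.ceil(fraction * len(ranked))
    selected = ranked[:n_sel]
    cutoff = selected[-1].statistic if selected else None
    return selected, cutoff
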