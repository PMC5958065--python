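"""Simulated-annealing logic-regression search for best-fitting haplotype trees.

For a candidate tree the model is a logistic regression of case status on the
binary tree indicator evaluated on every chromosome copy (two observations
per subject, each carrying the subject's phenotype).  Because the predictor
is a single binary indicator, the maximum-likelihood fit is closed-form in
the 2x2 (indicator x phenotype) chromosome counts, which makes scoring a tree
a handful of bit-level operations: per window, literal truth columns are
bit-packed once and tree evaluation reduces to bitwise AND/OR plus popcounts.

The search itself is standard simulated annealing over the tree space
(replace-leaf-SNP, flip-leaf-allele, toggle-operator, grow-leaf, prune-leaf
moves; geometric cooling), restarted from many random initial literals; the
best tree with the required number of distinct SNPs wins, with deterministic
canonical-key tie-breaking.  An exhaustive enumerator over all <=3-leaf trees
is provided for small windows.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .cohort import MISSING, PhasedCohort
from .tree import AND, OR, LogicTree, canonical_key, is_leaf, leaves
from .windows import GeneWindow

_MOVES = ("replace", "flip", "toggle", "grow", "prune")


@dataclass
class SearchConfig:
    """Simulated-annealing search settings.

    Defaults: 100 restarts of 2,000 iterations each with geometric cooling
    from ``t_start`` to ``t_end``.  ``move_weights`` are the proposal
    probabilities over (replace-leaf-SNP, flip-leaf-allele, toggle-operator,
    grow-leaf, prune-leaf); an inapplicable move falls through to the next
    applicable one.  Replace-leaf carries half the mass because the SNP
    choice is the dominant dimension of the space.  With
    ``require_full_snps`` only trees using min(3, window size) distinct SNPs
    are reported (the search may pass through smaller trees).
    """

    n_restarts: int = 100
    n_iterations: int = 2000
    t_start: float = 10.0
    t_end: float = 0.01
    move_weights: tuple[float, ...] = (0.50, 0.15, 0.10, 0.15, 0.10)
    max_leaves: int = 3
    require_full_snps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_start <= self.t_end or self.t_end <= 0:
            raise ValueError("need t_start > t_end > 0")
        w = np.asarray(self.move_weights, dtype=float)
        if len(w) != 5 or (w < 0).any() or not math.isclose(w.sum(), 1.0):
            raise ValueError("move_weights must be 5 probabilities summing to 1")

    def temperatures(self) -> np.ndarray:
        n = self.n_iterations
        return self.t_start * (self.t_end / self.t_start) ** (
            np.arange(n) / max(n - 1, 1))


@dataclass
class FitResult:
    """Best tree for one window with its chromosome-level model fit."""

    tree: LogicTree | None
    deviance: float
    beta: float
    n_used: int
    null_deviance: float
    window_id: str = ""
    constant: bool = False
    separation: bool = False
    n_restarts: int = 0


def _group_loglik(c: float, n: float) -> float:
    """Saturated-group binomial log-likelihood n*[p ln p + (1-p) ln(1-p)]."""
    if n <= 0:
        return 0.0
    ll = 0.0
    if c > 0:
        ll += c * math.log(c / n)
    if c < n:
        ll += (n - c) * math.log(1 - c / n)
    return ll


def indicator_deviance(ct: int, nt: int, n_case: int, n: int):
    """Closed-form logistic fit of phenotype on a binary indicator.

    Parameters are counts over chromosome observations: ``ct`` cases among
    ``nt`` indicator-true chromosomes, ``n_case`` cases among ``n`` total.
    Returns (deviance, beta, constant_flag, separation_flag).
    """
    null_dev = -2.0 * _group_loglik(n_case, n)
    if nt == 0 or nt == n:
        return null_dev, 0.0, True, False
    cf, nf = n_case - ct, n - nt
    dev = -2.0 * (_group_loglik(ct, nt) + _group_loglik(cf, nf))
    sep = dev == 0.0
    if 0 < ct < nt and 0 < cf < nf:
        beta = math.log(ct / (nt - ct)) - math.log(cf / (nf - cf))
    else:
        beta = math.inf if (ct == nt or cf == 0) else -math.inf
    return dev, beta, False, sep


def _popcount(x: np.ndarray) -> int:
    return int(np.bitwise_count(x).sum())


class _WindowEval:
    """Per-window scoring context over a local SNP index set.

    Literal truth columns for every (snp, allele) pair are precomputed; with
    no missing data they are bit-packed so a tree costs a few bitwise ops
    plus popcounts.  Scores are cached by canonical key (the tree space of a
    small window is tiny and simulated annealing revisits states often).
    """

    def __init__(self, haps: np.ndarray, phenotype: np.ndarray):
        self.n_chrom, self.k = haps.shape
        y = np.asarray(phenotype, dtype=np.int8)
        self.case_mask = np.repeat(y, 2).astype(bool)
        self.n_case = int(self.case_mask.sum())
        self.has_missing = bool((haps == MISSING).any())
        # truth columns per (local snp, allele)
        self.lit = [[np.ascontiguousarray(haps[:, s] == a) for a in (0, 1)]
                    for s in range(self.k)]
        if self.has_missing:
            self.not_missing = [np.ascontiguousarray(haps[:, s] != MISSING)
                                for s in range(self.k)]
            self.packed = None
        else:
            self.packed = [[np.packbits(self.lit[s][a]) for a in (0, 1)]
                           for s in range(self.k)]
            self.case_packed = np.packbits(self.case_mask)
        self.null_deviance = -2.0 * _group_loglik(self.n_case, self.n_chrom)
        self._cache: dict[tuple, tuple] = {}
        # tree -> (packed indicator, popcount); shared across phenotype
        # relabelings (the indicator does not depend on the phenotype)
        self._vcache: dict[tuple, tuple] = {}

    @classmethod
    def from_cohort(cls, cohort: PhasedCohort, snp_indices,
                    phenotype: np.ndarray | None = None) -> "_WindowEval":
        y = cohort.phenotype if phenotype is None else phenotype
        ev = cls(cohort.haps[:, np.asarray(snp_indices)], y)
        ev.snp_indices = np.asarray(snp_indices)
        return ev

    def with_phenotype(self, phenotype: np.ndarray) -> "_WindowEval":
        ev = object.__new__(_WindowEval)
        ev.__dict__.update(self.__dict__)
        y = np.asarray(phenotype, dtype=np.int8)
        ev.case_mask = np.repeat(y, 2).astype(bool)
        ev.n_case = int(ev.case_mask.sum())
        if not ev.has_missing:
            ev.case_packed = np.packbits(ev.case_mask)
        ev.null_deviance = -2.0 * _group_loglik(ev.n_case, ev.n_chrom)
        ev._cache = {}
        return ev

    # -- evaluation --------------------------------------------------------
    def _packed_eval(self, node) -> np.ndarray:
        if is_leaf(node):
            return self.packed[node[0]][node[1]]
        a = self._packed_eval(node[1])
        b = self._packed_eval(node[2])
        return (a & b) if node[0] == AND else (a | b)

    def _bool_eval(self, node) -> np.ndarray:
        if is_leaf(node):
            return self.lit[node[0]][node[1]]
        a = self._bool_eval(node[1])
        b = self._bool_eval(node[2])
        return (a & b) if node[0] == AND else (a | b)

    def score(self, node) -> tuple:
        """(deviance, beta, n_used, constant, separation) for a local tree.

        Cached by the raw tuple (structurally identical trees that differ
        only in operand order are scored once each; the state space of a
        small window is tiny either way).
        """
        hit = self._cache.get(node)
        if hit is not None:
            return hit
        if not self.has_missing:
            vhit = self._vcache.get(node)
            if vhit is None:
                v = self._packed_eval(node)
                nt = _popcount(v)
                self._vcache[node] = (v, nt)
            else:
                v, nt = vhit
            ct = _popcount(v & self.case_packed)
            dev, beta, const, sep = indicator_deviance(
                ct, nt, self.n_case, self.n_chrom)
            out = (dev, beta, self.n_chrom, const, sep)
        else:
            ok = np.ones(self.n_chrom, dtype=bool)
            for s in {s for s, _ in leaves(node)}:
                ok &= self.not_missing[s]
            # a subject with either chromosome missing at a leaf SNP is
            # dropped entirely from this tree's model
            subj_ok = ok[0::2] & ok[1::2]
            use = np.repeat(subj_ok, 2)
            v = self._bool_eval(node) & use
            nt = int(v.sum())
            ct = int((v & self.case_mask).sum())
            n = int(use.sum())
            n_case = int((use & self.case_mask).sum())
            dev, beta, const, sep = indicator_deviance(ct, nt, n_case, n)
            out = (dev, beta, n, const, sep)
        self._cache[node] = out
        return out


# ---------------------------------------------------------------------------
# public single-tree scoring
# ---------------------------------------------------------------------------

def haplotype_deviance(tree: LogicTree | tuple, cohort: PhasedCohort,
                       phenotype: np.ndarray | None = None) -> FitResult:
    """Score one tree (global SNP indices) on a cohort's 2N chromosomes."""
    root = tree.root if isinstance(tree, LogicTree) else tree
    snps = sorted({s for s, _ in leaves(root)})
    local = _translate(root, {s: i for i, s in enumerate(snps)})
    ev = _WindowEval.from_cohort(cohort, snps, phenotype)
    dev, beta, n, const, sep = ev.score(local)
    return FitResult(tree=LogicTree(root), deviance=dev, beta=beta, n_used=n,
                     null_deviance=ev.null_deviance, constant=const,
                     separation=sep)


def _translate(node, mapping: dict[int, int]):
    if is_leaf(node):
        return (mapping[node[0]], node[1])
    return (node[0], _translate(node[1], mapping),
            _translate(node[2], mapping))


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

def accept_probability(delta: float, temperature: float) -> float:
    """Metropolis rule: min(1, exp(-delta / T))."""
    if delta <= 0:
        return 1.0
    return math.exp(-delta / temperature)


def _leaf_paths(root):
    """Paths to leaves; trees have <= 3 leaves and depth <= 2."""
    if len(root) == 2:
        return ((),)
    out = []
    for i in (1, 2):
        c = root[i]
        if len(c) == 2:
            out.append((i,))
        else:
            out.append((i, 1))
            out.append((i, 2))
    return out


def _node_paths(root):
    if len(root) == 2:
        return ()
    out = [()]
    for i in (1, 2):
        if len(root[i]) == 3:
            out.append((i,))
    return out


def _get(node, path):
    for i in path:
        node = node[i]
    return node


def _replace_at(node, path, new):
    if not path:
        return new
    i = path[0]
    child = _replace_at(node[i], path[1:], new)
    return (node[0], child, node[2]) if i == 1 else (node[0], node[1], child)


def _nsnps(root) -> int:
    if len(root) == 2:
        return 1
    snps = {s for s, _ in leaves(root)}
    return len(snps)


def _propose(root, k: int, cum: tuple, max_leaves: int, r) -> tuple:
    """One proposal from a row of 4 pre-drawn uniforms.

    ``r[0]`` selects the move (resampling inapplicable moves falls through
    to the next applicable one in a fixed order), ``r[1..3]`` select the
    edit site and its replacement.
    """
    leaf_paths = _leaf_paths(root)
    n_leaves = len(leaf_paths)
    u = r[0]
    if u < cum[0] and k >= 2:
        m = 0
    elif u < cum[1]:
        m = 1
    elif u < cum[2] and n_leaves > 1:
        m = 2
    elif u < cum[3] and n_leaves < max_leaves:
        m = 3
    elif n_leaves > 1:
        m = 4
    else:
        m = 3 if n_leaves < max_leaves else 1
    if m == 0:  # replace-leaf-SNP
        path = leaf_paths[int(r[1] * n_leaves)]
        s, a = _get(root, path)
        new_s = int(r[2] * (k - 1))
        if new_s >= s:
            new_s += 1
        return _replace_at(root, path, (new_s, a))
    if m == 1:  # flip-leaf-allele
        path = leaf_paths[int(r[1] * n_leaves)]
        s, a = _get(root, path)
        return _replace_at(root, path, (s, 1 - a))
    if m == 2:  # toggle-operator
        node_paths = _node_paths(root)
        path = node_paths[int(r[1] * len(node_paths))]
        op, lc, rc = _get(root, path)
        return _replace_at(root, path, (OR if op == AND else AND, lc, rc))
    if m == 3:  # grow-leaf
        path = leaf_paths[int(r[1] * n_leaves)]
        leaf = _get(root, path)
        lit = (int(r[2] * k), 0 if r[3] < 0.25 or 0.5 <= r[3] < 0.75 else 1)
        op = AND if r[3] < 0.5 else OR
        return _replace_at(root, path, (op, leaf, lit))
    # prune-leaf
    path = leaf_paths[int(r[1] * n_leaves)]
    parent, last = path[:-1], path[-1]
    sibling = _get(root, parent + (3 - last,))
    return _replace_at(root, parent, sibling)


class _Best:
    """Track the minimum-deviance qualifying tree with canonical-key ties."""

    def __init__(self, target_snps: int):
        self.target = target_snps
        self.dev = math.inf
        self.key: str | None = None
        self.node = None

    def offer(self, node, dev: float) -> None:
        if dev > self.dev + 1e-12 or _nsnps(node) != self.target:
            return
        if dev < self.dev - 1e-12:
            self.dev, self.node, self.key = dev, node, canonical_key(node)
        elif abs(dev - self.dev) <= 1e-12:
            key = canonical_key(node)
            if self.key is None or key < self.key:
                self.node, self.key = node, key

    def merge(self, other: "_Best") -> None:
        if other.node is None:
            return
        if (other.dev < self.dev - 1e-12
                or (abs(other.dev - self.dev) <= 1e-12
                    and (self.key is None or other.key < self.key))):
            self.dev, self.node, self.key = other.dev, other.node, other.key


def _target_snps(k: int, config: SearchConfig) -> int:
    return min(3, k) if config.require_full_snps else 1


def _anneal(ev: _WindowEval, config: SearchConfig, rng,
            best: _Best) -> None:
    k = ev.k
    current = (int(rng.integers(k)), int(rng.integers(2)))
    cur_dev = ev.score(current)[0]
    best.offer(current, cur_dev)
    temps = config.temperatures()
    U = rng.random((config.n_iterations, 5))
    cum = tuple(np.cumsum(config.move_weights))
    score = ev.score
    max_leaves = config.max_leaves
    for i in range(config.n_iterations):
        r = U[i]
        prop = _propose(current, k, cum, max_leaves, r)
        dev = score(prop)[0]
        best.offer(prop, dev)
        delta = dev - cur_dev
        if delta <= 0 or r[4] < math.exp(-delta / temps[i]):
            current, cur_dev = prop, dev
    return


def _restart_rng(seed: int, window_id: str, restart: int):
    ss = np.random.SeedSequence(
        [int(seed), zlib.crc32(window_id.encode()) & 0x7FFFFFFF, int(restart)])
    return np.random.Generator(np.random.PCG64(ss))


def _result_from_best(ev: _WindowEval, best: _Best, window_id: str,
                      mapping, n_restarts: int) -> FitResult:
    if best.node is None:
        return FitResult(tree=None, deviance=ev.null_deviance, beta=0.0,
                         n_used=ev.n_chrom, null_deviance=ev.null_deviance,
                         window_id=window_id, constant=True,
                         n_restarts=n_restarts)
    dev, beta, n, const, sep = ev.score(best.node)
    gtree = LogicTree(_translate(best.node, mapping))
    return FitResult(tree=gtree, deviance=dev, beta=beta, n_used=n,
                     null_deviance=ev.null_deviance, window_id=window_id,
                     constant=const, separation=sep, n_restarts=n_restarts)


def anneal_once(cohort: PhasedCohort, window: GeneWindow,
                config: SearchConfig, restart_seed: int = 0) -> FitResult:
    """One annealing run from a deterministic restart seed."""
    snps = np.asarray(window.snp_indices_pruned)
    ev = _WindowEval.from_cohort(cohort, snps)
    best = _Best(_target_snps(ev.k, config))
    rng = _restart_rng(config.seed, window.window_id, restart_seed)
    _anneal(ev, config, rng, best)
    mapping = {i: int(s) for i, s in enumerate(snps)}
    return _result_from_best(ev, best, window.window_id, mapping, 1)


def _search_eval(ev: _WindowEval, window_id: str, config: SearchConfig,
                 mapping) -> FitResult:
    best = _Best(_target_snps(ev.k, config))
    for r in range(config.n_restarts):
        rng = _restart_rng(config.seed, window_id, r)
        _anneal(ev, config, rng, best)
    return _result_from_best(ev, best, window_id, mapping,
                             config.n_restarts)


def search_window(cohort: PhasedCohort, window: GeneWindow,
                  config: SearchConfig | None = None) -> FitResult:
    """Multi-restart search; minimum deviance over restarts wins."""
    config = config or SearchConfig()
    snps = np.asarray(window.snp_indices_pruned)
    ev = _WindowEval.from_cohort(cohort, snps)
    mapping = {i: int(s) for i, s in enumerate(snps)}
    return _search_eval(ev, window.window_id, config, mapping)


# ---------------------------------------------------------------------------
# exhaustive enumeration (small windows)
# ---------------------------------------------------------------------------

def _enumerate_roots(k: int, target: int):
    """All canonical trees over local SNPs with `target` distinct SNPs."""
    if target == 1:
        for s in range(k):
            for a in (0, 1):
                yield (s, a)
        return
    if target == 2:
        for i, j in combinations(range(k), 2):
            for ai, aj in product((0, 1), repeat=2):
                for op in (AND, OR):
                    yield (op, (i, ai), (j, aj))
        return
    for i, j, l in combinations(range(k), 3):
        for ai, aj, al in product((0, 1), repeat=3):
            a, b, c = (i, ai), (j, aj), (l, al)
            for op in (AND, OR):
                yield (op, (op, a, b), c)
            for lone, pair in (((a), (b, c)), ((b), (a, c)), ((c), (a, b))):
                yield (AND, lone, (OR, *pair))
                yield (OR, lone, (AND, *pair))


def exhaustive_search(cohort: PhasedCohort, window: GeneWindow,
                      config: SearchConfig | None = None) -> FitResult:
    """Enumerate every tree with the target number of distinct SNPs.

    Intended for small windows (cost grows with the cube of window size);
    serves as the global optimum the annealing search should attain.
    """
    config = config or SearchConfig()
    snps = np.asarray(window.snp_indices_pruned)
    ev = _WindowEval.from_cohort(cohort, snps)
    target = _target_snps(ev.k, config)
    best = _Best(target)
    for root in _enumerate_roots(ev.k, target):
        best.offer(root, ev.score(root)[0])
    mapping = {i: int(s) for i, s in enumerate(snps)}
    return _result_from_best(ev, best, window.window_id, mapping, 0)


class HaplotypeLogicRegression:
    """Model-style wrapper: best haplotype logic tree for one window.

    ``fit()`` runs the multi-restart annealing search; ``fit_exhaustive()``
    enumerates (small windows only).  Both return :class:`FitResult`.
    """

    def __init__(self, cohort: PhasedCohort, window: GeneWindow,
                 config: SearchConfig | None = None):
        self.cohort = cohort
        self.window = window
        self.config = config or SearchConfig()

    def fit(self) -> FitResult:
        return search_window(self.cohort, self.window, self.config)

    def fit_exhaustive(self) -> FitResult:
        return exhaustive_search(self.cohort, self.window, self.config)
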