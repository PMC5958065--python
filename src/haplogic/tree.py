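"""Boolean haplotype logic trees over (SNP, allele) literals.

A tree combines up to three literals of the form ``SNP == allele`` with
binary AND/OR nodes and is evaluated on a single phased haplotype.  Because
SNPs are biallelic, ``SNP == ref`` is the complement of ``SNP == alt``, so
explicit negation is never represented.  A subject's *copy count* L in
{0, 1, 2} is the number of their two haplotypes satisfying the tree — the
additive predictor of the association model.

Internally a tree is a nested tuple: a literal is ``(snp_index, allele)``
and an internal node is ``(op, left, right)`` with ``op`` in ``{"&", "|"}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import MISSING

AND = "&"
OR = "|"

Node = tuple  # (snp, allele) | (op, left, right)


def is_leaf(node: Node) -> bool:
    return len(node) == 2


def leaves(node: Node) -> list[tuple[int, int]]:
    if is_leaf(node):
        return [node]
    return leaves(node[1]) + leaves(node[2])


def tree_snps(node: Node) -> set[int]:
    return {s for s, _ in leaves(node)}


def n_distinct_snps(node: Node) -> int:
    return len(tree_snps(node))


def validate(node: Node, max_leaves: int = 3) -> None:
    ls = leaves(node)
    if not 1 <= len(ls) <= max_leaves:
        raise ValueError(f"tree must have 1..{max_leaves} leaves, got {len(ls)}")
    for s, a in ls:
        if a not in (0, 1):
            raise ValueError(f"literal allele must be 0 or 1, got {a}")


def evaluate(node: Node, haplotype: np.ndarray) -> bool | None:
    """Evaluate on one haplotype; returns None if any leaf SNP is missing."""
    hap = np.asarray(haplotype)
    if any(hap[s] == MISSING for s in tree_snps(node)):
        return None
    return bool(_eval(node, hap))


def _eval(node: Node, hap: np.ndarray):
    if is_leaf(node):
        return hap[node[0]] == node[1]
    if node[0] == AND:
        return _eval(node[1], hap) and _eval(node[2], hap)
    return _eval(node[1], hap) or _eval(node[2], hap)


def copy_count(node: Node, hap_pair) -> int | None:
    """Number of the two haplotypes satisfying the tree; None if either
    haplotype is missing at a leaf SNP."""
    r1 = evaluate(node, hap_pair[0])
    r2 = evaluate(node, hap_pair[1])
    if r1 is None or r2 is None:
        return None
    return int(r1) + int(r2)


def copy_counts(node: Node, haps: np.ndarray) -> np.ndarray:
    """Vectorized per-subject copy counts over a (2N, M) allele matrix.

    Returns an int8 array of length N with -1 where a subject has a missing
    allele at any leaf SNP on either chromosome.
    """
    snps = sorted(tree_snps(node))
    sub = haps[:, snps]
    ok = (sub != MISSING).all(axis=1)
    remap = {s: i for i, s in enumerate(snps)}
    val = _eval_vec(node, sub, remap)
    L = (val[0::2].astype(np.int8) + val[1::2].astype(np.int8))
    L[~(ok[0::2] & ok[1::2])] = -1
    return L


def _eval_vec(node: Node, sub: np.ndarray, remap: dict[int, int]) -> np.ndarray:
    if is_leaf(node):
        return sub[:, remap[node[0]]] == node[1]
    a = _eval_vec(node[1], sub, remap)
    b = _eval_vec(node[2], sub, remap)
    return (a & b) if node[0] == AND else (a | b)


# ---------------------------------------------------------------------------
# Canonical structural identity
# ---------------------------------------------------------------------------

def canonical_key(node: Node) -> str:
    """Structural canonical form as a string key.

    Commutative operands are sorted and chains of the same operator are
    flattened, so two trees get equal keys iff they are the same tree up to
    commutativity/associativity (not mere logical equivalence: ``A|B`` and
    ``A&B`` differ; so do structurally different but logically equal trees).
    """
    return _key(node)


def _key(node: Node) -> str:
    if is_leaf(node):
        return f"{node[0]}.{node[1]}"
    parts = sorted(_key(c) for c in _flatten(node, node[0]))
    return node[0] + "(" + ",".join(parts) + ")"


def _flatten(node: Node, op: str) -> list[Node]:
    if is_leaf(node) or node[0] != op:
        return [node]
    return _flatten(node[1], op) + _flatten(node[2], op)


def to_string(node: Node, variants=None) -> str:
    """Human-readable form, e.g. ``(rs1=C) or ((rs2=A) and (rs3=G))``.

    With ``variants`` the SNP index resolves to its rsID and the allele to
    the ref/alt base; otherwise indices and 0/1 codes are printed.
    """
    if is_leaf(node):
        s, a = node
        if variants is not None:
            v = variants[s]
            return f"({v.id}={v.alt if a == 1 else v.ref})"
        return f"(s{s}={a})"
    word = " and " if node[0] == AND else " or "
    lhs, rhs = to_string(node[1], variants), to_string(node[2], variants)
    if not is_leaf(node[1]):
        lhs = f"({lhs})"
    if not is_leaf(node[2]):
        rhs = f"({rhs})"
    return lhs + word + rhs


@dataclass(frozen=True)
class LogicTree:
    """Thin public wrapper around the tuple representation."""

    root: Node

    def __post_init__(self) -> None:
        validate(self.root)

    def evaluate(self, haplotype) -> bool | None:
        return evaluate(self.root, haplotype)

    def copy_count(self, hap_pair) -> int | None:
        return copy_count(self.root, hap_pair)

    def copy_counts(self, haps) -> np.ndarray:
        return copy_counts(self.root, haps)

    @property
    def key(self) -> str:
        return canonical_key(self.root)

    @property
    def snps(self) -> set[int]:
        return tree_snps(self.root)

    def describe(self, variants=None) -> str:
        return to_string(self.root, variants)
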