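"""Boolean logic-tree classifier.

A logic tree is a binary tree whose internal nodes are AND/OR operators and
whose leaves are literals — a binary predictor or its complement.  A subject
is classified as a case when the Boolean expression evaluates true.  Trees
are capped at ``max_leaves`` leaves (default 8), so a single tree can
express interactions of up to eight variables.

The disjunctive normal form (DNF) of a tree is an OR of AND-terms; each
term, a conjunction of literals, is a *prime implicant* — the unit whose
importance the forest quantifies.

Fitting minimises misclassification by simulated annealing over the
classical logic-regression move set (alternate a leaf or operator, grow or
prune a branch, split or delete a leaf).  During the search, predictor
columns are packed into machine-word bitmasks so a tree evaluation is a
handful of bitwise operations plus a popcount, independent of tree-library
overhead.
"""

from __future__ import annotations

import json
import math
import random
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Literal",
    "LogicTree",
    "PrimeImplicant",
    "AnnealingSchedule",
    "evaluate",
    "to_dnf",
    "score",
    "propose_move",
    "fit_tree",
]


class Literal(NamedTuple):
    predictor_index: int
    complemented: bool = False


class _Leaf:
    __slots__ = ("literal",)

    def __init__(self, literal: Literal):
        self.literal = literal


class _Op:
    __slots__ = ("op", "left", "right")

    def __init__(self, op: str, left, right):
        self.op = op  # "and" | "or"
        self.left = left
        self.right = right


def _copy_node(node):
    if isinstance(node, _Leaf):
        return _Leaf(node.literal)
    return _Op(node.op, _copy_node(node.left), _copy_node(node.right))


class LogicTree:
    """A Boolean AND/OR tree over binary literals."""

    __slots__ = ("root", "max_leaves")

    def __init__(self, root, max_leaves: int = 8):
        self.root = root
        self.max_leaves = max_leaves
        if self.n_leaves > max_leaves:
            raise ValueError(f"tree has {self.n_leaves} leaves, cap is {max_leaves}")

    # -- structure ---------------------------------------------------------

    @classmethod
    def single_leaf(cls, literal: Literal, max_leaves: int = 8) -> "LogicTree":
        return cls(_Leaf(literal), max_leaves)

    def copy(self) -> "LogicTree":
        return LogicTree(_copy_node(self.root), self.max_leaves)

    def _nodes(self):
        """(node, parent, is_left) triples in preorder."""
        out = []
        stack = [(self.root, None, False)]
        while stack:
            node, parent, is_left = stack.pop()
            out.append((node, parent, is_left))
            if isinstance(node, _Op):
                stack.append((node.left, node, True))
                stack.append((node.right, node, False))
        return out

    @property
    def n_leaves(self) -> int:
        return sum(1 for n, _, _ in self._nodes() if isinstance(n, _Leaf))

    @property
    def leaves(self) -> list[Literal]:
        return [n.literal for n, _, _ in self._nodes() if isinstance(n, _Leaf)]

    @property
    def predictor_indices(self) -> frozenset[int]:
        return frozenset(lit.predictor_index for lit in self.leaves)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Per-row 0/1 prediction on a binary predictor table."""
        X = np.asarray(X)

        def rec(node):
            if isinstance(node, _Leaf):
                col = X[:, node.literal.predictor_index].astype(bool)
                return ~col if node.literal.complemented else col
            a, b = rec(node.left), rec(node.right)
            return (a & b) if node.op == "and" else (a | b)

        return rec(self.root).astype(np.uint8)

    def evaluate_bits(self, cols: list[int], mask: int) -> int:
        """Evaluate on bit-packed columns (bit i = subject i); returns a bitmask."""

        def rec(node):
            if isinstance(node, _Leaf):
                v = cols[node.literal.predictor_index]
                return (v ^ mask) if node.literal.complemented else v
            a, b = rec(node.left), rec(node.right)
            return (a & b) if node.op == "and" else (a | b)

        return rec(self.root)

    # -- serialisation -----------------------------------------------------

    def to_text(self, names: list[str] | None = None) -> str:
        def nm(i):
            return names[i] if names is not None else f"x{i}"

        def rec(node):
            if isinstance(node, _Leaf):
                lit = node.literal
                return ("!" if lit.complemented else "") + nm(lit.predictor_index)
            joiner = " AND " if node.op == "and" else " OR "
            return "(" + rec(node.left) + joiner + rec(node.right) + ")"

        return rec(self.root)

    @classmethod
    def from_text(cls, text: str, names: list[str] | None = None, max_leaves: int = 8) -> "LogicTree":
        name_to_idx = {n: i for i, n in enumerate(names)} if names is not None else None
        tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        pos = 0

        def expect(tok):
            nonlocal pos
            if pos >= len(tokens) or tokens[pos] != tok:
                raise ValueError(f"expected {tok!r} at token {pos} of {text!r}")
            pos += 1

        def leaf(tok) -> _Leaf:
            comp = tok.startswith("!")
            name = tok[1:] if comp else tok
            if name_to_idx is not None:
                idx = name_to_idx[name]
            else:
                if not name.startswith("x"):
                    raise ValueError(f"cannot resolve predictor name {name!r} without a name list")
                idx = int(name[1:])
            return _Leaf(Literal(idx, comp))

        def rec():
            nonlocal pos
            if tokens[pos] == "(":
                expect("(")
                left = rec()
                op = tokens[pos].lower()
                if op not in ("and", "or"):
                    raise ValueError(f"expected AND/OR, got {tokens[pos]!r}")
                pos += 1
                right = rec()
                expect(")")
                return _Op(op, left, right)
            node = leaf(tokens[pos])
            pos += 1
            return node

        root = rec()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in {text!r}")
        return cls(root, max_leaves)

    def to_json(self) -> dict:
        def rec(node):
            if isinstance(node, _Leaf):
                return {"leaf": node.literal.predictor_index, "comp": node.literal.complemented}
            return {"op": node.op, "left": rec(node.left), "right": rec(node.right)}

        return {"max_leaves": self.max_leaves, "root": rec(self.root)}

    @classmethod
    def from_json(cls, obj: dict) -> "LogicTree":
        def rec(d):
            if "leaf" in d:
                return _Leaf(Literal(int(d["leaf"]), bool(d["comp"])))
            return _Op(d["op"], rec(d["left"]), rec(d["right"]))

        return cls(rec(obj["root"]), int(obj.get("max_leaves", 8)))

    def __repr__(self) -> str:
        return f"LogicTree({self.to_text()})"


# ---------------------------------------------------------------------------
# prime implicants


@dataclass(frozen=True)
class PrimeImplicant:
    """A conjunction of literals, canonicalised for cross-tree identity."""

    literals: tuple[Literal, ...]

    def __post_init__(self):
        canon = tuple(sorted(set(self.literals)))
        idxs = [l.predictor_index for l in canon]
        if len(set(idxs)) != len(idxs):
            raise ValueError("prime implicant contains a predictor and its complement")
        object.__setattr__(self, "literals", canon)

    @property
    def canonical_key(self) -> tuple:
        return self.literals

    @property
    def predictor_indices(self) -> frozenset[int]:
        return frozenset(l.predictor_index for l in self.literals)

    @property
    def order(self) -> int:
        return len(self.literals)

    def indicator(self, X: np.ndarray) -> np.ndarray:
        """Per-row 0/1: does the row satisfy every literal of the conjunction?"""
        X = np.asarray(X)
        out = np.ones(X.shape[0], dtype=bool)
        for lit in self.literals:
            col = X[:, lit.predictor_index].astype(bool)
            out &= ~col if lit.complemented else col
        return out.astype(np.uint8)

    def render(self, descriptors=None) -> str:
        parts = []
        for lit in self.literals:
            if descriptors is not None:
                parts.append(descriptors[lit.predictor_index].render(lit.complemented))
            else:
                parts.append(("!" if lit.complemented else "") + f"x{lit.predictor_index}")
        return " & ".join(parts)

    def __str__(self) -> str:
        return self.render()


def to_dnf(tree: LogicTree) -> list[PrimeImplicant]:
    """Disjunctive normal form of a tree as a list of prime implicants.

    Recursive distribution of AND over OR; contradictory terms (a literal
    and its complement) are dropped, duplicate literals merged, and
    absorbed terms (supersets of another term) removed.  The resulting OR
    of ANDs is logically equivalent to the tree.
    """

    def rec(node) -> list[frozenset[Literal]]:
        if isinstance(node, _Leaf):
            return [frozenset((node.literal,))]
        left, right = rec(node.left), rec(node.right)
        if node.op == "or":
            return left + right
        out = []
        for a in left:
            for b in right:
                term = a | b
                idxs = [l.predictor_index for l in term]
                if len(set(idxs)) != len(idxs):
                    continue  # contains x and !x: constant false
                out.append(term)
        return out

    terms = rec(tree.root)
    # dedupe + absorption: keep minimal terms only
    unique = sorted(set(terms), key=len)
    kept: list[frozenset[Literal]] = []
    for t in unique:
        if not any(k < t or k == t for k in kept):
            kept.append(t)
    return sorted(
        (PrimeImplicant(tuple(t)) for t in kept),
        key=lambda pi: pi.canonical_key,
    )


def evaluate(tree: LogicTree, X: np.ndarray) -> np.ndarray:
    return tree.evaluate(X)


def score(tree: LogicTree, dataset) -> float:
    """Misclassification fraction of the tree on a dataset (mean (y - yhat)^2)."""
    yhat = tree.evaluate(dataset.X)
    return float(np.mean((dataset.y.astype(int) - yhat.astype(int)) ** 2))


# ---------------------------------------------------------------------------
# moves


_MOVES = (
    "alternate_leaf",
    "alternate_complement",
    "alternate_operator",
    "grow_branch",
    "prune_branch",
    "split_leaf",
    "delete_leaf",
)


def _as_python_random(rng) -> random.Random:
    if isinstance(rng, random.Random):
        return rng
    if isinstance(rng, np.random.Generator):
        return random.Random(int(rng.integers(0, 2**63)))
    if rng is None:
        return random.Random()
    return random.Random(int(rng))


def legal_moves(tree: LogicTree) -> list[str]:
    nl = tree.n_leaves
    moves = ["alternate_leaf", "alternate_complement"]
    if nl > 1:
        moves += ["alternate_operator", "prune_branch", "delete_leaf"]
        if nl < tree.max_leaves:
            moves.append("grow_branch")
    if nl < tree.max_leaves:
        moves.append("split_leaf")
    return moves


def _random_literal(p: int, rnd: random.Random) -> Literal:
    return Literal(rnd.randrange(p), rnd.random() < 0.5)


def propose_move(tree: LogicTree, rng, p: int | None = None) -> LogicTree:
    """One random legal move from the classical logic-regression move set.

    ``p`` is the number of available predictors; by default the largest
    index already in the tree plus one (callers fitting to data should pass
    the true predictor count).  Never returns an empty tree and never
    exceeds ``max_leaves``.
    """
    rnd = _as_python_random(rng)
    if p is None:
        p = max(tree.predictor_indices) + 1
    new = tree.copy()
    move = rnd.choice(legal_moves(new))
    nodes = new._nodes()
    leaves = [(n, par, is_l) for n, par, is_l in nodes if isinstance(n, _Leaf)]
    internals = [(n, par, is_l) for n, par, is_l in nodes if isinstance(n, _Op)]

    if move == "alternate_leaf":
        leaf, _, _ = rnd.choice(leaves)
        old = leaf.literal
        while True:
            lit = _random_literal(p, rnd)
            if lit != old or p == 1:
                break
        leaf.literal = lit
    elif move == "alternate_complement":
        leaf, _, _ = rnd.choice(leaves)
        leaf.literal = Literal(leaf.literal.predictor_index, not leaf.literal.complemented)
    elif move == "alternate_operator":
        node, _, _ = rnd.choice(internals)
        node.op = "or" if node.op == "and" else "and"
    elif move == "split_leaf":
        leaf, parent, is_left = rnd.choice(leaves)
        repl = _Op(rnd.choice(("and", "or")), _Leaf(leaf.literal), _Leaf(_random_literal(p, rnd)))
        _replace_child(new, parent, is_left, repl)
    elif move == "grow_branch":
        node, parent, is_left = rnd.choice(internals)
        repl = _Op(rnd.choice(("and", "or")), node, _Leaf(_random_literal(p, rnd)))
        _replace_child(new, parent, is_left, repl)
    elif move == "prune_branch":
        node, parent, is_left = rnd.choice(internals)
        child = node.left if rnd.random() < 0.5 else node.right
        _replace_child(new, parent, is_left, child)
    elif move == "delete_leaf":
        leaf, parent, is_left = rnd.choice(leaves)
        # parent is an _Op because n_leaves > 1
        sibling = parent.right if is_left else parent.left
        gp = next((par, il) for n, par, il in nodes if n is parent)
        _replace_child(new, gp[0], gp[1], sibling)
    return new


def _replace_child(tree: LogicTree, parent, is_left: bool, repl) -> None:
    if parent is None:
        tree.root = repl
    elif is_left:
        parent.left = repl
    else:
        parent.right = repl


# ---------------------------------------------------------------------------
# fitting


@dataclass
class AnnealingSchedule:
    """Simulated-annealing controls for tree fitting.

    The start temperature is calibrated on a pilot of random moves so that
    roughly half of the worsening moves would be accepted; cooling is
    geometric down to a temperature at which fewer than 1% of typical
    worsening moves are accepted.  Explicit ``t_start``/``t_end`` override
    the calibration.
    """

    n_iter: int = 25_000
    pilot: int = 100
    t_start: float | None = None
    t_end: float | None = None

    @classmethod
    def fast(cls, n_iter: int = 600) -> "AnnealingSchedule":
        """Short schedule for permutation refits and small search spaces."""
        return cls(n_iter=n_iter, pilot=50)


def pack_columns(X: np.ndarray) -> tuple[list[int], int, int]:
    """Bit-pack each predictor column: bit i of column j is X[i, j]."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.uint8))
    n = X.shape[0]
    mask = (1 << n) - 1
    cols = [
        int.from_bytes(np.packbits(X[:, j], bitorder="little").tobytes(), "little")
        for j in range(X.shape[1])
    ]
    return cols, mask, n


def pack_vector(y: np.ndarray) -> int:
    return int.from_bytes(np.packbits(np.asarray(y, dtype=np.uint8), bitorder="little").tobytes(), "little")


def fit_tree(
    dataset,
    max_leaves: int = 8,
    schedule: AnnealingSchedule | None = None,
    rng=None,
) -> LogicTree:
    """Fit a logic tree by simulated annealing, minimising misclassification.

    Starts from a random single leaf; accepts worsening moves with
    probability exp(-delta/t) under geometric cooling; returns the
    best-scoring tree visited, preferring fewer leaves on ties.
    Bit-reproducible under a fixed ``rng``.
    """
    schedule = schedule or AnnealingSchedule()
    rnd = _as_python_random(rng)
    X, y = dataset.X, dataset.y
    n, p = X.shape
    if n == 0 or p == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    cols, mask, _ = pack_columns(X)
    ybits = pack_vector(y)

    if y.min() == y.max():
        warnings.warn("outcome is constant; returning a best-effort single-leaf tree")

    def tree_score(t: LogicTree) -> float:
        return (t.evaluate_bits(cols, mask) ^ ybits).bit_count() / n

    current = LogicTree.single_leaf(_random_literal(p, rnd), max_leaves)
    cur_score = tree_score(current)
    best, best_score, best_leaves = current.copy(), cur_score, current.n_leaves

    def consider_best(t: LogicTree, s: float) -> None:
        nonlocal best, best_score, best_leaves
        nl = t.n_leaves
        if s < best_score - 1e-12 or (abs(s - best_score) <= 1e-12 and nl < best_leaves):
            best, best_score, best_leaves = t.copy(), s, nl

    # pilot: calibrate temperature from the spread of worsening deltas
    if schedule.t_start is None or schedule.t_end is None:
        probe, probe_score = current.copy(), cur_score
        deltas = []
        for _ in range(schedule.pilot):
            cand = propose_move(probe, rnd, p)
            s = tree_score(cand)
            if s > probe_score:
                deltas.append(s - probe_score)
            probe, probe_score = cand, s
            consider_best(probe, probe_score)
        typical = sorted(deltas)[len(deltas) // 2] if deltas else 1.0 / n
        t_start = schedule.t_start if schedule.t_start is not None else typical / math.log(2.0)
        t_end = schedule.t_end if schedule.t_end is not None else typical / math.log(100.0)
        t_end = min(t_end, t_start)
        # the pilot walk is exploratory only: restart the chain at a fresh leaf
        current = LogicTree.single_leaf(_random_literal(p, rnd), max_leaves)
        cur_score = tree_score(current)
        consider_best(current, cur_score)
    else:
        t_start, t_end = schedule.t_start, schedule.t_end

    n_iter = max(1, schedule.n_iter)
    ratio = (t_end / t_start) ** (1.0 / n_iter) if t_start > 0 else 1.0
    t = t_start
    for _ in range(n_iter):
        cand = propose_move(current, rnd, p)
        s = tree_score(cand)
        delta = s - cur_score
        if delta <= 0 or (t > 0 and rnd.random() < math.exp(-delta / t)):
            current, cur_score = cand, s
            consider_best(current, cur_score)
        t *= ratio
    return best
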