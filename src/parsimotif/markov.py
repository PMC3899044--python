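"""Homogeneous Markov models, parsimonious context trees, and parsimonious
Markov motif models.

A parsimonious context tree (PCT) of depth ``d`` describes which of the
``d`` preceding positions matter for the nucleotide at a motif position,
and at which resolution.  Every inner node partitions the alphabet
{A, C, G, T} into child subsets; a leaf (always at depth ``d``) aggregates
the product set of the subsets along its path and carries one conditional
distribution.  A depth-``d`` PCT therefore interpolates between a single
leaf (the position ignores its context: PWM behaviour) and ``4**d`` leaves
(a full order-``d`` inhomogeneous Markov model).

Structure learning is exact MAP: the score of a tree is the sum of
Dirichlet-multinomial log marginals over its leaves plus ``L(tau) * ln(kappa)``
for a structure prior proportional to ``kappa ** n_leaves``.  The optimum is
found by a bottom-up dynamic program over the lattice of context product
sets; since |A| = 4, each inner node chooses among the 15 set partitions of
the alphabet.

An inhomogeneous parsimonious Markov model (PMM) of width W and maximal
order d is a sequence of W PCTs with depth ``min(i-1, d)`` at position i,
so position 1 always has a single leaf.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from ._seq import ALPHABET, context_index, encode

__all__ = [
    "HomogeneousMarkovModel",
    "fit_homogeneous_mm",
    "mm_log_prob",
    "leaf_log_marginal",
    "PCT",
    "PCTLeaf",
    "learn_pct",
    "pct_lookup",
    "InhomogeneousPMM",
    "fit_pmm",
    "pmm_log_prob",
    "leaf_statistics",
]

LN2 = math.log(2.0)

# ---------------------------------------------------------------------------
# alphabet subsets and set partitions (precomputed once)
# ---------------------------------------------------------------------------

# Non-empty subsets of {0,1,2,3} as sorted tuples, indexed 0..14.
SUBSETS: list[tuple[int, ...]] = [
    tuple(i for i in range(4) if (mask >> i) & 1) for mask in range(1, 16)
]
_SUBSET_INDEX = {s: i for i, s in enumerate(SUBSETS)}
_SUBSET_LABEL = ["".join(ALPHABET[i] for i in s) for s in SUBSETS]

# 0/1 membership matrix: MEMBER[s, a] == 1 iff symbol a is in subset s.
_MEMBER = np.zeros((15, 4))
for _s, _tup in enumerate(SUBSETS):
    _MEMBER[_s, list(_tup)] = 1.0
_SIZES = _MEMBER.sum(axis=1)


def _set_partitions() -> list[tuple[int, ...]]:
    """All 15 set partitions of {0,1,2,3}, each as a tuple of subset indices.

    Sorted by (number of blocks, block labels), which fixes the
    deterministic tie-break of the structure search: fewer blocks first,
    then lexicographic order of the sorted subset labels.
    """
    def rec(elems):
        if not elems:
            yield []
            return
        head, rest = elems[0], elems[1:]
        for k in range(len(rest) + 1):
            for others in itertools.combinations(rest, k):
                block = tuple(sorted((head,) + others))
                remaining = [e for e in rest if e not in others]
                for sub in rec(remaining):
                    yield [block] + sub

    parts = []
    for blocks in rec([0, 1, 2, 3]):
        blocks = sorted(blocks, key=lambda b: _SUBSET_LABEL[_SUBSET_INDEX[b]])
        parts.append(tuple(_SUBSET_INDEX[b] for b in blocks))
    parts = sorted(
        set(parts),
        key=lambda p: (len(p), tuple(_SUBSET_LABEL[b] for b in p)),
    )
    assert len(parts) == 15
    return parts


PARTITIONS: list[tuple[int, ...]] = _set_partitions()


# ---------------------------------------------------------------------------
# homogeneous Markov model (flanking / background)
# ---------------------------------------------------------------------------


class HomogeneousMarkovModel:
    """Homogeneous Markov chain over {A,C,G,T} with Dirichlet smoothing.

    Conditional distributions exist for every context length ``k`` from 0 to
    ``order``; the short-context tables are used for the first symbols of a
    sequence (or resolved from a supplied prefix).  Symmetric Dirichlet
    smoothing uses ``ess / 4**(k+1)`` pseudocounts per (context, symbol)
    cell, so the total prior mass is ``ess`` at every context length.
    """

    def __init__(self, order: int, counts: list[np.ndarray], ess: float = 4.0):
        if order < 0:
            raise ValueError("order must be >= 0")
        self.order = order
        self.ess = float(ess)
        self.counts = [np.asarray(c, dtype=float) for c in counts]
        self.cond_probs: list[np.ndarray] = []
        self.log_tables: list[np.ndarray] = []
        for k, cnt in enumerate(self.counts):
            alpha = ess / 4 ** (k + 1)
            denom = cnt.sum(axis=-1, keepdims=True) + 4 * alpha
            with np.errstate(invalid="ignore"):
                probs = (cnt + alpha) / denom
            # unobserved contexts with ess = 0: fall back to uniform
            probs = np.where(denom > 0, probs, 0.25)
            self.cond_probs.append(probs)
            with np.errstate(divide="ignore"):
                self.log_tables.append(np.log(probs))

    # -- scoring ------------------------------------------------------------

    def per_symbol_log_prob(self, codes: np.ndarray, prefix: np.ndarray | None = None) -> np.ndarray:
        """log P(x_t | context) for every position of ``codes``.

        ``prefix`` supplies left context (e.g. when the flanking model
        resumes after a motif window); without it, positions with fewer
        than ``order`` predecessors fall back to the short-context tables.
        """
        codes = np.asarray(codes, dtype=np.int64)
        n = codes.size
        out = np.empty(n)
        npre = 0 if prefix is None else len(prefix)
        full = codes if npre == 0 else np.concatenate([np.asarray(prefix, dtype=np.int64), codes])
        k = self.order
        # positions (in `full` coordinates) with a complete order-k context
        t0 = max(npre, k)
        if t0 < npre + n and k > 0:
            from numpy.lib.stride_tricks import sliding_window_view

            win = sliding_window_view(full, k)[t0 - k : npre + n - k]
            # column m holds full[t-k+m]; nearest predecessor (m=k-1) gets the
            # highest power, matching context_index's layer-order convention
            powers = 4 ** np.arange(k, dtype=np.int64)
            ctx = win.astype(np.int64) @ powers
            out[t0 - npre :] = self.log_tables[k][ctx, full[t0:]]
        elif k == 0:
            out[:] = self.log_tables[0][0, full[npre:]]
            return out
        # leading positions with short contexts
        for t in range(npre, min(t0, npre + n)):
            m = min(t, k)
            ctx_syms = full[t - m : t][::-1]  # nearest predecessor first
            idx = 0
            for j, s in enumerate(ctx_syms):
                idx += int(s) * 4 ** (m - 1 - j)
            out[t - npre] = self.log_tables[m][idx, full[t]]
        return out

    def log_prob(self, seq, start: int = 0, end: int | None = None, prefix=None) -> float:
        codes = encode(seq) if isinstance(seq, str) else np.asarray(seq)
        if end is None:
            end = codes.size
        if not (0 <= start <= end <= codes.size):
            raise ValueError("invalid [start, end) range")
        if start == end:
            return 0.0
        pre = codes[:start]
        if prefix is not None:
            pre = np.concatenate([np.asarray(prefix, dtype=np.int64), pre])
        return float(self.per_symbol_log_prob(codes[start:end], prefix=pre).sum())

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "homogeneous_mm",
            "order": self.order,
            "ess": self.ess,
            "counts": [c.tolist() for c in self.counts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HomogeneousMarkovModel":
        return cls(d["order"], [np.asarray(c) for c in d["counts"]], d["ess"])


def fit_homogeneous_mm(records, order: int, ess: float = 4.0) -> HomogeneousMarkovModel:
    """Estimate a homogeneous Markov model from sequences.

    Context length ``order`` counts come from all positions with a full
    context; each shorter context length ``k`` is estimated from the
    sequence-initial position ``t = k``.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    seqs = [r.seq if hasattr(r, "seq") else r for r in records]
    if not seqs:
        raise ValueError("no sequences")
    counts = [np.zeros((4**k, 4)) for k in range(order + 1)]
    for s in seqs:
        codes = encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.int64)
        n = codes.size
        for k in range(min(order, n)):
            ctx_syms = codes[:k][::-1]
            idx = int(context_index(ctx_syms[None, :])[0]) if k else 0
            counts[k][idx, codes[k]] += 1
        if n > order:
            k = order
            if k == 0:
                np.add.at(counts[0], (0, codes), 1)
            else:
                from numpy.lib.stride_tricks import sliding_window_view

                win = sliding_window_view(codes, k)[: n - k]
                powers = 4 ** np.arange(k, dtype=np.int64)
                ctx = win.astype(np.int64) @ powers
                flat = np.bincount(ctx * 4 + codes[k:], minlength=4 ** (k + 1))
                counts[k] += flat.reshape(4**k, 4)
    return HomogeneousMarkovModel(order, counts, ess)


def mm_log_prob(model: HomogeneousMarkovModel, seq, start: int = 0, end: int | None = None, given_prefix=None) -> float:
    """log probability of ``seq[start:end]`` under ``model`` (chain rule).

    ``given_prefix`` supplies context symbols preceding ``seq`` itself.
    """
    pre = None
    if given_prefix is not None:
        pre = encode(given_prefix) if isinstance(given_prefix, str) else np.asarray(given_prefix)
    return model.log_prob(seq, start, end, prefix=pre)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial leaf score
# ---------------------------------------------------------------------------


def leaf_log_marginal(counts, alpha) -> float:
    """log of the Dirichlet-multinomial marginal B(alpha+counts)/B(alpha).

    ``counts`` may be fractional (expected counts from EM); ``alpha`` is a
    scalar (symmetric) or a length-4 vector of positive hyperparameters.
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), counts.shape)
    if (alpha <= 0).any():
        raise ValueError("all Dirichlet hyperparameters must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return float(
        gammaln(alpha + counts).sum()
        - gammaln((alpha + counts).sum())
        - gammaln(alpha).sum()
        + gammaln(alpha.sum())
    )


def _leaf_scores_vec(counts: np.ndarray, alpha: np.ndarray, score: str) -> np.ndarray:
    """Vectorized leaf score; ``counts`` (..., 4), ``alpha`` (...) per symbol."""
    a = alpha[..., None]
    post = counts + a
    tot = post.sum(axis=-1)
    if score == "marginal":
        return (
            gammaln(post).sum(axis=-1)
            - gammaln(tot)
            - 4 * gammaln(alpha)
            + gammaln(4 * alpha)
        )
    elif score == "map":
        # profile score: plug the posterior-mean thetas back in
        theta = post / tot[..., None]
        return (post * np.log(theta)).sum(axis=-1)
    raise ValueError(f"unknown leaf score {score!r}")


# ---------------------------------------------------------------------------
# parsimonious context trees
# ---------------------------------------------------------------------------


@dataclass
class PCTLeaf:
    """One leaf: its path of alphabet subsets and the leaf distribution."""

    path: tuple[tuple[int, ...], ...]  # subsets, layer 1 (nearest) first
    counts: np.ndarray  # aggregated (possibly fractional) symbol counts, (4,)
    alpha: float  # per-symbol Dirichlet hyperparameter
    theta: np.ndarray  # posterior-mean conditional distribution, (4,)

    @property
    def n_contexts(self) -> int:
        return int(np.prod([len(b) for b in self.path])) if self.path else 1

    def context_words(self) -> list[tuple[int, ...]]:
        """All context words (layer order: nearest predecessor first)."""
        if not self.path:
            return [()]
        return [tuple(w) for w in itertools.product(*self.path)]

    def label(self) -> str:
        """Human-readable context, written in sequence order (as in figures)."""
        if not self.path:
            return "*"
        return "-".join("".join(ALPHABET[i] for i in b) for b in reversed(self.path))


@dataclass
class PCT:
    """A learned parsimonious context tree.

    ``leaves`` are in deterministic depth-first order (the order used for
    Roman-numeral context labels in conditional sequence logos);
    ``leaf_of_context`` maps a flattened context word (nearest predecessor
    most significant, see :func:`parsimotif._seq.context_index`) to its
    leaf index.
    """

    depth: int
    leaves: list[PCTLeaf]
    score: float
    log2_kappa: float
    ess: float
    leaf_of_context: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.leaf_of_context is None:
            table = np.empty(4**self.depth, dtype=np.int64)
            for li, leaf in enumerate(self.leaves):
                for word in leaf.context_words():
                    table[int(context_index(np.asarray(word, dtype=np.int64)[None, :])[0])] = li
            self.leaf_of_context = table
        # partition sanity
        assert self.leaf_of_context.size == 4**self.depth
        total_ctx = sum(l.n_contexts for l in self.leaves)
        assert total_ctx == 4**self.depth

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def log_theta_table(self) -> np.ndarray:
        """Expanded (4**depth, 4) table of log conditional probabilities."""
        thetas = np.stack([l.theta for l in self.leaves])
        with np.errstate(divide="ignore"):
            return np.log(thetas)[self.leaf_of_context]

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "score": self.score,
            "log2_kappa": self.log2_kappa,
            "ess": self.ess,
            "leaves": [
                {
                    "path": ["".join(ALPHABET[i] for i in b) for b in l.path],
                    "counts": l.counts.tolist(),
                    "alpha": l.alpha,
                    "theta": l.theta.tolist(),
                }
                for l in self.leaves
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCT":
        leaves = [
            PCTLeaf(
                path=tuple(tuple(ALPHABET.index(ch) for ch in b) for b in ld["path"]),
                counts=np.asarray(ld["counts"], dtype=float),
                alpha=float(ld["alpha"]),
                theta=np.asarray(ld["theta"], dtype=float),
            )
            for ld in d["leaves"]
        ]
        return cls(d["depth"], leaves, d["score"], d["log2_kappa"], d["ess"])


def learn_pct(
    context_counts,
    depth: int,
    log2_kappa: float,
    ess: float = 4.0,
    score: str = "marginal",
) -> PCT:
    """Exact MAP structure learning of a depth-``depth`` PCT.

    ``context_counts`` is an array of shape ``(4,)*depth + (4,)``: axis j
    indexes the (j+1)-th preceding symbol, the last axis the symbol itself.
    Fractional (expected) counts are fine.

    The objective is ``sum_leaves leaf_score(aggregated counts, alpha_leaf)
    + n_leaves * ln(2**log2_kappa)`` with BDeu-style hyperparameters
    ``alpha_leaf = ess * |context_set| / 4**(depth+1)`` per symbol, and
    ``leaf_score`` either the Dirichlet-multinomial log marginal
    (``score="marginal"``, the default) or the plug-in profile score used
    inside EM (``score="map"``).

    The search is exact: a bottom-up pass computes, for every product set of
    alphabet subsets, the best subtree score, choosing at each inner node
    the best of the 15 set partitions of {A,C,G,T}.  Ties prefer fewer
    blocks, then lexicographically smaller subset labels.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    N = np.asarray(context_counts, dtype=float)
    if N.shape != (4,) * depth + (4,):
        raise ValueError(f"context_counts must have shape {(4,)*depth + (4,)}")
    ln_kappa = log2_kappa * LN2
    d = depth

    # aggregate counts over every product set of subsets: shape (15,)*d + (4,)
    X = N
    for j in range(d):
        X = np.moveaxis(np.tensordot(_MEMBER, X, axes=(1, j)), 0, j)
    # product-set sizes: shape (15,)*d
    P = np.ones(())
    for _ in range(d):
        P = np.multiply.outer(P, _SIZES)
    alpha = ess * P / 4 ** (d + 1)

    S: list[np.ndarray] = [None] * (d + 1)
    S[d] = _leaf_scores_vec(X, alpha, score) + ln_kappa
    for j in range(d - 1, -1, -1):
        child = S[j + 1]  # shape (15,)*j + (15,)
        best = None
        for part in PARTITIONS:
            v = child[..., part[0]].copy()
            for b in part[1:]:
                v += child[..., b]
            best = v if best is None else np.maximum(best, v)
        S[j] = best

    root_score = float(S[0])

    # reconstruct the argmax tree, visiting only nodes on the optimal paths
    leaves: list[PCTLeaf] = []

    def descend(path_idx: tuple[int, ...]) -> None:
        j = len(path_idx)
        if j == d:
            cnt = X[path_idx] if d else X
            a = float(alpha[path_idx]) if d else float(alpha)
            theta = (cnt + a) / (cnt.sum() + 4 * a)
            leaves.append(
                PCTLeaf(
                    path=tuple(SUBSETS[s] for s in path_idx),
                    counts=np.asarray(cnt, dtype=float).copy(),
                    alpha=a,
                    theta=theta,
                )
            )
            return
        child = S[j + 1][path_idx]  # (15,)
        part_scores = [sum(float(child[b]) for b in part) for part in PARTITIONS]
        best = max(part_scores)
        tol = 1e-9 * max(1.0, abs(best))
        for part, sc in zip(PARTITIONS, part_scores):
            if sc >= best - tol:
                for b in part:
                    descend(path_idx + (b,))
                return

    descend(())
    return PCT(depth=d, leaves=leaves, score=root_score, log2_kappa=log2_kappa, ess=ess)


def pct_lookup(pct: PCT, context) -> PCTLeaf:
    """Return the unique leaf whose context set contains ``context``.

    ``context`` may be a string in sequence order (last character = nearest
    predecessor, as context words are printed in figures) or a tuple/array
    of codes in layer order (nearest predecessor first).
    """
    if isinstance(context, str):
        codes = np.asarray([ALPHABET.index(ch) for ch in reversed(context.upper())], dtype=np.int64)
    else:
        codes = np.asarray(context, dtype=np.int64)
    if codes.size != pct.depth:
        raise ValueError(f"context length {codes.size} != tree depth {pct.depth}")
    idx = int(context_index(codes[None, :])[0]) if pct.depth else 0
    return pct.leaves[int(pct.leaf_of_context[idx])]


# ---------------------------------------------------------------------------
# inhomogeneous parsimonious Markov motif model
# ---------------------------------------------------------------------------


@dataclass
class InhomogeneousPMM:
    """Width-W motif model: one PCT per position, depth ``min(i-1, d)``."""

    width: int
    max_order: int
    log2_kappa: float
    ess: float
    pcts: list[PCT]

    def __post_init__(self):
        assert len(self.pcts) == self.width
        for i, pct in enumerate(self.pcts):
            assert pct.depth == min(i, self.max_order), "depth rule violated"
        self._tables = None

    @property
    def total_leaves(self) -> int:
        return sum(p.n_leaves for p in self.pcts)

    def tables(self) -> list[np.ndarray]:
        """Per-position expanded log-theta tables, cached."""
        if self._tables is None:
            self._tables = [p.log_theta_table() for p in self.pcts]
        return self._tables

    def log_prob_words(self, words: np.ndarray) -> np.ndarray:
        """Vectorized log probability for an (n, W) array of encoded words."""
        words = np.asarray(words, dtype=np.int64)
        if words.ndim == 1:
            words = words[None, :]
        if words.shape[1] != self.width:
            raise ValueError("word length must equal model width")
        out = np.zeros(words.shape[0])
        tabs = self.tables()
        for i in range(self.width):
            d = min(i, self.max_order)
            ctx = context_index(words[:, i - d : i][:, ::-1]) if d else np.zeros(words.shape[0], dtype=np.int64)
            out += tabs[i][ctx, words[:, i]]
        return out

    def to_dict(self) -> dict:
        return {
            "type": "inhomogeneous_pmm",
            "width": self.width,
            "max_order": self.max_order,
            "log2_kappa": self.log2_kappa,
            "ess": self.ess,
            "pcts": [p.to_dict() for p in self.pcts],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InhomogeneousPMM":
        return cls(
            d["width"], d["max_order"], d["log2_kappa"], d["ess"],
            [PCT.from_dict(p) for p in d["pcts"]],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InhomogeneousPMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _encode_sites(sites) -> np.ndarray:
    if isinstance(sites, np.ndarray):
        return np.asarray(sites, dtype=np.int64)
    return np.stack([encode(s.seq if hasattr(s, "seq") else s) for s in sites]).astype(np.int64)


def position_context_counts(
    words: np.ndarray, i: int, depth: int, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted (context, symbol) count tensor for motif position ``i`` (0-based)."""
    n = words.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    ctx = context_index(words[:, i - depth : i][:, ::-1]) if depth else np.zeros(n, dtype=np.int64)
    flat = np.bincount(ctx * 4 + words[:, i], weights=w, minlength=4 ** (depth + 1))
    return flat.reshape((4,) * depth + (4,))


def fit_pmm(
    sites,
    width: int,
    max_order: int = 4,
    log2_kappa: float = 0.0,
    ess: float = 4.0,
    weights=None,
    score: str = "marginal",
) -> InhomogeneousPMM:
    """Fit a PMM to aligned width-``width`` words with optional weights.

    Per position, aggregates (possibly fractional) context counts over the
    ``min(i-1, max_order)`` preceding motif positions and runs the exact
    PCT structure search; leaf distributions are posterior means.
    """
    words = _encode_sites(sites)
    if words.shape[1] != width:
        raise ValueError(f"site length {words.shape[1]} != width {width}")
    pcts = []
    for i in range(width):
        d = min(i, max_order)
        counts = position_context_counts(words, i, d, weights)
        pcts.append(learn_pct(counts, d, log2_kappa, ess, score=score))
    return InhomogeneousPMM(width, max_order, log2_kappa, ess, pcts)


def pmm_log_prob(pmm: InhomogeneousPMM, word) -> float:
    """log probability of a single width-W word under the motif model."""
    codes = encode(word) if isinstance(word, str) else np.asarray(word, dtype=np.int64)
    return float(pmm.log_prob_words(codes[None, :])[0])


def leaf_statistics(pmm: InhomogeneousPMM) -> tuple[list[tuple[int, int]], int]:
    """Per-position (1-based) leaf counts and their total."""
    per_pos = [(i + 1, p.n_leaves) for i, p in enumerate(pmm.pcts)]
    return per_pos, sum(n for _, n in per_pos)
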