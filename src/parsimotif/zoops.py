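"""ZOOPS mixture model and the MAP-EM motif discovery algorithm.

The generative model for one sequence x of length L: with probability
``1 - gamma`` the whole sequence is emitted by a fixed homogeneous flanking
Markov model; with probability ``gamma`` a start position ell (uniform over
the ``L - W + 1`` valid starts) and a strand s (forward with probability
``strand_prob``) are drawn, the width-W window at ell is emitted by the
motif model (its reverse complement for the minus strand), and the rest by
the flanking model.  After the motif, the flanking chain conditions on the
actual observed symbols (the site's last ``order`` bases), which keeps the
joint distribution properly normalized.

Fitting maximizes the posterior density (likelihood times Dirichlet
pseudocount priors on motif leaves and occurrence probability, times the
structure prior ``kappa**n_leaves``) by EM over the latent occurrence,
position, and strand variables.  The M-step re-learns the PCT structures
from the expected counts (structural EM); structures and leaf parameters
maximize the same expected complete-data posterior, so the log posterior
trace is non-decreasing.

The user-facing entry point is the statsmodels-style pair
:class:`MotifDiscovery` / :class:`MotifDiscoveryResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode
from .markov import (
    LN2,
    HomogeneousMarkovModel,
    InhomogeneousPMM,
    fit_homogeneous_mm,
    learn_pct,
    leaf_statistics,
)

__all__ = [
    "ZOOPSModel",
    "ZOOPSConfig",
    "EMTrace",
    "Responsibilities",
    "zoops_log_likelihood",
    "e_step",
    "m_step",
    "fit_zoops_em",
    "MotifDiscovery",
    "MotifDiscoveryResults",
]

NEG_INF = -np.inf


@dataclass
class ZOOPSModel:
    """Motif model + fixed flanking model + latent-variable priors."""

    motif: InhomogeneousPMM
    flanking: HomogeneousMarkovModel
    gamma: float
    strand_prob: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if not (0.0 <= self.strand_prob <= 1.0):
            raise ValueError("strand_prob must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.motif.width

    def to_dict(self) -> dict:
        return {
            "type": "zoops",
            "gamma": self.gamma,
            "strand_prob": self.strand_prob,
            "motif": self.motif.to_dict(),
            "flanking": self.flanking.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZOOPSModel":
        return cls(
            InhomogeneousPMM.from_dict(d["motif"]),
            HomogeneousMarkovModel.from_dict(d["flanking"]),
            d["gamma"],
            d["strand_prob"],
        )

    def to_json(self, path, metadata: dict | None = None) -> None:
        d = self.to_dict()
        if metadata:
            d["metadata"] = metadata
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ZOOPSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ZOOPSConfig:
    """Knobs of one EM run (spec'd CLI names: width/order/log2-kappa/ess)."""

    width: int = 20
    max_order: int = 4
    log2_kappa: float = -4.5
    ess: float = 4.0
    restarts: int = 5
    max_iter: int = 100
    tol: float = 1e-6
    strand_prob: float = 0.5
    # leaf score used for structure search inside the M-step; "map" is the
    # profile score that makes the monotonicity guarantee exact
    em_score: str = "map"


@dataclass
class EMTrace:
    """Iteration-indexed log joint posterior of one EM run."""

    log_posteriors: list[float]
    restart: int
    seed: int
    converged: bool = False


@dataclass
class Responsibilities:
    """Posterior masses over the latent variables, one entry per sequence.

    ``r0[i]`` is the posterior of no occurrence; ``site[i]`` has shape
    (n_starts, 2) with columns (forward, reverse).  Masses sum to 1.
    """

    r0: np.ndarray
    site: list[np.ndarray]


# ---------------------------------------------------------------------------
# precomputed per-dataset arrays (flanking model is fixed during EM)
# ---------------------------------------------------------------------------


class _SequenceData:
    """Window matrices, context indices, and flanking scores for EM."""

    def __init__(self, records, width: int, max_order: int, flanking: HomogeneousMarkovModel):
        codes = []
        for r in records:
            s = r.seq if hasattr(r, "seq") else r
            codes.append(encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.int64))
        self.codes = codes
        self.width = width
        n = len(codes)
        self.nwin = np.array([max(0, c.size - width + 1) for c in codes], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.nwin)])
        total = int(self.offsets[-1])
        self.total_windows = total
        self.F = np.empty(n)
        Wm = np.empty((total, width), dtype=np.int8)
        ws = np.empty(total)
        for i, c in enumerate(codes):
            f = flanking.per_symbol_log_prob(c)
            self.F[i] = f.sum()
            if self.nwin[i]:
                o = self.offsets[i]
                Wm[o : o + self.nwin[i]] = sliding_window_view(c, width)
                cs = np.concatenate([[0.0], np.cumsum(f)])
                ws[o : o + self.nwin[i]] = cs[width:] - cs[:-width]
        self.Wm = Wm
        self.Rm = (3 - Wm[:, ::-1]).astype(np.int8)
        self.window_flank = ws
        self.seq_index = np.repeat(np.arange(n), self.nwin)
        # per-position flattened (context, symbol) indices, both strands
        self.idx_fwd: list[np.ndarray] = []
        self.idx_rev: list[np.ndarray] = []
        for i in range(width):
            d = min(i, max_order)
            self.idx_fwd.append(self._flat_index(self.Wm, i, d))
            self.idx_rev.append(self._flat_index(self.Rm, i, d))
        self.nonempty = np.nonzero(self.nwin)[0]

    @staticmethod
    def _flat_index(words: np.ndarray, i: int, d: int) -> np.ndarray:
        n = words.shape[0]
        if d == 0:
            return words[:, i].astype(np.int32)
        powers = 4 ** np.arange(d, dtype=np.int64)  # nearest predecessor highest
        ctx = words[:, i - d : i].astype(np.int64) @ powers
        return (ctx * 4 + words[:, i]).astype(np.int32)

    def motif_scores(self, pmm: InhomogeneousPMM) -> tuple[np.ndarray, np.ndarray]:
        tabs = pmm.tables()
        mp = np.zeros(self.total_windows)
        mm = np.zeros(self.total_windows)
        for i in range(self.width):
            flat = tabs[i].ravel()
            mp += flat[self.idx_fwd[i]]
            mm += flat[self.idx_rev[i]]
        return mp, mm


def _segment_reduce(values: np.ndarray, offsets: np.ndarray, ufunc, empty_value: float) -> np.ndarray:
    """Per-segment ufunc.reduce for contiguous segments, allowing empty ones."""
    nseg = len(offsets) - 1
    lens = np.diff(offsets)
    out = np.full(nseg, empty_value)
    nz = np.nonzero(lens)[0]
    if nz.size:
        out[nz] = ufunc.reduceat(values, offsets[nz])
    return out


def _forward(model: ZOOPSModel, data: _SequenceData):
    """E-step forward pass: responsibilities and per-sequence log likelihood."""
    with np.errstate(divide="ignore"):
        lg = np.log(model.gamma)
        l1g = np.log1p(-model.gamma) if model.gamma < 1 else NEG_INF
        lp = np.log(model.strand_prob)
        lm = np.log1p(-model.strand_prob) if model.strand_prob < 1 else NEG_INF
    mp, mm = data.motif_scores(model.motif)
    base = lg - np.log(data.nwin[data.seq_index]) - data.window_flank
    tp = base + lp + mp
    tm = base + lm + mm
    both_max = np.maximum(tp, tm)
    Mwin = _segment_reduce(both_max, data.offsets, np.maximum, NEG_INF)
    M = np.maximum(Mwin, l1g)
    M = np.where(np.isneginf(M), 0.0, M)  # degenerate: everything -inf
    Ms = M[data.seq_index]
    ep = np.exp(tp - Ms)
    em = np.exp(tm - Ms)
    Z = np.exp(l1g - M) + _segment_reduce(ep + em, data.offsets, np.add, 0.0)
    loglik = data.F + M + np.log(Z)
    r0 = np.exp(l1g - M) / Z
    Zs = Z[data.seq_index]
    rp = ep / Zs
    rm = em / Zs
    # sequences shorter than the motif: occurrence forced absent
    empty = data.nwin == 0
    if empty.any():
        loglik[empty] = data.F[empty]
        r0[empty] = 1.0
    return r0, rp, rm, loglik


def _log_prior(model: ZOOPSModel) -> float:
    """Log prior terms the EM ascends: Dirichlet pseudocount kernels on the
    motif leaves, the structure prior, and a Beta(1,1)-equivalent kernel on
    gamma.  (The fixed flanking model contributes a constant, omitted.)"""
    lp = 0.0
    for pct in model.motif.pcts:
        for leaf in pct.leaves:
            with np.errstate(divide="ignore"):
                lp += float(leaf.alpha * np.log(leaf.theta).sum())
        lp += pct.n_leaves * model.motif.log2_kappa * LN2
    with np.errstate(divide="ignore"):
        lp += math.log(model.gamma) if model.gamma > 0 else NEG_INF
        lp += math.log1p(-model.gamma) if model.gamma < 1 else NEG_INF
    return lp


def log_joint_posterior(model: ZOOPSModel, data: _SequenceData) -> float:
    _, _, _, loglik = _forward(model, data)
    return float(loglik.sum() + _log_prior(model))


# ---------------------------------------------------------------------------
# public per-record operations
# ---------------------------------------------------------------------------


def zoops_log_likelihood(model: ZOOPSModel, seq) -> float:
    """Marginal log likelihood of one sequence under the ZOOPS mixture.

    Sums over occurrence, start position, and strand.  For sequences
    shorter than the motif width the occurrence branch is absent.
    """
    codes = encode(seq.seq if hasattr(seq, "seq") else seq) if not isinstance(seq, np.ndarray) else seq
    data = _SequenceData([codes], model.width, model.motif.max_order, model.flanking)
    _, _, _, loglik = _forward(model, data)
    return float(loglik[0])


def zoops_log_likelihood_many(model: ZOOPSModel, records) -> np.ndarray:
    data = _SequenceData(records, model.width, model.motif.max_order, model.flanking)
    _, _, _, loglik = _forward(model, data)
    return loglik


def e_step(model: ZOOPSModel, records) -> Responsibilities:
    """Exact posteriors over (occurrence, position, strand) per sequence."""
    data = _SequenceData(records, model.width, model.motif.max_order, model.flanking)
    r0, rp, rm, _ = _forward(model, data)
    site = []
    for i in range(len(data.codes)):
        o, k = data.offsets[i], data.nwin[i]
        site.append(np.stack([rp[o : o + k], rm[o : o + k]], axis=1))
    return Responsibilities(r0=r0, site=site)


def _m_step_arrays(
    data: _SequenceData,
    r0: np.ndarray,
    rp: np.ndarray,
    rm: np.ndarray,
    config: ZOOPSConfig,
    old_motif: InhomogeneousPMM,
) -> tuple[InhomogeneousPMM, float]:
    n = len(data.codes)
    gamma = (float((1.0 - r0).sum()) + 1.0) / (n + 2.0)
    mass = float(rp.sum() + rm.sum())
    if mass <= 0.0:
        import logging

        logging.getLogger(__name__).warning("m_step: zero motif mass; motif left unchanged")
        return old_motif, gamma
    pcts = []
    for i in range(config.width):
        d = min(i, config.max_order)
        size = 4 ** (d + 1)
        flat = np.bincount(data.idx_fwd[i], weights=rp, minlength=size) + np.bincount(
            data.idx_rev[i], weights=rm, minlength=size
        )
        counts = flat.reshape((4,) * d + (4,))
        pcts.append(learn_pct(counts, d, config.log2_kappa, config.ess, score=config.em_score))
    motif = InhomogeneousPMM(config.width, config.max_order, config.log2_kappa, config.ess, pcts)
    return motif, gamma


def m_step(records, resp: Responsibilities, config: ZOOPSConfig, flanking: HomogeneousMarkovModel, old_motif: InhomogeneousPMM | None = None):
    """Refit motif and occurrence probability from responsibilities.

    Reverse-strand windows contribute their reverse complements; PCT
    structures are re-learned from the expected counts; the flanking model
    is untouched.  Returns ``(motif, gamma, strand_prob)``.
    """
    data = _SequenceData(records, config.width, config.max_order, flanking)
    rp = np.concatenate([s[:, 0] for s in resp.site]) if resp.site else np.zeros(0)
    rm = np.concatenate([s[:, 1] for s in resp.site]) if resp.site else np.zeros(0)
    if old_motif is None:
        old_motif = InhomogeneousPMM(
            config.width, config.max_order, config.log2_kappa, config.ess,
            [learn_pct(np.zeros((4,) * min(i, config.max_order) + (4,)), min(i, config.max_order),
                       config.log2_kappa, config.ess) for i in range(config.width)],
        )
    motif, gamma = _m_step_arrays(data, resp.r0, rp, rm, config, old_motif)
    return motif, gamma, config.strand_prob


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def fit_zoops_em(
    records,
    flanking: HomogeneousMarkovModel,
    config: ZOOPSConfig | None = None,
    seed: int = 0,
) -> tuple[ZOOPSModel, EMTrace]:
    """Run restarted MAP-EM and return the best model and its trace.

    Each restart initializes responsibilities by assigning every sequence a
    uniformly drawn (position, strand) with occurrence mass 0.5, then
    starts with an M-step.  Iterations alternate E and M steps until the
    relative change of the log joint posterior falls below ``tol``.
    """
    config = config or ZOOPSConfig()
    data = _SequenceData(records, config.width, config.max_order, flanking)
    if data.total_windows == 0:
        raise ValueError("all sequences are shorter than the motif width")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.restarts)]
    best: tuple[float, ZOOPSModel, EMTrace] | None = None
    for restart, rseed in enumerate(child_seeds):
        rng = np.random.default_rng(rseed)
        rp = np.zeros(data.total_windows)
        rm = np.zeros(data.total_windows)
        r0 = np.ones(len(data.codes))
        for i in data.nonempty:
            ell = int(rng.integers(0, data.nwin[i]))
            s = int(rng.integers(0, 2))
            (rp if s == 0 else rm)[data.offsets[i] + ell] = 0.5
            r0[i] = 0.5
        motif, gamma = _m_step_arrays(data, r0, rp, rm, config, old_motif=None)  # type: ignore[arg-type]
        model = ZOOPSModel(motif, flanking, gamma, config.strand_prob)
        trace = EMTrace(log_posteriors=[], restart=restart, seed=rseed)
        prev = None
        prev_delta = None
        for _ in range(config.max_iter):
            r0, rp, rm, loglik = _forward(model, data)
            F = float(loglik.sum() + _log_prior(model))
            trace.log_posteriors.append(F)
            if prev is not None:
                delta = abs(F - prev)
                # EM often starts slowly before taking off, so stop only when
                # the improvement is both small and no longer growing
                if (
                    prev_delta is not None
                    and delta <= config.tol * (abs(prev) + 1.0)
                    and delta <= prev_delta
                ):
                    trace.converged = True
                    break
                prev_delta = delta
            prev = F
            motif, gamma = _m_step_arrays(data, r0, rp, rm, config, old_motif=model.motif)
            model = ZOOPSModel(motif, flanking, gamma, config.strand_prob)
        final = trace.log_posteriors[-1]
        if best is None or final > best[0]:
            best = (final, model, trace)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------


class MotifDiscovery:
    """De novo ZOOPS motif discovery model for a set of DNA sequences.

    Parameters
    ----------
    sequences
        Positive sequences (strings or :class:`~parsimotif.io.SequenceRecord`).
    width, max_order
        Motif width and maximal context order of the parsimonious Markov
        motif model (defaults 20 and 4, the usual CTCF setting).
    log2_kappa
        Structure prior on the log2 scale; very negative values force the
        PWM limit, very positive ones the full order-``max_order`` model.
    flanking
        Pre-trained homogeneous Markov model for non-motif sequence.  If
        omitted, an order-``flank_order`` model is fitted to ``sequences``
        (for classification studies pass the background model trained on
        the union of positive and negative training data instead).
    """

    def __init__(
        self,
        sequences,
        width: int = 20,
        max_order: int = 4,
        log2_kappa: float = -4.5,
        ess: float = 4.0,
        flanking: HomogeneousMarkovModel | None = None,
        flank_order: int = 2,
        strand_prob: float = 0.5,
    ):
        self.sequences = list(sequences)
        if not self.sequences:
            raise ValueError("no sequences")
        self.config = ZOOPSConfig(
            width=width, max_order=max_order, log2_kappa=log2_kappa, ess=ess,
            strand_prob=strand_prob,
        )
        self.flanking = flanking or fit_homogeneous_mm(self.sequences, flank_order, ess)

    def fit(
        self,
        restarts: int = 5,
        seed: int = 0,
        max_iter: int = 100,
        tol: float = 1e-6,
    ) -> "MotifDiscoveryResults":
        cfg = self.config
        cfg.restarts, cfg.max_iter, cfg.tol = restarts, max_iter, tol
        model, trace = fit_zoops_em(self.sequences, self.flanking, cfg, seed)
        return MotifDiscoveryResults(self, model, trace)


class MotifDiscoveryResults:
    """Fitted ZOOPS motif model: estimates, EM diagnostics, and predictions."""

    def __init__(self, model: MotifDiscovery, zoops: ZOOPSModel, trace: EMTrace):
        self.model = model
        self.zoops = zoops
        self.trace = trace

    @property
    def motif(self) -> InhomogeneousPMM:
        return self.zoops.motif

    @property
    def gamma(self) -> float:
        return self.zoops.gamma

    def responsibilities(self, records=None) -> Responsibilities:
        return e_step(self.zoops, records if records is not None else self.model.sequences)

    def log_likelihood(self, records=None) -> np.ndarray:
        return zoops_log_likelihood_many(
            self.zoops, records if records is not None else self.model.sequences
        )

    def site_map(self, records=None) -> list[tuple[int, int] | None]:
        """Per sequence, the MAP (start, strand) of the site, or None.

        ``start`` is 0-based; ``strand`` 0 = forward, 1 = reverse.  None
        means the no-occurrence state has the largest posterior mass.
        """
        resp = self.responsibilities(records)
        out = []
        for r0, site in zip(resp.r0, resp.site):
            if site.size == 0 or r0 >= site.max():
                out.append(None)
            else:
                ell, s = np.unravel_index(int(site.argmax()), site.shape)
                out.append((int(ell), int(s)))
        return out

    def predict_sites(self, pos_records, neg_records, alpha: float = 1e-4, **kw):
        """Threshold-based site prediction; see :mod:`parsimotif.prediction`."""
        from . import prediction

        neg = prediction.window_likelihoods(self.motif, neg_records)
        thr = prediction.compute_threshold(neg["log_likelihood"].to_numpy(), alpha)
        return prediction.predict_sites(self.motif, pos_records, thr, **kw)

    def summary(self) -> str:
        per_pos, total = leaf_statistics(self.motif)
        lines = [
            "ZOOPS motif discovery results",
            "=" * 46,
            f"sequences:            {len(self.model.sequences)}",
            f"motif width:          {self.motif.width}",
            f"max context order:    {self.motif.max_order}",
            f"log2 kappa:           {self.motif.log2_kappa:g}",
            f"ess:                  {self.motif.ess:g}",
            f"gamma (occurrence):   {self.gamma:.4f}",
            f"strand prob (fwd):    {self.zoops.strand_prob:g}",
            f"total PCT leaves:     {total}",
            f"EM restarts:          {self.model.config.restarts} (best: #{self.trace.restart})",
            f"EM iterations:        {len(self.trace.log_posteriors)}"
            + (" (converged)" if self.trace.converged else ""),
            f"log joint posterior:  {self.trace.log_posteriors[-1]:.3f}",
            "-" * 46,
            "leaves per position:  "
            + " ".join(str(n) for _, n in per_pos),
        ]
        return "\n".join(lines)
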