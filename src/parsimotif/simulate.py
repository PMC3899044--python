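"""Synthetic sequence data with the exact statistical structure the
analysis assumes.

Backgrounds come from a low-order homogeneous Markov chain with a
human-like base composition (CpG-depleted, mild run persistence); planted
motifs follow a declared per-position dependency structure (each position
is either independent or conditioned on an adjacent run of up to four
immediately preceding positions), inserted zero-or-once per sequence at a
uniform position on a random strand.  Ground truth (occurrence, start,
strand, word) is recorded for every sequence, so discovery, prediction,
and dependency statistics can all be checked against the generating law.

All probability tables in :func:`default_dependent_motif` are fixture
values, not estimates from any real data set; they are shaped to mimic a
CTCF-like motif (conserved core, strong nearest-neighbour coupling at
position 17, higher-order coupling at position 19).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import ALPHABET, decode, encode, revcomp_codes
from .io import LabeledDataSet, SequenceRecord, make_labeled_dataset
from .markov import HomogeneousMarkovModel

__all__ = [
    "MotifSpec",
    "MotifPosition",
    "SyntheticTruth",
    "TruthEntry",
    "default_background_mm",
    "default_dependent_motif",
    "sample_background",
    "sample_sites",
    "plant_zoops",
    "make_benchmark",
    "BenchmarkConfig",
    "analytic_mi",
    "context_symbol_joint",
    "conditional_law",
    "site_recovery",
]


@dataclass
class MotifPosition:
    """One motif column: independent, or conditioned on the preceding run.

    ``context_len`` = 0 means an independent column with ``table`` of shape
    (1, 4); ``context_len`` = c > 0 conditions on the c immediately
    preceding positions with ``table`` of shape (4**c, 4), rows indexed
    with the nearest predecessor as the most significant digit.
    """

    context_len: int
    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (4**self.context_len, 4):
            raise ValueError("table shape does not match context length")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional tables must be normalized")


@dataclass
class MotifSpec:
    """Generative law of a planted motif; provenance: fixture, not empirical data."""

    width: int
    positions: list[MotifPosition]
    note: str = "fixture, not empirical data"

    def __post_init__(self):
        if len(self.positions) != self.width:
            raise ValueError("one MotifPosition per column required")
        for i, p in enumerate(self.positions):
            if p.context_len > min(i, 4):
                raise ValueError(
                    f"position {i + 1}: context length {p.context_len} exceeds "
                    f"the allowed adjacent-run of {min(i, 4)} predecessors"
                )

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "note": self.note,
            "positions": [
                {"context_len": p.context_len, "table": p.table.tolist()}
                for p in self.positions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifSpec":
        return cls(
            d["width"],
            [MotifPosition(p["context_len"], np.asarray(p["table"])) for p in d["positions"]],
            d.get("note", "fixture, not empirical data"),
        )


@dataclass
class TruthEntry:
    id: str
    has_site: bool
    site_start: int | None = None  # 0-based window start
    site_strand: str | None = None  # "+" | "-"
    site_word: str | None = None  # motif word as sampled (forward orientation)


@dataclass
class SyntheticTruth:
    entries: list[TruthEntry] = field(default_factory=list)

    def by_id(self) -> dict[str, TruthEntry]:
        return {e.id: e for e in self.entries}


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------


def default_background_mm() -> HomogeneousMarkovModel:
    """Order-2 background chain with human-like composition.

    Base composition ~41% GC, CpG dinucleotides depleted to a quarter of
    their independence expectation, and a mild persistence bonus for
    single-nucleotide runs (a genuinely second-order feature).
    """
    base = np.array([0.295, 0.205, 0.205, 0.295])
    p1 = np.tile(base, (4, 1))
    p1[1, 2] *= 0.25  # C followed by G
    p1 /= p1.sum(axis=1, keepdims=True)
    # rows of the order-2 table are indexed nearest-predecessor-most-significant:
    # row = s_{t-1} * 4 + s_{t-2}
    p2 = np.empty((16, 4))
    for prev in range(4):
        for prev2 in range(4):
            row = p1[prev].copy()
            if prev == prev2:
                row[prev] *= 1.3  # run persistence
            p2[prev * 4 + prev2] = row / row.sum()
    counts = [base[None, :], p1, p2]
    # counts equal to the target conditionals with ess=0 reproduce them exactly
    return HomogeneousMarkovModel(order=2, counts=counts, ess=0.0)


def _indep(p) -> MotifPosition:
    p = np.asarray(p, dtype=float)
    return MotifPosition(0, (p / p.sum())[None, :])


def _conserved(sym: int, strength: float = 0.85) -> MotifPosition:
    p = np.full(4, (1.0 - strength) / 3.0)
    p[sym] = strength
    return MotifPosition(0, p[None, :])


def _coupled1(rows: dict[int, list[float]], default: list[float]) -> MotifPosition:
    """First-order column: one conditional row per predecessor symbol."""
    t = np.stack([np.asarray(rows.get(s, default), dtype=float) for s in range(4)])
    return MotifPosition(1, t / t.sum(axis=1, keepdims=True))


def default_dependent_motif() -> MotifSpec:
    """Width-20 CTCF-like fixture with planted order-1..4 dependencies.

    The design mimics the qualitative anatomy of the CTCF core motif: a
    moderately conserved central block (positions 4-15) whose columns carry
    mild nearest-neighbour coupling, and an unconserved 3' block whose
    information lives almost entirely in dependencies.  Position 16 is
    uniform; position 17 is a near-deterministic function of 16 (a
    permutation coupling, so its *marginal* is uniform and a PWM sees
    nothing there, analytic MI ~ 1.4 bit); position 18 is a softer
    permutation coupling of 17; position 19 is conditioned on the run
    15-18 through a table that ignores position 16, so its dependencies
    reach back to the fourth predecessor; position 20 couples moderately
    to 19 and position 2 weakly to 1.  All tables are fixture values, not
    estimates from any data set.
    """
    A, C, G, T = 0, 1, 2, 3
    pos: list[MotifPosition] = []
    # 1-3: near-uniform 5' end, weak coupling at 2
    pos.append(_indep([0.30, 0.25, 0.25, 0.20]))
    pos.append(_coupled1({A: [0.40, 0.20, 0.20, 0.20], C: [0.20, 0.40, 0.20, 0.20],
                          G: [0.20, 0.20, 0.40, 0.20]}, [0.20, 0.20, 0.20, 0.40]))
    pos.append(_indep([0.25, 0.25, 0.30, 0.20]))
    # 4-15: conserved core, consensus CCACCAGGTGGC, with mild first-order
    # modulation of the consensus probability at every other column
    def cons_row(sym, p):
        row = np.full(4, (1 - p) / 3)
        row[sym] = p
        return row.tolist()

    pos.append(_conserved(C, 0.85))                                     # 4
    pos.append(_coupled1({C: cons_row(C, 0.92)}, cons_row(C, 0.75)))    # 5 | 4
    pos.append(_conserved(A, 0.80))                                     # 6
    pos.append(_coupled1({A: cons_row(C, 0.88)}, cons_row(C, 0.72)))    # 7 | 6
    pos.append(_conserved(C, 0.85))                                     # 8
    pos.append(_coupled1({C: cons_row(A, 0.85)}, cons_row(A, 0.68)))    # 9 | 8
    pos.append(_conserved(G, 0.90))                                     # 10
    pos.append(_conserved(G, 0.85))                                     # 11
    pos.append(_coupled1({G: cons_row(T, 0.85)}, cons_row(A, 0.65)))    # 12 | 11
    pos.append(_conserved(G, 0.90))                                     # 13
    pos.append(_coupled1({G: cons_row(G, 0.88)}, cons_row(G, 0.75)))    # 14 | 13
    pos.append(_conserved(G, 0.75))                                     # 15
    # 16: uniform driver of the strong coupling at 17
    pos.append(_indep([0.25, 0.25, 0.25, 0.25]))
    # 17: near-deterministic permutation of 16 (A->G, C->C, G->T, T->A);
    # uniform marginal, so the information is invisible to a PWM
    perm17 = {A: G, C: C, G: T, T: A}
    t17 = np.full((4, 4), 0.08 / 3)
    for s, target in perm17.items():
        t17[s, target] = 0.92
    pos.append(MotifPosition(1, t17))
    # 18: permutation coupling to 17 (A->C, C->T, G->A, T->G), again with a
    # near-uniform marginal
    perm18 = {A: C, C: T, G: A, T: G}
    t18 = np.full((4, 4), 0.28 / 3)
    for s, target in perm18.items():
        t18[s, target] = 0.72
    pos.append(MotifPosition(1, t18))
    # 19: conditioned on the run 15-18; the table is constant in position 16,
    # so the effective parents are 15, 17, and 18
    t19 = np.empty((256, 4))
    for s15 in range(4):
        for s16 in range(4):
            for s17 in range(4):
                for s18 in range(4):
                    if s18 == C:
                        if s17 == G:
                            row = [0.84, 0.10, 0.03, 0.03]
                        elif s15 in (C, G):
                            row = [0.84, 0.03, 0.10, 0.03]
                        else:
                            row = [0.84, 0.065, 0.065, 0.03]
                    elif s18 == T:
                        if s17 == G:
                            row = [0.10, 0.03, 0.84, 0.03]
                        elif s15 in (C, G):
                            row = [0.03, 0.10, 0.84, 0.03]
                        else:
                            row = [0.065, 0.065, 0.84, 0.03]
                    else:
                        if s17 == G:
                            row = [0.45, 0.20, 0.25, 0.10]
                        else:
                            row = [0.35, 0.30, 0.25, 0.10]
                    # context row index: nearest predecessor (18) most significant
                    idx = ((s18 * 4 + s17) * 4 + s16) * 4 + s15
                    t19[idx] = row
    pos.append(MotifPosition(4, t19))
    # 20: moderate permutation coupling to 19 (A->T, C->G, G->C, T->A)
    perm20 = {A: T, C: G, G: C, T: A}
    t20 = np.full((4, 4), 0.5 / 3)
    for s, target in perm20.items():
        t20[s, target] = 0.5
    pos.append(MotifPosition(1, t20))
    return MotifSpec(width=20, positions=pos)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_background(
    n: int,
    length_range: tuple[int, int] = (189, 888),
    mm: HomogeneousMarkovModel | None = None,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Sample background sequences from a homogeneous Markov chain.

    Lengths are uniform on the inclusive range (default 189-888 bp, the
    length span of the reference ChIP-seq positives).
    """
    mm = mm or default_background_mm()
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    maxlen = int(lengths.max()) if n else 0
    order = mm.order
    sym = np.zeros((n, maxlen), dtype=np.int8)
    u = rng.random((n, maxlen))
    for t in range(maxlen):
        k = min(t, order)
        # context over the last k symbols, nearest predecessor most significant
        ctx = np.zeros(n, dtype=np.int64)
        for j in range(1, k + 1):
            ctx += sym[:, t - j].astype(np.int64) * 4 ** (k - j)
        cum = np.cumsum(mm.cond_probs[k][ctx], axis=1)
        sym[:, t] = (u[:, t][:, None] > cum).sum(axis=1)
    return [
        SequenceRecord(id=f"bg_{i:05d}", seq=decode(sym[i, : lengths[i]]))
        for i in range(n)
    ]


def sample_sites(spec: MotifSpec, n: int, seed: int = 0) -> np.ndarray:
    """Sample n motif words as an (n, width) code array."""
    rng = np.random.default_rng(seed)
    words = np.zeros((n, spec.width), dtype=np.int64)
    u = rng.random((n, spec.width))
    for i, p in enumerate(spec.positions):
        c = p.context_len
        if c == 0:
            rows = np.zeros(n, dtype=np.int64)
        else:
            powers = 4 ** np.arange(c - 1, -1, -1, dtype=np.int64)
            rows = words[:, i - c : i][:, ::-1] @ powers
        cum = np.cumsum(p.table[rows], axis=1)
        words[:, i] = (u[:, i][:, None] > cum).sum(axis=1)
    return words


def plant_zoops(
    background_records,
    motif_spec: MotifSpec,
    occurrence_prob: float = 0.9,
    strand_prob: float = 0.5,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Overwrite a zero-or-one motif occurrence into each background sequence.

    Per sequence: Bernoulli occurrence, uniform start, Bernoulli strand
    (forward with probability ``strand_prob``); the sampled word is
    reverse-complemented before insertion for minus-strand sites.
    Sequences shorter than the width never receive a site.
    """
    rng = np.random.default_rng(seed)
    W = motif_spec.width
    n = len(background_records)
    words = sample_sites(motif_spec, n, seed=int(rng.integers(2**31)))
    occur = rng.random(n) < occurrence_prob
    start_draw = rng.integers(0, 2**31, size=n)
    minus = rng.random(n) >= strand_prob
    records, truth = [], SyntheticTruth()
    for i, rec in enumerate(background_records):
        codes = encode(rec.seq)
        has = bool(occur[i])
        if has and codes.size < W:
            import logging

            logging.getLogger(__name__).info(
                "plant_zoops: %s shorter than width, site forced absent", rec.id
            )
            has = False
        if not has:
            records.append(SequenceRecord(id=rec.id, seq=rec.seq))
            truth.entries.append(TruthEntry(id=rec.id, has_site=False))
            continue
        start = int(start_draw[i]) % (codes.size - W + 1)
        word = words[i]
        codes[start : start + W] = revcomp_codes(word) if minus[i] else word
        records.append(SequenceRecord(id=rec.id, seq=decode(codes)))
        truth.entries.append(
            TruthEntry(
                id=rec.id,
                has_site=True,
                site_start=start,
                site_strand="-" if minus[i] else "+",
                site_word=decode(word),
            )
        )
    return records, truth


@dataclass
class BenchmarkConfig:
    """Default study conditions of the synthetic benchmark."""

    n_pos: int = 1500
    n_neg: int = 3000
    length_range: tuple[int, int] = (189, 888)
    occurrence_prob: float = 0.9
    strand_prob: float = 0.5
    split_ratio: tuple[int, int] = (2, 1)


def make_benchmark(
    config: BenchmarkConfig | None = None,
    seed: int = 0,
    motif_spec: MotifSpec | None = None,
) -> tuple[LabeledDataSet, SyntheticTruth]:
    """Assemble a labelled benchmark: planted positives, background negatives.

    Defaults: 1,500 positives / 3,000 negatives, lengths 189-888 bp,
    2:1 train/test split per class.
    """
    cfg = config or BenchmarkConfig()
    spec = motif_spec or default_dependent_motif()
    ss = np.random.SeedSequence(seed)
    s_bgpos, s_bgneg, s_plant, s_split = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    bg_pos = sample_background(cfg.n_pos, cfg.length_range, seed=s_bgpos)
    positives, truth = plant_zoops(bg_pos, spec, cfg.occurrence_prob, cfg.strand_prob, s_plant)
    positives = [SequenceRecord(id=f"pos_{i:05d}", seq=r.seq) for i, r in enumerate(positives)]
    for i, e in enumerate(truth.entries):
        e.id = f"pos_{i:05d}"
    negatives = sample_background(cfg.n_neg, cfg.length_range, seed=s_bgneg)
    negatives = [SequenceRecord(id=f"neg_{i:05d}", seq=r.seq) for i, r in enumerate(negatives)]
    dataset = make_labeled_dataset(positives, negatives, cfg.split_ratio, s_split)
    return dataset, truth


# ---------------------------------------------------------------------------
# analytic statistics of the generative law
# ---------------------------------------------------------------------------


def _closure(spec: MotifSpec, lo: int, i: int) -> int:
    """Smallest m such that all parents of positions m..i lie in m..i (1-based)."""
    m = lo
    changed = True
    while changed:
        changed = False
        for p in range(m, i + 1):
            c = spec.positions[p - 1].context_len
            if c and p - c < m:
                m = p - c
                changed = True
    return m


def _joint(spec: MotifSpec, m: int, i: int) -> np.ndarray:
    """Exact joint over positions m..i (axes in ascending position order)."""
    npos = i - m + 1
    if 4**npos > 4**12:
        raise ValueError("joint support too large to enumerate")
    grids = np.indices((4,) * npos)
    prob = np.ones((4,) * npos)
    for p in range(m, i + 1):
        mp = spec.positions[p - 1]
        c = mp.context_len
        ax = p - m
        if c == 0:
            rows = np.zeros_like(grids[0])
        else:
            rows = np.zeros_like(grids[0])
            for j in range(1, c + 1):
                rows = rows * 4 + grids[ax - j]
        prob = prob * mp.table[rows, grids[ax]]
    return prob


def context_symbol_joint(spec: MotifSpec, i: int, k: int) -> np.ndarray:
    """Joint P(preceding k-mer, symbol at i) as a (4**k, 4) array.

    Context rows follow the package convention: nearest predecessor most
    significant.  ``i`` is 1-based and must exceed ``k``.
    """
    if i <= k:
        raise ValueError("position must exceed the context order")
    m = _closure(spec, i - k, i)
    J = _joint(spec, m, i)
    # marginalize positions before i-k
    J = J.sum(axis=tuple(range(i - k - m)))
    # axes now (s_{i-k}, ..., s_{i-1}, s_i); reorder context to nearest-first
    J = np.transpose(J, tuple(range(k - 1, -1, -1)) + (k,))
    return J.reshape(4**k, 4)


def analytic_mi(spec: MotifSpec, i: int, k: int) -> float:
    """Exact MI (bits) of position i and its preceding k-mer under the law."""
    J = context_symbol_joint(spec, i, k)
    pc = J.sum(axis=1, keepdims=True)
    ps = J.sum(axis=0, keepdims=True)
    nz = J > 0
    return float((J[nz] * np.log2(J[nz] / (pc @ ps)[nz])).sum())


def conditional_law(spec: MotifSpec, i: int, context_words) -> tuple[float, np.ndarray]:
    """Probability mass and conditional symbol law of a set of contexts.

    ``context_words`` are length-d tuples in layer order (nearest
    predecessor first), as produced by PCT leaves.  Returns
    ``(P(context set), P(symbol at i | context set))``.
    """
    words = list(context_words)
    d = len(words[0]) if words else 0
    if d == 0:
        J = context_symbol_joint(spec, i, 1).sum(axis=0) if i > 1 else spec.positions[0].table[0]
        return 1.0, np.asarray(J)
    J = context_symbol_joint(spec, i, d)
    powers = 4 ** np.arange(d - 1, -1, -1, dtype=np.int64)
    rows = np.array([np.dot(w, powers) for w in words], dtype=np.int64)
    mass = J[rows].sum()
    law = J[rows].sum(axis=0) / mass if mass > 0 else np.full(4, 0.25)
    return float(mass), law


def site_recovery(
    truth: SyntheticTruth, records, site_map, tol: int = 1
) -> float:
    """Fraction of planted sites recovered by a discovery run.

    A ZOOPS model is identifiable only up to a global window shift and
    strand orientation (the reverse-complemented, shifted motif explains
    the same data).  A motif learned with a shift of s places the MAP
    window at truth+s for forward-planted sites and truth-s for
    reverse-planted ones, so the canonical coordinate is the offset signed
    by the true strand.  A planted site counts as recovered when its MAP
    (start, strand) matches the run's modal alignment transform within
    ``tol`` positions.  When discovery converges to the aligned
    orientation with zero shift this reduces to plain |start - truth| <= tol.
    """
    from collections import Counter

    tm = truth.by_id()
    total = 0
    obs: list[tuple[int, bool]] = []
    for rec, m in zip(records, site_map):
        e = tm.get(rec.id)
        if e is None or not e.has_site:
            continue
        total += 1
        if m is None:
            continue
        same = (m[1] == 0) == (e.site_strand == "+")
        sign = 1 if e.site_strand == "+" else -1
        obs.append((sign * (m[0] - e.site_start), same))
    if total == 0:
        raise ValueError("no planted sites in the provided records")
    counts = Counter(obs)
    best = 0
    for (d0, o0) in counts:
        hit = sum(c for (d, o), c in counts.items() if o == o0 and abs(d - d0) <= tol)
        best = max(best, hit)
    return best / total
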