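"""Threshold-based prediction of individual binding sites.

Every width-W window of every sequence is scored on both strands with the
motif model alone.  The decision threshold is the empirical quantile of
the same window scores computed on a negative (control) set, at a
significance level alpha chosen by the user; windows at or above the
threshold are reported as sites.  Unlike the ZOOPS training assumption,
this scan can report multiple sites per sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import decode, encode
from .markov import InhomogeneousPMM

__all__ = ["ScoredSite", "window_likelihoods", "compute_threshold", "predict_sites"]


@dataclass
class ScoredSite:
    """One predicted site; ``start`` is 1-based within its sequence.

    ``site_seq`` is the word as scored, i.e. reverse-complemented for
    minus-strand hits; ``start`` refers to the window's left edge in
    forward-sequence coordinates either way.
    """

    sequence_id: str
    start: int
    strand: str  # "+" | "-"
    log_likelihood: float
    site_seq: str


def _iter_codes(records):
    for i, r in enumerate(records):
        s = r.seq if hasattr(r, "seq") else r
        rid = getattr(r, "id", str(i))
        yield rid, encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.int64)


def window_likelihoods(model: InhomogeneousPMM, records) -> pd.DataFrame:
    """Motif log likelihood of every window on both strands.

    Returns a DataFrame with columns (id, start, strand, log_likelihood);
    ``start`` is 1-based.  Sequences shorter than the width yield nothing.
    """
    W = model.width
    ids, starts, strands, scores = [], [], [], []
    for rid, codes in _iter_codes(records):
        if codes.size < W:
            continue
        win = sliding_window_view(codes, W)
        rc = 3 - win[:, ::-1]
        sp = model.log_prob_words(win)
        sm = model.log_prob_words(rc)
        k = win.shape[0]
        ids.extend([rid] * (2 * k))
        starts.extend(list(range(1, k + 1)) * 2)
        strands.extend(["+"] * k + ["-"] * k)
        scores.extend(sp.tolist() + sm.tolist())
    return pd.DataFrame(
        {"id": ids, "start": starts, "strand": strands, "log_likelihood": scores}
    )


def compute_threshold(neg_window_likelihoods, alpha: float) -> float:
    """Empirical (1-alpha)-quantile of negative window log likelihoods.

    Ceiling/type-1 convention, matching the specificity threshold of the
    classification module: the smallest value t such that at least
    ``ceil((1-alpha) * n)`` of the list are <= t.
    """
    vals = np.asarray(neg_window_likelihoods, dtype=float)
    if vals.size == 0:
        raise ValueError("empty negative window list")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    k = math.ceil((1.0 - alpha) * vals.size)
    return float(np.sort(vals)[k - 1])


def predict_sites(
    model: InhomogeneousPMM,
    pos_records,
    threshold: float,
    non_overlapping: bool = False,
) -> list[ScoredSite]:
    """All window-strand hits with log likelihood >= threshold.

    With ``non_overlapping=True`` a greedy best-first pass keeps, per
    sequence, only hits that do not overlap an already accepted one.
    """
    W = model.width
    out: list[ScoredSite] = []
    for rid, codes in _iter_codes(pos_records):
        if codes.size < W:
            continue
        win = sliding_window_view(codes, W)
        rc = 3 - win[:, ::-1]
        sp = model.log_prob_words(win)
        sm = model.log_prob_words(rc)
        hits = []
        for ell in np.nonzero(sp >= threshold)[0]:
            hits.append((float(sp[ell]), int(ell), "+", decode(win[ell])))
        for ell in np.nonzero(sm >= threshold)[0]:
            hits.append((float(sm[ell]), int(ell), "-", decode(rc[ell])))
        if non_overlapping:
            hits.sort(key=lambda h: (-h[0], h[1], h[2]))
            taken: list[int] = []
            kept = []
            for h in hits:
                if all(abs(h[1] - t) >= W for t in taken):
                    kept.append(h)
                    taken.append(h[1])
            hits = kept
        hits.sort(key=lambda h: (h[1], h[2]))
        out.extend(
            ScoredSite(rid, ell + 1, strand, score, word)
            for score, ell, strand, word in hits
        )
    return out


def sites_table(sites: list[ScoredSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.sequence_id for s in sites],
            "start": [s.start for s in sites],
            "strand": [s.strand for s in sites],
            "log_likelihood": [s.log_likelihood for s in sites],
            "site_seq": [s.site_seq for s in sites],
        }
    )


def sites_bed(sites: list[ScoredSite], records) -> pd.DataFrame:
    """BED6 rows for sites whose parent records carry genome coordinates."""
    coords = {
        r.id: r.source_coords
        for r in records
        if getattr(r, "source_coords", None) is not None
    }
    rows = []
    for s in sites:
        if s.sequence_id not in coords:
            continue
        chrom, gstart, _gend, _ = coords[s.sequence_id]
        a = gstart + s.start - 1
        rows.append((chrom, a, a + len(s.site_seq), s.sequence_id, s.log_likelihood, s.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
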