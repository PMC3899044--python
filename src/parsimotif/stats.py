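"""Statistical characterization of aligned binding sites.

Position-wise nucleotide frequencies and information content (sequence
logo data), order-k mutual information between a position and its
preceding k-mer with a G-test for significance, and conditional sequence
logos that display, for one motif position, the conditional nucleotide
frequencies of every context class (leaf) of a parsimonious context tree,
with stack widths proportional to how many sites fall in each class.

MI is the plug-in (maximum-likelihood) estimate in bits, range [0, 2] for
a 4-letter alphabet; ``G = 2 n ln(2) MI`` is the classical G statistic
for independence in the 4 x 4**k contingency table, compared against a
chi-square with ``(4-1)(4**k - 1)`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._seq import ALPHABET, context_index, encode
from .markov import PCT

__all__ = [
    "MIStat",
    "ConditionalLogoData",
    "ContextEntry",
    "column_frequencies",
    "mutual_information",
    "mi_profile",
    "conditional_logo",
    "render_logo",
    "render_conditional_logo",
    "roman",
]


def _encode_sites(sites) -> np.ndarray:
    if isinstance(sites, np.ndarray):
        return np.asarray(sites, dtype=np.int64)
    return np.stack([encode(s.site_seq if hasattr(s, "site_seq") else (s.seq if hasattr(s, "seq") else s)) for s in sites]).astype(np.int64)


def roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
            (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for v, sym in vals:
        while n >= v:
            out += sym
            n -= v
    return out


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def column_frequencies(sites) -> tuple[np.ndarray, np.ndarray]:
    """Per-position relative frequencies and information content.

    Returns ``(freqs, ic)`` with ``freqs`` of shape (W, 4) and
    ``ic = 2 - H`` in bits per position (no small-sample correction).
    """
    words = _encode_sites(sites)
    n, W = words.shape
    freqs = np.stack([np.bincount(words[:, i], minlength=4) / n for i in range(W)])
    ic = np.array([2.0 - _entropy_bits(freqs[i]) for i in range(W)])
    return freqs, ic


@dataclass
class MIStat:
    """Mutual information between position i and its preceding k-mer."""

    position: int  # 1-based, > order
    order: int
    mi_bits: float
    g_statistic: float
    df: int
    p_value: float
    significant: bool = True


def mutual_information(sites, i: int, k: int, method: str = "chi2", n_perm: int = 1000, seed: int = 0) -> MIStat:
    """Plug-in MI (bits) of position ``i`` (1-based) and its preceding k-mer.

    The p-value comes from the upper tail of a chi-square for the G
    statistic by default; ``method="permutation"`` shuffles the focal
    column instead.
    """
    if i <= k:
        raise ValueError(f"position {i} has no preceding {k}-mer within the motif")
    words = _encode_sites(sites)
    n, W = words.shape
    if not (1 <= i <= W):
        raise ValueError("position outside motif")
    idx = i - 1
    ctx = context_index(words[:, idx - k : idx][:, ::-1])
    sym = words[:, idx]

    def _mi(ctx_v, sym_v) -> float:
        joint = np.bincount(ctx_v * 4 + sym_v, minlength=4**k * 4).reshape(4**k, 4) / n
        pc = joint.sum(axis=1, keepdims=True)
        ps = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        return float((joint[nz] * np.log2(joint[nz] / (pc @ ps)[nz])).sum())

    mi = _mi(ctx, sym)
    g = 2.0 * n * np.log(2.0) * mi
    df = 3 * (4**k - 1)
    if method == "chi2":
        p = float(chi2.sf(g, df))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.array([_mi(ctx, rng.permutation(sym)) for _ in range(n_perm)])
        p = float((np.count_nonzero(null >= mi) + 1) / (n_perm + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MIStat(position=i, order=k, mi_bits=mi, g_statistic=g, df=df, p_value=p)


def mi_profile(sites, max_order: int = 4, level: float = 1e-3, method: str = "chi2") -> list[MIStat]:
    """MI grid for all valid (position, order) pairs, flagged at ``level``."""
    words = _encode_sites(sites)
    W = words.shape[1]
    out = []
    for k in range(1, max_order + 1):
        for i in range(k + 1, W + 1):
            st = mutual_information(words, i, k, method=method)
            st.significant = st.p_value <= level
            out.append(st)
    return out


def mi_table(stats: list[MIStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [s.position for s in stats],
            "order": [s.order for s in stats],
            "mi_bits": [s.mi_bits for s in stats],
            "g": [s.g_statistic for s in stats],
            "df": [s.df for s in stats],
            "p_value": [s.p_value for s in stats],
            "significant": [s.significant for s in stats],
        }
    )


@dataclass
class ContextEntry:
    label: str  # Roman numeral
    context: str  # human-readable context description (sequence order)
    cond_freqs: np.ndarray  # (4,), raw relative frequencies (zeros if empty)
    n_sites: int
    width_fraction: float
    info_content_bits: float


@dataclass
class ConditionalLogoData:
    position: int  # 1-based
    entries: list[ContextEntry]


def conditional_logo(sites, pct: PCT, position: int) -> ConditionalLogoData:
    """Conditional nucleotide frequencies of each PCT leaf at one position.

    Leaves are taken in tree-traversal order and labeled with Roman
    numerals; widths are the fraction of sites whose preceding context
    falls in each leaf.  Frequencies are raw relative frequencies; leaves
    matching no site get zero vectors (rendered as empty slots).
    """
    words = _encode_sites(sites)
    n, W = words.shape
    idx = position - 1
    d = pct.depth
    if d > idx:
        raise ValueError(f"PCT depth {d} exceeds the {idx} predecessors of position {position}")
    ctx = context_index(words[:, idx - d : idx][:, ::-1]) if d else np.zeros(n, dtype=np.int64)
    leaf_ids = pct.leaf_of_context[ctx]
    entries = []
    for li, leaf in enumerate(pct.leaves):
        mask = leaf_ids == li
        m = int(mask.sum())
        if m:
            freqs = np.bincount(words[mask, idx], minlength=4) / m
            ic = 2.0 - _entropy_bits(freqs)
        else:
            freqs = np.zeros(4)
            ic = 0.0
        entries.append(
            ContextEntry(
                label=roman(li + 1),
                context=leaf.label(),
                cond_freqs=freqs,
                n_sites=m,
                width_fraction=m / n,
                info_content_bits=ic,
            )
        )
    return ConditionalLogoData(position=position, entries=entries)


def conditional_logo_table(data: ConditionalLogoData) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [e.label for e in data.entries],
            "context": [e.context for e in data.entries],
            "n_sites": [e.n_sites for e in data.entries],
            "width_fraction": [e.width_fraction for e in data.entries],
            "ic_bits": [e.info_content_bits for e in data.entries],
            **{ALPHABET[a]: [e.cond_freqs[a] for e in data.entries] for a in range(4)},
        }
    )


# ---------------------------------------------------------------------------
# SVG rendering (matplotlib)
# ---------------------------------------------------------------------------

_LETTER_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def _draw_stack(ax, x, width, freqs, scale):
    """Draw one IC-scaled letter stack with its base at y=0."""
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    fp = FontProperties(family="DejaVu Sans", weight="bold")
    order = np.argsort(freqs)  # smallest at the bottom
    y = 0.0
    for a in order:
        h = float(freqs[a]) * scale
        if h <= 0:
            continue
        tp = TextPath((0, 0), ALPHABET[a], size=1.0, prop=fp)
        bb = tp.get_extents()
        tf = (
            Affine2D()
            .translate(-bb.x0, -bb.y0)
            .scale(width * 0.9 / bb.width, h / bb.height)
            .translate(x + width * 0.05, y)
        )
        ax.add_patch(PathPatch(tf.transform_path(tp), color=_LETTER_COLORS[ALPHABET[a]], lw=0))
        y += h


def _save_svg(fig, path):
    fig.savefig(path, format="svg", metadata={"Date": None})


def render_logo(freqs: np.ndarray, ic: np.ndarray, path) -> None:
    """Sequence logo SVG: stack heights are IC-scaled letter frequencies."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty logo data")
    W = freqs.shape[0]
    with plt.rc_context({"svg.hashsalt": "parsimotif"}):
        fig, ax = plt.subplots(figsize=(0.45 * W + 1, 2.2))
        for i in range(W):
            _draw_stack(ax, i + 0.5, 1.0, freqs[i], float(ic[i]))
        ax.set_xlim(0.5, W + 0.5)
        ax.set_ylim(0, 2.0)
        ax.set_xticks(range(1, W + 1))
        ax.set_ylabel("bits")
        ax.set_xlabel("position")
        fig.tight_layout()
        _save_svg(fig, path)
        plt.close(fig)


def render_conditional_logo(data: ConditionalLogoData, path) -> None:
    """Conditional sequence logo SVG: one stack per context, width-scaled."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not data.entries:
        raise ValueError("empty conditional logo data")
    with plt.rc_context({"svg.hashsalt": "parsimotif"}):
        fig, ax = plt.subplots(figsize=(8, 2.6))
        x = 0.0
        for e in data.entries:
            w = max(e.width_fraction, 0.0)
            if w > 0 and e.n_sites > 0:
                _draw_stack(ax, x, w, e.cond_freqs, e.info_content_bits)
            if w > 0.005:
                ax.text(x + w / 2, -0.18, e.label, ha="center", va="top", fontsize=7)
            x += w
        ax.set_xlim(0, max(x, 1e-9))
        ax.set_ylim(-0.35, 2.0)
        ax.set_ylabel("bits")
        ax.set_title(f"conditional logo, position {data.position}")
        ax.set_xticks([])
        fig.tight_layout()
        _save_svg(fig, path)
        plt.close(fig)
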