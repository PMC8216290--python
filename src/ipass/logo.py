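"""Score-weighted probability logos over all valid amber contexts.

All 12-mer flanking contexts whose four in-frame codons ((-6..-4),
(-3..-1), (+4..+6), (+7..+9)) are sense codons — 61^4 = 13,845,841 of
the 4^12 possible 12-mers — are scored with the model (stop fixed to
UAG).  The logo statistic per (position, nucleotide) cell is a pooled
two-sample two-tailed Student's t comparing the scores of k-mers
carrying that nucleotide at that position against all others: positive
t marks enrichment among high-scoring contexts, negative t depletion.

Two computation routes are provided.  :func:`weighted_logo` consumes
any stream of (k-mer, score) pairs, accumulating only per-cell counts,
sums and sums of squares (O(1) memory).  :func:`logo_from_model`
covers the full 13.8M contexts exactly by exploiting the additivity of
the linear model: scores decompose into an upstream and a downstream
hexamer term, so all moments reduce to sums over the 61^2 = 3721
hexamers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from ipass.contexts import AMBER, RNA_BASES, SENSE_CODONS, SequenceContext
from ipass.model import POSITIONS, IpassModel, feature_names

N_VALID_CONTEXTS = 61**4  # 13,845,841
N_ALL_12MERS = 4**12

_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


def enumerate_valid_contexts() -> Iterator[tuple[str, str]]:
    """Yield every (upstream 6-mer, downstream 6-mer) pair whose four
    in-frame codons are all sense codons, in lexicographic order."""
    for u1, u2 in itertools.product(SENSE_CODONS, repeat=2):
        up = u1 + u2
        for d1, d2 in itertools.product(SENSE_CODONS, repeat=2):
            yield up, d1 + d2


def count_valid_contexts() -> int:
    """Exhaustively count the enumerated contexts (checks 61^4)."""
    return sum(1 for _ in enumerate_valid_contexts())


def _position_weights(model: IpassModel) -> tuple[float, np.ndarray]:
    """Per-(position, base) additive contributions for UAG k-mers.

    Returns (const, C) with C of shape (12, 4):  score of a k-mer is
    const + sum_p C[p, base_at_p].  The GC column's weight is folded
    into each base's contribution (1/15 per G or C) and the stop's G
    into the constant.
    """
    c0, e = model.effective_linear_form()
    names = feature_names()
    idx = {name: i for i, name in enumerate(names)}
    e_gc = e[idx["gc"]]
    const = c0 + e[idx["stop_UAG"]] + e_gc / 15.0  # UAG contributes one G
    C = np.zeros((12, 4))
    for pi, p in enumerate(POSITIONS):
        label = f"{'m' if p < 0 else 'p'}{abs(p)}"
        for bi, b in enumerate(RNA_BASES):
            C[pi, bi] = e[idx[f"{label}_{b}"]]
            if b in "GC":
                C[pi, bi] += e_gc / 15.0
    return float(const), C


def score_all(
    model: IpassModel, stream: Iterable[tuple[str, str]] | None = None
) -> Iterator[tuple[str, float]]:
    """Score a stream of (upstream, downstream) pairs with stop fixed to UAG.

    Defaults to the full enumeration.  Uses the additive decomposition
    of the linear model (per-position weight lookup), which equals the
    naive encode-then-dot computation exactly.
    """
    const, C = _position_weights(model)
    if stream is None:
        stream = enumerate_valid_contexts()
    for up, down in stream:
        kmer = up + down
        s = const + sum(C[p, _BASE_INDEX[b]] for p, b in enumerate(kmer))
        yield kmer, float(s)


@dataclass
class LogoTable:
    """Per-(position, nucleotide) logo statistics.

    ``t``/``p``/``n`` are 12 x 4 arrays (rows in position order -6..-1,
    +4..+9; columns A,C,G,U).  ``zero_variance`` flags cells where the
    pooled variance vanished and t was set to 0 by convention.
    """

    t: np.ndarray
    p: np.ndarray
    n: np.ndarray
    zero_variance: np.ndarray
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi, pos in enumerate(POSITIONS):
            for bi, b in enumerate(RNA_BASES):
                rows.append(
                    {
                        "position": pos,
                        "nucleotide": b,
                        "t": self.t[pi, bi],
                        "p": self.p[pi, bi],
                        "n": int(self.n[pi, bi]),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def top_cell(self) -> tuple[int, str, float]:
        """(position, nucleotide, t) of the maximal |t| cell."""
        pi, bi = np.unravel_index(np.argmax(np.abs(self.t)), self.t.shape)
        return POSITIONS[pi], RNA_BASES[bi], float(self.t[pi, bi])


def _t_from_moments(
    n1: np.ndarray, s1: np.ndarray, q1: np.ndarray, N: int, S: float, Q: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled two-sample t of group (n1, s1, q1) vs the complement of
    totals (N, S, Q); q's are sums of squares."""
    n2 = N - n1
    s2 = S - s1
    q2 = Q - q1
    ok = (n1 >= 1) & (n2 >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        ss1 = q1 - s1**2 / n1
        ss2 = q2 - s2**2 / n2
        sp2 = (ss1 + ss2) / (N - 2)
        denom = np.sqrt(np.clip(sp2, 0.0, None) * (1.0 / n1 + 1.0 / n2))
    zero = ok & (denom <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (m1 - m2) / np.where(denom <= 0, 1.0, denom))
    t = np.where(ok, t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df=N - 2)
    return t, p, zero


def weighted_logo(scores: Iterable[tuple[str, float]]) -> LogoTable:
    """Build the logo from a stream of (12-mer, score) pairs.

    Only streaming moments (count, sum, sum of squares per cell plus
    grand totals) are kept; memory is O(1) in the stream length.
    """
    n = np.zeros((12, 4))
    s = np.zeros((12, 4))
    q = np.zeros((12, 4))
    N = 0
    S = 0.0
    Q = 0.0
    for kmer, score in scores:
        N += 1
        S += score
        Q += score * score
        for pi, b in enumerate(kmer):
            bi = _BASE_INDEX[b]
            n[pi, bi] += 1
            s[pi, bi] += score
            q[pi, bi] += score * score
    if N < 2:
        raise ValueError("need at least two scored k-mers")
    t, p, zero = _t_from_moments(n, s, q, N, S, Q)
    return LogoTable(t=t, p=p, n=n, zero_variance=zero, total=N)


def _hexamer_arrays(model: IpassModel) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """All 3721 sense-codon hexamers as base-index rows, plus their
    additive score contributions for the upstream and downstream halves."""
    const, C = _position_weights(model)
    codons = np.array(
        [[_BASE_INDEX[b] for b in c] for c in SENSE_CODONS], dtype=np.int8
    )
    first = np.repeat(codons, len(codons), axis=0)
    second = np.tile(codons, (len(codons), 1))
    hexamers = np.concatenate([first, second], axis=1)  # (3721, 6)
    up_contrib = C[np.arange(6)[None, :], hexamers].sum(axis=1)
    down_contrib = C[np.arange(6, 12)[None, :], hexamers].sum(axis=1)
    return const, hexamers, up_contrib, down_contrib


def logo_from_model(model: IpassModel) -> LogoTable:
    """Exact logo over all 13,845,841 valid contexts.

    Scores of a linear model split as const + a_u + b_d over the
    upstream/downstream hexamers u, d, so every cell's count, sum and
    sum of squares is a closed-form aggregate over the 3721 hexamers —
    the full pass never materializes the 13.8M scores.
    """
    const, hexamers, up_c, down_c = _hexamer_arrays(model)
    H = len(hexamers)  # 3721
    a = const + up_c  # fold the constant into the upstream term
    b = down_c
    Sa, Qa = a.sum(), (a**2).sum()
    Sb, Qb = b.sum(), (b**2).sum()
    N = H * H
    S = H * Sa + H * Sb
    Q = H * Qa + 2.0 * Sa * Sb + H * Qb

    n = np.zeros((12, 4))
    s = np.zeros((12, 4))
    q = np.zeros((12, 4))
    for half, contrib, So, Qo in (
        (0, a, Sb, Qb),  # upstream positions: sum over d of (a_u + b_d)^2
        (6, b, Sa, Qa),
    ):
        for j in range(6):
            col = hexamers[:, j]
            for bi in range(4):
                mask = col == bi
                m = int(mask.sum())
                c = contrib[mask]
                n[half + j, bi] = m * H
                s[half + j, bi] = H * c.sum() + m * So
                q[half + j, bi] = H * (c**2).sum() + 2.0 * c.sum() * So + m * Qo
    t, p, zero = _t_from_moments(n, s, q, N, S, Q)
    return LogoTable(t=t, p=p, n=n, zero_variance=zero, total=N)


def render_logo(table: LogoTable, path: str | Path) -> None:
    """Optional stacked-letter rendering (letter height = t)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "U": "#e31a1c"}
    fig, ax = plt.subplots(figsize=(8, 3))
    for pi, pos in enumerate(POSITIONS):
        up, down = 0.0, 0.0
        for bi, base in enumerate(RNA_BASES):
            tv = table.t[pi, bi]
            if tv >= 0:
                ax.bar(pi, tv, bottom=up, width=0.8, color=colors[base])
                ax.text(pi, up + tv / 2, base, ha="center", va="center", fontsize=7)
                up += tv
            else:
                ax.bar(pi, tv, bottom=down, width=0.8, color=colors[base])
                ax.text(pi, down + tv / 2, base, ha="center", va="center", fontsize=7)
                down += tv
    ax.set_xticks(range(12), [str(p) for p in POSITIONS])
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("position relative to UAG")
    ax.set_ylabel("t value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
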