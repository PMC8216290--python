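"""Model-guided design of amber sites.

Two tasks the scores feed directly: ranking the candidate amber
positions within an ORF, and raising the score of a fixed position by
*silent* mutation of the two codons on each side of UAG — synonymous
exchanges leave the encoded protein untouched while reshaping the
-6..-1 / +4..+9 nucleotide context.  A score gain of at least 2.5
after synonymous exchange is the default recommendation threshold for
expecting a real efficiency improvement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import unambiguous_rna_by_id

from ipass.contexts import AMBER, SENSE_CODONS, AmberSite, SequenceContext, scan_orf
from ipass.model import IpassModel, classify_permissive

DELTA_CUTOFF = 2.5

_STANDARD_TABLE = unambiguous_rna_by_id[1]  # standard genetic code

#: amino acid encoded by each sense codon (RNA, standard code)
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _SYNONYMS.setdefault(_aa, ())
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _SYNONYMS[_aa] = _SYNONYMS[_aa] + (_codon,)


def synonymous_codons(codon: str) -> tuple[str, ...]:
    """All sense codons encoding the same amino acid (input included)."""
    codon = codon.upper().replace("T", "U")
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"{codon!r} is not a sense codon of the standard code")
    return _SYNONYMS[aa]


def translate_codons(codons: tuple[str, ...]) -> str:
    return "".join(CODON_TO_AA[c] for c in codons)


@dataclass(frozen=True)
class SilentVariant:
    """One synonymous recoding of the four codons flanking an amber site."""

    site: AmberSite
    upstream_codons: tuple[str, str]
    downstream_codons: tuple[str, str]
    context: SequenceContext
    score: float
    delta: float

    @property
    def recommended(self) -> bool:
        return self.delta >= DELTA_CUTOFF


def enumerate_silent_variants(
    site: AmberSite, model: IpassModel
) -> list[SilentVariant]:
    """All synonymous recodings of the two codons on each side of UAG.

    Requires a frame-aligned site (flanks lie on codon boundaries of
    the parent ORF).  The Cartesian product of the four codons'
    synonym classes is scored; the result is sorted by score
    descending, ties broken lexicographically on the flanking context,
    and always contains the original (delta 0).
    """
    if not site.frame_aligned:
        raise ValueError(
            "flanks are not codon-aligned with the parent ORF "
            "(site context drawn partly from UTR sequence)"
        )
    ctx = site.context
    u1, u2 = ctx.upstream[:3], ctx.upstream[3:]
    d1, d2 = ctx.downstream[:3], ctx.downstream[3:]
    original_score = model.score(ctx)
    variants = []
    for a, b, c, d in itertools.product(
        synonymous_codons(u1),
        synonymous_codons(u2),
        synonymous_codons(d1),
        synonymous_codons(d2),
    ):
        vctx = SequenceContext(a + b, AMBER, c + d)
        s = model.score(vctx)
        variants.append(
            SilentVariant(
                site=site,
                upstream_codons=(a, b),
                downstream_codons=(c, d),
                context=vctx,
                score=s,
                delta=s - original_score,
            )
        )
    variants.sort(key=lambda v: (-v.score, str(v.context)))
    return variants


def rank_sites(
    orf: str,
    model: IpassModel,
    flank5: str = "",
    flank3: str = "",
    parent_id: str = "orf",
    delta_cutoff: float = DELTA_CUTOFF,
) -> pd.DataFrame:
    """Scan an ORF, score every candidate amber position, and attach the
    best silent variant per site.

    Returns one row per scannable codon, sorted by score descending:
    codon index, original codon, context, score, permissive call, best
    variant context/score, delta, and a recommendation flag
    (delta >= ``delta_cutoff``).  Sites whose flanks come from UTR
    sequence are scored but not optimized.
    """
    rows = []
    for site in scan_orf(orf, flank5, flank3, parent_id=parent_id):
        score = model.score(site.context)
        if site.frame_aligned:
            best = enumerate_silent_variants(site, model)[0]
            best_ctx, best_score = str(best.context), best.score
        else:
            best_ctx, best_score = str(site.context), score
        delta = best_score - score
        rows.append(
            {
                "codon_index": site.codon_index,
                "original_codon": site.original_codon,
                "context": str(site.context),
                "score": score,
                "permissive": classify_permissive(score),
                "best_variant": best_ctx,
                "best_score": best_score,
                "delta": delta,
                "recommended": delta >= delta_cutoff,
                "frame_aligned": site.frame_aligned,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("score", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
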