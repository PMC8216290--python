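"""Stop-codon sequence contexts.

A *sequence context* is the 15 nt window around a stop codon: six
nucleotides upstream (positions -6..-1), the stop triplet itself
(+1..+3) and six nucleotides downstream (+4..+9).  The downstream
window therefore covers the first two in-frame codons of the 3'
trailer.  Contexts are the unit every other module consumes: the
regression model is trained on them, the optimizer mutates them, the
logo enumerates them.

The canonical internal alphabet is RNA (A/C/G/U); DNA input is
converted on entry.  Ambiguity codes are rejected outright — the
downstream model has no defined encoding for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

RNA_BASES = "ACGU"
STOP_CODONS = ("UAA", "UAG", "UGA")
AMBER = "UAG"

#: sense codons of the standard genetic code, lexicographic over A<C<G<U
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in RNA_BASES
    for b in RNA_BASES
    for c in RNA_BASES
    if a + b + c not in STOP_CODONS
)

_VALID = set("ACGTU")


class SequenceError(ValueError):
    """Invalid nucleotide sequence or context geometry."""


def validate_sequence(seq: str, alphabet_policy: str = "either") -> str:
    """Canonicalize a nucleotide string to uppercase RNA.

    Parameters
    ----------
    seq:
        Non-empty nucleotide string, DNA or RNA, any case.
    alphabet_policy:
        ``"rna"`` rejects T, ``"dna"`` rejects U, ``"either"`` accepts
        both.  T is always mapped to U in the returned string.

    Raises
    ------
    SequenceError
        On an empty string, an unknown policy, or any character outside
        the plain four-letter alphabet (ambiguity codes included); the
        message names the 1-based offending position.
    """
    if alphabet_policy not in ("rna", "dna", "either"):
        raise SequenceError(f"unknown alphabet policy {alphabet_policy!r}")
    if not seq:
        raise SequenceError("empty sequence")
    up = seq.upper()
    forbidden = {"rna": "T", "dna": "U", "either": ""}[alphabet_policy]
    for i, ch in enumerate(up, start=1):
        if ch not in _VALID or ch in forbidden:
            raise SequenceError(
                f"invalid character {ch!r} at position {i} "
                f"(policy {alphabet_policy})"
            )
    return up.replace("T", "U")


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class SequenceContext:
    """The -6..+9 window around a stop codon.

    ``upstream`` covers positions -6..-1, ``stop`` the triplet at
    +1..+3, ``downstream`` positions +4..+9.  ``gc`` is the G+C
    fraction over all 15 nt and is derived, never supplied.
    """

    upstream: str
    stop: str
    downstream: str

    def __post_init__(self) -> None:
        for name, s, n in (
            ("upstream", self.upstream, 6),
            ("downstream", self.downstream, 6),
        ):
            canon = validate_sequence(s, "rna")
            if canon != s:
                object.__setattr__(self, name, canon)
            if len(s) != n:
                raise SequenceError(f"{name} must be {n} nt, got {len(s)}")
        stop = validate_sequence(self.stop, "rna")
        object.__setattr__(self, "stop", stop)
        if stop not in STOP_CODONS:
            raise SequenceError(f"stop must be one of {STOP_CODONS}, got {stop!r}")

    @property
    def gc(self) -> float:
        """G+C fraction of the 15 nt from -6 to +9."""
        return _gc_fraction(self.upstream + self.stop + self.downstream)

    @property
    def kmer(self) -> str:
        """The flanking 12-mer (upstream + downstream, stop excised)."""
        return self.upstream + self.downstream

    def __str__(self) -> str:
        return self.upstream + self.stop + self.downstream


@dataclass(frozen=True)
class AmberSite:
    """A (possible) amber position within a parent ORF.

    ``codon_index`` is 1-based.  ``original_codon`` is the sense codon
    occupying the position before substitution by UAG (``"UAG"`` if the
    position already is amber).  ``frame_aligned`` records whether all
    six flanking nucleotides on each side come from in-frame codons of
    the parent ORF, which the silent-mutation optimizer requires.
    """

    parent_id: str
    codon_index: int
    context: SequenceContext
    original_codon: str = AMBER
    frame_aligned: bool = True

    def __post_init__(self) -> None:
        if self.context.stop != AMBER:
            raise SequenceError("AmberSite context must have a UAG stop")


def extract_stop_context(cds: str, three_prime: str, *, alphabet_policy: str = "either") -> SequenceContext:
    """Extract the -6..+9 context of a CDS's terminal stop codon.

    ``cds`` must be a full coding sequence ending in its stop codon
    (length a multiple of 3, at least 9 nt so six coding nucleotides
    precede the stop); ``three_prime`` supplies at least 6 nt of 3'
    trailer.  An in-frame stop upstream of the terminal one is an
    error, reported with its 1-based codon index.
    """
    cds = validate_sequence(cds, alphabet_policy)
    three_prime = validate_sequence(three_prime, alphabet_policy)
    if len(cds) % 3 != 0:
        raise SequenceError(f"CDS length {len(cds)} is not a multiple of 3")
    if len(cds) < 9:
        raise SequenceError("CDS too short: need >= 6 coding nt before the stop")
    if len(three_prime) < 6:
        raise SequenceError(
            f"need >= 6 nt of 3' sequence, got {len(three_prime)}"
        )
    stop = cds[-3:]
    if stop not in STOP_CODONS:
        raise SequenceError(f"CDS does not end in a stop codon (got {stop!r})")
    internal = [
        i // 3 + 1
        for i in range(0, len(cds) - 3, 3)
        if cds[i : i + 3] in STOP_CODONS
    ]
    if internal:
        raise SequenceError(
            f"internal in-frame stop codon(s) at codon index {internal}"
        )
    return SequenceContext(upstream=cds[-9:-3], stop=stop, downstream=three_prime[:6])


def extract_from_cdna(cdna: str, cds_start: int, cds_end: int, *, alphabet_policy: str = "either") -> SequenceContext:
    """Extract a stop context from a cDNA given 1-based inclusive CDS coordinates.

    The CDS slice (stop codon included) must end in a stop, and the
    cDNA must extend at least 6 nt past ``cds_end``.
    """
    cdna = validate_sequence(cdna, alphabet_policy)
    if not (1 <= cds_start < cds_end <= len(cdna)):
        raise SequenceError(
            f"CDS coordinates {cds_start}..{cds_end} out of range for "
            f"cDNA of length {len(cdna)}"
        )
    return extract_stop_context(cdna[cds_start - 1 : cds_end], cdna[cds_end:])


def scan_orf(
    orf: str,
    flank5: str = "",
    flank3: str = "",
    parent_id: str = "orf",
    *,
    alphabet_policy: str = "either",
) -> list[AmberSite]:
    """Enumerate the amber contexts obtained by replacing each codon by UAG.

    A terminal stop codon on ``orf`` is stripped and does not serve as
    downstream sequence.  For each remaining codon position the context
    that would exist were that codon UAG is built from the 6 nt on each
    side, drawn from the ORF itself or, where the ORF runs out, from
    ``flank5``/``flank3`` (UTR sequence; such sites are marked as not
    frame-aligned).  Positions still lacking 6 nt on either side are
    skipped.
    """
    orf = validate_sequence(orf, alphabet_policy)
    flank5 = validate_sequence(flank5, alphabet_policy) if flank5 else ""
    flank3 = validate_sequence(flank3, alphabet_policy) if flank3 else ""
    if len(orf) % 3 != 0:
        raise SequenceError(f"ORF length {len(orf)} is not a multiple of 3")
    if orf[-3:] in STOP_CODONS:
        orf = orf[:-3]
    n_codons = len(orf) // 3
    sites: list[AmberSite] = []
    for p in range(1, n_codons + 1):
        start = 3 * (p - 1)
        left = orf[:start]
        right = orf[start + 3 :]
        need_left = 6 - len(left)
        need_right = 6 - len(right)
        if need_left > 0:
            if len(flank5) < need_left:
                continue
            upstream = flank5[len(flank5) - need_left :] + left
            aligned = False
        else:
            upstream = left[-6:]
            aligned = True
        if need_right > 0:
            if len(flank3) < need_right:
                continue
            downstream = right + flank3[:need_right]
            aligned = False
        else:
            downstream = right[:6]
        sites.append(
            AmberSite(
                parent_id=parent_id,
                codon_index=p,
                context=SequenceContext(upstream, AMBER, downstream),
                original_codon=orf[start : start + 3],
                frame_aligned=aligned,
            )
        )
    return sites


def dedupe_contexts(
    records: Iterable[tuple[str, SequenceContext]],
) -> list[tuple[str, SequenceContext]]:
    """Drop duplicate contexts per protein, keeping first occurrences.

    Isoforms of one protein frequently share the terminal exon; only
    distinct (upstream, stop, downstream) strings are retained per
    protein identifier, in stable input order.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for pid, ctx in records:
        key = (pid, str(ctx))
        if key not in seen:
            seen.add(key)
            out.append((pid, ctx))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, *, alphabet_policy: str = "either") -> dict[str, str]:
    """Read a (multi-record, line-wrapped) FASTA into id -> canonical RNA."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out[rec.id] = validate_sequence(str(rec.seq), alphabet_policy)
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    if not out:
        raise SequenceError(f"no FASTA records in {path}")
    return out


def context_from_15mer(s: str) -> SequenceContext:
    """Build a SequenceContext from a 15 nt string (-6..+9)."""
    s = validate_sequence(s)
    if len(s) != 15:
        raise SequenceError(f"context string must be 15 nt, got {len(s)}")
    return SequenceContext(s[:6], s[6:9], s[9:])


def contexts_to_table(records: Sequence[tuple[str, SequenceContext]]) -> pd.DataFrame:
    """Tabulate (id, context) pairs with the on-disk column layout."""
    return pd.DataFrame(
        {
            "id": [pid for pid, _ in records],
            "context_m6_p9": [str(c) for _, c in records],
            "stop": [c.stop for _, c in records],
            "gc": [c.gc for _, c in records],
        }
    )


def write_context_table(records: Sequence[tuple[str, SequenceContext]], path: str | Path) -> None:
    contexts_to_table(records).to_csv(path, sep="\t", index=False)


def read_context_table(path: str | Path) -> list[tuple[str, SequenceContext]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        (str(row.id), context_from_15mer(row.context_m6_p9))
        for row in df.itertuples()
    ]
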