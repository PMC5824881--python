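"""Scanning 3'UTR sequences for miRNA seed-match sites.

Coordinates are 0-based half-open offsets on the UTR sense strand (miRNA
targeting is sense-strand by definition, so only that strand is scanned).
``N`` or any other non-ACGT letter never matches a word.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List

from .seeds import MatureMirna, SeedWordSet, classify_pair, seed_words

__all__ = ["UtrRecord", "SiteHit", "find_seed_sites", "find_3comp_sites"]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-1A", "3comp")


@dataclass(frozen=True)
class UtrRecord:
    """One gene's 3'UTR sequence (DNA over A/C/G/T/N)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("UTR record must have a non-empty gene_id")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SiteHit:
    """One seed-match site in one UTR."""

    gene_id: str
    family_key: str
    site_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("site coordinates must satisfy 0 <= start < end")


def _occurrences(haystack: str, needle: str) -> Iterator[int]:
    """All (possibly overlapping) start offsets of ``needle`` in ``haystack``."""
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def find_seed_sites(utr: UtrRecord, words: SeedWordSet) -> List[SiteHit]:
    """All canonical seed sites of one family in one UTR.

    Longest-site precedence keeps the universe non-redundant: an 8mer match
    reports a single 8mer hit and suppresses the constituent 7mer-m8 hit at
    the same start and the 7mer-1A hit at start+1.  Scanning is exhaustive
    left-to-right, so distinct physical sites are all reported.
    """
    seq = utr.sequence
    starts_8 = set(_occurrences(seq, words.word_8mer))
    hits = [
        SiteHit(utr.gene_id, words.family_key, "8mer", s, s + 8)
        for s in sorted(starts_8)
    ]
    for s in _occurrences(seq, words.word_7m8):
        if s not in starts_8:
            hits.append(SiteHit(utr.gene_id, words.family_key, "7mer-m8", s, s + 7))
    suppressed_7a1 = {s + 1 for s in starts_8}
    for s in _occurrences(seq, words.word_7a1):
        if s not in suppressed_7a1:
            hits.append(SiteHit(utr.gene_id, words.family_key, "7mer-1A", s, s + 7))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _seed_window_states(mirna: MatureMirna, window: str) -> List[str]:
    """Pairing states of miRNA nt 2-8 against a 7 nt UTR window (antiparallel)."""
    # miRNA nt (2+i) opposes window[6-i].
    return [
        classify_pair(mirna.sequence[1 + i], window[6 - i]) for i in range(7)
    ]


def _has_3p_block(mirna: MatureMirna, seq: str, seed_start: int) -> bool:
    """True if miRNA nt 13-17 form >= 4 consecutive WC pairs with UTR sequence
    1-6 nt 5' of the seed-match window starting at ``seed_start``."""
    if len(mirna.sequence) < 17:
        return False
    for gap in range(1, 7):
        run = best = 0
        for j in range(5):  # miRNA nt 13+j opposes utr[seed_start - gap - 1 - j]
            pos = seed_start - gap - 1 - j
            if pos >= 0 and classify_pair(mirna.sequence[12 + j], seq[pos]) == "WC":
                run += 1
                best = max(best, run)
            else:
                run = 0
        if best >= 4:
            return True
    return False


def find_3comp_sites(utr: UtrRecord, mirna: MatureMirna) -> List[SiteHit]:
    """3'-compensatory sites: an imperfect seed rescued by 3' pairing.

    A window is typed ``3comp`` when the seed region (miRNA nt 2-8) pairs
    with exactly six Watson-Crick pairs plus exactly one G:U wobble or one
    mismatch, and a block of at least four consecutive Watson-Crick pairs
    exists between miRNA nt 13-17 and UTR sequence 1-6 nt 5' of the seed
    window.  Canonical (perfect seed) sites are never reported as 3comp.
    This is a deliberately simple operational rule; the site class has no
    single standard definition.
    """
    seq = utr.sequence
    if len(seq) < 7:
        return []
    words = seed_words(mirna)
    canonical_spans = [
        (h.start, h.end) for h in find_seed_sites(utr, words)
    ]
    hits: List[SiteHit] = []
    for s in range(len(seq) - 6):
        window = seq[s : s + 7]
        if set(window) - set("ACGT"):
            continue
        if any(cs <= s and s + 7 <= ce for cs, ce in canonical_spans):
            continue  # already a canonical site
        states = _seed_window_states(mirna, window)
        n_wc = states.count("WC")
        n_gu = states.count("GU")
        n_mm = states.count("mismatch")
        if n_wc == 6 and (n_gu == 1 or n_mm == 1) and _has_3p_block(mirna, seq, s):
            hits.append(SiteHit(utr.gene_id, words.family_key, "3comp", s, s + 7))
    return hits
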