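"""Mature miRNAs, seed-derived target words, and miRNA:target pairing profiles.

A miRNA recognises targets mainly through its *seed*, nucleotides 2-8 counted
from the 5' end.  The canonical 3'UTR site types are named after the part of
the seed they match:

* ``7mer-m8`` -- reverse complement of miRNA nt 2-8;
* ``7mer-1A`` -- reverse complement of nt 2-7 followed by an ``A`` opposite
  miRNA position 1 (the A is a feature of the site, not a base pair);
* ``8mer``   -- the 7mer-m8 word followed by that position-1 ``A``.

Target words are DNA (the 3'UTR strand that the scan runs over); miRNA
sequences are RNA.  miRNAs with an identical nt 2-8 seed form one *family*
and are keyed by their shared 7mer-m8 word.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Sequence

from Bio.Seq import Seq

__all__ = [
    "MatureMirna",
    "SeedWordSet",
    "PairState",
    "seed_words",
    "pairing_profile",
    "revcomp_dna",
    "rna_to_dna",
]

_RNA_ALPHABET = frozenset("ACGU")
_DNA_ALPHABET = frozenset("ACGT")

#: Watson-Crick partners, miRNA (RNA) base -> target (DNA) base.
_WC_PARTNER = {"A": "T", "C": "G", "G": "C", "U": "A"}
#: G:U wobble partners, miRNA base -> target base.
_GU_PARTNER = {"G": "T", "U": "G"}

PairState = Literal["WC", "GU", "mismatch", "unpaired"]


def rna_to_dna(sequence: str) -> str:
    """Transcribe an RNA string into its DNA spelling (U -> T)."""
    return sequence.upper().replace("U", "T")


def revcomp_dna(sequence: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA: a name and its RNA sequence, 5'->3'.

    The sequence must be at least 8 nt so that a full seed (nt 2-8) exists.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.name:
            raise ValueError("miRNA must have a non-empty name")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.name!r}: sequence contains non-RNA letters {sorted(bad)}"
            )
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.name!r}: sequence shorter than 8 nt, no full seed"
            )

    @property
    def seed(self) -> str:
        """Seed region, nt 2-8, as RNA."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class SeedWordSet:
    """The DNA target-site words derived from one miRNA seed.

    ``family_key`` equals ``word_7m8`` and identifies the seed family.
    """

    family_key: str
    word_8mer: str
    word_7m8: str
    word_7a1: str

    def __post_init__(self) -> None:
        for word in (self.word_8mer, self.word_7m8, self.word_7a1):
            bad = set(word) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"seed word {word!r} contains non-DNA letters")
        if self.word_8mer != self.word_7m8 + "A":
            raise ValueError("word_8mer must be word_7m8 + 'A'")
        if self.word_7a1 != self.word_7m8[1:] + "A":
            raise ValueError("word_7a1 must be word_7m8[1:] + 'A'")
        if self.family_key != self.word_7m8:
            raise ValueError("family_key must equal word_7m8")

    @property
    def heptamers(self) -> tuple:
        """The two 7 nt words (7mer-m8, 7mer-1A)."""
        return (self.word_7m8, self.word_7a1)


def seed_words(mirna: MatureMirna) -> SeedWordSet:
    """Derive the canonical DNA target-site words from a mature miRNA.

    The 7mer-m8 word is the DNA reverse complement of miRNA nt 2-8; the
    7mer-1A word is the reverse complement of nt 2-7 followed by ``A``; the
    8mer word is the 7mer-m8 word followed by ``A``.
    """
    dna = rna_to_dna(mirna.sequence)
    word_7m8 = revcomp_dna(dna[1:8])
    return SeedWordSet(
        family_key=word_7m8,
        word_8mer=word_7m8 + "A",
        word_7m8=word_7m8,
        word_7a1=word_7m8[1:] + "A",
    )


def classify_pair(mirna_base: str, utr_base: str) -> PairState:
    """Classify one miRNA(RNA):target(DNA) base opposition."""
    if _WC_PARTNER.get(mirna_base) == utr_base:
        return "WC"
    if _GU_PARTNER.get(mirna_base) == utr_base:
        return "GU"
    return "mismatch"


def pairing_profile(mirna: MatureMirna, utr_window: str) -> List[PairState]:
    """Per-position pairing classification of a miRNA against a UTR window.

    The window is aligned antiparallel with its 3' end opposite miRNA nt 1,
    i.e. miRNA position ``i`` (1-based from the miRNA 5' end) opposes window
    base ``utr_window[len(utr_window) - i]``.  Positions the window does not
    reach are ``unpaired``.  Returns one state per miRNA position, index 0
    holding position 1.
    """
    window = utr_window.upper()
    bad = set(window) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"UTR window contains non-ACGT letters {sorted(bad)}")
    length = len(window)
    profile: List[PairState] = []
    for i in range(1, len(mirna.sequence) + 1):
        j = length - i
        if j < 0:
            profile.append("unpaired")
        else:
            profile.append(classify_pair(mirna.sequence[i - 1], window[j]))
    return profile


def collapse_families(mirnas: Sequence[MatureMirna]) -> dict:
    """Group miRNAs by identical nt 2-8 seed.

    Returns a mapping family_key -> list of members (input order preserved).
    miRNAs sharing a name but not a sequence are rejected: that is almost
    always an input error.
    """
    seen_names: dict = {}
    families: dict = {}
    for m in mirnas:
        prior = seen_names.get(m.name)
        if prior is not None and prior != m.sequence:
            raise ValueError(
                f"duplicate miRNA name {m.name!r} with conflicting sequences"
            )
        seen_names[m.name] = m.sequence
        key = seed_words(m).family_key
        families.setdefault(key, []).append(m)
    return families
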