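"""Pyrimidine-collapsed trinucleotide substitution channels.

Somatic single-nucleotide variants are classified into 96 classes: six
substitution types with a pyrimidine reference base (C>A, C>G, C>T, T>A,
T>C, T>G) crossed with the 16 combinations of 5' and 3' flanking bases.
A substitution observed at a purine reference base is mapped onto the
reverse-complement strand before lookup, the convention used by COSMIC
SBS catalogs, so each genomic (triplet, alternate) pair belongs to exactly
one channel.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-centered substitution types, in catalog order
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

N_CHANNELS = 96

_SUB_INDEX = {(s[0], s[2]): i for i, s in enumerate(SUBSTITUTION_TYPES)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: canonical channel labels, e.g. ``"A[C>A]A"``; index = 16*sub + 4*five + three
CHANNEL_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
)

LABEL_TO_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase A/C/G/T only)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_index(triplet: str, alt: str) -> int:
    """Channel of a substitution given its genomic triplet context.

    ``triplet`` is the reference trinucleotide centered on the mutated base;
    ``alt`` is the alternate allele on the same (genome forward) strand. If
    the central base is a purine, both are reverse-complemented before
    lookup.
    """
    if len(triplet) != 3 or any(b not in _BASE_INDEX for b in triplet):
        raise ValueError(f"invalid triplet {triplet!r}")
    if alt not in _BASE_INDEX:
        raise ValueError(f"invalid alternate allele {alt!r}")
    ref = triplet[1]
    if ref not in PYRIMIDINES:
        triplet = revcomp(triplet)
        alt = COMPLEMENT[alt]
        ref = triplet[1]
    if alt == ref:
        raise ValueError("reference and alternate alleles are identical")
    sub = _SUB_INDEX[(ref, alt)]
    return 16 * sub + 4 * _BASE_INDEX[triplet[0]] + _BASE_INDEX[triplet[2]]


def channel_label(index: int) -> str:
    """Human-readable label (e.g. ``"T[C>T]G"``) for a channel index."""
    return CHANNEL_LABELS[index]
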