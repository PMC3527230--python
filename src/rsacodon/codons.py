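"""Sense-codon alphabet of the standard genetic code and substitution classification.

The substitution process acts on the 61 sense codons (stop codons TAA, TAG,
TGA are excluded from the state space). Every ordered pair of sense codons
falls into exactly one substitution class: identical, multi-nucleotide
(instantaneous rate zero), or a single-nucleotide change that is synonymous
or nonsynonymous and a transition (A<->G, C<->T) or a transversion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: Stop codons of the standard code (TAA, TAG, TGA).
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


class SubstitutionType(Enum):
    """Category of an ordered codon pair in the rate matrix."""

    IDENTICAL = "identical"
    MULTI = "multi"
    SYN_TS = "synonymous_transition"
    SYN_TV = "synonymous_transversion"
    NONSYN_TS = "nonsynonymous_transition"
    NONSYN_TV = "nonsynonymous_transversion"


@dataclass(frozen=True)
class CodonAlphabet:
    """The 61 sense codons in lexicographic order (A<C<G<T) with translations."""

    codons: tuple[str, ...]
    aa_of: dict[str, str] = field(repr=False)
    index: dict[str, int] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.codons)

    def __contains__(self, codon: str) -> bool:
        return codon in self.index


@lru_cache(maxsize=1)
def sense_codons() -> CodonAlphabet:
    """Return the fixed standard-code alphabet of 61 sense codons.

    Ordering is lexicographic over A<C<G<T; every rate and transition matrix
    in this package uses this order.
    """
    table = standard_dna_table.forward_table
    codons = tuple(
        "".join(c)
        for c in itertools.product(NUCLEOTIDES, repeat=3)
        if "".join(c) not in STOP_CODONS
    )
    aa_of = {c: table[c] for c in codons}
    index = {c: k for k, c in enumerate(codons)}
    return CodonAlphabet(codons=codons, aa_of=aa_of, index=index)


def is_transition(a: str, b: str) -> bool:
    """True if the unordered nucleotide pair {a, b} is {A,G} or {C,T}."""
    return frozenset((a, b)) in _TRANSITION_PAIRS


def classify(i: str, j: str) -> SubstitutionType:
    """Classify the ordered sense-codon pair (i, j).

    The classification is symmetric under argument swap: synonymy compares
    the encoded amino acids, and transition/transversion status depends only
    on the unordered pair of changed nucleotides.

    Raises
    ------
    ValueError
        If either argument is not a sense codon.
    """
    alphabet = sense_codons()
    for c in (i, j):
        if c not in alphabet:
            raise ValueError(f"not a sense codon of the standard code: {c!r}")
    if i == j:
        return SubstitutionType.IDENTICAL
    diffs = [(a, b) for a, b in zip(i, j) if a != b]
    if len(diffs) > 1:
        return SubstitutionType.MULTI
    a, b = diffs[0]
    ts = is_transition(a, b)
    syn = alphabet.aa_of[i] == alphabet.aa_of[j]
    if syn:
        return SubstitutionType.SYN_TS if ts else SubstitutionType.SYN_TV
    return SubstitutionType.NONSYN_TS if ts else SubstitutionType.NONSYN_TV


@lru_cache(maxsize=1)
def substitution_masks() -> dict[SubstitutionType, np.ndarray]:
    """61x61 boolean masks for each substitution class, in alphabet order.

    The four single-change masks plus MULTI and IDENTICAL partition the
    61x61 ordered pairs.
    """
    alphabet = sense_codons()
    n = alphabet.size
    masks = {kind: np.zeros((n, n), dtype=bool) for kind in SubstitutionType}
    for a, ci in enumerate(alphabet.codons):
        for b, cj in enumerate(alphabet.codons):
            masks[classify(ci, cj)][a, b] = True
    for m in masks.values():
        m.setflags(write=False)
    return masks


def single_step_neighbors(codon: str) -> list[str]:
    """Sense codons reachable from ``codon`` by one nucleotide change (<= 9)."""
    alphabet = sense_codons()
    if codon not in alphabet:
        raise ValueError(f"not a sense codon: {codon!r}")
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS:
                out.append(mutant)
    return out
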