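"""The codon state space and substitution classification.

Codon substitution models operate on the 61 sense codons of the standard
genetic code (the three stop codons TAA, TAG and TGA are excluded because
selection removes them from protein-coding sequences).  Every matrix and
vector in this package is indexed by the fixed lexicographic codon order
defined here (A < C < G < T, stops removed).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _CodonTable

NUCLEOTIDES = "ACGT"

_NCBI_STANDARD = _CodonTable.unambiguous_dna_by_id[1]

#: Standard genetic code, codon -> one-letter amino acid ('*' = stop).
STANDARD_CODE: dict[str, str] = dict(_NCBI_STANDARD.forward_table)
STANDARD_CODE.update({c: "*" for c in _NCBI_STANDARD.stop_codons})

STOP_CODONS = frozenset(_NCBI_STANDARD.stop_codons)

#: Purines / pyrimidines; a substitution within either set is a transition.
_TRANSITION_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})


class SubstitutionClass(enum.Enum):
    """Classification of an ordered codon pair for GY94-style rate matrices."""

    IDENTICAL = "identical"
    SYNONYMOUS_TRANSITION = "synonymous_transition"
    SYNONYMOUS_TRANSVERSION = "synonymous_transversion"
    NONSYNONYMOUS_TRANSITION = "nonsynonymous_transition"
    NONSYNONYMOUS_TRANSVERSION = "nonsynonymous_transversion"
    MULTIPLE = "multiple"


@dataclass(frozen=True)
class CodonSpace:
    """The 61 sense codons in fixed lexicographic order with index maps."""

    codons: tuple[str, ...]
    index: dict[str, int] = field(repr=False)
    aa_of: dict[str, str] = field(repr=False)
    stop_codons: frozenset[str] = STOP_CODONS

    def __post_init__(self) -> None:
        if len(self.codons) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(self.codons)}")

    @property
    def n_states(self) -> int:
        return len(self.codons)


class UnsupportedCodeError(ValueError):
    """Raised for genetic-code identifiers other than the standard code."""


class InvalidStateError(ValueError):
    """Raised when a stop codon or malformed codon enters the state space."""


def build_codon_space(code_id: str = "standard") -> CodonSpace:
    """Build the 61-state codon space for the standard genetic code.

    Parameters
    ----------
    code_id:
        Genetic-code identifier.  Only ``"standard"`` (NCBI table 1) is
        supported; the code table itself is data-driven so that alternative
        codes could be added.
    """
    if code_id != "standard":
        raise UnsupportedCodeError(f"unsupported genetic code: {code_id!r}")
    codons = tuple(
        "".join(c)
        for c in itertools.product(NUCLEOTIDES, repeat=3)
        if "".join(c) not in STOP_CODONS
    )
    return CodonSpace(
        codons=codons,
        index={c: i for i, c in enumerate(codons)},
        aa_of={c: STANDARD_CODE[c] for c in codons},
    )


def classify_substitution(c1: str, c2: str, space: CodonSpace) -> SubstitutionClass:
    """Classify the codon pair ``(c1, c2)``; symmetric in its arguments.

    Single-nucleotide changes are split by transition/transversion and by
    whether the encoded amino acid changes; codons differing at two or more
    positions are ``MULTIPLE`` (their instantaneous rate is zero in GY94
    models, which do not allow double substitutions).
    """
    for c in (c1, c2):
        if c not in space.index:
            raise InvalidStateError(f"not a sense codon: {c!r}")
    if c1 == c2:
        return SubstitutionClass.IDENTICAL
    diffs = [(a, b) for a, b in zip(c1, c2) if a != b]
    if len(diffs) > 1:
        return SubstitutionClass.MULTIPLE
    is_transition = frozenset(diffs[0]) in _TRANSITION_PAIRS
    synonymous = space.aa_of[c1] == space.aa_of[c2]
    if synonymous:
        return (
            SubstitutionClass.SYNONYMOUS_TRANSITION
            if is_transition
            else SubstitutionClass.SYNONYMOUS_TRANSVERSION
        )
    return (
        SubstitutionClass.NONSYNONYMOUS_TRANSITION
        if is_transition
        else SubstitutionClass.NONSYNONYMOUS_TRANSVERSION
    )
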