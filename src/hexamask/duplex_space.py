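"""Strand algebra and exhaustive enumeration of the unique dsDNA k-mer space.

A double-stranded DNA word of length ``k`` is read off either strand, so a
strand and its reverse complement denote the same physical duplex.  The
canonical representative chosen here is the lexicographic minimum of the
pair under the ordering ``A < C < G < T``, the convention used by most
k-mer tooling.  For even ``k`` a strand can equal its own reverse
complement (a reverse-complement palindrome, e.g. ``GAATTC``); such
duplexes have one strand representation instead of two, which is why the
number of distinct duplexes is ``(4**k + 4**(k//2)) / 2`` for even ``k``
and ``4**k / 2`` for odd ``k`` — 2080 for ``k = 6``.

Each duplex also carries a weak/strong *mask*: positionwise, A/T base
pairs (two hydrogen bonds) are written ``W`` and C/G pairs (three bonds)
are written ``S``, per the standard IUPAC degenerate codes.  The mask is
a property of the base-pair sequence, not of the strand choice:
complementing a strand leaves its mask unchanged, while reversing the
strand reverses the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "VALID_BASES",
    "Duplex",
    "canonicalize",
    "complement",
    "embed_in_flanks",
    "enumerate_duplexes",
    "duplex_space_size",
    "mask_of",
    "reverse",
    "reverse_complement",
    "validate_strand",
    "validate_mask",
]

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_MASK = str.maketrans("ACGT", "WSSW")

#: enumerate_duplexes refuses k above this unless the caller raises the cap.
DEFAULT_MAX_K = 10


class InvalidStrandError(ValueError):
    """A string is not a valid strand over {A, C, G, T}."""


def validate_strand(s: str, *, allow_n: bool = False) -> str:
    """Validate and return a strand, uppercasing lowercase input.

    Parameters
    ----------
    s
        Candidate nucleotide string.
    allow_n
        Accept ``N`` (unknown base) in addition to A/C/G/T.  Promoter
        sequences may carry N; enumeration and scoring never do.

    Raises
    ------
    InvalidStrandError
        If the string is empty or contains a disallowed character; the
        message names the first offending 1-based position.
    """
    if not isinstance(s, str):
        raise InvalidStrandError(f"strand must be a string, got {type(s).__name__}")
    if not s:
        raise InvalidStrandError("strand must be nonempty")
    s = s.upper()
    allowed = VALID_BASES | {"N"} if allow_n else VALID_BASES
    for i, base in enumerate(s):
        if base not in allowed:
            raise InvalidStrandError(
                f"invalid character {base!r} at position {i + 1} (expected one of "
                f"{''.join(sorted(allowed))})"
            )
    return s


def validate_mask(m: str) -> str:
    """Validate and return a weak/strong mask string over {W, S}."""
    if not isinstance(m, str):
        raise InvalidStrandError(f"mask must be a string, got {type(m).__name__}")
    if not m:
        raise InvalidStrandError("mask must be nonempty")
    m = m.upper()
    for i, sym in enumerate(m):
        if sym not in ("W", "S"):
            raise InvalidStrandError(
                f"invalid mask symbol {sym!r} at position {i + 1} (expected W or S)"
            )
    return m


def complement(s: str) -> str:
    """Base-pairing complement (A<->T, C<->G), orientation preserved."""
    return validate_strand(s).translate(_COMPLEMENT)


def reverse(s: str) -> str:
    """Reverse the strand (read 3' -> 5')."""
    return validate_strand(s)[::-1]


def reverse_complement(s: str) -> str:
    """The opposite strand read 5' -> 3'; an involution."""
    return validate_strand(s).translate(_COMPLEMENT)[::-1]


def mask_of(s: str) -> str:
    """Weak/strong mask of a strand: A,T -> W; C,G -> S.

    The mask classifies base *pairs*, so ``mask_of(complement(s)) ==
    mask_of(s)`` and ``mask_of(reverse_complement(s))`` equals the
    reversed mask.
    """
    return validate_strand(s).translate(_MASK)


@dataclass(frozen=True, order=True)
class Duplex:
    """A double-stranded k-mer identified by its canonical strand.

    ``canonical`` is the lexicographic minimum of the strand and its
    reverse complement under A < C < G < T.  ``palindromic`` is true iff
    the canonical strand equals its own reverse complement, in which
    case the duplex has a single strand representation.
    """

    canonical: str

    def __post_init__(self) -> None:
        s = validate_strand(self.canonical)
        rc = reverse_complement(s)
        if rc < s:
            raise InvalidStrandError(
                f"{s} is not canonical: its reverse complement {rc} sorts lower"
            )
        object.__setattr__(self, "canonical", s)

    @property
    def k(self) -> int:
        return len(self.canonical)

    @property
    def palindromic(self) -> bool:
        return self.canonical == reverse_complement(self.canonical)

    @property
    def mask(self) -> str:
        return mask_of(self.canonical)

    @property
    def gc_count(self) -> int:
        """Number of G+C bases (strong pairs); strand-choice invariant."""
        return sum(1 for b in self.canonical if b in "GC")

    def __str__(self) -> str:
        return self.canonical


def canonicalize(s: str) -> Duplex:
    """Map a strand to the duplex it belongs to.

    ``canonicalize(s) == canonicalize(reverse_complement(s))`` for every
    strand, realising the reverse-complement equivalence.
    """
    s = validate_strand(s)
    return Duplex(min(s, reverse_complement(s)))


def duplex_space_size(k: int) -> int:
    """Closed-form count of distinct duplexes of length ``k``.

    ``(4**k + 4**(k//2)) // 2`` for even ``k`` (the ``4**(k/2)``
    reverse-complement palindromes are their own partner); ``4**k // 2``
    for odd ``k`` (no palindromes exist at odd length).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def enumerate_duplexes(k: int, *, max_k: int = DEFAULT_MAX_K) -> list[Duplex]:
    """All distinct double-stranded k-mers, in lexicographic order.

    Walks the 4**k strands in lexicographic order and keeps those that
    are their own canonical representative, so every raw strand maps
    into exactly one returned duplex.  For ``k = 6`` this yields the
    2080-element hexanucleotide duplex space.

    Raises
    ------
    ValueError
        If ``k < 1`` or ``k`` exceeds ``max_k`` (memory guard; raise the
        cap explicitly for larger spaces).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > max_k:
        raise ValueError(
            f"k={k} exceeds the configured cap of {max_k}; pass max_k to override"
        )
    out: list[Duplex] = []
    for tup in product("ACGT", repeat=k):
        s = "".join(tup)
        if s <= reverse_complement(s):
            out.append(Duplex(s))
    return out


def embed_in_flanks(s: str, flank_length: int = 4, flank_pattern: str = "AT") -> str:
    """Embed a strand centrally between A/T-only flanks on both ends.

    Models the construction of B-form receptor duplexes where the k-mer
    of interest sits in the middle of a longer oligo flanked by
    ``flank_length`` A/T base pairs at each terminus (a hexamer with the
    default flank of 4 becomes a 14-mer).  The flank strand sequence is
    a convention, not a constraint of the base-pair description: any
    A/T-only pattern satisfies it.  The default tiles ``AT``
    (``ATAT...``); pass e.g. ``flank_pattern="A"`` for poly-A flanks.
    """
    s = validate_strand(s)
    if flank_length < 0:
        raise ValueError(f"flank_length must be >= 0, got {flank_length}")
    if flank_length == 0:
        return s
    pattern = validate_strand(flank_pattern)
    if set(pattern) - set("AT"):
        raise ValueError(f"flank pattern must contain only A/T, got {flank_pattern!r}")
    tiled = (pattern * flank_length)[:flank_length]
    return tiled + s + tiled
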