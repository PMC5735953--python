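"""Motif grammars for cis-regulatory element scanning.

Two motif kinds are supported:

* :class:`ConsensusMotif` — a single degenerate pattern over the IUPAC
  nucleotide alphabet (e.g. the G-box ``CACGTG`` or the PIF5-like element
  ``CANNNNCATGTG``).
* :class:`SpacedDyadMotif` — two short cores separated by a variable-length
  run of unconstrained nucleotides, the grammar of everted-repeat ARF
  binding sites such as ``TGTC[N]{11,13}GACA``.

The built-in catalog (:func:`builtin_catalog`) carries the auxin-response
(AuxRE), brassinosteroid (BZR1 G-box) and light-signalling (PIF) elements
used for promoter-class enrichment analysis of the Arabidopsis SAUR family.

Matching semantics, shared with :mod:`dyadscan.scan`: matching is
case-insensitive over the sequence, and a sequence character outside
``{A,C,G,T}`` never matches any pattern position — an ``N`` in an assembly
never creates a hit, even against a pattern ``N``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = [
    "IUPAC_CODES",
    "ConsensusMotif",
    "SpacedDyadMotif",
    "Motif",
    "MotifCatalog",
    "builtin_catalog",
    "expand_iupac",
    "reverse_complement",
    "is_self_reverse_complementary",
]

#: IUPAC nucleotide ambiguity codes -> admitted unambiguous bases.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of unambiguous bases an IUPAC code admits.

    >>> sorted(expand_iupac("M"))
    ['A', 'C']
    """
    try:
        return IUPAC_CODES[code.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"invalid IUPAC code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (ambiguity codes included).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = seq.upper()
    for ch in s:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character: {ch!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _validate_pattern(pattern: str, what: str, min_len: int) -> str:
    p = pattern.upper()
    if len(p) < min_len:
        raise ValueError(f"{what} must be at least {min_len} nt, got {pattern!r}")
    for ch in p:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} in {what} {pattern!r}")
    return p


@dataclass(frozen=True)
class ConsensusMotif:
    """A single degenerate consensus pattern.

    Parameters
    ----------
    name : str
        Unique identifier within a catalog.
    pattern : str
        IUPAC string, at least 4 nt.
    strand_mode : {"both_strands", "forward_only"}
        Whether occurrences of the reverse complement are also reported.
        Palindromic patterns are scanned once on the forward strand
        regardless, so palindrome hits are never double counted.
    """

    name: str
    pattern: str
    strand_mode: str = "both_strands"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", _validate_pattern(self.pattern, "pattern", 4))
        if self.strand_mode not in ("both_strands", "forward_only"):
            raise ValueError(f"unknown strand_mode: {self.strand_mode!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        """True if the pattern equals its own reverse complement."""
        return self.pattern == reverse_complement(self.pattern)


@dataclass(frozen=True)
class SpacedDyadMotif:
    """Two IUPAC cores separated by ``spacer_min``..``spacer_max`` free bases.

    The spacer counts nucleotides strictly between the cores, so
    ``SpacedDyadMotif("x", "TGTC", "GACA", 11, 11)`` matches a 19-nt window.
    Spacer bases must be unambiguous ``ACGT``; ambiguous sequence characters
    inside the spacer void the match.
    """

    name: str
    core5: str
    core3: str
    spacer_min: int
    spacer_max: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "core5", _validate_pattern(self.core5, "core5", 1))
        object.__setattr__(self, "core3", _validate_pattern(self.core3, "core3", 1))
        if not (0 <= self.spacer_min <= self.spacer_max <= 50):
            raise ValueError(
                f"spacer range must satisfy 0 <= min <= max <= 50, got "
                f"[{self.spacer_min}, {self.spacer_max}]"
            )

    def length_for_spacer(self, spacer: int) -> int:
        """Total match length for a given spacer length."""
        return len(self.core5) + spacer + len(self.core3)

    @property
    def max_length(self) -> int:
        return self.length_for_spacer(self.spacer_max)


Motif = Union[ConsensusMotif, SpacedDyadMotif]


def is_self_reverse_complementary(motif: SpacedDyadMotif) -> bool:
    """True if the dyad's full pattern family is its own reverse complement.

    Reverse-complementing ``core5 + N*s + core3`` gives
    ``revcomp(core3) + N*s + revcomp(core5)`` for every spacer ``s``, so the
    family is closed under reverse complement exactly when
    ``core5 == revcomp(core3)`` (which implies ``core3 == revcomp(core5)``).
    Everted repeats like TGTC...GACA have this property; scanning them on
    both strands would report every occurrence twice.
    """
    return motif.core5 == reverse_complement(motif.core3)


class MotifCatalog:
    """An ordered, name-unique collection of motifs."""

    def __init__(self, entries: Iterable[Motif] = ()) -> None:
        self._entries: dict[str, Motif] = {}
        for m in entries:
            self.add(m)

    def add(self, motif: Motif) -> None:
        if motif.name in self._entries:
            raise ValueError(f"duplicate motif name: {motif.name!r}")
        self._entries[motif.name] = motif

    def __iter__(self) -> Iterator[Motif]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> Motif:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"motif not in catalog: {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def subset(self, names: Iterable[str]) -> "MotifCatalog":
        return MotifCatalog(self[n] for n in names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifCatalog):
            return NotImplemented
        return self._entries == other._entries

    # -- TSV round trip ----------------------------------------------------

    _FIELDS = [
        "name",
        "kind",
        "pattern",
        "core5",
        "core3",
        "spacer_min",
        "spacer_max",
        "strand_mode",
    ]

    def to_tsv(self, path: Union[str, Path, io.TextIOBase]) -> None:
        """Write the catalog as a UTF-8 TSV with a header row."""
        own = isinstance(path, (str, Path))
        fh = open(path, "w", encoding="utf-8", newline="") if own else path
        try:
            w = csv.DictWriter(fh, fieldnames=self._FIELDS, delimiter="\t")
            w.writeheader()
            for m in self:
                if isinstance(m, ConsensusMotif):
                    w.writerow(
                        {"name": m.name, "kind": "consensus",
                         "pattern": m.pattern, "strand_mode": m.strand_mode}
                    )
                else:
                    w.writerow(
                        {"name": m.name, "kind": "dyad", "core5": m.core5,
                         "core3": m.core3, "spacer_min": m.spacer_min,
                         "spacer_max": m.spacer_max}
                    )
        finally:
            if own:
                fh.close()

    @classmethod
    def from_tsv(cls, path: Union[str, Path, io.TextIOBase]) -> "MotifCatalog":
        """Read a catalog written by :meth:`to_tsv` (or hand-authored)."""
        own = isinstance(path, (str, Path))
        fh = open(path, encoding="utf-8", newline="") if own else path
        cat = cls()
        try:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or "name" not in reader.fieldnames:
                raise ValueError("motif TSV must have a header row with a 'name' column")
            for lineno, row in enumerate(reader, start=2):
                kind = (row.get("kind") or "").strip()
                try:
                    if kind == "consensus":
                        cat.add(ConsensusMotif(
                            row["name"],
                            row["pattern"],
                            (row.get("strand_mode") or "both_strands").strip(),
                        ))
                    elif kind == "dyad":
                        cat.add(SpacedDyadMotif(
                            row["name"], row["core5"], row["core3"],
                            int(row["spacer_min"]), int(row["spacer_max"]),
                        ))
                    else:
                        raise ValueError(f"unknown motif kind: {kind!r}")
                except (ValueError, KeyError, TypeError) as exc:
                    raise ValueError(f"motif TSV line {lineno}: {exc}") from exc
        finally:
            if own:
                fh.close()
        return cat


def builtin_catalog() -> MotifCatalog:
    """The built-in cis-element catalog for SAUR promoter-class analysis.

    Contains the single AuxRE cores (TGTCTC and TGTCGG, scanned on both
    strands), the combined everted-repeat AuxRE ``TGTC[N]{11,13}GACA`` and
    its relaxed GGTC-core variants, the BZR1 G-box ``CACGTG``, the PIF core
    ``CATGTG``, and the two PIF5-like extended consensus motifs recovered
    from auxin-induced (Class I) and non-auxin-responsive (Class II)
    promoters.
    """
    return MotifCatalog([
        ConsensusMotif("AuxRE_TGTCTC", "TGTCTC", "both_strands"),
        ConsensusMotif("AuxRE_TGTCGG", "TGTCGG", "both_strands"),
        SpacedDyadMotif("AuxRE_combined", "TGTC", "GACA", 11, 13),
        SpacedDyadMotif("AuxRE_relaxed_GGTC11", "GGTC", "GACA", 11, 11),
        SpacedDyadMotif("AuxRE_relaxed_GGTC9", "GGTC", "GACA", 9, 9),
        ConsensusMotif("BZR1_Gbox", "CACGTG", "both_strands"),
        ConsensusMotif("PIF_core", "CATGTG", "both_strands"),
        ConsensusMotif("ClassI_PIF5like", "CANNNNCATGTG", "both_strands"),
        ConsensusMotif("ClassII_PIF5like", "CAMNNANGTG", "both_strands"),
    ])
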