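"""Motif scanning: exhaustive occurrence lists and per-gene presence calls.

Scanning is exact consensus matching (no mismatches, no scores). All
overlapping occurrences are reported. Coordinates are 0-based half-open in
promoter-local space, 5'->3' of the stored sequence; the strand field says
which orientation of the motif matched relative to that sequence.

Strand handling:

* Consensus motifs with ``strand_mode="both_strands"`` are scanned in both
  orientations, except palindromes, which are scanned forward only (a
  palindrome's reverse-orientation hits are the same windows).
* Spaced dyads that are their own reverse complement (everted repeats such
  as TGTC...GACA) are scanned forward only for the same reason; other dyads
  are scanned in both orientations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .motifs import (
    ConsensusMotif,
    Motif,
    MotifCatalog,
    SpacedDyadMotif,
    expand_iupac,
    is_self_reverse_complementary,
    reverse_complement,
)
from .promoters import PromoterSet

__all__ = [
    "MotifHit",
    "scan_consensus",
    "scan_dyad",
    "scan_motif",
    "build_presence",
    "hits_to_frame",
    "write_hits_tsv",
    "write_presence_tsv",
    "read_presence_tsv",
    "hits_to_bed6",
]

HIT_COLUMNS = ["gene_id", "motif", "start", "end", "strand", "spacer_len"]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in promoter-local coordinates."""

    gene_id: str
    motif_name: str
    start: int
    end: int
    strand: str
    spacer_len: Optional[int] = None  # dyads only


def _pattern_regex(pattern: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all found; IUPAC codes become
    # character classes over ACGT only, so sequence N never matches.
    body = "".join("[" + "".join(sorted(expand_iupac(c))) + "]" for c in pattern)
    return re.compile(f"(?=({body}))")


def _find(seq: str, pattern: str) -> list[int]:
    return [m.start() for m in _pattern_regex(pattern).finditer(seq)]


def scan_consensus(seq: str, motif: ConsensusMotif, gene_id: str = "") -> list[MotifHit]:
    """All occurrences of a consensus motif in ``seq``, sorted by position."""
    s = seq.upper()
    w = len(motif.pattern)
    hits = [
        MotifHit(gene_id, motif.name, i, i + w, "+")
        for i in _find(s, motif.pattern)
    ]
    if motif.strand_mode == "both_strands" and not motif.is_palindromic:
        hits += [
            MotifHit(gene_id, motif.name, i, i + w, "-")
            for i in _find(s, reverse_complement(motif.pattern))
        ]
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


def scan_dyad(seq: str, motif: SpacedDyadMotif, gene_id: str = "") -> list[MotifHit]:
    """All occurrences of a spaced dyad, over every admissible spacer length.

    Spacer positions must be unambiguous ACGT; each (position, spacer,
    orientation) combination is reported separately, so nested occurrences
    with different spacers all appear.
    """
    s = seq.upper()
    orientations = [(motif.core5, motif.core3, "+")]
    if not is_self_reverse_complementary(motif):
        orientations.append(
            (reverse_complement(motif.core3), reverse_complement(motif.core5), "-")
        )
    hits = []
    for c5, c3, strand in orientations:
        for spacer in range(motif.spacer_min, motif.spacer_max + 1):
            pat = c5 + "N" * spacer + c3
            w = len(pat)
            hits += [
                MotifHit(gene_id, motif.name, i, i + w, strand, spacer)
                for i in _find(s, pat)
            ]
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


def scan_motif(seq: str, motif: Motif, gene_id: str = "") -> list[MotifHit]:
    if isinstance(motif, ConsensusMotif):
        return scan_consensus(seq, motif, gene_id)
    return scan_dyad(seq, motif, gene_id)


def build_presence(pset: PromoterSet, catalog: MotifCatalog
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every promoter against every catalog motif.

    Returns ``(presence, hits)``: a boolean |genes| x |motifs| DataFrame
    (True iff the promoter has at least one occurrence) and the full hit
    table with columns ``gene_id, motif, start, end, strand, spacer_len``.
    """
    rows = []
    genes = pset.gene_ids
    names = catalog.names
    presence = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"),
                            columns=names, dtype=bool)
    for rec in pset:
        for motif in catalog:
            found = scan_motif(rec.sequence, motif, rec.gene_id)
            if found:
                presence.at[rec.gene_id, motif.name] = True
                rows += [
                    (h.gene_id, h.motif_name, h.start, h.end, h.strand, h.spacer_len)
                    for h in found
                ]
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return presence, hits


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.motif_name, h.start, h.end, h.strand, h.spacer_len)
         for h in hits],
        columns=HIT_COLUMNS,
    )


def write_hits_tsv(hits: pd.DataFrame, path: Union[str, Path],
                   pset: Optional[PromoterSet] = None) -> None:
    """Write the hit table as TSV.

    If a promoter set is supplied, a ``tss_offset`` column is added: the
    motif start as a negative distance upstream of the transcription start
    (the promoter 3' end), the coordinate style used in figure annotations
    like "-1538".
    """
    out = hits.copy()
    if pset is not None:
        lengths = {r.gene_id: len(r) for r in pset}
        out["tss_offset"] = [
            s - lengths[g] for g, s in zip(out["gene_id"], out["start"])
        ]
    out.to_csv(path, sep="\t", index=False)


def write_presence_tsv(presence: pd.DataFrame, path: Union[str, Path]) -> None:
    presence.astype(int).to_csv(path, sep="\t")


def read_presence_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df.astype(bool)


def hits_to_bed6(hits: pd.DataFrame, pset: PromoterSet,
                 path: Union[str, Path]) -> int:
    """Write hits with genomic provenance as BED6 (0-based half-open).

    Promoter-local coordinates are mapped through each record's provenance;
    hits on promoters without provenance are skipped. Returns the number of
    BED lines written. The BED strand is the motif orientation in genomic
    space (promoter strand combined with hit strand).
    """
    n = 0
    flip = {"+": "-", "-": "+"}
    with open(path, "w", encoding="utf-8") as fh:
        for row in hits.itertuples(index=False):
            rec = pset[row.gene_id] if row.gene_id in pset else None
            if rec is None or rec.provenance is None:
                continue
            pv = rec.provenance
            if pv.strand == "+":
                g_start, g_end = pv.start + row.start, pv.start + row.end
                strand = row.strand
            else:
                g_start, g_end = pv.end - row.end, pv.end - row.start
                strand = flip[row.strand]
            fh.write(
                f"{pv.chrom}\t{g_start}\t{g_end}\t{row.gene_id}|{row.motif}\t0\t{strand}\n"
            )
            n += 1
    return n
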