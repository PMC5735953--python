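"""Promoter sets: FASTA I/O, upstream extraction and background sampling.

A *promoter* here is a fixed-length window immediately 5' of a gene's
annotated start, read on the gene's coding strand (default 3000 nt, the
window used throughout the enrichment analysis). Windows are fixed-length
and may overlap neighbouring genes; they are clipped only at chromosome
edges.

Coordinates are 0-based half-open internally. GFF3 input (1-based closed)
is converted on read; provenance carried on records stays 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .motifs import reverse_complement

__all__ = [
    "CLASS_LABELS",
    "Provenance",
    "PromoterRecord",
    "PromoterSet",
    "read_promoters",
    "read_labels",
    "write_labels",
    "extract_upstream",
    "extract_many",
    "sample_background",
]

#: Recognised promoter class labels.
CLASS_LABELS = ("class_I", "class_II", "background", "unlabeled")


@dataclass(frozen=True)
class Provenance:
    """Genomic origin of a promoter window (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass
class PromoterRecord:
    """A labeled upstream sequence, optionally with genomic provenance."""

    gene_id: str
    sequence: str
    class_label: str = "unlabeled"
    provenance: Optional[Provenance] = None
    clipped: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.provenance is not None:
            span = self.provenance.end - self.provenance.start
            if span != len(self.sequence):
                raise ValueError(
                    f"{self.gene_id}: provenance span {span} != sequence length "
                    f"{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class PromoterSet:
    """An ordered collection of :class:`PromoterRecord` with unique gene ids."""

    def __init__(self, records: Iterable[PromoterRecord] = (),
                 metadata: Optional[dict] = None) -> None:
        self._records: dict[str, PromoterRecord] = {}
        self.metadata: dict = dict(metadata or {})
        for rec in records:
            self.add(rec)

    def add(self, rec: PromoterRecord) -> None:
        if rec.gene_id in self._records:
            raise ValueError(f"duplicate gene id: {rec.gene_id!r}")
        self._records[rec.gene_id] = rec

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._records[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    @property
    def labels(self) -> dict[str, str]:
        """gene_id -> class label for every record."""
        return {r.gene_id: r.class_label for r in self}

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self:
            counts[r.class_label] = counts.get(r.class_label, 0) + 1
        return counts

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        return PromoterSet((self._records[g] for g in gene_ids),
                           metadata=dict(self.metadata))

    def relabel(self, labels: Mapping[str, str]) -> "PromoterSet":
        """Return a copy with class labels replaced from a gene->class map."""
        out = []
        for r in self:
            if r.gene_id in labels:
                out.append(replace(r, class_label=labels[r.gene_id]))
            else:
                out.append(replace(r))
        return PromoterSet(out, metadata=dict(self.metadata))

    def write_fasta(self, path: Union[str, Path]) -> None:
        """Write records as FASTA; headers are the bare gene ids."""
        records = [
            SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
            for r in self
        ]
        SeqIO.write(records, str(path), "fasta")


def read_labels(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column gene->class TSV (header optional)."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"labels TSV line {lineno}: expected 2 columns")
            gene, cls = parts[0].strip(), parts[1].strip()
            if lineno == 1 and cls not in CLASS_LABELS:
                continue  # header row
            if cls not in CLASS_LABELS:
                raise ValueError(
                    f"labels TSV line {lineno}: unknown class {cls!r}; "
                    f"expected one of {CLASS_LABELS}"
                )
            labels[gene] = cls
    return labels


def write_labels(labels: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tclass\n")
        for gene, cls in labels.items():
            fh.write(f"{gene}\t{cls}\n")


def read_promoters(fasta_source: Union[str, Path],
                   labels: Optional[Mapping[str, str]] = None) -> PromoterSet:
    """Load a promoter set from FASTA, attaching class labels where given.

    Records without a label get class ``unlabeled``. Labels naming genes
    absent from the FASTA raise a warning listing them; the set is still
    built.
    """
    labels = dict(labels or {})
    pset = PromoterSet(metadata={"source": str(fasta_source)})
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        cls = labels.get(rec.id, "unlabeled")
        pset.add(PromoterRecord(rec.id, str(rec.seq), cls))
    if len(pset) == 0:
        raise ValueError(f"no FASTA records found in {fasta_source}")
    missing = sorted(g for g in labels if g not in pset)
    if missing:
        warnings.warn(
            f"{len(missing)} labeled gene(s) absent from FASTA: {', '.join(missing)}",
            stacklevel=2,
        )
    return pset


# ---------------------------------------------------------------------------
# Upstream extraction from genome + annotation
# ---------------------------------------------------------------------------

def _open_gff(annotation: Union[str, Path, gffutils.FeatureDB]) -> gffutils.FeatureDB:
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    return gffutils.create_db(
        str(annotation), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )


def _open_genome(genome: Union[str, Path, Fasta]) -> Fasta:
    if isinstance(genome, Fasta):
        return genome
    return Fasta(str(genome))


def _gene_bounds(db: gffutils.FeatureDB, gene_id: str) -> tuple[str, int, int, str]:
    """(chrom, start0, end0, strand) of a gene, 0-based half-open.

    The gene feature's bounds are used; by GFF3 convention these span all
    mRNA isoforms, so the 5'-most transcription start on the gene's strand
    is the gene boundary itself.
    """
    try:
        feat = db[gene_id]
    except (gffutils.FeatureNotFoundError, KeyError):
        raise KeyError(f"gene not found in annotation: {gene_id!r}") from None
    if feat.strand not in "+-":
        raise ValueError(f"{gene_id}: gene has no strand in annotation")
    return feat.seqid, feat.start - 1, feat.end, feat.strand


def extract_upstream(genome: Union[str, Path, Fasta],
                     annotation: Union[str, Path, gffutils.FeatureDB],
                     gene_id: str,
                     length: int = 3000,
                     class_label: str = "unlabeled") -> PromoterRecord:
    """Extract the fixed-length upstream window of one gene.

    For a ``+`` strand gene starting at 0-based position ``s`` the window is
    ``[max(0, s - length), s)`` on the forward strand; for a ``-`` strand
    gene ending at ``e`` (exclusive) it is ``[e, min(chrom_len, e + length))``
    reverse-complemented, so the stored sequence always reads 5'->3' toward
    the gene. Windows truncated at a chromosome edge are flagged ``clipped``.
    """
    fa = _open_genome(genome)
    db = _open_gff(annotation)
    chrom, g_start, g_end, strand = _gene_bounds(db, gene_id)
    if chrom not in fa:
        raise KeyError(f"{gene_id}: chromosome {chrom!r} not in genome")
    chrom_len = len(fa[chrom])

    if strand == "+":
        start, end = max(0, g_start - length), g_start
    else:
        start, end = g_end, min(chrom_len, g_end + length)
    if end <= start:
        raise ValueError(
            f"{gene_id}: zero-length upstream region (gene at chromosome edge)"
        )
    seq = str(fa[chrom][start:end]).upper()
    if strand == "-":
        seq = reverse_complement(seq)
    return PromoterRecord(
        gene_id, seq, class_label,
        provenance=Provenance(chrom, start, end, strand),
        clipped=(end - start) < length,
    )


def extract_many(genome: Union[str, Path, Fasta],
                 annotation: Union[str, Path, gffutils.FeatureDB],
                 gene_ids: Iterable[str],
                 length: int = 3000,
                 labels: Optional[Mapping[str, str]] = None,
                 on_missing: str = "warn") -> PromoterSet:
    """Extract upstream windows for many genes.

    ``on_missing`` is ``"warn"`` (skip absent genes with a warning) or
    ``"raise"``.
    """
    fa = _open_genome(genome)
    db = _open_gff(annotation)
    labels = dict(labels or {})
    pset = PromoterSet(metadata={"upstream_length": length})
    missing = []
    for gid in gene_ids:
        try:
            rec = extract_upstream(fa, db, gid, length,
                                   labels.get(gid, "unlabeled"))
        except KeyError:
            if on_missing == "raise":
                raise
            missing.append(gid)
            continue
        pset.add(rec)
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from annotation: {', '.join(missing)}",
            stacklevel=2,
        )
    pset.metadata["n_missing"] = len(missing)
    return pset


def sample_background(universe: PromoterSet,
                      n: int = 500,
                      exclude: Iterable[str] = (),
                      seed: int = 0) -> PromoterSet:
    """Sample ``n`` distinct promoters, excluding the given gene ids.

    All sampled records are relabeled ``background``. The same seed always
    yields the same selection.
    """
    exclude = set(exclude)
    available = [g for g in universe.gene_ids if g not in exclude]
    if len(available) < n:
        raise ValueError(
            f"cannot sample {n} background promoters: only {len(available)} "
            f"available after exclusions"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(available), size=n, replace=False)
    picked = [available[i] for i in sorted(chosen)]
    sub = universe.subset(picked).relabel({g: "background" for g in picked})
    sub.metadata.update({"background_seed": seed, "background_n": n})
    return sub
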