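"""Synthetic promoter studies with planted motifs and full ground truth.

The generator emulates the design of the SAUR promoter enrichment study:
50 auxin-induced (Class I) promoters, 20 non-auxin-responsive (Class II)
promoters and 500 background promoters, each a 3000-nt window, with
cis-elements planted per class at the rates observed in that study
(e.g. the combined everted-repeat AuxRE in 22% of Class I, none of
Class II, 7% of background).

Sequences are i.i.d. draws from a mononucleotide composition (default
A/T-rich, 36% GC, typical of Arabidopsis intergenic DNA). Planting
overwrites a window with a concrete realisation of the motif, keeping the
promoter length fixed; at most one instance per (motif, promoter) is
planted. Chance occurrences arising from the background process are left
in place and count as real hits downstream — as in real promoters, where
presence, not provenance, is what the statistics see.

Reproducibility: one master seed; promoter ``i`` uses the dedicated stream
``default_rng([seed, i])``, so any single promoter can be regenerated
without generating the rest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .motifs import (
    ConsensusMotif,
    Motif,
    MotifCatalog,
    SpacedDyadMotif,
    builtin_catalog,
    expand_iupac,
    is_self_reverse_complementary,
    reverse_complement,
)
from .promoters import PromoterRecord, PromoterSet, write_labels

__all__ = [
    "Planting",
    "StudyDesign",
    "PlantedInstance",
    "GroundTruth",
    "generate_background_sequence",
    "plant_motif",
    "generate_study",
    "write_study_bundle",
    "DEFAULT_PLANTINGS",
    "ARABIDOPSIS_COMPOSITION",
]

#: Mononucleotide probabilities (A, C, G, T); ~36% GC.
ARABIDOPSIS_COMPOSITION = (0.32, 0.18, 0.18, 0.32)

#: Per-class planting rates mirroring the observed presence fractions of
#: the promoter study: combined AuxRE 11/50 Class I, 0/20 Class II, 0.07
#: background; BZR1 G-box 10/50 vs 0/20; Class I PIF5-like motif 28/50,
#: 2/20, 56/500. Classes absent from this list get rate 0 (chance only).
DEFAULT_PLANTINGS: tuple[tuple[str, str, float], ...] = (
    ("AuxRE_combined", "class_I", 0.22),
    ("AuxRE_combined", "background", 0.07),
    ("BZR1_Gbox", "class_I", 0.20),
    ("ClassI_PIF5like", "class_I", 0.56),
    ("ClassI_PIF5like", "class_II", 0.10),
    ("ClassI_PIF5like", "background", 0.112),
)


@dataclass(frozen=True)
class Planting:
    """Plant ``motif_name`` in each promoter of ``class_label`` w.p. ``rate``."""

    motif_name: str
    class_label: str
    rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"planting rate must be in [0, 1], got {self.rate}")


@dataclass
class StudyDesign:
    """Sizes, composition, planting rates and seed of a synthetic study."""

    n_class_I: int = 50
    n_class_II: int = 20
    n_background: int = 500
    length: int = 3000
    base_composition: tuple[float, float, float, float] = ARABIDOPSIS_COMPOSITION
    plantings: tuple[Planting, ...] = tuple(
        Planting(*p) for p in DEFAULT_PLANTINGS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_class_I, self.n_class_II, self.n_background) < 0:
            raise ValueError("class sizes must be nonnegative")
        if self.length < 0:
            raise ValueError("length must be nonnegative")
        comp = tuple(float(p) for p in self.base_composition)
        if len(comp) != 4 or min(comp) < 0 or abs(sum(comp) - 1.0) > 1e-9:
            raise ValueError(
                "base_composition must be 4 probabilities over A,C,G,T summing to 1"
            )
        object.__setattr__(self, "base_composition", comp)
        self.plantings = tuple(
            p if isinstance(p, Planting) else Planting(*p) for p in self.plantings
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["plantings"] = [dataclasses.asdict(p) for p in self.plantings]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyDesign":
        d = json.loads(text)
        d["plantings"] = tuple(Planting(**p) for p in d["plantings"])
        d["base_composition"] = tuple(d["base_composition"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedInstance:
    """Ground-truth record of one planted motif occurrence."""

    gene_id: str
    motif_name: str
    start: int
    strand: str
    spacer_len: Optional[int]  # dyads only


class GroundTruth:
    """All planted instances of a study, indexable by gene."""

    def __init__(self) -> None:
        self._by_gene: dict[str, list[PlantedInstance]] = {}

    def add(self, inst: PlantedInstance) -> None:
        self._by_gene.setdefault(inst.gene_id, []).append(inst)

    def for_gene(self, gene_id: str) -> list[PlantedInstance]:
        return list(self._by_gene.get(gene_id, []))

    def planted_genes(self, motif_name: str) -> set[str]:
        return {
            g for g, insts in self._by_gene.items()
            if any(i.motif_name == motif_name for i in insts)
        }

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_gene.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i.gene_id, i.motif_name, i.start, i.strand, i.spacer_len)
            for insts in self._by_gene.values() for i in insts
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "motif", "start", "strand", "spacer_len"]
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_background_sequence(length: int,
                                 base_composition: Sequence[float],
                                 rng: np.random.Generator) -> str:
    """I.i.d. sequence of ``length`` bases from a mononucleotide composition."""
    if length == 0:
        return ""
    comp = np.asarray(base_composition, dtype=float)
    edges = np.cumsum(comp)
    edges[-1] = 1.0  # guard against round-off at the top edge
    idx = np.searchsorted(edges, rng.random(length), side="right")
    return _BASES[idx].tobytes().decode("ascii")


def _realize_consensus(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(sorted(expand_iupac(c))) for c in pattern
    )


def _realize(motif: Motif, base_composition: Sequence[float],
             rng: np.random.Generator) -> tuple[str, Optional[int]]:
    """Sample a concrete (forward-orientation) instance; returns (seq, spacer)."""
    if isinstance(motif, ConsensusMotif):
        return _realize_consensus(motif.pattern, rng), None
    spacer = int(rng.integers(motif.spacer_min, motif.spacer_max + 1))
    return (
        _realize_consensus(motif.core5, rng)
        + generate_background_sequence(spacer, base_composition, rng)
        + _realize_consensus(motif.core3, rng),
        spacer,
    )


def _wants_reverse(motif: Motif, rng: np.random.Generator) -> bool:
    """Pick an orientation: uniform for motifs whose two orientations are
    distinguishable, forward otherwise."""
    if isinstance(motif, ConsensusMotif):
        if motif.strand_mode == "forward_only" or motif.is_palindromic:
            return False
    elif is_self_reverse_complementary(motif):
        return False
    return bool(rng.integers(2))


def plant_motif(record: PromoterRecord, motif: Motif,
                rng: np.random.Generator,
                base_composition: Sequence[float] = ARABIDOPSIS_COMPOSITION,
                position: Optional[int] = None,
                strand: Optional[str] = None,
                avoid: Sequence[tuple[int, int]] = ()) -> PlantedInstance:
    """Overwrite a window of ``record.sequence`` with a motif instance.

    Position (uniform over legal starts) and strand (uniform where the two
    orientations differ) are sampled when not given. ``avoid`` lists
    half-open intervals the instance must not overlap (used to keep
    multiple plantings in one promoter from destroying each other); it is
    ignored when ``position`` is given explicitly.
    """
    instance, spacer = _realize(motif, base_composition, rng)
    w = len(instance)
    if w > len(record.sequence):
        raise ValueError(
            f"motif {motif.name!r} ({w} nt) does not fit in a "
            f"{len(record.sequence)}-nt sequence"
        )
    if strand is None:
        strand = "-" if _wants_reverse(motif, rng) else "+"
    if position is None:
        limit = len(record.sequence) - w
        position = int(rng.integers(0, limit + 1))
        for _ in range(1000):
            if all(position + w <= s or position >= e for s, e in avoid):
                break
            position = int(rng.integers(0, limit + 1))
        else:
            raise RuntimeError("could not place motif clear of existing plantings")
    written = reverse_complement(instance) if strand == "-" else instance
    record.sequence = (
        record.sequence[:position] + written + record.sequence[position + w:]
    )
    return PlantedInstance(record.gene_id, motif.name, position, strand, spacer)


def _gene_ids(design: StudyDesign) -> list[tuple[str, str]]:
    ids = []
    for label, n, stem in (
        ("class_I", design.n_class_I, "classI"),
        ("class_II", design.n_class_II, "classII"),
        ("background", design.n_background, "bg"),
    ):
        width = max(2, len(str(n)))
        ids += [(f"{stem}_{i + 1:0{width}d}", label) for i in range(n)]
    return ids


def generate_study(design: StudyDesign,
                   catalog: Optional[MotifCatalog] = None
                   ) -> tuple[PromoterSet, GroundTruth]:
    """Generate the full labeled promoter set plus planting ground truth.

    Each promoter of a class independently receives one instance of each
    planted motif with the class's rate. Deterministic for a fixed design
    (seed included).
    """
    catalog = catalog or builtin_catalog()
    for p in design.plantings:
        if p.motif_name not in catalog:
            raise ValueError(f"planting references unknown motif: {p.motif_name!r}")
    pset = PromoterSet(metadata={
        "upstream_length": design.length,
        "source": "synthetic",
        "seed": design.seed,
    })
    truth = GroundTruth()
    for i, (gene_id, label) in enumerate(_gene_ids(design)):
        rng = np.random.default_rng([design.seed, i])
        rec = PromoterRecord(
            gene_id,
            generate_background_sequence(design.length, design.base_composition, rng),
            label,
        )
        occupied: list[tuple[int, int]] = []
        for planting in design.plantings:
            if planting.class_label != label:
                continue
            if rng.random() >= planting.rate:
                continue
            inst = plant_motif(
                rec, catalog[planting.motif_name], rng,
                design.base_composition, avoid=occupied,
            )
            motif = catalog[planting.motif_name]
            w = (len(motif.pattern) if isinstance(motif, ConsensusMotif)
                 else motif.length_for_spacer(inst.spacer_len))
            occupied.append((inst.start, inst.start + w))
            truth.add(inst)
        pset.add(rec)
    return pset, truth


def write_study_bundle(design: StudyDesign, out_dir: Union[str, Path],
                       catalog: Optional[MotifCatalog] = None
                       ) -> tuple[PromoterSet, GroundTruth]:
    """Generate a study and write promoters.fasta, labels.tsv,
    ground_truth.tsv and design.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pset, truth = generate_study(design, catalog)
    pset.write_fasta(out / "promoters.fasta")
    write_labels(pset.labels, out / "labels.tsv")
    truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    (out / "design.json").write_text(design.to_json(), encoding="utf-8")
    return pset, truth
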