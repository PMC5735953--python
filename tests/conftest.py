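"""Shared fixtures: a tiny synthetic genome + annotation, and a default
synthetic study generated once per session."""

import zlib

import numpy as np
import pytest

from dyadscan.motifs import builtin_catalog
from dyadscan.simulate import StudyDesign, generate_study

GFF_TEXT = """\
##gff-version 3
chr1\ttest\tgene\t5001\t8000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t5001\t8000\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\ttest\tgene\t2001\t5000\t.\t-\t.\tID=geneB
chr1\ttest\tgene\t1201\t1500\t.\t+\t.\tID=geneC
chr2\ttest\tgene\t101\t200\t.\t-\t.\tID=geneD
"""

CHROM_LENGTHS = {"chr1": 9000, "chr2": 2000}


def _random_chromosome(length, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def genome_sequences():
    return {name: _random_chromosome(n, seed=zlib.crc32(name.encode()))
            for name, n in CHROM_LENGTHS.items()}


@pytest.fixture(scope="session")
def genome_fasta(tmp_path_factory, genome_sequences):
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in genome_sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path


@pytest.fixture(scope="session")
def gff_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "genes.gff3"
    path.write_text(GFF_TEXT)
    return path


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def default_study():
    """One default-design study (50/20/500 x 3000 nt), generated once."""
    design = StudyDesign(seed=11)
    pset, truth = generate_study(design)
    return design, pset, truth
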