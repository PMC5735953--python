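"""Synthetic study generator: determinism, planting ground truth, and the
statistical structure of the background process."""

import math

import numpy as np
import pytest

from dyadscan.motifs import MotifCatalog, builtin_catalog
from dyadscan.promoters import PromoterRecord
from dyadscan.scan import build_presence, scan_motif
from dyadscan.simulate import (
    DEFAULT_PLANTINGS,
    Planting,
    StudyDesign,
    generate_background_sequence,
    generate_study,
    plant_motif,
    write_study_bundle,
)

UNIFORM = (0.25, 0.25, 0.25, 0.25)


class TestBackgroundSequence:
    def test_degenerate_composition(self):
        rng = np.random.default_rng(0)
        assert generate_background_sequence(30, (1, 0, 0, 0), rng) == "A" * 30

    def test_zero_length(self):
        assert generate_background_sequence(0, UNIFORM,
                                            np.random.default_rng(0)) == ""

    def test_stream_determinism(self):
        a = generate_background_sequence(500, UNIFORM, np.random.default_rng(3))
        b = generate_background_sequence(500, UNIFORM, np.random.default_rng(3))
        assert a == b

    def test_uniform_frequencies_within_binomial_ci(self):
        # 99% CI for each base count at n=3000, p=0.25
        seq = generate_background_sequence(3000, UNIFORM,
                                           np.random.default_rng(12))
        half = 2.576 * math.sqrt(3000 * 0.25 * 0.75)
        for base in "ACGT":
            assert abs(seq.count(base) - 750) < half


class TestPlantMotif:
    def _record(self, length=200, seed=0):
        return PromoterRecord(
            "g", generate_background_sequence(length, UNIFORM,
                                              np.random.default_rng(seed)))

    @pytest.mark.parametrize("motif_name", [
        "AuxRE_combined", "BZR1_Gbox", "ClassI_PIF5like", "ClassII_PIF5like",
    ])
    def test_planted_instance_is_recovered_by_scanner(self, motif_name, catalog):
        motif = catalog[motif_name]
        for seed in range(25):
            rec = self._record(seed=seed)
            rng = np.random.default_rng(seed + 1000)
            inst = plant_motif(rec, motif, rng, UNIFORM)
            hits = scan_motif(rec.sequence, motif, "g")
            assert any(h.start == inst.start and h.strand == inst.strand
                       for h in hits), (motif_name, seed)

    def test_explicit_position(self, catalog):
        rec = self._record(3000)
        inst = plant_motif(rec, catalog["AuxRE_combined"],
                           np.random.default_rng(5), UNIFORM, position=100)
        assert inst.start == 100
        hits = scan_motif(rec.sequence, catalog["AuxRE_combined"], "g")
        assert any(h.start == 100 and 119 <= h.end <= 121 for h in hits)

    def test_palindrome_planted_on_minus_found_forward(self, catalog):
        rec = self._record()
        inst = plant_motif(rec, catalog["BZR1_Gbox"],
                           np.random.default_rng(2), UNIFORM, strand="-")
        hits = scan_motif(rec.sequence, catalog["BZR1_Gbox"], "g")
        assert any(h.start == inst.start for h in hits)

    def test_motif_longer_than_sequence_rejected(self, catalog):
        rec = PromoterRecord("g", "ACGTACGTAC")
        with pytest.raises(ValueError, match="does not fit"):
            plant_motif(rec, catalog["AuxRE_combined"],
                        np.random.default_rng(0), UNIFORM)

    def test_avoid_intervals_respected(self, catalog):
        rec = self._record(60)
        rng = np.random.default_rng(9)
        inst = plant_motif(rec, catalog["BZR1_Gbox"], rng, UNIFORM,
                           avoid=[(0, 30), (36, 60)])
        assert 30 <= inst.start and inst.start + 6 <= 36


class TestStudyDesign:
    def test_validation(self):
        with pytest.raises(ValueError, match="composition"):
            StudyDesign(base_composition=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="rate"):
            StudyDesign(plantings=(Planting("BZR1_Gbox", "class_I", 1.5),))
        with pytest.raises(ValueError, match="nonnegative"):
            StudyDesign(n_class_I=-1)

    def test_json_round_trip(self):
        design = StudyDesign(seed=42)
        assert StudyDesign.from_json(design.to_json()) == design

    def test_unknown_planted_motif_rejected(self):
        design = StudyDesign(plantings=(Planting("NoSuch", "class_I", 0.5),))
        with pytest.raises(ValueError, match="NoSuch"):
            generate_study(design)


class TestGenerateStudy:
    def test_default_design_class_counts(self, default_study):
        _, pset, _ = default_study
        assert len(pset) == 570
        assert pset.class_counts() == {"class_I": 50, "class_II": 20,
                                       "background": 500}

    def test_rate_one_plants_in_every_promoter(self, catalog):
        design = StudyDesign(
            n_class_I=12, n_class_II=0, n_background=0, length=150,
            plantings=(Planting("BZR1_Gbox", "class_I", 1.0),), seed=4)
        pset, truth = generate_study(design)
        presence, _ = build_presence(pset, catalog.subset(["BZR1_Gbox"]))
        assert int(presence["BZR1_Gbox"].sum()) == 12
        assert len(truth.planted_genes("BZR1_Gbox")) == 12

    def test_every_planted_instance_recovered(self, default_study, catalog):
        _, pset, truth = default_study
        frame = truth.to_frame()
        assert len(frame) > 0
        for row in frame.itertuples(index=False):
            hits = scan_motif(pset[row.gene_id].sequence,
                              catalog[row.motif], row.gene_id)
            assert any(h.start == row.start for h in hits), row

    def test_multiple_plantings_do_not_destroy_each_other(self, catalog):
        design = StudyDesign(
            n_class_I=20, n_class_II=0, n_background=0, length=120,
            plantings=(Planting("AuxRE_combined", "class_I", 1.0),
                       Planting("BZR1_Gbox", "class_I", 1.0),
                       Planting("ClassI_PIF5like", "class_I", 1.0)),
            seed=8)
        pset, truth = generate_study(design)
        for row in truth.to_frame().itertuples(index=False):
            hits = scan_motif(pset[row.gene_id].sequence,
                              catalog[row.motif], row.gene_id)
            assert any(h.start == row.start for h in hits), row

    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        design = StudyDesign(n_class_I=6, n_class_II=4, n_background=10,
                             length=400, seed=17)
        write_study_bundle(design, tmp_path / "a")
        write_study_bundle(design, tmp_path / "b")
        for name in ("promoters.fasta", "labels.tsv", "ground_truth.tsv",
                     "design.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_different_seeds_differ_only_in_sequences(self):
        kw = dict(n_class_I=5, n_class_II=3, n_background=4, length=300)
        a, _ = generate_study(StudyDesign(seed=1, **kw))
        b, _ = generate_study(StudyDesign(seed=2, **kw))
        assert a.gene_ids == b.gene_ids
        assert a.class_counts() == b.class_counts()
        assert any(a[g].sequence != b[g].sequence for g in a.gene_ids)

    def test_planted_fraction_matches_rate(self):
        """Mean planted Class I fraction over replicates ~ the 0.22 rate.

        The rate is the combined-AuxRE Class I planting rate (11/50 in the
        emulated study); checked on the ground truth, since chance
        occurrences from the background process add presence on top.
        """
        rate = dict(((m, c), r) for m, c, r in DEFAULT_PLANTINGS)[
            ("AuxRE_combined", "class_I")]
        assert rate == 0.22
        n_rep, n_genes = 400, 50
        fractions = []
        for rep in range(n_rep):
            design = StudyDesign(n_class_I=n_genes, n_class_II=0,
                                 n_background=0, length=60, seed=30_000 + rep)
            _, truth = generate_study(design)
            fractions.append(len(truth.planted_genes("AuxRE_combined")) / n_genes)
        sem = math.sqrt(rate * (1 - rate) / (n_rep * n_genes))
        assert abs(np.mean(fractions) - rate) < 4 * sem

    def test_chance_hits_match_analytic_expectation(self, catalog):
        """Unplanted uniform-composition background: G-box hits per 3000-nt
        promoter are Poisson-like with mean (3000-6+1)/4^6 (palindrome,
        counted once per window)."""
        design = StudyDesign(n_class_I=0, n_class_II=0, n_background=200,
                             length=3000, base_composition=UNIFORM,
                             plantings=(), seed=99)
        pset, truth = generate_study(design)
        assert len(truth) == 0
        total = sum(
            len(scan_motif(rec.sequence, catalog["BZR1_Gbox"], rec.gene_id))
            for rec in pset)
        expected = 200 * (3000 - 6 + 1) / 4 ** 6
        assert abs(total - expected) < 5 * math.sqrt(expected)
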