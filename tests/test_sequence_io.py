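"""FASTA/MEME IO, upstream extraction and mutant probe design."""

import numpy as np
import pytest
from Bio.Seq import Seq

from palmotifs import (
    FeatureRecord,
    FrequencyMatrix,
    MotifRecord,
    UpstreamSet,
    design_mutant_probe,
    extract_upstream,
    read_meme_minimal,
    write_meme_minimal,
)
from palmotifs.sequence_io import MemeParseError, read_feature_tsv

from conftest import random_pwm


@pytest.fixture
def contig_10kb():
    rng = np.random.default_rng(0)
    return "".join(rng.choice(list("ACGT"), 10_000))


class TestExtractUpstream:
    def test_plus_strand_region_precedes_gene(self, contig_10kb):
        genome = {"chr": contig_10kb}
        feats = [FeatureRecord("chr", 500, 1400, "+", "geneA")]
        rec = extract_upstream(genome, feats, length=200)[0]
        assert (rec.start, rec.end) == (300, 500)
        assert rec.sequence == contig_10kb[300:500]
        assert not rec.truncated

    def test_minus_strand_region_follows_gene_reverse_complemented(self, contig_10kb):
        genome = {"chr": contig_10kb}
        feats = [FeatureRecord("chr", 500, 1400, "-", "geneB")]
        rec = extract_upstream(genome, feats, length=200)[0]
        assert (rec.start, rec.end) == (1400, 1600)
        assert rec.sequence == str(Seq(contig_10kb[1400:1600]).reverse_complement())

    def test_contig_edge_truncates_with_flag(self, contig_10kb):
        genome = {"chr": contig_10kb}
        feats = [FeatureRecord("chr", 100, 900, "+", "geneC")]
        rec = extract_upstream(genome, feats, length=200)[0]
        assert (rec.start, rec.end) == (0, 100)
        assert len(rec.sequence) == 100
        assert rec.truncated

    def test_unknown_contig_error_names_feature(self, contig_10kb):
        genome = {"chr": contig_10kb}
        feats = [FeatureRecord("plasmid", 500, 900, "+", "geneD")]
        with pytest.raises(KeyError, match="geneD"):
            extract_upstream(genome, feats)

    def test_region_never_overlaps_gene_body(self, contig_10kb):
        rng = np.random.default_rng(1)
        genome = {"chr": contig_10kb}
        feats = [
            FeatureRecord(
                "chr", s := int(rng.integers(0, 9000)), s + int(rng.integers(99, 900)) + 1,
                "+" if rng.integers(2) else "-", f"g{i}",
            )
            for i in range(50)
        ]
        for feat, rec in zip(feats, extract_upstream(genome, feats)):
            assert rec.end <= feat.start or rec.start >= feat.end

    def test_strand_symmetry_on_mirrored_contig(self, contig_10kb):
        """Minus-strand extraction equals plus-strand extraction on the
        reverse-complemented contig with mirrored coordinates."""
        rng = np.random.default_rng(2)
        L = len(contig_10kb)
        rc_contig = str(Seq(contig_10kb).reverse_complement())
        for i in range(100):
            s = int(rng.integers(300, 9_000))
            e = s + int(rng.integers(100, 900))
            minus = extract_upstream({"c": contig_10kb},
                                     [FeatureRecord("c", s, e, "-", "g")])[0]
            mirrored = extract_upstream({"c": rc_contig},
                                        [FeatureRecord("c", L - e, L - s, "+", "g")])[0]
            assert minus.sequence == mirrored.sequence


class TestFastaRoundTrip:
    def test_round_trip(self, tmp_path):
        up = UpstreamSet.from_sequences([("g1", "ACGTACGTAC"), ("g2", "TTTTGGGGCC")])
        path = tmp_path / "u.fa"
        up.to_fasta(path)
        back = UpstreamSet.from_fasta(path)
        assert back.ids == ["g1", "g2"]
        assert [r.sequence for r in back] == ["ACGTACGTAC", "TTTTGGGGCC"]


class TestMemeMinimal:
    def test_round_trip_preserves_matrix_and_nsites(self, tmp_path):
        rng = np.random.default_rng(3)
        motifs = [
            MotifRecord(id=f"m{i}", matrix=random_pwm(rng, int(rng.integers(5, 20))),
                        nsites=int(rng.integers(20, 200)), coverage=1.0)
            for i in range(3)
        ]
        path = tmp_path / "motifs.meme"
        write_meme_minimal(motifs, path)
        back = read_meme_minimal(path)
        assert [m.id for m in back] == [m.id for m in motifs]
        for a, b in zip(motifs, back):
            assert b.nsites == a.nsites
            assert np.abs(a.matrix.probs - b.matrix.probs).max() <= 1e-6

    def test_uniform_fixture_file(self, tmp_path):
        path = tmp_path / "u.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF uniform\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0\n"
            "0.25 0.25 0.25 0.25\n0.25 0.25 0.25 0.25\n"
        )
        motifs = read_meme_minimal(path)
        assert len(motifs) == 1
        assert motifs[0].width == 2
        np.testing.assert_allclose(motifs[0].matrix.probs, 0.25)

    def test_row_count_mismatch_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF broken\n"
            "letter-probability matrix: alength= 4 w= 4 nsites= 10 E= 0\n"
            "0.25 0.25 0.25 0.25\n0.25 0.25 0.25 0.25\n0.25 0.25 0.25 0.25\n"
        )
        with pytest.raises(MemeParseError, match="broken"):
            read_meme_minimal(path)

    def test_missing_version_line_is_parse_error(self, tmp_path):
        path = tmp_path / "nover.meme"
        path.write_text("ALPHABET= ACGT\nMOTIF x\n")
        with pytest.raises(MemeParseError, match="version"):
            read_meme_minimal(path)

    def test_unnormalised_column_is_parse_error(self, tmp_path):
        path = tmp_path / "unnorm.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF x\n"
            "letter-probability matrix: alength= 4 w= 1 nsites= 10 E= 0\n"
            "0.9 0.9 0.9 0.9\n"
        )
        with pytest.raises(MemeParseError, match="sum"):
            read_meme_minimal(path)

    def test_biopython_parses_our_output(self, tmp_path):
        """Independent parser cross-check of the writer."""
        from Bio import motifs as bio_motifs

        rng = np.random.default_rng(4)
        rec = MotifRecord(id="xcheck", matrix=random_pwm(rng, 9),
                          nsites=100, coverage=1.0)
        path = tmp_path / "x.meme"
        write_meme_minimal([rec], path)
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        assert parsed[0].name == "xcheck"
        assert parsed[0].length == 9
        arr = np.array([parsed[0].pwm[b] for b in "ACGT"])
        # Bio.motifs reconstructs integer counts and renormalises, so
        # per-cell agreement is only ~2/nsites
        assert np.abs(arr - rec.matrix.probs).max() <= 2.0 / rec.nsites


class TestFeatureTsv:
    def test_read_five_columns(self, tmp_path):
        path = tmp_path / "feats.tsv"
        path.write_text("# contig\tstart\tend\tstrand\tgene\nchr1\t10\t900\t+\tgeneA\n")
        feats = read_feature_tsv(path)
        assert feats == [FeatureRecord("chr1", 10, 900, "+", "geneA")]

    def test_wrong_column_count_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t10\t900\t+\n")
        with pytest.raises(ValueError, match="5"):
            read_feature_tsv(path)


class TestGff3Adapter:
    def test_cds_features_converted_to_half_open(self, tmp_path):
        from palmotifs.sequence_io import read_gff3_cds

        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t900\t.\t+\t.\tID=gene1\n"
            "chr1\tsrc\tCDS\t101\t900\t.\t+\t0\tID=cds1;Parent=gene1\n"
            "chr1\tsrc\tCDS\t2001\t2500\t.\t-\t0\tID=cds2\n"
        )
        feats = read_gff3_cds(gff)
        assert feats == [
            FeatureRecord("chr1", 100, 900, "+", "cds1"),
            FeatureRecord("chr1", 2000, 2500, "-", "cds2"),
        ]


class TestProbeDesign:
    def _pwm_with_peaks(self, width, hot):
        probs = np.full((4, width), 0.25)
        for j in hot:
            probs[:, j] = [0.97, 0.01, 0.01, 0.01]
        return FrequencyMatrix(probs=probs / probs.sum(axis=0, keepdims=True))

    @pytest.mark.parametrize("base, mutated", [("G", "A"), ("A", "G"), ("C", "T"), ("T", "C")])
    def test_transition_rules(self, base, mutated):
        pwm = self._pwm_with_peaks(4, [0, 3])
        site = base + "CC" + base
        out, positions = design_mutant_probe(pwm, site)
        assert positions == [0, 3]
        assert out == mutated + "CC" + mutated

    def test_two_most_conserved_selected(self):
        pwm = self._pwm_with_peaks(4, [1, 2])
        out, positions = design_mutant_probe(pwm, "AAAA")
        assert positions == [1, 2]
        assert out == "AGGA"

    def test_ties_broken_leftmost(self):
        pwm = self._pwm_with_peaks(5, [0, 2, 4])  # three equal peaks
        _, positions = design_mutant_probe(pwm, "GGGGG")
        assert positions == [0, 2]

    def test_exactly_two_changes_and_double_application_restores(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 12)
        site = "".join(rng.choice(list("ACGT"), 12))
        out, positions = design_mutant_probe(pwm, site)
        assert len(out) == len(site)
        assert sum(a != b for a, b in zip(out, site)) == 2
        back, positions2 = design_mutant_probe(pwm, out)
        assert back == site.upper() and positions2 == positions

    def test_width_one_rejected(self):
        pwm = FrequencyMatrix(probs=np.array([[1.0], [0], [0], [0]]))
        with pytest.raises(ValueError):
            design_mutant_probe(pwm, "A")
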