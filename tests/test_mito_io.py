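import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import mito_io
from mitocomp.mito_io import (
    CoordinateError,
    FormatError,
    GeneFeature,
    MitoGenome,
    extract_cds,
    read_fasta,
    read_genbank,
    reverse_complement,
    summarize_annotation,
    write_fasta,
    write_genbank,
)

MINIMAL_GB = """LOCUS       test0001                 300 bp    DNA     circular INV 01-JAN-2000
DEFINITION  minimal test record.
ACCESSION   test0001
FEATURES             Location/Qualifiers
     CDS             1..300
                     /gene="cox1"
                     /transl_table=4
ORIGIN
{origin}
//
"""

JOINED_GB = """LOCUS       test0002                 300 bp    DNA     circular INV 01-JAN-2000
DEFINITION  joined test record.
ACCESSION   test0002
FEATURES             Location/Qualifiers
     CDS             join(1..100,201..300)
                     /gene="cox1"
                     /transl_table=4
ORIGIN
{origin}
//
"""


def _origin_block(seq):
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        parts = " ".join(chunk[j : j + 10].lower() for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return "\n".join(lines)


def _cds300():
    # ATG + 98 ordinary codons + TAA = 300 nt
    return "ATG" + "GCT" * 98 + "TAA"


@pytest.fixture()
def minimal_path(tmp_path):
    p = tmp_path / "minimal.gb"
    p.write_text(MINIMAL_GB.format(origin=_origin_block(_cds300())))
    return str(p)


class TestReadGenbank:
    def test_single_cds_plus_strand(self, minimal_path):
        g = read_genbank(minimal_path)
        assert g.length == 300
        assert g.circular
        (feat,) = g.features
        assert feat.name == "cox1"
        assert feat.exons == [(1, 300)]
        assert feat.strand == "+"

    def test_join_produces_exon_boundaries(self, tmp_path):
        seq = _cds300()[:100] + "T" * 100 + _cds300()[100:200] + "TAA" + "A" * 97
        # make a 300bp sequence with CDS join(1..100,201..300)
        seq = seq[:300]
        p = tmp_path / "joined.gb"
        p.write_text(JOINED_GB.format(origin=_origin_block(seq)))
        g = read_genbank(str(p))
        cds = extract_cds(g, "cox1")
        assert len(cds.nt) == 200
        assert cds.exon_boundaries == [100]
        assert cds.nt == seq[:100] + seq[200:300]

    def test_intron_inferred_from_exon_gap(self, tmp_path):
        seq = "A" * 300
        p = tmp_path / "joined.gb"
        p.write_text(JOINED_GB.format(origin=_origin_block(seq)))
        g = read_genbank(str(p))
        (intr,) = g.introns
        assert intr.host_gene == "cox1"
        assert intr.genome_interval == (101, 200)
        assert intr.index == 1

    def test_parse_failure_names_file(self, tmp_path):
        p = tmp_path / "junk.gb"
        p.write_text("this is not a genbank record\n")
        with pytest.raises(FormatError, match="junk.gb"):
            read_genbank(str(p))

    def test_roundtrip_preserves_features(self, small_genome, tmp_path):
        genome, _ = small_genome
        dest = tmp_path / "rt.gb"
        write_genbank(genome, str(dest))
        back = read_genbank(str(dest))
        assert back.sequence == genome.sequence
        assert back.circular == genome.circular
        key = lambda f: (f.name, f.kind, f.strand, tuple(f.exons))
        assert sorted(map(key, back.features)) == sorted(map(key, genome.features))
        assert sorted(
            (i.host_gene, i.genome_interval) for i in back.introns
        ) == sorted((i.host_gene, i.genome_interval) for i in genome.introns)


class TestMitoGenomeInvariants:
    def test_feature_out_of_bounds(self):
        with pytest.raises(CoordinateError):
            MitoGenome(
                id="x",
                sequence="ACGT" * 10,
                features=[GeneFeature("g", "PCG", "+", [(30, 60)])],
            )

    def test_ambiguity_rejected(self):
        with pytest.raises(FormatError):
            MitoGenome(id="x", sequence="ACGRT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            MitoGenome(id="x", sequence="")


class TestExtractCds:
    def test_single_exon_plus(self, small_genome):
        genome, manifest = small_genome
        cds = extract_cds(genome, "atp6")
        assert cds.nt == manifest["genes"]["atp6"]["cds"]
        assert cds.exon_boundaries == []

    def test_minus_strand_is_reverse_complement(self, small_genome):
        genome, manifest = small_genome
        feat = next(f for f in genome.features if f.strand == "-" and f.kind == "PCG")
        raw = genome.sequence[feat.start - 1 : feat.end]
        cds = extract_cds(genome, feat.name)
        assert cds.nt == reverse_complement(raw)

    def test_spliced_matches_manifest(self, small_genome):
        genome, manifest = small_genome
        cds = extract_cds(genome, "cox1")
        assert cds.nt == manifest["genes"]["cox1"]["cds"]
        assert cds.exon_boundaries == [383]
        assert len(cds.nt) == 3 * len(cds.aa) + 3  # stop included

    def test_exon_lengths_sum_to_cds(self, small_genome):
        genome, _ = small_genome
        for f in genome.features:
            if f.kind != "PCG":
                continue
            cds = extract_cds(genome, f.name)
            assert f.spliced_length == len(cds.nt)

    def test_reverse_complemented_genome_gives_same_cds(self, small_genome):
        genome, _ = small_genome
        L = genome.length
        flipped = MitoGenome(
            id="rc",
            sequence=reverse_complement(genome.sequence),
            features=[
                GeneFeature(
                    f.name,
                    f.kind,
                    "-" if f.strand == "+" else "+",
                    sorted((L - e + 1, L - s + 1) for s, e in f.exons),
                    f.product,
                )
                for f in genome.features
            ],
        )
        for gene in ("cox1", "atp6", "nad5"):
            assert extract_cds(flipped, gene).nt == extract_cds(genome, gene).nt

    def test_missing_gene_raises(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(KeyError):
            extract_cds(genome, "nope")


class TestFasta:
    def test_case_and_u_normalization(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x extra tokens\nacgu\n")
        assert read_fasta(str(p)) == [("x", "ACGT")]

    def test_two_records_in_order(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nAC\nGT\n>b\nTTTT\n")
        assert read_fasta(str(p)) == [("a", "ACGT"), ("b", "TTTT")]

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(str(p))

    def test_empty_record_raises(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\n>b\nACGT\n")
        with pytest.raises(FormatError):
            read_fasta(str(p))

    @settings(max_examples=25, deadline=None)
    @given(
        records=st.lists(
            st.tuples(
                st.text(alphabet=string.ascii_letters + string.digits, min_size=1, max_size=12),
                st.text(alphabet="ACGT", min_size=1, max_size=200),
            ),
            min_size=1,
            max_size=5,
            unique_by=lambda t: t[0],
        )
    )
    def test_roundtrip_identity(self, records, tmp_path_factory):
        p = tmp_path_factory.mktemp("fasta") / "rt.fa"
        write_fasta(records, str(p))
        assert read_fasta(str(p)) == records


class TestSummarize:
    def test_counts_match_manifest(self, small_genome):
        genome, manifest = small_genome
        s = summarize_annotation(genome)
        assert s.n_pcg == 15
        assert s.n_intronic_orf == 1
        assert s.n_pcg_incl_intronic == 16
        assert s.n_intron == len(manifest["introns"]) == 1
        assert s.n_rrna == 2
        assert s.n_trna == 6
        assert s.len_rnl == 3768
        assert s.len_rns == 1973

    def test_empty_genome_all_zero(self):
        g = MitoGenome(id="bare", sequence="ACGT" * 100)
        s = summarize_annotation(g)
        assert (
            s.n_pcg == s.n_trna == s.n_rrna == s.n_intron == s.n_intronic_orf == 0
        )
        assert s.len_rns is None and s.len_rnl is None

    def test_summary_table_columns(self, small_genome):
        genome, _ = small_genome
        df = mito_io.summary_table([genome])
        assert list(df.columns) == [
            "genome_id", "n_pcg", "n_trna", "n_rrna",
            "n_intron", "n_intronic_orf", "len_rns", "len_rnl",
        ]
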