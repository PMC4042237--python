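"""Junction enumeration, three-frame translation rules, DNA backtracking."""

import pytest
from hypothesis import given, settings, strategies as st

from juncpep.annotation_io import GenePair
from juncpep.insilico_digest import digest_junction
from juncpep.junction_builder import (
    JunctionNucSeq,
    enumerate_fusion_junctions,
    enumerate_splicing_junctions,
    reconstruct_dna,
    translate_junction,
    translate_nt,
)

from conftest import make_gene


def jn(sequence: str, junction_nt: int, kind: str = "fusion") -> JunctionNucSeq:
    return JunctionNucSeq(
        upstream_exon_id="eU",
        downstream_exon_id="eD",
        upstream_gene="GENEA",
        downstream_gene="GENEA" if kind == "splicing" else "GENEB",
        kind=kind,
        sequence=sequence,
        junction_nt=junction_nt,
    )


class TestEnumeration:
    @pytest.mark.parametrize("na,nb", [(2, 3), (1, 1), (1, 4)])
    def test_fusion_count_is_2ab(self, na, nb):
        models = {
            "GENEA": make_gene("GENEA", ["ATGAAA"] * na, gene_id="ga"),
            "GENEB": make_gene("GENEB", ["GGGTTT"] * nb, gene_id="gb"),
        }
        out = enumerate_fusion_junctions(GenePair.make("GENEA", "GENEB"), models)
        assert len(out) == 2 * na * nb
        # both orientations present
        assert {j.upstream_gene for j in out} == {"GENEA", "GENEB"}

    def test_fusion_concatenation_and_offset(self):
        models = {
            "GENEA": make_gene("GENEA", ["ATGAAA"], gene_id="ga"),
            "GENEB": make_gene("GENEB", ["GGGTAA"], gene_id="gb"),
        }
        out = enumerate_fusion_junctions(GenePair.make("GENEA", "GENEB"), models)
        ab = next(j for j in out if j.upstream_gene == "GENEA")
        assert ab.sequence == "ATGAAAGGGTAA"
        assert ab.junction_nt == 6

    def test_unresolvable_symbol_raises(self):
        models = {"GENEA": make_gene("GENEA", ["ATGAAA"])}
        with pytest.raises(KeyError, match="GENEB"):
            enumerate_fusion_junctions(GenePair.make("GENEA", "GENEB"), models)

    @pytest.mark.parametrize("n_exons,expected", [(1, 0), (2, 1), (3, 3), (5, 10)])
    def test_splicing_count_is_n_choose_2(self, n_exons, expected):
        gm = make_gene("GENEA", ["ATGAAA"] * n_exons)
        out = enumerate_splicing_junctions(gm)
        assert len(out) == expected

    def test_splicing_order_and_offset(self):
        gm = make_gene("GENEA", ["ATGAAA", "CCC", "GGGTTT"])
        out = enumerate_splicing_junctions(gm)
        pairs = {(j.upstream_exon_id, j.downstream_exon_id) for j in out}
        assert pairs == {
            ("geneae1", "geneae2"),
            ("geneae1", "geneae3"),
            ("geneae2", "geneae3"),
        }
        e1e3 = next(j for j in out if j.downstream_exon_id == "geneae3"
                    and j.upstream_exon_id == "geneae1")
        assert e1e3.junction_nt == 6  # length of exon 1


class TestTranslateJunction:
    def test_clean_frame0(self):
        out = translate_junction(jn("ATGAAAGGGTTT", 6))
        f0 = next(p for p in out if p.frame == 0)
        assert f0.aa_sequence == "MKGF"
        assert (f0.junction_left_aa, f0.junction_right_aa) == (2, 2)
        assert not f0.straddle

    def test_stop_before_junction_kills_frame(self):
        out = translate_junction(jn("TAAAAAGGGGGG", 6))
        assert all(p.frame != 0 for p in out)

    def test_stop_in_first_downstream_codon_discards_frame(self):
        # frame 0 survives the stop rule but retains no downstream residue
        out = translate_junction(jn("ATGAAATAGGGG", 6))
        assert all(p.frame != 0 for p in out)

    def test_downstream_stop_truncates(self):
        out = translate_junction(jn("ATGAAAGGGTAATTT", 6))
        f0 = next(p for p in out if p.frame == 0)
        assert f0.aa_sequence == "MKG"
        assert f0.junction_right_aa == 1

    def test_straddling_stop_kills_frame(self):
        # frame 1: codons TGA... -> stop spans positions 1-3 around junction 2
        out = translate_junction(jn("ATGAAAGGGTTT", 2))
        # TGA is a stop straddling the junction: frame 1 must be gone
        assert not [p for p in out if p.frame == 1]

    def test_n_codon_translates_to_x_not_stop(self):
        out = translate_junction(jn("TANAAAGGGTTT", 6))
        f0 = next(p for p in out if p.frame == 0)
        assert f0.aa_sequence.startswith("X")

    def test_non_nucleotide_raises(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            translate_junction(jn("ATGAAAGGQTTT", 6))


NT = st.text(alphabet="ACGT", min_size=3, max_size=45)


@settings(max_examples=200, derandomize=True)
@given(up=NT, down=NT, frame_seed=st.integers(0, 1000))
def test_translation_invariants(up, down, frame_seed):
    """Retained frames: no stops, side bookkeeping sums, straddle parity."""
    junction = jn(up + down, len(up))
    for p in translate_junction(junction):
        assert "*" not in p.aa_sequence
        assert p.junction_right_aa >= 1
        straddle_n = 1 if p.straddle else 0
        assert p.junction_left_aa + p.junction_right_aa + straddle_n == len(
            p.aa_sequence
        )
        if p.junction_left_aa > 0:  # junction codon region covered by the frame
            assert p.straddle == ((junction.junction_nt - p.frame) % 3 != 0)
        # re-translating the stored frame reproduces the sequence
        full = translate_nt(junction.sequence[p.frame:])
        assert full.startswith(p.aa_sequence) or full[: len(p.aa_sequence)] == p.aa_sequence


class TestReconstructDna:
    def test_junction_peptide_backtracks_to_codon_span(self):
        out = translate_junction(jn("ATGAAAGGGTTTAGAGAT", 6))
        f0 = next(p for p in out if p.frame == 0)  # MKGFRD
        peps = digest_junction(f0, min_len=2)
        pep = next(p for p in peps if p.sequence == "MKGFR")
        dna, (up, down, frame) = reconstruct_dna(pep)
        assert dna == "ATGAAAGGGTTTAGA"
        assert (up, down, frame) == ("eU", "eD", 0)
        assert translate_nt(dna) == pep.sequence

    def test_roundtrip_for_all_generated_peptides(self, small_dataset):
        ds = small_dataset
        checked = 0
        for entry in ds.database.component("Fusion")[:50]:
            for prov in entry.meta.provenance[:2]:
                from juncpep.insilico_digest import PeptideRecord

                pep = PeptideRecord(
                    sequence=entry.sequence,
                    kind="fusion",
                    left_aa=1,
                    right_aa=1,
                    straddle_in_peptide=False,
                    misc_left=0,
                    misc_right=0,
                    provenance=(prov,),
                )
                dna, _ = reconstruct_dna(pep)
                assert translate_nt(dna) == entry.sequence
                checked += 1
        assert checked > 0

    def test_missing_provenance_raises(self):
        from juncpep.insilico_digest import PeptideRecord

        pep = PeptideRecord("MKGFR", "fusion", 1, 3, False, 0, 0, provenance=())
        with pytest.raises(ValueError, match="provenance"):
            reconstruct_dna(pep)

    def test_span_outside_translation_raises(self):
        out = translate_junction(jn("ATGAAAGGGTTT", 6))
        f0 = next(p for p in out if p.frame == 0)
        peps = digest_junction(f0, min_len=2)
        bad = peps[0]
        from dataclasses import replace

        prov = replace(bad.provenance[0], start_res=40)
        bad = replace(bad, provenance=(prov,))
        with pytest.raises(ValueError, match="span|encode"):
            reconstruct_dna(bad)
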