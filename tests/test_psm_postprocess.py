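"""Target-decoy FDR filter, category precedence, evidence integration."""

import numpy as np
import pandas as pd
import pytest

from juncpep.db_assembler import (
    DatabaseEntry,
    PeptideDatabase,
    build_decoys,
    merge_entries,
)
from juncpep.psm_postprocess import (
    OMSSA,
    PSM,
    XTANDEM,
    PostprocessConfig,
    categorize_peptide,
    fdr_filter,
    group_distribution,
    integrate_evidence,
    junction_span_ok,
    load_psms,
    run_postprocess,
)

from test_db_assembler import junction_peptides


def psm(i, score, decoy=False, raw="f1.raw", pep="PEPTIDEK", engine="xtandem"):
    return PSM(f"s{i}", raw, pep, score, engine, is_decoy=decoy)


CONF = PostprocessConfig()


class TestFdrFilter:
    def test_no_decoys_all_accepted(self):
        psms = [psm(i, 50 + i) for i in range(5)]
        assert len(fdr_filter(psms, XTANDEM, CONF)) == 5

    def test_single_low_ranked_decoy_cuts_tail(self):
        psms = [psm(i, 100 - i) for i in range(10)] + [psm(99, 50, decoy=True)]
        accepted = fdr_filter(psms, XTANDEM, CONF)
        # FDR at rank 11 = 2*1/11, far above 1e-6
        assert len(accepted) == 10
        assert not any(p.is_decoy for p in accepted)

    def test_decoy_at_rank_one_empties_acceptance(self):
        psms = [psm(0, 1000, decoy=True)] + [psm(i, 100 - i) for i in range(5)]
        assert fdr_filter(psms, XTANDEM, CONF) == []

    def test_lower_better_direction(self):
        psms = [
            psm(0, 1e-9, engine="omssa"),
            psm(1, 1e-8, engine="omssa"),
            psm(2, 0.5, engine="omssa", decoy=True),
        ]
        accepted = fdr_filter(psms, OMSSA, CONF)
        assert [p.spectrum_id for p in accepted] == ["s0", "s1"]

    def test_exact_tie_puts_decoy_after_target(self):
        psms = [psm(0, 50.0, decoy=True), psm(1, 50.0)]
        accepted = fdr_filter(psms, XTANDEM, CONF)
        assert [p.spectrum_id for p in accepted] == ["s1"]

    def test_mixed_raw_files_rejected(self):
        with pytest.raises(ValueError, match="one raw file"):
            fdr_filter([psm(0, 1), psm(1, 2, raw="f2.raw")], XTANDEM, CONF)

    def test_formula_matches_hand_computation_with_loose_alpha(self):
        # 3 targets, then decoy, then target: FDR(4)=2/4, FDR(5)=2/5
        psms = [psm(0, 90), psm(1, 80), psm(2, 70),
                psm(3, 60, decoy=True), psm(4, 50)]
        loose = PostprocessConfig(fdr_alpha=0.5)
        accepted = fdr_filter(psms, XTANDEM, loose)
        assert len(accepted) == 5  # 2*1/5 = 0.4 <= 0.5 at the last rank
        tighter = PostprocessConfig(fdr_alpha=0.45)
        assert len(fdr_filter(psms, XTANDEM, tighter)) == 5  # 0.4 <= 0.45
        assert len(fdr_filter(psms, XTANDEM, PostprocessConfig(fdr_alpha=0.3))) == 3

    def test_zero_decoys_accepted_over_randomized_tables(self):
        """At alpha=1e-6 any decoy forces FDR >= 2/k > alpha for k < 2e6."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 400))
            psms = [
                psm(i, float(rng.normal(50, 20)), decoy=bool(rng.random() < 0.3))
                for i in range(n)
            ]
            accepted = fdr_filter(psms, XTANDEM, CONF)
            assert not any(p.is_decoy for p in accepted)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(6)
        psms = [
            psm(i, float(rng.normal(50, 20)), decoy=bool(rng.random() < 0.3))
            for i in range(200)
        ]
        alphas = [1e-6, 0.01, 0.1, 0.5, 0.9]
        sets = [
            {p.spectrum_id for p in fdr_filter(psms, XTANDEM, PostprocessConfig(fdr_alpha=a))}
            for a in alphas
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


@pytest.fixture
def toy_db():
    # fusion entry MKGGGFFFR (junction after 2 residues)
    peps = junction_peptides("ATGAAAGGTGGAGGCTTTTTCTTCAGA", 6)
    # splicing entry with the same sequence to exercise precedence
    spl = junction_peptides("ATGAAAGGTGGAGGCTTTTTCTTCAGA", 6, kind="splicing")
    entries = merge_entries(peps + spl)
    entries.append(DatabaseEntry("prot1", "Annotated", "WWWAAAKEEEDDDRWWW"))
    entries.append(DatabaseEntry("cont1", "Contaminated", "CCCCCC"))
    entries += build_decoys(entries)
    return PeptideDatabase(entries)


class TestCategorize:
    def test_precedence(self, toy_db):
        assert categorize_peptide("MKGGGFFFR", toy_db) == "Splicing"
        assert categorize_peptide("AAAKEEEDDDR", toy_db) == "Annotated"
        assert categorize_peptide("CCCC", toy_db) == "Contaminated"
        assert categorize_peptide("HHHHHH", toy_db) == "none"

    def test_fusion_only_sequence(self):
        peps = junction_peptides("ATGAAAGGTGGAGGCTTTTTCTTCAGA", 6)
        entries = merge_entries(peps)
        entries += build_decoys(entries)
        db = PeptideDatabase(entries)
        assert categorize_peptide("MKGGGFFFR", db) == "Fusion"

    def test_never_fusion_when_annotated_substring(self, small_dataset):
        db = small_dataset.database
        for e in db.component("Annotated")[:5]:
            frag = e.sequence[2:12]
            assert categorize_peptide(frag, db) != "Fusion"


class TestJunctionSpan:
    def test_side_counts(self, toy_db):
        entry = toy_db.component("Fusion")[0]  # MKGGGFFFR, left=2
        assert not junction_span_ok("MKGGGFFFR", entry, CONF)  # left side only 2
        relaxed = PostprocessConfig(min_side_aa=2)
        assert junction_span_ok("MKGGGFFFR", entry, relaxed)
        assert not junction_span_ok("GGGFFFR", entry, relaxed)  # no left residues

    def test_straddle_counts_to_neither_side(self):
        # junction after 10 nt: frame 0 straddles codon 3 (nt 9-11)
        from juncpep.junction_builder import translate_junction
        from test_junction_builder import jn as mkjn

        jp = next(
            p
            for p in translate_junction(
                mkjn("ATGAAAGGTGCTTTTTCTTCAGAGAT", 10)
            )
            if p.frame == 0
        )
        assert jp.straddle
        from juncpep.insilico_digest import digest_junction

        peps = digest_junction(jp)
        entries = merge_entries(peps)
        entry = entries[0]
        left = entry.meta.junction_left_aa
        seq = entry.sequence
        ok = junction_span_ok(seq, entry, PostprocessConfig(min_side_aa=left))
        assert ok == (left >= 1 and len(seq) - left - 1 >= left)

    def test_missing_metadata_raises(self, toy_db):
        annotated = toy_db.component("Annotated")[0]
        with pytest.raises(ValueError, match="junction metadata"):
            junction_span_ok("AAA", annotated, CONF)


def _accepted(pep, engine, spectra):
    return [
        PSM(sid, raw, pep, 80.0, engine) for raw, sid in spectra
    ]


class TestIntegrateEvidence:
    DB_NT = "ATGGCTGCAAAAGGTGGAGGCTTTTTCGATGATAAG"  # MAAKGGGFFDDK, junction at 12 nt

    @pytest.fixture
    def db(self):
        peps = junction_peptides(self.DB_NT, 12)
        entries = merge_entries(peps)
        entries += build_decoys(entries)
        return PeptideDatabase(entries)

    @property
    def pep(self):
        return "MAAKGGGFFDDK"

    def test_shared_spectrum_retained(self, db):
        acc = {
            "xtandem": _accepted(self.pep, "xtandem", [("f1", "s1"), ("f1", "s2")]),
            "omssa": _accepted(self.pep, "omssa", [("f1", "s2")]),
        }
        out = integrate_evidence(acc, {}, db, CONF)
        assert len(out) == 1
        c = out[0]
        assert c.evidence.both_engines and c.evidence.shared_spectrum
        assert c.category == "Fusion"
        assert c.spectrum_counts == {"xtandem": 2, "omssa": 1}

    def test_disjoint_spectra_dropped(self, db):
        acc = {
            "xtandem": _accepted(self.pep, "xtandem", [("f1", "s1")]),
            "omssa": _accepted(self.pep, "omssa", [("f1", "s9")]),
        }
        assert integrate_evidence(acc, {}, db, CONF) == []

    def test_conservation_rescues_single_engine(self, db):
        acc = {"xtandem": _accepted(self.pep, "xtandem", [("f1", "s1")]), "omssa": []}
        out = integrate_evidence(acc, {self.pep: True}, db, CONF)
        assert len(out) == 1
        assert out[0].evidence.conserved and not out[0].evidence.both_engines

    def test_one_engine_unconserved_dropped(self, db):
        acc = {"xtandem": _accepted(self.pep, "xtandem", [("f1", "s1")]), "omssa": []}
        assert integrate_evidence(acc, {}, db, CONF) == []

    def test_min_side_rule_excludes_short_side(self, db):
        acc = {
            "xtandem": _accepted(self.pep, "xtandem", [("f1", "s1")]),
            "omssa": _accepted(self.pep, "omssa", [("f1", "s1")]),
        }
        strict = PostprocessConfig(min_side_aa=5)  # entry has 4 left residues
        assert integrate_evidence(acc, {}, db, strict) == []

    def test_unknown_conserved_peptides_warn(self, db):
        acc = {
            "xtandem": _accepted(self.pep, "xtandem", [("f1", "s1")]),
            "omssa": _accepted(self.pep, "omssa", [("f1", "s1")]),
        }
        with pytest.warns(UserWarning, match="conservation"):
            integrate_evidence(acc, {"NOTSEEN": True}, db, CONF)


class TestGroupDistribution:
    def make_char(self, db):
        acc = {
            "xtandem": _accepted("MAAKGGGFFDDK", "xtandem",
                                 [("scc.raw", "s1"), ("scc.raw", "s2")]),
            "omssa": _accepted("MAAKGGGFFDDK", "omssa", [("scc.raw", "s1")]),
        }
        chars = integrate_evidence(acc, {}, db, CONF)
        psms = [p for v in acc.values() for p in v]
        return chars, psms

    @pytest.fixture
    def db(self):
        peps = junction_peptides(TestIntegrateEvidence.DB_NT, 12)
        entries = merge_entries(peps)
        entries += build_decoys(entries)
        return PeptideDatabase(entries)

    def test_exclusive_label(self, db):
        chars, psms = self.make_char(db)
        table = group_distribution(chars, psms, {"scc.raw": "SCC"})
        assert list(table.exclusivity) == ["SCC_only"]
        assert chars[0].group_counts == {"SCC": 3}

    def test_mixed_without_normal(self, db):
        chars, psms = self.make_char(db)
        psms.append(PSM("s7", "adc.raw", "MAAKGGGFFDDK", 70.0, "xtandem"))
        table = group_distribution(
            chars, psms, {"scc.raw": "SCC", "adc.raw": "ADC", "n.raw": "Normal"}
        )
        row = table.iloc[0]
        assert row.exclusivity == "mixed"
        assert (row.SCC, row.ADC, row.Normal) == (3, 1, 0)

    def test_unmapped_raw_file_raises(self, db):
        chars, psms = self.make_char(db)
        with pytest.raises(ValueError, match="scc.raw"):
            group_distribution(chars, psms, {"other.raw": "SCC"})

    def test_empty_characterized_empty_table(self, db):
        table = group_distribution([], [], {"scc.raw": "SCC"})
        assert table.empty


class TestLoadPsms:
    def test_loads_and_flags_decoys(self, tmp_path, small_dataset):
        db = small_dataset.database
        decoy_id = db.component("Reversal")[0].entry_id
        df = pd.DataFrame(
            {
                "spectrum_id": ["s1", "s2", "s3"],
                "raw_file": ["f1"] * 3,
                "peptide": ["PEPTIDEK"] * 3,
                "score": [10.0, 20.0, 30.0],
                "matched_entry_id": ["fus_000001", decoy_id, None],
            }
        )
        path = tmp_path / "psms.tsv"
        df.to_csv(path, sep="\t", index=False)
        psms = load_psms(path, XTANDEM, db)
        assert len(psms) == 3
        assert [p.is_decoy for p in psms] == [False, True, False]

    def test_nonnumeric_scores_dropped_with_warning(self, tmp_path, small_dataset):
        path = tmp_path / "psms.tsv"
        path.write_text(
            "spectrum_id\traw_file\tpeptide\tscore\n"
            "s1\tf1\tPEPK\t10\ns2\tf1\tPEPK\toops\n"
        )
        with pytest.warns(UserWarning, match="non-numeric"):
            psms = load_psms(path, XTANDEM, small_dataset.database)
        assert len(psms) == 1

    def test_missing_column_raises(self, tmp_path, small_dataset):
        path = tmp_path / "psms.tsv"
        path.write_text("spectrum_id\tpeptide\ns1\tPEPK\n")
        with pytest.raises(ValueError, match="missing required column"):
            load_psms(path, XTANDEM, small_dataset.database)

    def test_empty_table_empty_list(self, tmp_path, small_dataset):
        path = tmp_path / "psms.tsv"
        path.write_text("spectrum_id\traw_file\tpeptide\tscore\n")
        assert load_psms(path, XTANDEM, small_dataset.database) == []


def test_run_postprocess_recovers_planted_truth(small_dataset):
    ds = small_dataset
    chars, table, accepted = run_postprocess(
        ds.database, ds.search.tables, ds.search.group_map, ds.search.conservation
    )
    expected = ds.truth.expected_reported_sequences()
    assert {c.sequence for c in chars} == set(expected)
    for c in chars:
        assert c.category == expected[c.sequence].expected_category
        assert c.exclusivity == expected[c.sequence].expected_exclusivity
    assert not any(p.is_decoy for acc in accepted.values() for p in acc)
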