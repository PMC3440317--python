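"""Dataset construction: annotation reading, length normalisation,
redundancy reduction, negative sampling, fold assignment."""

import numpy as np
import pytest

import tripitope as tp
from tripitope.datasets import (
    EpitopeDataset,
    EpitopeRecord,
    eligible_negative_windows,
    pairwise_identity,
    write_fasta,
)

ANTIGEN = "MKVLAAAQQPWWRDSTGHIKCCDEFNPQRSYVLMAEKWTG"  # 40 residues


def _record(eid="E1", start=7, end=17):
    return EpitopeRecord(
        epitope_id=eid,
        antigen_id="A1",
        antigen_seq=ANTIGEN,
        epitope_seq=ANTIGEN[start:end],
        start=start,
        end=end,
    )


def test_record_span_must_match_antigen():
    with pytest.raises(ValueError, match="does not match"):
        EpitopeRecord("E1", "A1", ANTIGEN, "WWWWW", 0, 5)
    with pytest.raises(ValueError, match="outside antigen"):
        EpitopeRecord("E1", "A1", ANTIGEN, ANTIGEN[30:40], 30, 41)


def _write_inputs(tmp_path, rows, antigens=None):
    fasta = tmp_path / "antigens.fasta"
    write_fasta(fasta, antigens or [("A1", ANTIGEN)])
    tsv = tmp_path / "epitopes.tsv"
    header = "epitope_id\tantigen_id\tepitope_seq\tstart\tend\tis_tcell_related\n"
    tsv.write_text(header + "".join(rows))
    return tsv, fasta


def test_read_epitope_table_validates_and_deduplicates(tmp_path):
    epi = ANTIGEN[7:17]
    rows = [
        f"E1\tA1\t{epi}\t8\t17\t0\n",          # explicit 1-based span
        f"E2\tA1\t{epi}\t\t\t0\n",              # duplicate sequence -> collapsed
        f"E3\tA1\t{ANTIGEN[20:30]}\t\t\t0\n",  # span inferred by unique search
        "E4\tA1\tWWWWWWW\t\t\t0\n",             # not found -> rejected
        f"E5\tA1\t{ANTIGEN[0:8]}\t\t\t1\n",    # T-cell flagged -> rejected
        f"E6\tZZ\t{epi}\t\t\t0\n",              # unknown antigen -> rejected
        f"E7\tA1\t{ANTIGEN[20:30]}\t1\t10\t0\n",  # mismatched span -> rejected
    ]
    tsv, fasta = _write_inputs(tmp_path, rows)
    records = tp.read_epitope_table(tsv, fasta)
    assert [r.epitope_id for r in records] == ["E1", "E3"]
    assert records[1].start == 20 and records[1].end == 30


def test_ambiguous_substring_rejected(tmp_path):
    antigen = "AAQQPAAQQPAA"
    tsv, fasta = _write_inputs(
        tmp_path, ["E1\tA1\tQQP\t\t\t0\n"], antigens=[("A1", antigen)]
    )
    assert tp.read_epitope_table(tsv, fasta) == []


class TestNormalizeLength:
    def test_long_epitope_trimmed_about_centre(self):
        rec = _record(start=5, end=29)  # 24 residues
        pep = tp.normalize_length(rec, 20)
        assert pep.seq == ANTIGEN[7:27]  # 2 trimmed each side

    def test_short_epitope_extended_symmetrically(self):
        rec = _record(start=10, end=26)  # 16 residues
        pep = tp.normalize_length(rec, 20)
        assert (pep.start, pep.end) == (8, 28)

    def test_odd_leftover_resolved_toward_n_terminus(self):
        rec = _record(start=10, end=25)  # 15 residues, deficit 5
        pep = tp.normalize_length(rec, 20)
        assert (pep.start, pep.end) == (7, 27)  # 3 added N-side, 2 C-side

    def test_terminal_epitope_extends_into_available_side(self):
        rec = _record(start=0, end=10)
        pep = tp.normalize_length(rec, 20)
        assert (pep.start, pep.end) == (0, 20)

    def test_antigen_too_short_returns_none(self):
        short = ANTIGEN[:15]
        rec = EpitopeRecord("E1", "A1", short, short[2:12], 2, 12)
        assert tp.normalize_length(rec, 20) is None

    def test_feasible_window_oracle(self):
        """The chosen window is always a feasible L-window containing the
        epitope centre, verified against exhaustive window enumeration."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            antigen = "".join(rng.choice(list(tp.AMINO_ACIDS), size=n))
            s = int(rng.integers(0, n - 5))
            e = int(rng.integers(s + 3, min(n, s + 30) + 1))
            rec = EpitopeRecord("E", "A", antigen, antigen[s:e], s, e)
            pep = tp.normalize_length(rec, 20)
            feasible = [w for w in range(n - 19)]
            if not feasible:
                assert pep is None
                continue
            assert pep.start in feasible
            centre = (s + e) / 2
            # centre of the epitope lies inside (or at the edge of) the window
            assert pep.start <= centre <= pep.end


def test_reduce_redundancy_identical_and_chain():
    assert tp.reduce_redundancy(["AAAA", "AAAA"]) == [0]
    # A~B and B~C at 50%, A~C at 0%: one survivor by single linkage
    chain = ["AAAA", "AACC", "CCCC"]
    assert tp.reduce_redundancy(chain, identity_ceiling=0.5) == [0]
    # all-distinct peptides below the ceiling all survive
    distinct = ["AAAA", "CCCC", "DDDD", "EEEE"]
    assert tp.reduce_redundancy(distinct, identity_ceiling=0.3) == [0, 1, 2, 3]


def test_pairwise_identity_values():
    ident = pairwise_identity(["AAAA", "AABB".replace("B", "C"), "AAAA"])
    assert ident[0, 1] == pytest.approx(0.5)
    assert ident[0, 2] == pytest.approx(1.0)


def test_sample_negatives_avoids_epitope_spans():
    rng = np.random.default_rng(1)
    antigens = {}
    for i in range(10):
        seq = "".join(rng.choice(list(tp.AMINO_ACIDS), size=90))
        antigens[f"A{i}"] = (seq, [(10, 25), (55, 70)])
    negs = tp.sample_negatives(antigens, L=20, n=30, seed=3)
    assert len(negs) == 30
    for p in negs:
        spans = antigens[p.antigen_id][1]
        assert all(p.start >= e or p.end <= s for s, e in spans)
        assert p.seq == antigens[p.antigen_id][0][p.start:p.end]
    again = tp.sample_negatives(antigens, L=20, n=30, seed=3)
    assert [p.seq for p in again] == [p.seq for p in negs]


def test_sample_negatives_errors_when_covered():
    antigens = {"A1": (ANTIGEN, [(0, len(ANTIGEN))])}
    assert eligible_negative_windows(ANTIGEN, [(0, len(ANTIGEN))], 20) == []
    with pytest.raises(ValueError, match="eligible negative windows"):
        tp.sample_negatives(antigens, L=20, n=5, seed=0)


def test_assign_folds_balance_and_hygiene():
    # identical peptides end up in one fold
    folds = tp.assign_folds(["AAAA"] * 6, k=3)
    assert len(set(folds.tolist())) == 1
    # mutually dissimilar peptides balance to within one
    rng = np.random.default_rng(5)
    peps = ["".join(rng.choice(list(tp.AMINO_ACIDS), size=30)) for _ in range(23)]
    folds = tp.assign_folds(peps, k=5, seed=2)
    sizes = np.bincount(folds, minlength=5)
    assert sizes.max() - sizes.min() <= 1
    # exhaustive cross-fold check
    ident = pairwise_identity(peps)
    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):
            if folds[i] != folds[j]:
                assert ident[i, j] <= 0.20


def test_manifest_round_trip(tmp_path, small_benchmark):
    dataset, _ = small_benchmark
    path = tmp_path / "dataset.tsv"
    dataset.to_manifest(path)
    again = EpitopeDataset.from_manifest(path)
    assert again.length == dataset.length
    assert [p.seq for p in again.positives] == [p.seq for p in dataset.positives]
    assert np.array_equal(again.folds_neg, dataset.folds_neg)
    dataset.to_manifest(tmp_path / "again.tsv")
    assert (tmp_path / "again.tsv").read_bytes() == path.read_bytes()


def test_dataset_invariants_enforced():
    pep = tp.Peptide("A" * 20, "A1", 0, 20, 1)
    neg = tp.Peptide("C" * 20, "A1", 0, 20, 0)
    with pytest.raises(ValueError, match="equal in count"):
        EpitopeDataset(20, [pep], [], np.array([0]), np.array([]))
    with pytest.raises(ValueError, match="dataset length"):
        EpitopeDataset(
            20, [tp.Peptide("A" * 10, "A1", 0, 10, 1)], [neg],
            np.array([0]), np.array([0]),
        )


def test_build_dataset_end_to_end():
    spec = tp.GeneratorSpec(n_antigens=40, n_epitopes_per_antigen=2, seed=13)
    corpus = tp.generate_corpus(spec)
    ds = tp.build_dataset(corpus.records, L=20, seed=13)
    assert len(ds.positives) == len(ds.negatives)
    assert all(len(p.seq) == 20 for p in ds.all_peptides())
    assert all(p.label == 1 for p in ds.positives)
    # negatives never intersect an annotated span of their antigen
    spans_by_antigen = {}
    for r in corpus.records:
        spans_by_antigen.setdefault(r.antigen_id, []).append((r.start, r.end))
    for p in ds.negatives:
        for s, e in spans_by_antigen.get(p.antigen_id, []):
            assert p.start >= e or p.end <= s
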