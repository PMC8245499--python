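import pytest

from acpstep import (
    deduplicate_exact,
    greedy_cluster_identity,
    make_dataset,
    pairwise_identity,
    read_fasta,
    sample_negatives,
    split_train_test,
    validate_peptide,
    write_fasta,
)
from acpstep.data import filter_valid


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "in.fasta"
    p.write_text(">p1|ACP\nFLWCPCLKKC\n>p2|nonACP\nglfdiikkiaesf\n>p3\nGLFDIIKKIAESF\n")
    return p


class TestFastaIO:
    def test_parse_labels_and_case(self, fasta_file):
        ds = read_fasta(fasta_file)
        assert len(ds) == 3
        assert ds.loc[0, "label"] == "ACP"
        assert ds.loc[0, "sequence"] == "FLWCPCLKKC"
        assert ds.loc[1, "sequence"] == "GLFDIIKKIAESF"  # uppercased
        assert ds.loc[1, "label"] == "nonACP"
        assert ds.loc[2, "label"] == "UNLABELED"

    def test_round_trip(self, tmp_path, fasta_file):
        ds = read_fasta(fasta_file)
        out = tmp_path / "out.fasta"
        write_fasta(ds, out)
        again = read_fasta(out)
        assert (again["sequence"] == ds["sequence"]).all()
        assert (again["label"] == ds["label"]).all()

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            ds = read_fasta(p)
        assert len(ds) == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate ids"):
            make_dataset([("a", "KKKKKKKKKKK", "ACP"), ("a", "RRRRRRRRRRR", "ACP")])


class TestValidation:
    @pytest.mark.parametrize(
        "seq, ok, reason",
        [
            ("FLWCPCLKKC", False, "TOO_SHORT"),  # length 10 fails the >10 filter
            ("GLFDIIKKIAESF", True, None),
            ("GLFDIIKKIAESZ", False, "NON_CANONICAL"),
            ("GLFDIIKKIAEX", False, "NON_CANONICAL"),
        ],
    )
    def test_validate(self, seq, ok, reason):
        assert validate_peptide(seq) == (ok, reason)

    def test_relaxed_min_length(self):
        assert validate_peptide("FLWCPCLKKC", min_length=10) == (True, None)

    def test_filter_valid_reports_reasons(self):
        ds = make_dataset(
            [("a", "GLFDIIKKIAESF", "ACP"), ("b", "KKK", "ACP"), ("c", "GLFDIIKKIAESZ", "ACP")]
        )
        kept, rejected = filter_valid(ds)
        assert kept["id"].tolist() == ["a"]
        assert dict(zip(rejected["id"], rejected["reason"])) == {
            "b": "TOO_SHORT",
            "c": "NON_CANONICAL",
        }


class TestDeduplication:
    def test_within_class_first_seen_wins(self):
        ds = make_dataset([("a", "KKKKKKKKKKK", "ACP"), ("b", "KKKKKKKKKKK", "ACP")])
        out = deduplicate_exact(ds)
        assert out["id"].tolist() == ["a"]

    def test_cross_class_conflict_removes_both(self):
        s = "KLWKKWAKKWLK"
        ds = make_dataset([("a", s, "ACP"), ("b", s, "nonACP"), ("c", "GLFDIIKKIAESF", "ACP")])
        out = deduplicate_exact(ds)
        assert out["id"].tolist() == ["c"]

    def test_idempotent_and_identity_on_unique(self):
        ds = make_dataset([("a", "KKKKKKKKKKK", "ACP"), ("b", "RRRRRRRRRRR", "nonACP")])
        once = deduplicate_exact(ds)
        assert once.equals(deduplicate_exact(once))
        assert once.equals(ds)


class TestIdentityClustering:
    def test_single_substitution_identity(self):
        # 10 matching columns over an 11-column alignment
        assert pairwise_identity("AAAAAAAAAAK", "AAAAAAAAAAR") == pytest.approx(10 / 11)

    @pytest.mark.parametrize(
        "threshold, expected_n", [(0.90, 1), (0.95, 2)]
    )
    def test_threshold_boundary(self, threshold, expected_n):
        ds = make_dataset(
            [("a", "AAAAAAAAAAK", "ACP"), ("b", "AAAAAAAAAAR", "ACP")]
        )
        assert len(greedy_cluster_identity(ds, threshold)) == expected_n

    def test_identical_sequences_collapse(self):
        ds = make_dataset([("a", "KLWKKWAKKWLK", "ACP"), ("b", "KLWKKWAKKWLK", "nonACP")])
        # same sequence but different classes: clustering is per class
        assert len(greedy_cluster_identity(ds, 0.9)) == 2

    def test_monotone_in_threshold(self, rng, random_sequences):
        ds = make_dataset(
            [(f"s{i}", s, "ACP") for i, s in enumerate(random_sequences[:30])]
        )
        sizes = [len(greedy_cluster_identity(ds, t)) for t in (1.0, 0.8, 0.6, 0.4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_threshold(self):
        ds = make_dataset([("a", "KKKKKKKKKKK", "ACP")])
        with pytest.raises(ValueError):
            greedy_cluster_identity(ds, 0.0)


class TestSampling:
    def _pools(self):
        pos = make_dataset([(f"p{i}", "K" * (11 + i % 3), "ACP") for i in range(10)])
        neg = make_dataset([(f"n{i}", "G" * (11 + i % 5), "nonACP") for i in range(30)])
        return pos, neg

    def test_ratio_counts(self):
        pos, neg = self._pools()
        out = sample_negatives(pos, neg, ratio=2.0, seed=1)
        assert len(out) == 30
        assert (out["label"] == "nonACP").sum() == 20

    def test_ratio_zero_returns_positives(self):
        pos, neg = self._pools()
        assert len(sample_negatives(pos, neg, ratio=0.0, seed=1)) == len(pos)

    def test_deterministic(self):
        pos, neg = self._pools()
        a = sample_negatives(pos, neg, ratio=1.5, seed=7)
        b = sample_negatives(pos, neg, ratio=1.5, seed=7)
        assert a.equals(b)

    def test_insufficient_pool(self):
        pos, neg = self._pools()
        with pytest.raises(ValueError, match="required"):
            sample_negatives(pos, neg, ratio=4.0, seed=1)


class TestSplit:
    def _ds(self, n_pos=50, n_neg=100):
        rows = [(f"p{i}", "K" * (11 + i % 7), "ACP") for i in range(n_pos)]
        rows += [(f"n{i}", "G" * (11 + i % 7), "nonACP") for i in range(n_neg)]
        return make_dataset(rows)

    def test_partition_and_stratification(self):
        ds = self._ds()
        train, test = split_train_test(ds, 0.2, seed=0)
        assert len(train) + len(test) == len(ds)
        assert set(train["id"]).isdisjoint(test["id"])
        assert set(train["id"]) | set(test["id"]) == set(ds["id"])
        # per-class proportions within one record of the 20 % target
        assert abs((test["label"] == "ACP").sum() - 10) <= 1
        assert abs((test["label"] == "nonACP").sum() - 20) <= 1

    def test_deterministic(self):
        ds = self._ds()
        t1 = split_train_test(ds, 0.25, seed=3)
        t2 = split_train_test(ds, 0.25, seed=3)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_bad_fraction(self, frac):
        with pytest.raises(ValueError):
            split_train_test(self._ds(), frac, seed=0)

    def test_degenerate_class(self):
        ds = make_dataset([("a", "KKKKKKKKKKK", "ACP")])
        with pytest.raises(ValueError):
            split_train_test(ds, 0.5, seed=0)
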