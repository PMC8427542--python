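import numpy as np
import pytest

from phagelift.model import CNNFragmentClassifier
from phagelift.network import NetworkConfig, initialize_weights
from phagelift.predict import (
    CutoffPolicy,
    classify,
    combine_scores,
    predict_file,
    predict_records,
    route_and_score,
    split_long_sequence,
)
from phagelift.seqio import NucleotideSequence, read_prediction_report, write_fasta
from phagelift.simulate import GROUPS


def _random_seq(n, seed=0, name="s"):
    rng = np.random.default_rng(seed)
    return NucleotideSequence(name, "".join(rng.choice(list("ACGT"), n)))


@pytest.fixture(scope="module")
def untrained_models():
    """Per-group models with random (untrained) weights: routing and report
    mechanics do not depend on training."""
    models = {}
    for name, group in GROUPS.items():
        config = NetworkConfig(L=group.model_input_length, F=4, M=6, R=4)
        w = initialize_weights(config, np.random.default_rng(hash(name) % 2**31))
        models[name] = CNNFragmentClassifier.from_weights(w, config)
    return models


class TestSplitLongSequence:
    def test_4000bp_split(self):
        pieces = split_long_sequence(_random_seq(4000))
        assert [p.length for p in pieces] == [1800, 1800, 400]

    def test_exact_multiple(self):
        pieces = split_long_sequence(_random_seq(3600))
        assert [p.length for p in pieces] == [1800, 1800]

    def test_boundary_remainder(self):
        pieces = split_long_sequence(_random_seq(1801))
        assert [p.length for p in pieces] == [1800, 1]

    def test_concatenation_identity(self):
        seq = _random_seq(5431)
        pieces = split_long_sequence(seq)
        assert "".join(p.bases for p in pieces) == seq.bases

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            split_long_sequence(_random_seq(1800))


class TestCombineScores:
    def test_worked_arithmetic(self):
        assert combine_scores([(1800, 0.8), (1800, 0.8), (400, 0.2)]) == pytest.approx(0.74)

    def test_constant_scores(self):
        assert combine_scores([(100, 0.3), (1700, 0.3)]) == pytest.approx(0.3)

    def test_single_piece_identity(self):
        assert combine_scores([(1234, 0.61)]) == 0.61

    def test_bounded_by_piece_scores(self):
        rng = np.random.default_rng(1)
        pieces = [(int(l), float(s)) for l, s in
                  zip(rng.integers(1, 1800, 10), rng.random(10))]
        s = combine_scores(pieces)
        assert min(p[1] for p in pieces) <= s <= max(p[1] for p in pieces)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_scores([])


class TestClassify:
    @pytest.mark.parametrize(
        "score,t,expected",
        [
            (0.9, 0.0, "virulent"),
            (0.2, 0.0, "temperate"),
            (0.6, 0.5, "uncertain"),   # inside the (0.25, 0.75) band
            (0.2, 0.5, "temperate"),
            (0.76, 0.5, "virulent"),
            (0.5, 0.0, "uncertain"),   # exact tie is never silently coerced
        ],
    )
    def test_band_rules(self, score, t, expected):
        assert classify(score, CutoffPolicy(t)) == expected

    def test_monotone_in_score(self):
        order = {"temperate": 0, "uncertain": 1, "virulent": 2}
        for t in (0.0, 0.3, 0.8):
            labels = [classify(s, CutoffPolicy(t)) for s in np.linspace(0, 1, 101)]
            ranks = [order[l] for l in labels]
            assert ranks == sorted(ranks)

    def test_raising_t_never_decreases_uncertain(self):
        scores = np.random.default_rng(2).random(200)
        counts = []
        for t in (0.0, 0.2, 0.5, 0.9):
            counts.append(sum(classify(s, CutoffPolicy(t)) == "uncertain" for s in scores))
        assert counts == sorted(counts)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify(1.2)
        with pytest.raises(ValueError):
            CutoffPolicy(1.0)


class TestRouting:
    def test_in_range_uses_own_group(self, untrained_models):
        seq = _random_seq(250, seed=3)
        expected = untrained_models["A"].decision_function([seq.bases])[0]
        assert route_and_score(seq, untrained_models) == pytest.approx(expected)

    def test_short_sequence_falls_back_to_group_a(self, untrained_models):
        seq = _random_seq(60, seed=4)
        expected = untrained_models["A"].decision_function([seq.bases])[0]
        assert route_and_score(seq, untrained_models) == pytest.approx(expected)

    def test_long_sequence_is_length_weighted_combination(self, untrained_models):
        seq = _random_seq(5000, seed=5)
        pieces = split_long_sequence(seq)
        assert [p.length for p in pieces] == [1800, 1800, 1400]
        piece_scores = [
            float(untrained_models["D"].decision_function([p.bases])[0]) for p in pieces
        ]
        expected = combine_scores([(p.length, s) for p, s in zip(pieces, piece_scores)])
        assert route_and_score(seq, untrained_models) == pytest.approx(expected)

    def test_deterministic(self, untrained_models):
        seq = _random_seq(777, seed=6)
        assert route_and_score(seq, untrained_models) == route_and_score(seq, untrained_models)

    def test_missing_group_errors_with_name(self, untrained_models):
        partial = {k: v for k, v in untrained_models.items() if k != "C"}
        with pytest.raises(KeyError, match="C"):
            route_and_score(_random_seq(1000, seed=7), partial)


class TestPredictFile:
    def test_report_cardinality_order_and_partition(self, tmp_path, untrained_models):
        seqs = [_random_seq(n, seed=n, name=f"s{i}") for i, n in
                enumerate([150, 700, 2500])]
        fasta = tmp_path / "in.fasta"
        write_fasta(seqs, fasta)
        out = tmp_path / "out.tsv"
        summary = predict_file(fasta, untrained_models, CutoffPolicy(0.0), out)
        records = read_prediction_report(out)
        assert [r.id for r in records] == ["s0", "s1", "s2"]
        assert summary["total"] == 3
        assert summary["virulent"] + summary["temperate"] + summary["uncertain"] == 3

    def test_empty_fasta(self, tmp_path, untrained_models):
        fasta = tmp_path / "in.fasta"
        fasta.write_text("")
        out = tmp_path / "out.tsv"
        summary = predict_file(fasta, untrained_models, CutoffPolicy(0.0), out)
        assert summary == {"virulent": 0, "temperate": 0, "uncertain": 0, "total": 0}
        assert read_prediction_report(out) == []

    def test_batched_scores_match_single_routing(self, untrained_models):
        seqs = [_random_seq(n, seed=n + 50, name=f"q{n}") for n in
                [90, 250, 450, 1500, 2000]]
        records = predict_records(seqs, untrained_models)
        for seq, rec in zip(seqs, records):
            assert rec.score == pytest.approx(route_and_score(seq, untrained_models), abs=1e-6)


class TestCli:
    def test_predict_command_end_to_end(self, tmp_path, untrained_models):
        from click.testing import CliRunner

        from phagelift.cli import main
        from phagelift.training import save_manifest

        manifest = save_manifest(untrained_models, tmp_path / "models")
        fasta = tmp_path / "in.fasta"
        write_fasta([_random_seq(300, seed=9, name="c1")], fasta)
        out = tmp_path / "report.tsv"
        runner = CliRunner()
        result = runner.invoke(main, [
            "predict", "--in", str(fasta), "--out", str(out),
            "--models", str(manifest), "--cutoff", "0.5",
        ])
        assert result.exit_code == 0, result.output
        records = read_prediction_report(out)
        assert len(records) == 1 and records[0].id == "c1"

    def test_predict_missing_input_fails(self, tmp_path):
        from click.testing import CliRunner

        from phagelift.cli import main

        runner = CliRunner()
        result = runner.invoke(main, [
            "predict", "--in", str(tmp_path / "nope.fasta"),
            "--out", str(tmp_path / "o.tsv"), "--models", str(tmp_path),
        ])
        assert result.exit_code != 0
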