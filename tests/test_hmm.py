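import math

import numpy as np
import pytest

from _oracles import brute_forward, brute_viterbi, random_sequence, random_toy_hmm
from aureomine.hmm import (
    BACKGROUND,
    AA_INDEX,
    HMMError,
    NullCalibration,
    ProfileHMM,
    build_hmm,
    calibrate_null,
    evalue,
    fit_gumbel_moments,
    fit_gumbel_tail,
    forward_score,
    forward_scores,
    iterative_search,
    path_to_match_row,
    read_hmm,
    viterbi_align,
    write_hmm,
)
from aureomine.seqio import SeqRecord
from aureomine.synthetic import SimConfig, generate_dataset


class TestBuildHMM:
    def test_two_identical_rows(self):
        """Ungapped identical rows give M = 3 and the count-plus-
        pseudocount emission (2 + w*bg) / (2 + w) for the observed letter."""
        hmm = build_hmm([("a", "MKW"), ("b", "MKW")], pseudocount_weight=1.0)
        assert hmm.model_length == 3
        for k, ch in enumerate("MKW"):
            expected = (2 + BACKGROUND[AA_INDEX[ch]]) / 3.0
            assert hmm.match_emissions[k, AA_INDEX[ch]] == pytest.approx(expected)

    def test_all_gap_column_is_insert(self):
        hmm = build_hmm([("a", "M-W"), ("b", "M-W")])
        assert hmm.model_length == 2

    def test_half_gap_column_is_insert_strict_rule(self):
        """Gap fraction exactly at the 0.5 threshold fails the strict-less
        match rule, so the column becomes an insert state."""
        rows = [("a", "MKW"), ("b", "M-W"), ("c", "MAW"), ("d", "M-W")]
        hmm = build_hmm(rows, occupancy_threshold=0.5)
        assert hmm.model_length == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(HMMError, match="ragged"):
            build_hmm([("a", "MKW"), ("b", "MK")])

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(HMMError, match="zero match columns"):
            build_hmm([("a", "--"), ("b", "--")])

    def test_normalization_preserved(self, two_family_records):
        fam_a, _ = two_family_records
        rows = [(r.id, r.sequence) for r in fam_a]  # equal-length seeds
        hmm = build_hmm(rows)
        hmm.validate()  # raises on any unnormalized bundle


class TestScoring:
    def test_single_w_emitter(self):
        """M=1 model strongly emitting W scores ~log2(e_W/bg_W) on 'W'
        minus the begin->M and M->end transition costs."""
        em = np.full((1, 20), 1e-9)
        em[0, AA_INDEX["W"]] = 1 - 19e-9
        ie = np.tile(BACKGROUND, (2, 1))
        trans = np.zeros((2, 7))
        trans[0] = [0.9, 0.05, 0.05, 0.5, 0.5, 1.0, 0.0]
        trans[1] = [0.9, 0.1, 0.0, 0.5, 0.5, 1.0, 0.0]
        hmm = ProfileHMM(em, ie, trans, BACKGROUND.copy())
        got = forward_score(hmm, "W")
        assert got == pytest.approx(brute_forward(hmm, "W"), abs=1e-9)
        direct = math.log2(1.0 / BACKGROUND[AA_INDEX["W"]]) + math.log2(0.9) + math.log2(0.9)
        assert got >= direct - 1e-6  # forward also sums the minor paths

    def test_forward_and_viterbi_match_enumeration(self, rng):
        """Forward and Viterbi equal the all-paths oracle on toy models
        (M <= 3, |seq| <= 4) to 1e-9 in log space."""
        for _ in range(100):
            hmm = random_toy_hmm(rng)
            seq = random_sequence(rng, int(rng.integers(1, 5)))
            f = forward_score(hmm, seq)
            v, _path = viterbi_align(hmm, seq)
            assert f == pytest.approx(brute_forward(hmm, seq), abs=1e-9)
            assert v == pytest.approx(brute_viterbi(hmm, seq), abs=1e-9)
            assert v <= f + 1e-9

    def test_batch_scores_match_single(self, rng):
        hmm = random_toy_hmm(rng)
        seqs = [random_sequence(rng, int(rng.integers(1, 6))) for _ in range(20)]
        batch = forward_scores(hmm, seqs)
        for s, expected in zip(seqs, batch):
            assert forward_score(hmm, s) == pytest.approx(expected, abs=1e-9)

    def test_x_scores_as_background(self):
        """X emits with background probability in model and null, so
        replacing a residue by X shifts the score toward zero odds."""
        hmm = build_hmm([("a", "MKW"), ("b", "MKW")])
        assert forward_score(hmm, "XXX") == pytest.approx(
            brute_forward(hmm, "XXX"), abs=1e-9
        )

    def test_viterbi_deterministic_path_on_tied_model(self):
        """With uniform emissions every path through an M=1 model scores
        the same; the documented M < D < I priority picks match."""
        em = np.tile(BACKGROUND, (1, 1))
        ie = np.tile(BACKGROUND, (2, 1))
        trans = np.zeros((2, 7))
        trans[0] = [1 / 3, 1 / 3, 1 / 3, 0.5, 0.5, 1.0, 0.0]
        trans[1] = [0.5, 0.5, 0.0, 0.5, 0.5, 1.0, 0.0]
        hmm = ProfileHMM(em, ie, trans, BACKGROUND.copy())
        _, path = viterbi_align(hmm, "A")
        assert path == ["M1"]

    def test_match_row_projection(self):
        hmm = build_hmm([("a", "MKW"), ("b", "MKW")])
        _, path = viterbi_align(hmm, "MW")
        row = path_to_match_row(hmm, "MW", path)
        assert len(row) == 3 and row.replace("-", "") in {"MW", "M", "W"}


class TestCalibration:
    def test_zero_variance_rejected(self):
        with pytest.raises(HMMError, match="variance"):
            fit_gumbel_moments(np.full(500, 1.25))

    def test_moments_recover_gumbel_parameters(self, rng):
        """On a genuine Gumbel(mu=2, lambda=0.7) sample the moments
        estimator recovers both parameters."""
        sample = rng.gumbel(loc=2.0, scale=1 / 0.7, size=5000)
        mu, lam = fit_gumbel_moments(sample)
        assert mu == pytest.approx(2.0, abs=0.1)
        assert lam == pytest.approx(0.7, abs=0.05)

    def test_tail_fit_recovers_gumbel_tail(self, rng):
        sample = rng.gumbel(loc=2.0, scale=1 / 0.7, size=20000)
        mu, lam = fit_gumbel_tail(sample)
        # tail fit targets the survival function, so compare quantiles
        q_fit = mu + math.log(1e4) / lam
        q_true = 2.0 + math.log(1e4) / 0.7
        assert q_fit == pytest.approx(q_true, rel=0.1)

    def test_calibration_stability_in_n(self, rng):
        ds = generate_dataset(SimConfig(rng_seed=5, n_decoys=0, n_families=0,
                                        family_distances=()))
        model = build_hmm(ds.seed_msa)
        cal1 = calibrate_null(model, BACKGROUND, 800, 50, np.random.default_rng(1))
        cal2 = calibrate_null(model, BACKGROUND, 1600, 50, np.random.default_rng(2))
        assert cal1.gumbel_lambda == pytest.approx(cal2.gumbel_lambda, rel=0.5)
        assert cal1.gumbel_mu == pytest.approx(cal2.gumbel_mu, abs=5.0)

    def test_evalue_closed_forms(self):
        cal = NullCalibration(gumbel_mu=3.0, gumbel_lambda=0.8, n_null=100)
        # score far below mu: tail probability 1, E = db_size
        assert evalue(cal, -1e5, 5000) == pytest.approx(5000)
        # at the location parameter the tail is 1 - exp(-1)
        assert evalue(cal, 3.0, 1000) == pytest.approx(1000 * (1 - math.exp(-1)))
        # monotone decreasing in score
        assert evalue(cal, 4.0, 1000) < evalue(cal, 3.0, 1000)


class TestIterativeSearch:
    def test_strict_length_filter(self, rng):
        """A planted homolog padded to exactly 100 residues is never
        reported: the filter keeps proteins strictly under 100."""
        ds = generate_dataset(SimConfig(rng_seed=8, members_per_family=5,
                                        n_decoys=100))
        long_member = ds.records[0]
        padded = SeqRecord(
            id="padded100",
            sequence=(long_member.sequence * 2)[:100],
        )
        assert len(padded.sequence) == 100
        db = ds.records + [padded]
        hits = iterative_search(ds.seed_msa, db, calibration_n=300,
                                rng=np.random.default_rng(0))
        assert "padded100" not in {h.sequence_id for h in hits}

    def test_empty_filtered_database_warns(self):
        msa = [("a", "MKW"), ("b", "MKW")]
        db = [SeqRecord(id="big", sequence="A" * 150)]
        with pytest.warns(RuntimeWarning, match="length filter"):
            assert iterative_search(msa, db) == []

    def test_empty_seed_rejected(self):
        with pytest.raises(HMMError, match="seed"):
            iterative_search([], [SeqRecord(id="s", sequence="MKW")])

    def test_round2_superset_with_distant_family(self):
        """A family at substitution distance 0.5 is largely invisible to
        the seed model but becomes reachable once round-1 hits expand
        the alignment: round-2 hits contain round-1 hits."""
        ds = generate_dataset(
            SimConfig(rng_seed=12, n_families=2, family_distances=(0.1, 0.5),
                      members_per_family=8, n_decoys=500)
        )
        h1 = iterative_search(ds.seed_msa, ds.records, n_iterations=1,
                              calibration_n=500, rng=np.random.default_rng(6))
        h2 = iterative_search(ds.seed_msa, ds.records, n_iterations=2,
                              calibration_n=500, rng=np.random.default_rng(6))
        ids1, ids2 = {h.sequence_id for h in h1}, {h.sequence_id for h in h2}
        assert ids1 <= ids2
        far = {p.id for p in ds.truth.planted if p.family == 1}
        assert len(ids2 & far) >= len(ids1 & far)
        assert all(h.iteration == 1 for h in h1)

    def test_hit_invariants(self):
        ds = generate_dataset(SimConfig(rng_seed=3, members_per_family=5,
                                        n_decoys=200))
        hits = iterative_search(ds.seed_msa, ds.records, calibration_n=500,
                                rng=np.random.default_rng(1))
        ids = [h.sequence_id for h in hits]
        assert len(ids) == len(set(ids))  # deduplicated
        assert all(h.e_value >= 0 and h.iteration in (1, 2) for h in hits)


class TestSerialization:
    def test_roundtrip_preserves_scores(self, rng, tmp_path):
        hmm = random_toy_hmm(rng)
        path = tmp_path / "model.ahmm"
        write_hmm(hmm, path)
        loaded = read_hmm(path)
        seq = random_sequence(rng, 4)
        assert forward_score(loaded, seq) == pytest.approx(
            forward_score(hmm, seq), abs=1e-12
        )

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.ahmm"
        p.write_text("#something-else/9\n")
        with pytest.raises(HMMError, match="format"):
            read_hmm(p)
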