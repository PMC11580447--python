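import pytest

from aureomine.seqio import SeqRecord
from aureomine.synthetic import (
    DEFAULT_SEED,
    SimConfig,
    SyntheticError,
    generate_dataset,
    generate_protein_db,
    generate_synthetic_bgc,
    mutate_peptide,
    sample_decoy,
    write_dataset,
)


def hamming_diff(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


class TestMutatePeptide:
    def test_fraction_zero_identity(self, rng):
        rec, n = mutate_peptide(DEFAULT_SEED, 0.0, rng)
        assert rec.sequence == DEFAULT_SEED.sequence and n == 0

    def test_fraction_one_all_substituted(self, rng):
        seed = SeqRecord(id="s", sequence="MKAGLVIWTP")
        rec, n = mutate_peptide(seed, 1.0, rng)
        assert n == 10
        assert hamming_diff(rec.sequence, seed.sequence) == 10

    def test_exact_substitution_count_by_recount(self, rng):
        """fraction 0.2 on a 50-residue seed gives exactly 10 Hamming
        differences, verified by independent character comparison."""
        seed = SeqRecord(id="s", sequence=DEFAULT_SEED.sequence[:50])
        rec, n = mutate_peptide(seed, 0.2, rng)
        assert n == 10
        assert hamming_diff(rec.sequence, seed.sequence) == 10

    def test_at_most_one_tryptophan_lost(self, rng):
        n_w_seed = DEFAULT_SEED.sequence.count("W")
        for _ in range(50):
            rec, _ = mutate_peptide(DEFAULT_SEED, 0.3, rng)
            lost = sum(
                1
                for s, m in zip(DEFAULT_SEED.sequence, rec.sequence)
                if s == "W" and m != "W"
            )
            assert lost <= 1
            assert rec.sequence.count("W") >= n_w_seed - 1

    def test_fraction_out_of_range(self, rng):
        with pytest.raises(SyntheticError):
            mutate_peptide(DEFAULT_SEED, 1.5, rng)


class TestGenerateProteinDb:
    def test_counts_and_partition(self):
        cfg = SimConfig(n_families=2, family_distances=(0.1, 0.6),
                        members_per_family=3, n_decoys=5, rng_seed=4)
        records, truth = generate_protein_db(cfg)
        assert len(records) == 11
        assert len(truth.planted) == 6 and len(truth.decoy_ids) == 5
        all_ids = {r.id for r in records}
        assert set(truth.planted_ids) | set(truth.decoy_ids) == all_ids
        assert not set(truth.planted_ids) & set(truth.decoy_ids)
        assert set(truth.taxonomy) == all_ids

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(rng_seed=9, members_per_family=4, n_decoys=20)
        d1 = write_dataset(generate_dataset(cfg), tmp_path / "a")
        d2 = write_dataset(generate_dataset(cfg), tmp_path / "b")
        for key in d1:
            assert d1[key].read_bytes() == d2[key].read_bytes(), key

    def test_family_distance_ordering(self):
        """Members of the closer family have higher Hamming identity to
        the seed than members of the farther family."""
        cfg = SimConfig(n_families=2, family_distances=(0.1, 0.6),
                        members_per_family=5, n_decoys=0, rng_seed=2)
        records, truth = generate_protein_db(cfg)
        by_id = {r.id: r for r in records}
        idents = {0: [], 1: []}
        for p in truth.planted:
            seq = by_id[p.id].sequence
            ident = 1 - hamming_diff(seq, DEFAULT_SEED.sequence) / len(seq)
            assert ident == pytest.approx(p.identity_to_seed)
            idents[p.family].append(ident)
        assert min(idents[0]) > max(idents[1])

    def test_decoy_length_filter_exercised(self):
        cfg = SimConfig(rng_seed=1, n_decoys=30, decoy_length_range=(40, 120))
        records, truth = generate_protein_db(cfg)
        decoy_lens = [len(r.sequence) for r in records if r.id in set(truth.decoy_ids)]
        assert any(l >= 100 for l in decoy_lens)
        assert any(l < 100 for l in decoy_lens)

    def test_phyla_alternate(self):
        cfg = SimConfig(n_families=2, family_distances=(0.1, 0.3),
                        members_per_family=2, n_decoys=0, rng_seed=0)
        _, truth = generate_protein_db(cfg)
        phyla = {truth.taxonomy[p.id].phylum for p in truth.planted}
        assert phyla == {"Actinomycetota", "Bacillota"}

    def test_config_validation(self):
        with pytest.raises(SyntheticError):
            SimConfig(n_families=1, family_distances=(0.1, 0.2))
        with pytest.raises(SyntheticError):
            SimConfig(family_distances=(0.1, 1.2))
        with pytest.raises(SyntheticError):
            SimConfig(operon_layouts=("spiral",))


class TestSyntheticBgc:
    def test_single_layout(self, rng):
        contig = generate_synthetic_bgc("single", DEFAULT_SEED, rng)
        assert len(contig.core_gene_ids) == 1
        core = [f for f in contig.features if f.gene_id in contig.core_gene_ids]
        assert all("core peptide" in f.product for f in core)

    def test_multi8_layout(self, rng):
        contig = generate_synthetic_bgc("multi_8", DEFAULT_SEED, rng)
        assert len(contig.core_gene_ids) == 8
        cores = [f for f in contig.features if f.gene_id in contig.core_gene_ids]
        span = max(f.end for f in cores) - min(f.start for f in cores)
        assert span < 5000  # tandem copies within one operon window

    def test_contig_edge_layout(self, rng):
        contig = generate_synthetic_bgc("contig_edge", DEFAULT_SEED, rng)
        core = [f for f in contig.features if f.gene_id in contig.core_gene_ids][0]
        assert contig.length - core.end < 2000

    def test_opposite_strand_layout(self, rng):
        contig = generate_synthetic_bgc("opposite_strand", DEFAULT_SEED, rng)
        core = [f for f in contig.features if f.gene_id in contig.core_gene_ids][0]
        machinery = [
            f for f in contig.features
            if "ABC" in f.product or "regulator" in f.product
        ]
        assert machinery and all(f.strand != core.strand for f in machinery)

    def test_unknown_layout_rejected(self, rng):
        with pytest.raises(SyntheticError):
            generate_synthetic_bgc("spiral", DEFAULT_SEED, rng)


class TestDecoys:
    def test_decoy_length_and_alphabet(self, rng):
        rec = sample_decoy(75, rng, decoy_id="d")
        assert len(rec.sequence) == 75
        assert set(rec.sequence) <= set("ACDEFGHIKLMNPQRSTVWY")
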