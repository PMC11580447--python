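import numpy as np
import pytest

from aureomine.cluster_network import (
    IdentityMatrix,
    NetworkError,
    build_ssn,
    greedy_cluster,
    identity_matrix,
    write_clusters,
    write_edge_list,
    write_node_attributes,
)
from aureomine.align import pairwise_pid
from aureomine.seqio import SeqRecord


class TestIdentityMatrix:
    def test_single_record(self):
        m = identity_matrix([SeqRecord(id="a", sequence="MKW")])
        assert m.values.tolist() == [[100.0]]

    def test_identical_pair(self):
        m = identity_matrix(
            [SeqRecord(id="a", sequence="MKWL"), SeqRecord(id="b", sequence="MKWL")]
        )
        assert m.values[0, 1] == 100.0

    def test_symmetry_on_synthetic_peptides(self, two_family_records):
        fam_a, fam_b = two_family_records
        m = identity_matrix(fam_a + fam_b)
        assert np.array_equal(m.values, m.values.T)
        assert (np.diag(m.values) == 100.0).all()

    def test_invalid_matrix_rejected(self):
        with pytest.raises(NetworkError, match="diagonal"):
            IdentityMatrix(ids=["a"], values=np.array([[99.0]]))


class TestSSN:
    def _matrix(self, pids):
        ids = sorted({x for pair in pids for x in pair})
        n = len(ids)
        v = np.full((n, n), 100.0)
        for (a, b), pid in pids.items():
            i, j = ids.index(a), ids.index(b)
            v[i, j] = v[j, i] = pid
        return IdentityMatrix(ids=ids, values=v)

    def test_threshold_splits_components(self):
        m = self._matrix({("a", "b"): 90, ("a", "c"): 10, ("b", "c"): 10})
        ssn = build_ssn(m, 64.29)
        assert ssn.components == [["a", "b"], ["c"]]
        assert ssn.singletons == ["c"]

    def test_all_below_threshold_all_singletons(self):
        m = self._matrix({("a", "b"): 10, ("a", "c"): 20, ("b", "c"): 30})
        ssn = build_ssn(m, 64.29)
        assert ssn.n_components == 3
        assert len(ssn.singletons) == 3

    def test_edge_strictly_greater_than_threshold(self):
        m = self._matrix({("a", "b"): 64.29})
        ssn = build_ssn(m, 64.29)
        assert ssn.singletons == ["a", "b"]  # equality does not connect

    def test_two_planted_families_two_components(self, two_family_records):
        """Families ~90% identical within, ~30% between, split into
        exactly two components at the 64.29% edge threshold."""
        fam_a, fam_b = two_family_records
        ssn = build_ssn(identity_matrix(fam_a + fam_b), 64.29)
        assert ssn.n_components == 2
        comps = {frozenset(c) for c in ssn.components}
        assert comps == {
            frozenset(r.id for r in fam_a),
            frozenset(r.id for r in fam_b),
        }

    def test_components_invariant_under_reordering(self, two_family_records):
        fam_a, fam_b = two_family_records
        records = fam_a + fam_b
        ssn1 = build_ssn(identity_matrix(records), 64.29)
        ssn2 = build_ssn(identity_matrix(records[::-1]), 64.29)
        assert {frozenset(c) for c in ssn1.components} == {
            frozenset(c) for c in ssn2.components
        }

    def test_exports(self, tmp_path, two_family_records):
        fam_a, fam_b = two_family_records
        phylum = {r.id: "Actinomycetota" for r in fam_a + fam_b}
        ssn = build_ssn(identity_matrix(fam_a + fam_b), 64.29, phylum)
        write_edge_list(ssn, tmp_path / "edges.tsv")
        write_node_attributes(ssn, tmp_path / "nodes.tsv")
        edges = (tmp_path / "edges.tsv").read_text().splitlines()
        assert edges[0] == "source\ttarget\tpid"
        nodes = (tmp_path / "nodes.tsv").read_text().splitlines()
        assert len(nodes) == len(fam_a) + len(fam_b) + 1


class TestGreedyCluster:
    def test_identical_duplicates_one_cluster(self):
        recs = [SeqRecord(id="a", sequence="MKWLA"), SeqRecord(id="b", sequence="MKWLA")]
        cs = greedy_cluster(recs, 0.9)
        assert len(cs.clusters) == 1
        assert set(cs.clusters[0].members) == {"a", "b"}

    def test_distant_pair_two_singletons(self):
        recs = [
            SeqRecord(id="a", sequence="MKWLAGIVTP"),
            SeqRecord(id="b", sequence="CDEFHNQRSY"),
        ]
        cs = greedy_cluster(recs, 0.9)
        assert len(cs.clusters) == 2

    def test_idempotent_on_representatives(self, two_family_records):
        fam_a, fam_b = two_family_records
        records = fam_a + fam_b
        cs = greedy_cluster(records, 0.9)
        by_id = {r.id: r for r in records}
        reps = [by_id[r] for r in cs.representative_ids()]
        cs2 = greedy_cluster(reps, 0.9)
        assert cs2.representative_ids() == cs.representative_ids()

    def test_coverage_and_partition(self, two_family_records):
        fam_a, fam_b = two_family_records
        records = fam_a + fam_b
        cs = greedy_cluster(records, 0.80)
        by_id = {r.id: r for r in records}
        seen = [m for c in cs.clusters for m in c.members]
        assert sorted(seen) == sorted(by_id)  # exact partition
        for c in cs.clusters:
            rep = by_id[c.representative]
            for m in c.members:
                assert pairwise_pid(rep, by_id[m]) / 100.0 >= 0.80

    def test_representatives_longest_first(self, rng):
        recs = [
            SeqRecord(id="short", sequence="MKW"),
            SeqRecord(id="long", sequence="CDEFHNQRSYCDEFHNQRSY"),
        ]
        cs = greedy_cluster(recs, 0.9)
        assert cs.clusters[0].representative == "long"

    def test_export(self, tmp_path):
        recs = [SeqRecord(id="a", sequence="MKWLA"), SeqRecord(id="b", sequence="MKWLA")]
        cs = greedy_cluster(recs, 0.9)
        write_clusters(cs, tmp_path / "clusters.tsv")
        lines = (tmp_path / "clusters.tsv").read_text().splitlines()
        assert lines[0] == "representative\tmember"
        assert len(lines) == 3
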