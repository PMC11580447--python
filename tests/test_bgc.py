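import numpy as np
import pytest

from aureomine.bgc import (
    BGCError,
    classify_gene_role,
    extract_bgc,
    find_bgcs,
    tabulate_bgcs,
    write_synteny_svg,
)
from aureomine.seqio import GeneFeature, TaxonomyRow
from aureomine.synthetic import DEFAULT_SEED, generate_synthetic_bgc


class TestRoleClassification:
    @pytest.mark.parametrize(
        "product,role",
        [
            ("ABC-type lipoprotein export system multi-drug efflux pump subunit "
             "AcrA (membrane fusion protein)", "transport"),
            ("PH domain-containing protein", "membrane"),
            ("bPH_2 domain-containing protein", "membrane"),
            ("LacI family transcriptional regulator", "regulator"),
            ("helix-turn-helix domain-containing protein", "regulator"),
            ("excinuclease ABC subunit B", "repair"),
            ("hypothetical protein", "hypothetical"),
            ("", "other"),
            ("DNA polymerase III", "other"),
            ("ABC transporter ATP-binding protein", "transport"),
        ],
    )
    def test_keyword_roles(self, product, role):
        assert classify_gene_role(product) == role

    def test_precedence_is_total(self):
        # text matching several role vocabularies resolves by precedence
        assert classify_gene_role(
            "PH domain protein with ABC transporter activity"
        ) == "transport"

    def test_custom_keywords(self):
        rules = {"transport": ["flippase"]}
        assert classify_gene_role("lipid flippase", rules) == "transport"
        assert classify_gene_role("hypothetical protein", rules) == "other"


def _simple_contig(core_strand="+"):
    return [
        GeneFeature("c1", 1000, 1900, "+", "g1", "hypothetical protein"),
        GeneFeature("c1", 2000, 2160, core_strand, "core1",
                    "aureocin A53 family leaderless bacteriocin core peptide"),
        GeneFeature("c1", 2300, 3200, "+", "g2", "ABC transporter ATP-binding protein"),
        GeneFeature("c1", 3300, 3900, "-", "g3", "transcriptional regulator"),
        GeneFeature("c1", 9000, 9600, "+", "g4", "hypothetical protein"),
    ]


class TestExtractBgc:
    def test_window_membership_and_flags(self):
        bgc = extract_bgc(_simple_contig(), ["core1"], window_bp=5000,
                          contig_length=20000)
        assert bgc.n_core == 1 and bgc.category == "single"
        assert {f.gene_id for f in bgc.features} == {"g1", "core1", "g2", "g3"}
        assert bgc.has_transport and bgc.has_regulator and not bgc.has_membrane
        assert bgc.opposite_strand_machinery  # regulator on '-', core on '+'
        assert bgc.window == (1, 7160)
        assert bgc.contig_edge  # left edge truncates the 5-kb window

    def test_core_absent_is_error(self):
        with pytest.raises(BGCError, match="nope"):
            extract_bgc(_simple_contig(), ["nope"])

    def test_window_never_exceeds_contig(self):
        bgc = extract_bgc(_simple_contig(), ["core1"], window_bp=5000,
                          contig_length=4000)
        assert bgc.window[1] == 4000 and bgc.contig_edge


class TestSyntheticLayouts:
    @pytest.mark.parametrize("layout,n_core,flag", [
        ("single", 1, None),
        ("multi_8", 8, None),
        ("contig_edge", 1, "contig_edge"),
        ("opposite_strand", 1, "opposite_strand_machinery"),
    ])
    def test_layout_recovery(self, layout, n_core, flag, rng):
        contig = generate_synthetic_bgc(layout, DEFAULT_SEED, rng)
        bgcs = find_bgcs(contig.features, contig.core_gene_ids, 5000,
                         {contig.contig_id: contig.length})
        assert len(bgcs) == 1
        bgc = bgcs[0]
        assert bgc.n_core == n_core
        assert bgc.category == ("multi" if n_core > 1 else "single")
        if flag:
            assert getattr(bgc, flag)
        if layout == "single":
            assert not bgc.contig_edge and not bgc.opposite_strand_machinery

    def test_distant_cores_split_into_two_bgcs(self):
        features = _simple_contig() + [
            GeneFeature("c1", 40000, 40160, "+", "core2",
                        "aureocin A53 family leaderless bacteriocin core peptide"),
        ]
        bgcs = find_bgcs(features, ["core1", "core2"], 5000, {"c1": 60000})
        assert len(bgcs) == 2
        assert all(b.category == "single" for b in bgcs)


class TestTabulation:
    def _mixed_bgcs(self, rng):
        out = []
        for i, layout in enumerate(["single", "single", "single", "multi_4"]):
            contig = generate_synthetic_bgc(layout, DEFAULT_SEED, rng,
                                            contig_id=f"c{i}")
            out.extend(find_bgcs(contig.features, contig.core_gene_ids, 5000,
                                 {contig.contig_id: contig.length}))
        return out

    def test_totals(self, rng):
        bgcs = self._mixed_bgcs(rng)
        table = tabulate_bgcs(bgcs)
        assert table["n_bgcs"].sum() == 4
        assert table["n_core_peptides"].sum() == 7
        assert table["n_single"].sum() == 3
        assert table["n_multi"].sum() == 1

    def test_counts_invariant_under_shuffling(self, rng):
        bgcs = self._mixed_bgcs(rng)
        t1 = tabulate_bgcs(bgcs)
        t2 = tabulate_bgcs(bgcs[::-1])
        assert t1.equals(t2)

    def test_empty_input(self):
        table = tabulate_bgcs([])
        assert len(table) == 0
        assert "n_core_peptides" in table.columns

    def test_taxonomy_grouping(self, rng):
        bgcs = self._mixed_bgcs(rng)
        taxonomy = {
            b.contig: TaxonomyRow(b.contig, "Bacillota", "GenusX", "GenusX sp")
            for b in bgcs
        }
        table = tabulate_bgcs(bgcs, taxonomy)
        assert len(table) == 1 and table.loc[0, "phylum"] == "Bacillota"


class TestSvg:
    def test_writes_wellformed_svg(self, rng, tmp_path):
        contig = generate_synthetic_bgc("single", DEFAULT_SEED, rng)
        (bgc,) = find_bgcs(contig.features, contig.core_gene_ids, 5000,
                           {contig.contig_id: contig.length})
        path = tmp_path / "sketch.svg"
        write_synteny_svg(bgc, path)
        text = path.read_text()
        assert text.startswith("<svg") and text.rstrip().endswith("</svg>")
        assert text.count("<polygon") == len(bgc.features)
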