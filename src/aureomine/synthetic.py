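"""Synthetic databases, operons and taxonomy with a ground-truth ledger.

The generator emulates the statistical structure the mining analysis
assumes, so the whole pipeline is testable without downloads:

* planted core-peptide families at controlled substitution distances
  from a short (~52 aa) cationic, tryptophan-rich seed peptide;
* decoy proteins drawn i.i.d. from a Dirichlet-overdispersed background
  composition (no homologous signal — a proper score null), with
  lengths that straddle the 100-residue cutoff so the length filter is
  exercised;
* operon layouts covering the observed archetypes: a single core gene
  with its transport/membrane/regulator neighborhood, tandem multi-core
  operons (up to eight copies), a cluster truncated at a contig edge,
  and transport machinery on the strand opposite the core gene;
* a taxonomy table alternating phyla between families so the
  phylum-contrast rank test always has two non-empty groups.

Everything is deterministic under a fixed ``rng_seed`` — the written
FASTA/GFF/TSV files are byte-identical across runs.

The default seed peptide is a designed synthetic sequence, not any real
bacteriocin: 52 residues, strongly cationic, with tryptophans at
positions 21 and 32 (echoing the conserved positions of the family)
plus a third at position 45.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .align import star_msa
from .hmm import AA_INDEX, ALPHABET, BACKGROUND
from .seqio import (
    GeneFeature,
    SeqRecord,
    TaxonomyRow,
    write_alignment_fasta,
    write_fasta,
    write_features,
    write_taxonomy,
)

#: Designed 52-aa cationic seed; W at 1-based positions 21, 32 and 45.
DEFAULT_SEED_SEQUENCE = (
    "MGKAIKGLAK" "GAVKRIAGLA" "W" "KAGIKVLQGA" "W" "GKVASLIKGA" "GKWLAKIAGK"
)
assert len(DEFAULT_SEED_SEQUENCE) == 52
assert DEFAULT_SEED_SEQUENCE[20] == "W" and DEFAULT_SEED_SEQUENCE[31] == "W"

DEFAULT_SEED = SeqRecord(id="seed", sequence=DEFAULT_SEED_SEQUENCE,
                         description="synthetic cationic seed peptide")

CORE_PRODUCT = "aureocin A53 family leaderless bacteriocin core peptide"

VALID_LAYOUTS = ("single", "contig_edge", "opposite_strand") + tuple(
    f"multi_{k}" for k in range(2, 9)
)

#: Dirichlet concentration for per-decoy compositions; modest
#: overdispersion comparable to real short-protein compositional spread.
DECOY_DIRICHLET_CONCENTRATION = 50.0


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed_peptide: SeqRecord = DEFAULT_SEED
    n_families: int = 2
    family_distances: tuple[float, ...] = (0.1, 0.3)
    members_per_family: int = 10
    n_decoys: int = 200
    decoy_length_range: tuple[int, int] = (40, 120)
    rng_seed: int = 0
    operon_layouts: tuple[str, ...] = (
        "single",
        "multi_8",
        "contig_edge",
        "opposite_strand",
    )

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.members_per_family < 0 or self.n_decoys < 0:
            raise SyntheticError("counts must be nonnegative")
        if len(self.family_distances) != self.n_families:
            raise SyntheticError("need one substitution distance per family")
        if any(not 0.0 <= d <= 1.0 for d in self.family_distances):
            raise SyntheticError("family distances must lie in [0, 1]")
        lo, hi = self.decoy_length_range
        if lo < 1 or hi < lo:
            raise SyntheticError("invalid decoy length range")
        for layout in self.operon_layouts:
            if layout not in VALID_LAYOUTS:
                raise SyntheticError(f"unknown operon layout {layout!r}")


@dataclass(frozen=True)
class PlantedPeptide:
    id: str
    family: int
    n_substitutions: int
    identity_to_seed: float


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: exactly partitions the database ids."""

    planted: list[PlantedPeptide]
    decoy_ids: list[str]
    taxonomy: dict[str, TaxonomyRow]

    @property
    def planted_ids(self) -> list[str]:
        return [p.id for p in self.planted]


# ---------------------------------------------------------------------------
# Peptide mutation


def _substitution_background() -> np.ndarray:
    """Background with K/R enriched, preserving the family's cationic bias."""
    bg = BACKGROUND.copy()
    bg[AA_INDEX["K"]] += 0.10
    bg[AA_INDEX["R"]] += 0.10
    return bg / bg.sum()


_SUB_BG = _substitution_background()


def mutate_peptide(
    seed: SeqRecord,
    substitution_fraction: float,
    rng: np.random.Generator,
    new_id: str | None = None,
) -> tuple[SeqRecord, int]:
    """Substitute ``round(fraction * length)`` positions of the seed.

    Positions are chosen without replacement; at most one tryptophan
    position is selected whenever that leaves enough non-W positions to
    realize the requested count (the family's conserved tryptophans are
    what the profile model keys on).  Replacement residues are drawn
    from a K/R-enriched background and always differ from the original,
    so the realized Hamming identity to the seed is exactly
    ``1 - n_substitutions / length``.

    Returns the mutated record and the realized substitution count.
    """
    if not 0.0 <= substitution_fraction <= 1.0:
        raise SyntheticError("substitution_fraction must lie in [0, 1]")
    seq = list(seed.sequence)
    length = len(seq)
    n_sub = int(round(substitution_fraction * length))
    other_pos = [i for i, ch in enumerate(seq) if ch != "W"]
    sel = {int(p) for p in rng.permutation(length)[:n_sub]}
    # cap the selected W positions at one, unless the count forces more
    allowed_w = 1 if n_sub <= len(other_pos) + 1 else n_sub - len(other_pos)
    sel_w = sorted(p for p in sel if seq[p] == "W")
    if len(sel_w) > allowed_w:
        order = rng.permutation(len(sel_w))
        keep = {sel_w[int(i)] for i in order[:allowed_w]}
        drop = [p for p in sel_w if p not in keep]
        avail = [p for p in other_pos if p not in sel]
        repl = rng.choice(len(avail), size=len(drop), replace=False)
        for d, ri in zip(drop, repl):
            sel.remove(d)
            sel.add(avail[int(ri)])
    positions = sorted(sel)
    for pos in positions:
        original = seq[pos]
        while True:
            new = ALPHABET[rng.choice(20, p=_SUB_BG)]
            if new != original:
                break
        seq[pos] = new
    rec = SeqRecord(
        id=new_id or f"{seed.id}_mut",
        sequence="".join(seq),
        description=f"synthetic mutant, {n_sub} substitutions",
    )
    return rec, n_sub


# ---------------------------------------------------------------------------
# Decoys


def sample_decoy(
    length: int,
    rng: np.random.Generator,
    background: np.ndarray = BACKGROUND,
    concentration: float = DECOY_DIRICHLET_CONCENTRATION,
    decoy_id: str = "decoy",
) -> SeqRecord:
    """One i.i.d. decoy protein with its own Dirichlet-drawn composition."""
    alpha = concentration * (0.9 * background + 0.1 / 20.0)
    p = rng.dirichlet(alpha)
    idx = rng.choice(20, size=length, p=p)
    return SeqRecord(
        id=decoy_id,
        sequence="".join(ALPHABET[i] for i in idx),
        description="synthetic decoy protein",
    )


# ---------------------------------------------------------------------------
# Database generation


_PHYLA = ("Actinomycetota", "Bacillota")


def generate_protein_db(config: SimConfig) -> tuple[list[SeqRecord], SyntheticTruth]:
    """Planted families plus decoys, with a complete truth ledger.

    Families alternate phylum labels (Actinomycetota, Bacillota, ...);
    when the decoy length range straddles 100 at least one decoy of
    length >= 100 is guaranteed, so the length filter always has
    something to reject.
    """
    rng = np.random.default_rng(config.rng_seed)
    records: list[SeqRecord] = []
    planted: list[PlantedPeptide] = []
    taxonomy: dict[str, TaxonomyRow] = {}

    length = len(config.seed_peptide.sequence)
    for fam in range(config.n_families):
        distance = config.family_distances[fam]
        phylum = _PHYLA[fam % 2]
        genus = f"Synthogenus{fam}"
        for m in range(config.members_per_family):
            rec_id = f"fam{fam}_m{m}"
            rec, n_sub = mutate_peptide(
                config.seed_peptide, distance, rng, new_id=rec_id
            )
            records.append(rec)
            planted.append(
                PlantedPeptide(
                    id=rec_id,
                    family=fam,
                    n_substitutions=n_sub,
                    identity_to_seed=1.0 - n_sub / length,
                )
            )
            taxonomy[rec_id] = TaxonomyRow(
                rec_id, phylum, genus, f"{genus} sp{fam}"
            )

    lo, hi = config.decoy_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_decoys)
    if config.n_decoys and lo < 100 <= hi and not (lengths >= 100).any():
        lengths[-1] = hi
    decoy_ids: list[str] = []
    for i, dl in enumerate(lengths):
        rec_id = f"decoy{i}"
        records.append(sample_decoy(int(dl), rng, decoy_id=rec_id))
        decoy_ids.append(rec_id)
        taxonomy[rec_id] = TaxonomyRow(
            rec_id, _PHYLA[i % 2], "Decoygenus", "Decoygenus sp"
        )

    truth = SyntheticTruth(planted=planted, decoy_ids=decoy_ids, taxonomy=taxonomy)
    ids = [r.id for r in records]
    assert len(set(ids)) == len(ids)
    assert set(truth.planted_ids) | set(decoy_ids) == set(ids)
    return records, truth


# ---------------------------------------------------------------------------
# Operon layouts


@dataclass
class SyntheticContig:
    contig_id: str
    length: int
    features: list[GeneFeature]
    core_gene_ids: list[str]
    layout: str


_FLANK_BP = 6000  # padding so a +/-5 kb window is not truncated accidentally


def generate_synthetic_bgc(
    layout: str,
    core: SeqRecord,
    rng: np.random.Generator,
    contig_id: str = "contig1",
) -> SyntheticContig:
    """Emit the CDS features of one operon archetype.

    ``single`` places one core gene amid transport/membrane/regulator
    neighbors; ``multi_k`` plants k tandem core genes in one operon
    window; ``contig_edge`` ends the contig less than 2 kb after the
    core gene; ``opposite_strand`` puts the transporter and regulator on
    the minus strand with the core on plus.
    """
    if layout not in VALID_LAYOUTS:
        raise SyntheticError(f"unknown operon layout {layout!r}")
    core_nt = 3 * (len(core.sequence) + 1)

    def gap() -> int:
        return int(rng.integers(50, 201))

    def filler_len() -> int:
        return int(rng.integers(300, 901))

    plan: list[tuple[str, int, str]] = []  # (product, nt length, strand)
    n_core = 1
    if layout.startswith("multi_"):
        n_core = int(layout.split("_")[1])

    if layout == "contig_edge":
        plan = [
            ("hypothetical protein", filler_len(), "+"),
            ("ABC transporter ATP-binding protein", filler_len(), "+"),
            ("PH domain-containing protein", filler_len(), "+"),
            (CORE_PRODUCT, core_nt, "+"),
        ]
    elif layout == "opposite_strand":
        plan = [
            ("hypothetical protein", filler_len(), "+"),
            ("ABC transporter ATP-binding protein", filler_len(), "-"),
            ("transcriptional regulator", filler_len(), "-"),
            (CORE_PRODUCT, core_nt, "+"),
            ("hypothetical protein", filler_len(), "+"),
        ]
    else:  # single or multi_k
        plan = [("hypothetical protein", filler_len(), "+")]
        plan += [(CORE_PRODUCT, core_nt, "+")] * n_core
        plan += [
            ("ABC transporter ATP-binding protein", filler_len(), "+"),
            ("PH domain-containing protein", filler_len(), "+"),
            ("transcriptional regulator", filler_len(), "+"),
            ("hypothetical protein", filler_len(), "+"),
        ]

    features: list[GeneFeature] = []
    core_ids: list[str] = []
    pos = _FLANK_BP + 1
    for i, (product, nt_len, strand) in enumerate(plan):
        start = pos
        end = start + nt_len - 1
        gene_id = f"{contig_id}_g{i + 1}"
        features.append(
            GeneFeature(
                contig=contig_id,
                start=start,
                end=end,
                strand=strand,
                gene_id=gene_id,
                product=product,
            )
        )
        if product == CORE_PRODUCT:
            core_ids.append(gene_id)
        pos = end + 1 + gap()

    last_end = features[-1].end
    if layout == "contig_edge":
        # contig stops short: < 2 kb of sequence after the core gene
        contig_length = last_end + int(rng.integers(200, 1800))
    else:
        contig_length = last_end + _FLANK_BP
    return SyntheticContig(
        contig_id=contig_id,
        length=contig_length,
        features=features,
        core_gene_ids=core_ids,
        layout=layout,
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience


@dataclass
class SyntheticDataset:
    config: SimConfig
    records: list[SeqRecord]
    truth: SyntheticTruth
    contigs: list[SyntheticContig]
    seed_msa: list[tuple[str, str]]


def generate_dataset(config: SimConfig = SimConfig()) -> SyntheticDataset:
    """Database + truth + operon contigs + a seed alignment, all seeded.

    The seed alignment is the seed peptide plus four close mutants
    (8% substitution), star-aligned — the synthetic stand-in for a
    curated alignment of known family members.
    """
    records, truth = generate_protein_db(config)
    rng = np.random.default_rng(config.rng_seed + 1)
    contigs = [
        generate_synthetic_bgc(layout, config.seed_peptide, rng, f"contig{i + 1}")
        for i, layout in enumerate(config.operon_layouts)
    ]
    seed_rng = np.random.default_rng(config.rng_seed + 2)
    seed_family = [config.seed_peptide] + [
        mutate_peptide(config.seed_peptide, 0.08, seed_rng, new_id=f"seedmut{i}")[0]
        for i in range(4)
    ]
    seed_msa = star_msa(seed_family)
    return SyntheticDataset(
        config=config,
        records=records,
        truth=truth,
        contigs=contigs,
        seed_msa=seed_msa,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize a dataset; same config + seed gives byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "db": outdir / "db.fasta",
        "seed_msa": outdir / "seed_msa.fasta",
        "truth": outdir / "truth.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "features": outdir / "features.gff3",
        "contigs": outdir / "contigs.tsv",
    }
    write_fasta(dataset.records, paths["db"])
    write_alignment_fasta(dataset.seed_msa, paths["seed_msa"])
    with open(paths["truth"], "w") as fh:
        fh.write("id\tkind\tfamily\tn_substitutions\tidentity_to_seed\n")
        for p in dataset.truth.planted:
            fh.write(
                f"{p.id}\tplanted\t{p.family}\t{p.n_substitutions}\t"
                f"{p.identity_to_seed:.6f}\n"
            )
        for d in dataset.truth.decoy_ids:
            fh.write(f"{d}\tdecoy\t\t\t\n")
    write_taxonomy(
        [dataset.truth.taxonomy[k] for k in sorted(dataset.truth.taxonomy)],
        paths["taxonomy"],
    )
    all_features = [f for contig in dataset.contigs for f in contig.features]
    write_features(all_features, paths["features"])
    with open(paths["contigs"], "w") as fh:
        fh.write("contig\tlength\tlayout\tcore_gene_ids\n")
        for contig in dataset.contigs:
            fh.write(
                f"{contig.contig_id}\t{contig.length}\t{contig.layout}\t"
                + ",".join(contig.core_gene_ids)
                + "\n"
            )
    return paths
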