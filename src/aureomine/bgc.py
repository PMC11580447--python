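"""Gene-neighborhood classification around mined core-peptide genes.

Each CDS near a core gene is assigned a functional role by matching its
product annotation against keyword lists (packaged as data and
overridable), with a fixed precedence so every feature gets exactly one
role: core > transport > membrane > regulator > repair > hypothetical >
other.  The neighborhood window is +/-5 kb around the core-gene span —
characterized leaderless-bacteriocin operons fit comfortably inside
5 kb — and core genes closer than the window merge into one cluster,
which is how tandem multi-core operons (up to eight copies observed)
are counted as single BGCs.

Two structural flags mirror the archetypes seen in real assemblies:
``contig_edge`` when the window is truncated by a contig end (the
cluster may continue on a lost fragment), and
``opposite_strand_machinery`` when transport or regulator genes sit on
the strand opposite the core gene — an organization that may indicate a
non-functional or unusually regulated operon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._data import load_table
from .seqio import GeneFeature, TaxonomyRow

ROLE_PRECEDENCE = ("core", "transport", "membrane", "regulator", "repair", "hypothetical")

#: role -> case-insensitive substrings matched against product text
DEFAULT_ROLE_KEYWORDS: dict[str, list[str]] = load_table("role_keywords.json")


class BGCError(ValueError):
    pass


def classify_gene_role(
    product: str, keywords: Mapping[str, Sequence[str]] | None = None
) -> str:
    """First matching role in precedence order; unmatched text is 'other'."""
    rules = keywords if keywords is not None else DEFAULT_ROLE_KEYWORDS
    text = (product or "").lower()
    for role in ROLE_PRECEDENCE:
        for pattern in rules.get(role, []):
            if pattern.lower() in text:
                return role
    return "other"


@dataclass
class BGC:
    """One core-peptide gene cluster with its classified neighborhood."""

    contig: str
    core_gene_ids: list[str]
    features: list[GeneFeature]          # all CDS overlapping the window
    roles: dict[str, str]                # gene_id -> role
    window: tuple[int, int]              # 1-based inclusive, clipped to contig
    has_transport: bool
    has_membrane: bool
    has_regulator: bool
    contig_edge: bool
    opposite_strand_machinery: bool

    @property
    def n_core(self) -> int:
        return len(self.core_gene_ids)

    @property
    def category(self) -> str:
        return "multi" if self.n_core >= 2 else "single"

    @property
    def functional_operon(self) -> bool:
        """Transport plus membrane-or-regulator machinery present
        (a structural flag, not a biological claim)."""
        return self.has_transport and (self.has_membrane or self.has_regulator)


def extract_bgc(
    features: Sequence[GeneFeature],
    core_ids: Sequence[str],
    window_bp: int = 5000,
    contig_length: int | None = None,
    keywords: Mapping[str, Sequence[str]] | None = None,
) -> BGC:
    """Build one BGC around the given core genes of a single contig.

    The window spans the merged core-gene span +/- ``window_bp``,
    clipped to [1, contig_length]; ``contig_edge`` records whether
    clipping occurred.  All CDS overlapping the window are included and
    role-classified; core genes are assigned the 'core' role by
    identity, not by product text.
    """
    by_id = {f.gene_id: f for f in features}
    missing = [c for c in core_ids if c not in by_id]
    if missing:
        raise BGCError(f"core gene id(s) absent from features: {missing}")
    cores = [by_id[c] for c in core_ids]
    contigs = {f.contig for f in cores}
    if len(contigs) != 1:
        raise BGCError(f"core genes span multiple contigs: {sorted(contigs)}")
    contig = contigs.pop()

    span_start = min(f.start for f in cores)
    span_end = max(f.end for f in cores)
    raw_lo = span_start - window_bp
    raw_hi = span_end + window_bp
    lo = max(1, raw_lo)
    hi = raw_hi if contig_length is None else min(contig_length, raw_hi)
    contig_edge = raw_lo < 1 or (contig_length is not None and raw_hi > contig_length)

    window_feats = [
        f
        for f in features
        if f.contig == contig and f.end >= lo and f.start <= hi
    ]
    window_feats.sort(key=lambda f: (f.start, f.end, f.gene_id))
    core_set = set(core_ids)
    roles = {
        f.gene_id: ("core" if f.gene_id in core_set else classify_gene_role(f.product, keywords))
        for f in window_feats
    }
    core_strands = {f.strand for f in cores}
    machinery_roles = {"transport", "regulator"}
    opposite = any(
        roles[f.gene_id] in machinery_roles and f.strand not in core_strands
        for f in window_feats
    )
    present = set(roles.values())
    return BGC(
        contig=contig,
        core_gene_ids=sorted(core_set, key=lambda c: by_id[c].start),
        features=window_feats,
        roles=roles,
        window=(lo, hi),
        has_transport="transport" in present,
        has_membrane="membrane" in present,
        has_regulator="regulator" in present,
        contig_edge=contig_edge,
        opposite_strand_machinery=opposite,
    )


def find_bgcs(
    features: Sequence[GeneFeature],
    core_ids: Sequence[str],
    window_bp: int = 5000,
    contig_lengths: Mapping[str, int] | None = None,
    merge_bp: int | None = None,
    keywords: Mapping[str, Sequence[str]] | None = None,
) -> list[BGC]:
    """Group core genes into operons and extract one BGC per group.

    Core genes on the same contig whose gene spans lie within
    ``merge_bp`` (default: the window size) of each other chain into
    one cluster.
    """
    if merge_bp is None:
        merge_bp = window_bp
    by_id = {f.gene_id: f for f in features}
    missing = [c for c in core_ids if c not in by_id]
    if missing:
        raise BGCError(f"core gene id(s) absent from features: {missing}")
    per_contig: dict[str, list[GeneFeature]] = {}
    for cid in core_ids:
        per_contig.setdefault(by_id[cid].contig, []).append(by_id[cid])
    bgcs: list[BGC] = []
    for contig in sorted(per_contig):
        cores = sorted(per_contig[contig], key=lambda f: f.start)
        group: list[GeneFeature] = [cores[0]]
        groups: list[list[GeneFeature]] = [group]
        for f in cores[1:]:
            if f.start - group[-1].end <= merge_bp:
                group.append(f)
            else:
                group = [f]
                groups.append(group)
        clen = contig_lengths.get(contig) if contig_lengths else None
        for group in groups:
            bgcs.append(
                extract_bgc(
                    features,
                    [f.gene_id for f in group],
                    window_bp=window_bp,
                    contig_length=clen,
                    keywords=keywords,
                )
            )
    return bgcs


# ---------------------------------------------------------------------------
# Tabulation

_FLAG_COLS = [
    "has_transport",
    "has_membrane",
    "has_regulator",
    "contig_edge",
    "opposite_strand_machinery",
    "functional_operon",
]


def tabulate_bgcs(
    bgcs: Sequence[BGC], taxonomy: Mapping[str, TaxonomyRow] | None = None
) -> pd.DataFrame:
    """Per-taxon BGC summary: counts of BGCs and core peptides,
    single/multi breakdown, flag frequencies.

    Rows are ordered by BGC count descending, then name ascending; an
    empty input yields an empty table with the full header.
    """
    rows = []
    for bgc in bgcs:
        tax = taxonomy.get(bgc.contig) if taxonomy else None
        rows.append(
            {
                "phylum": tax.phylum if tax else "",
                "genus": tax.genus if tax else "",
                "species": tax.species if tax else "",
                "n_core": bgc.n_core,
                "is_single": bgc.category == "single",
                **{c: getattr(bgc, c) for c in _FLAG_COLS},
            }
        )
    cols = [
        "phylum", "genus", "species", "n_bgcs", "n_core_peptides",
        "n_single", "n_multi",
    ] + _FLAG_COLS
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["phylum", "genus", "species"], as_index=False)
        .agg(
            n_bgcs=("n_core", "size"),
            n_core_peptides=("n_core", "sum"),
            n_single=("is_single", "sum"),
            **{c: (c, "sum") for c in _FLAG_COLS},
        )
    )
    grouped["n_multi"] = grouped["n_bgcs"] - grouped["n_single"]
    grouped = grouped[cols]
    grouped = grouped.sort_values(
        by=["n_bgcs", "phylum", "genus", "species"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return grouped


# ---------------------------------------------------------------------------
# Synteny sketch (plain-text SVG, arrow glyphs colored by role)

ROLE_COLORS = {
    "core": "#000000",
    "transport": "#d62728",
    "membrane": "#1f77b4",
    "regulator": "#2ca02c",
    "repair": "#ff7f0e",
    "hypothetical": "#aaaaaa",
    "other": "#cccccc",
}


def write_synteny_svg(bgc: BGC, path: str | Path, scale: float = 0.05) -> None:
    """Minimal synteny sketch: one arrow per CDS, colored by role."""
    lo, hi = bgc.window
    width = (hi - lo + 1) * scale + 40
    height = 80
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height}" viewBox="0 0 {width:.0f} {height}">',
        f'<text x="5" y="12" font-size="10">{bgc.contig} '
        f"[{lo}-{hi}] n_core={bgc.n_core}</text>",
        f'<line x1="20" y1="50" x2="{width - 20:.0f}" y2="50" stroke="#888"/>',
    ]
    for f in bgc.features:
        x0 = 20 + (f.start - lo) * scale
        x1 = 20 + (f.end - lo) * scale
        color = ROLE_COLORS[bgc.roles[f.gene_id]]
        head = min(6.0, x1 - x0)
        if f.strand == "+":
            points = f"{x0},42 {x1 - head},42 {x1},50 {x1 - head},58 {x0},58"
        else:
            points = f"{x1},42 {x0 + head},42 {x0},50 {x0 + head},58 {x1},58"
        parts.append(
            f'<polygon points="{points}" fill="{color}" stroke="#333" '
            f'stroke-width="0.5"><title>{f.gene_id}: {f.product}</title></polygon>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")
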