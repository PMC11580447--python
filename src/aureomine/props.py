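"""Physicochemical profiling of core peptides and the phylum rank test.

Aureocin A53-like peptides are short, highly cationic and tryptophan
rich; the profile used to characterize them comprises length, GRAVY
(mean Kyte-Doolittle hydropathy), average molecular weight, net charge
at a stated pH, and the isoelectric point.  Charge follows the
Henderson-Hasselbalch model with the EMBOSS pK set (packaged as data and
swappable); pI is the bisection root of the charge curve, which is
strictly decreasing in pH and therefore has a unique zero whenever the
curve changes sign on [0, 14].

The Kruskal-Wallis rank test contrasts property distributions between
phyla (Actinomycetota vs Bacillota in the intended use).

Dose conversion for activity assays (ug/mL to uM) lives here too:
100 ug/mL of a 6.3 kDa peptide is 15.9 uM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from ._data import load_table
from .seqio import CANONICAL_AA, SeqRecord

WATER_DA = 18.0153


KYTE_DOOLITTLE: dict[str, float] = load_table("kyte_doolittle.json")
RESIDUE_MASS_AVG: dict[str, float] = load_table("residue_masses_avg.json")
_EMBOSS = load_table("pk_emboss.json")

#: EMBOSS pK scale: termini plus ionizable side chains.
PK_EMBOSS: dict[str, float | dict[str, float]] = _EMBOSS


def _check_canonical(seq: str, op: str) -> None:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    bad = set(seq) - set(CANONICAL_AA)
    if bad:
        raise ValueError(
            f"{op}: sequence contains non-canonical residues {sorted(bad)}; "
            "X is not allowed in property calculations"
        )


def gravy(seq: str | SeqRecord) -> float:
    """Grand average of hydropathy: mean per-residue Kyte-Doolittle value."""
    s = seq.sequence if isinstance(seq, SeqRecord) else seq
    _check_canonical(s, "gravy")
    return sum(KYTE_DOOLITTLE[ch] for ch in s) / len(s)


def molecular_weight(seq: str | SeqRecord) -> float:
    """Average (not monoisotopic) molecular weight in Da.

    Sum of average residue masses plus one water for the free termini.
    """
    s = seq.sequence if isinstance(seq, SeqRecord) else seq
    _check_canonical(s, "molecular_weight")
    return sum(RESIDUE_MASS_AVG[ch] for ch in s) + WATER_DA


def net_charge(
    seq: str | SeqRecord, pH: float = 7.0, pk_scale: Mapping | None = None
) -> float:
    """Henderson-Hasselbalch net charge at ``pH`` (elementary charges).

    Positive contributions from the N-terminus and K/R/H side chains,
    ``1 / (1 + 10**(pH - pK))`` each; negative contributions from the
    C-terminus and D/E/C/Y side chains, ``-1 / (1 + 10**(pK - pH))``.
    """
    s = seq.sequence if isinstance(seq, SeqRecord) else seq
    _check_canonical(s, "net_charge")
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    pk = pk_scale if pk_scale is not None else PK_EMBOSS
    charge = 1.0 / (1.0 + 10.0 ** (pH - pk["n_terminus"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pk["c_terminus"] - pH))
    for ch in s:
        if ch in pk["positive"]:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pk["positive"][ch]))
        elif ch in pk["negative"]:
            charge -= 1.0 / (1.0 + 10.0 ** (pk["negative"][ch] - pH))
    return charge


def isoelectric_point(
    seq: str | SeqRecord, pk_scale: Mapping | None = None, tol: float = 1e-3
) -> float:
    """Bisection root of :func:`net_charge` over pH in [0, 14].

    The charge curve is strictly decreasing, so the root is unique.  If
    the charge has the same sign at both ends of the interval (possible
    only with exotic pK scales) the boundary with the smaller absolute
    charge is returned and a ``RuntimeWarning`` is issued.
    """
    import warnings

    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo, pk_scale)
    c_hi = net_charge(seq, hi, pk_scale)
    if c_lo <= 0 or c_hi >= 0:
        boundary = lo if abs(c_lo) <= abs(c_hi) else hi
        warnings.warn(
            "net charge does not change sign on [0, 14]; returning boundary pH",
            RuntimeWarning,
            stacklevel=2,
        )
        return boundary
    while hi - lo > tol * 1e-3:  # shrink well below tol so |charge(pI)| <= tol
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pk_scale) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dose_to_molar(dose_ug_per_ml: float, mw_da: float) -> float:
    """Convert an assay dose in ug/mL to uM, reported to one decimal.

    (ug/mL) / (g/mol) = mmol/L / 1000, hence the factor 1000 to reach uM.
    """
    if dose_ug_per_ml <= 0 or mw_da <= 0:
        raise ValueError("dose and molecular weight must be positive")
    return round(dose_ug_per_ml / mw_da * 1000.0, 1)


# ---------------------------------------------------------------------------
# Summary tables


@dataclass(frozen=True)
class PeptideProperties:
    length: int
    gravy: float
    mw: float
    charge: float
    pI: float


def peptide_properties(rec: SeqRecord, pH: float = 7.0) -> PeptideProperties:
    return PeptideProperties(
        length=len(rec.sequence),
        gravy=gravy(rec),
        mw=molecular_weight(rec),
        charge=net_charge(rec, pH),
        pI=isoelectric_point(rec),
    )


def properties_table(records: Sequence[SeqRecord], pH: float = 7.0) -> pd.DataFrame:
    """Per-peptide property table (id, length, gravy, mw, charge, pI)."""
    rows = []
    for rec in records:
        p = peptide_properties(rec, pH)
        rows.append(
            {
                "id": rec.id,
                "length": p.length,
                "gravy": p.gravy,
                "mw": p.mw,
                "charge": p.charge,
                "pI": p.pI,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "length", "gravy", "mw", "charge", "pI"]
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


@dataclass(frozen=True)
class RankTestResult:
    H: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = k - 1).

    Degenerate input where every value is identical yields H = 0, p = 1
    rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis: empty group")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise ValueError("kruskal_wallis: need at least 3 observations")
    df = len(groups) - 1
    flat = {v for g in groups for v in g}
    if len(flat) == 1:
        return RankTestResult(H=0.0, df=df, p=1.0)
    H, p = stats.kruskal(*groups)
    return RankTestResult(H=float(H), df=df, p=float(p))


def property_group_test(
    table: pd.DataFrame, phylum_by_id: Mapping[str, str]
) -> pd.DataFrame:
    """Kruskal-Wallis per property, grouping peptides by phylum.

    Peptides with no phylum assignment are dropped; properties are the
    numeric columns of :func:`properties_table`.
    """
    labeled = table.assign(phylum=table["id"].map(phylum_by_id)).dropna(
        subset=["phylum"]
    )
    labeled = labeled[labeled["phylum"] != ""]
    phyla = sorted(labeled["phylum"].unique())
    if len(phyla) < 2:
        raise ValueError("need at least two phyla with assigned peptides")
    rows = []
    for prop in ["length", "gravy", "mw", "charge", "pI"]:
        groups = [labeled.loc[labeled["phylum"] == ph, prop].to_numpy() for ph in phyla]
        res = kruskal_wallis(groups)
        rows.append({"property": prop, "H": res.H, "df": res.df, "p": res.p})
    return pd.DataFrame(rows, columns=["property", "H", "df", "p"])
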