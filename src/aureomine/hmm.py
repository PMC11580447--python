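"""Profile HMM construction, glocal scoring, E-value calibration and the
two-round iterative mining loop.

The model is a classic match/insert/delete profile built from a seed
alignment: alignment columns whose gap fraction is strictly below the
occupancy threshold become match states; emissions are count estimates
smoothed toward a packaged amino-acid background by a single
pseudocount weight; transitions are estimated from the observed state
paths with Laplace smoothing.

Scoring is *glocal* — the entire model against the entire sequence —
because the targets are whole small proteins and hits are kept only when
the homology spans the whole protein.  Scores are log2-odds (bits)
against an i.i.d. background null; the forward recursion sums over all
paths, Viterbi maximizes with a fixed M < D < I tie-break.  An X residue
emits with background probability in both model and null, so it
contributes odds 1 (zero bits).

Significance uses a Gumbel (type-I extreme value) survival law whose
parameters come from a censored exponential-tail fit to forward scores
of shuffled-composition null sequences; E = db_size * P(null >= score).  The calibration is a
self-contained stand-in for an external search engine's significance
machinery and is deliberately swappable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._data import load_table
from .seqio import CANONICAL_AA, SeqRecord

ALPHABET = CANONICAL_AA  # 20 canonical letters; X handled separately
AA_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
X_INDEX = 20  # sentinel column with zero log-odds emission

#: Background amino-acid frequencies (packaged data; sums to 1).
BACKGROUND = np.array([load_table("aa_background.json")[ch] for ch in ALPHABET])
BACKGROUND /= BACKGROUND.sum()

GAP_CHARS = {"-", "."}

#: transition bundle order per node
TRANS_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
_T = {name: i for i, name in enumerate(TRANS_NAMES)}

EULER_GAMMA = 0.5772156649015329


class HMMError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Map a sequence to alphabet indices; X maps to the sentinel column."""
    try:
        return np.array([AA_INDEX.get(ch, X_INDEX) for ch in seq], dtype=np.int64)
    except TypeError:  # pragma: no cover
        raise HMMError(f"cannot encode sequence {seq!r}")


@dataclass
class ProfileHMM:
    """Glocal profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions``: (M, 20) rows summing to 1 (match states 1..M).
    ``insert_emissions``: (M+1, 20) rows summing to 1 (insert states
    0..M; insert 0 precedes match 1).
    ``transitions``: (M+1, 7) in :data:`TRANS_NAMES` order; row k holds
    the node-k bundle (begin acts as the match state of node 0, and at
    node M the "next match" target is the end state, so MD and DD are 0
    there).  Each source-state triple/pair sums to 1.
    """

    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    pseudocount_weight: float = 1.0

    @property
    def model_length(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self) -> None:
        M = self.model_length
        if M < 1:
            raise HMMError("model must have at least one match state")
        if self.insert_emissions.shape != (M + 1, 20):
            raise HMMError("insert_emissions must be (M+1, 20)")
        if self.transitions.shape != (M + 1, 7):
            raise HMMError("transitions must be (M+1, 7)")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        for name, table in (
            ("match", self.match_emissions),
            ("insert", self.insert_emissions),
        ):
            if not np.allclose(table.sum(axis=1), 1.0, atol=atol):
                raise HMMError(f"{name} emission rows must sum to 1")
            if (table < 0).any():
                raise HMMError(f"negative {name} emission probability")
        t = self.transitions
        m_rows = t[:, [_T["MM"], _T["MI"], _T["MD"]]].sum(axis=1)
        i_rows = t[:, [_T["IM"], _T["II"]]].sum(axis=1)
        d_rows = t[:, [_T["DM"], _T["DD"]]].sum(axis=1)
        if not np.allclose(m_rows, 1.0, atol=atol):
            raise HMMError("M-state transition bundles must sum to 1")
        if not np.allclose(i_rows, 1.0, atol=atol):
            raise HMMError("I-state transition bundles must sum to 1")
        # D bundle at node 0 is unused (begin cannot be a delete state)
        if not np.allclose(d_rows[1:], 1.0, atol=atol):
            raise HMMError("D-state transition bundles must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=atol):
            raise HMMError("background must sum to 1")

    # -- log-odds tables used by the scorers -------------------------------
    def _log_tables(self):
        with np.errstate(divide="ignore"):
            lt = np.log2(self.transitions)
            # emission log-odds with an extra zero column for X
            lem = np.log2(self.match_emissions / self.background)
            lei = np.log2(self.insert_emissions / self.background)
        lem = np.hstack([lem, np.zeros((self.model_length, 1))])
        lei = np.hstack([lei, np.zeros((self.model_length + 1, 1))])
        return lt, lem, lei


# ---------------------------------------------------------------------------
# Model construction


def build_hmm(
    msa: Sequence[tuple[str, str]] | Sequence[str],
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of sequences.

    ``msa`` is a list of (id, row) pairs or bare rows of equal length.
    Columns whose gap fraction is strictly below ``occupancy_threshold``
    become match states (a column at exactly the threshold is an insert
    column).  Emissions are ``(counts + w * background) / (n + w)``;
    transitions come from the observed per-row state paths with
    add-one (Laplace) smoothing over the transitions the architecture
    allows at each node.
    """
    rows = [r[1] if isinstance(r, tuple) else r for r in msa]
    if len(rows) < 2:
        raise HMMError("need at least 2 aligned rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise HMMError("ragged alignment")
    if width == 0:
        raise HMMError("empty alignment")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    if pseudocount_weight < 0:
        raise HMMError("pseudocount_weight must be nonnegative")
    n_rows = len(rows)

    is_match = []
    for c in range(width):
        gap_frac = sum(1 for r in rows if r[c] in GAP_CHARS) / n_rows
        is_match.append(gap_frac < occupancy_threshold)
    M = sum(is_match)
    if M == 0:
        raise HMMError("alignment yields zero match columns")

    w = pseudocount_weight
    match_counts = np.zeros((M, 20))
    insert_counts = np.zeros((M + 1, 20))
    trans_counts = np.zeros((M + 1, 7))

    for row in rows:
        node = 0
        prev = "M"  # begin behaves as the node-0 match state
        for c, ch in enumerate(row):
            if is_match[c]:
                state = "D" if ch in GAP_CHARS else "M"
                trans_counts[node, _T[prev + state]] += 1
                node += 1
                prev = state
                if state == "M" and ch != "X":
                    match_counts[node - 1, AA_INDEX[ch]] += 1
            else:
                if ch in GAP_CHARS:
                    continue  # gap in an insert column emits nothing
                trans_counts[node, _T[prev + "I"]] += 1
                prev = "I"
                if ch != "X":
                    insert_counts[node, AA_INDEX[ch]] += 1
        # exit to the end state (recorded as *M at node M)
        trans_counts[M, _T[prev + "M"]] += 1

    match_em = (match_counts + w * bg) / (
        match_counts.sum(axis=1, keepdims=True) + w
    )
    insert_em = (insert_counts + w * bg) / (
        insert_counts.sum(axis=1, keepdims=True) + w
    )

    transitions = np.zeros((M + 1, 7))
    for k in range(M + 1):
        last = k == M
        groups = {
            "M": ["MM", "MI"] + ([] if last else ["MD"]),
            "I": ["IM", "II"],
            "D": ["DM"] + ([] if last else ["DD"]),
        }
        for names in groups.values():
            idx = [_T[n] for n in names]
            smoothed = trans_counts[k, idx] + 1.0  # Laplace over allowed targets
            transitions[k, idx] = smoothed / smoothed.sum()
    return ProfileHMM(
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=transitions,
        background=bg.copy(),
        pseudocount_weight=w,
    )


# ---------------------------------------------------------------------------
# Scoring


def forward_score(hmm: ProfileHMM, seq: SeqRecord | str) -> float:
    """Glocal forward bit score: log2 P(seq|model) / P(seq|background),
    summed over all state paths through the whole model."""
    s = seq.sequence if isinstance(seq, SeqRecord) else seq
    if not s:
        raise HMMError("cannot score an empty sequence")
    return float(forward_scores(hmm, [s])[0])


def forward_scores(hmm: ProfileHMM, seqs: Sequence[SeqRecord | str]) -> np.ndarray:
    """Vectorized glocal forward scores (bits) for a batch of sequences.

    Sequences are grouped by length internally; the dynamic program runs
    once per length group with the batch as the trailing axis.
    """
    strs = [s.sequence if isinstance(s, SeqRecord) else s for s in seqs]
    if any(not s for s in strs):
        raise HMMError("cannot score an empty sequence")
    out = np.empty(len(strs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(strs):
        by_len.setdefault(len(s), []).append(i)
    lt, lem, lei = hmm._log_tables()
    for length, idxs in by_len.items():
        batch = np.stack([encode(strs[i]) for i in idxs])  # (B, L)
        out[np.array(idxs)] = _forward_batch(hmm, batch, lt, lem, lei)
    return out


def _forward_batch(hmm, batch, lt, lem, lei) -> np.ndarray:
    B, L = batch.shape
    M = hmm.model_length
    ninf = -np.inf
    tMM, tMI, tMD = lt[:, 0], lt[:, 1], lt[:, 2]
    tIM, tII = lt[:, 3], lt[:, 4]
    tDM, tDD = lt[:, 5], lt[:, 6]

    fM = np.full((B, M + 1), ninf)
    fI = np.full((B, M + 1), ninf)
    fD = np.full((B, M + 1), ninf)
    fM[:, 0] = 0.0  # begin
    for k in range(1, M + 1):
        src = fM[:, k - 1] + tMD[k - 1] if k == 1 else np.logaddexp2(
            fM[:, k - 1] + tMD[k - 1], fD[:, k - 1] + tDD[k - 1]
        )
        fD[:, k] = src

    for i in range(L):
        x = batch[:, i]  # (B,)
        em = lem[:, x].T  # (B, M): match emission log-odds for residue x
        ei = lei[:, x].T  # (B, M+1)
        prev_any = np.logaddexp2(
            np.logaddexp2(fM[:, :-1] + tMM[:-1], fI[:, :-1] + tIM[:-1]),
            fD[:, :-1] + tDM[:-1],
        )  # (B, M): into match k from node k-1
        new_M = np.full((B, M + 1), ninf)
        new_M[:, 1:] = em + prev_any
        new_I = ei + np.logaddexp2(fM + tMI, fI + tII)
        new_D = np.full((B, M + 1), ninf)
        # D-chain sweep (sequential in k); new_M[:, 0] is -inf once a
        # residue has been emitted, so D_1 is unreachable here
        new_D[:, 1] = new_M[:, 0] + tMD[0]
        for k in range(2, M + 1):
            new_D[:, k] = np.logaddexp2(
                new_M[:, k - 1] + tMD[k - 1], new_D[:, k - 1] + tDD[k - 1]
            )
        fM, fI, fD = new_M, new_I, new_D

    return np.logaddexp2(
        np.logaddexp2(fM[:, M] + tMM[M], fI[:, M] + tIM[M]), fD[:, M] + tDM[M]
    )


_STATE_PRIORITY = {"M": 0, "D": 1, "I": 2}  # tie-break order


def viterbi_align(hmm: ProfileHMM, seq: SeqRecord | str) -> tuple[float, list[str]]:
    """Best single glocal path and its bit score.

    The path is a list of state labels like ``["M1", "I1", "D2", ...]``
    (begin/end omitted).  Ties are broken by the fixed state order
    M < D < I, applied to the predecessor choice at every cell, so the
    lexicographically-first path among optimal paths is returned.
    """
    s = seq.sequence if isinstance(seq, SeqRecord) else seq
    if not s:
        raise HMMError("cannot score an empty sequence")
    x = encode(s)
    L, M = len(x), hmm.model_length
    lt, lem, lei = hmm._log_tables()
    tMM, tMI, tMD = lt[:, 0], lt[:, 1], lt[:, 2]
    tIM, tII = lt[:, 3], lt[:, 4]
    tDM, tDD = lt[:, 5], lt[:, 6]
    ninf = -np.inf

    # v[state][i][k]; back[state][i][k] = predecessor state label
    vM = np.full((L + 1, M + 1), ninf)
    vI = np.full((L + 1, M + 1), ninf)
    vD = np.full((L + 1, M + 1), ninf)
    bM = np.empty((L + 1, M + 1), dtype="U1")
    bI = np.empty((L + 1, M + 1), dtype="U1")
    bD = np.empty((L + 1, M + 1), dtype="U1")
    vM[0, 0] = 0.0
    for k in range(1, M + 1):
        cands = [("M", vM[0, k - 1] + tMD[k - 1]), ("D", vD[0, k - 1] + tDD[k - 1])]
        lbl, val = _argmax(cands)
        vD[0, k], bD[0, k] = val, lbl

    for i in range(1, L + 1):
        em = lem[:, x[i - 1]]  # (M,)
        ei = lei[:, x[i - 1]]  # (M+1,)
        for k in range(M + 1):
            if k >= 1:
                cands = [
                    ("M", vM[i - 1, k - 1] + tMM[k - 1]),
                    ("D", vD[i - 1, k - 1] + tDM[k - 1]),
                    ("I", vI[i - 1, k - 1] + tIM[k - 1]),
                ]
                lbl, val = _argmax(cands)
                vM[i, k], bM[i, k] = val + em[k - 1], lbl
            cands = [("M", vM[i - 1, k] + tMI[k]), ("I", vI[i - 1, k] + tII[k])]
            lbl, val = _argmax(cands)
            vI[i, k], bI[i, k] = val + ei[k], lbl
        for k in range(1, M + 1):
            cands = [("M", vM[i, k - 1] + tMD[k - 1]), ("D", vD[i, k - 1] + tDD[k - 1])]
            lbl, val = _argmax(cands)
            vD[i, k], bD[i, k] = val, lbl

    finals = [
        ("M", vM[L, M] + tMM[M]),
        ("D", vD[L, M] + tDM[M]),
        ("I", vI[L, M] + tIM[M]),
    ]
    lbl, score = _argmax(finals)

    path: list[str] = []
    i, k, state = L, M, lbl
    while not (state == "M" and k == 0):
        path.append(f"{state}{k}")
        if state == "M":
            prev = bM[i, k]
            i, k = i - 1, k - 1
        elif state == "I":
            prev = bI[i, k]
            i = i - 1
        else:
            prev = bD[i, k]
            k = k - 1
        state = prev
    path.reverse()
    return float(score), path


def _argmax(cands: list[tuple[str, float]]) -> tuple[str, float]:
    best = max(v for _, v in cands)
    for lbl in ("M", "D", "I"):
        for name, v in cands:
            if name == lbl and v == best:
                return name, v
    raise AssertionError  # pragma: no cover


def path_to_match_row(hmm: ProfileHMM, seq: SeqRecord | str, path: list[str]) -> str:
    """Project a Viterbi path onto the model's match columns.

    Match-state emissions land in their column, deletes become gaps,
    insert-emitted residues are dropped (the trimmed-alignment
    convention).  The result is an M-character aligned row.
    """
    s = seq.sequence if isinstance(seq, SeqRecord) else seq
    row = ["-"] * hmm.model_length
    i = 0
    for label in path:
        state, node = label[0], int(label[1:])
        if state == "M":
            row[node - 1] = s[i]
            i += 1
        elif state == "I":
            i += 1
    return "".join(row)


# ---------------------------------------------------------------------------
# E-value calibration


@dataclass(frozen=True)
class NullCalibration:
    """Gumbel law fitted to null forward scores (bits)."""

    gumbel_mu: float
    gumbel_lambda: float
    n_null: int

    def __post_init__(self) -> None:
        if self.gumbel_lambda <= 0:
            raise HMMError("gumbel_lambda must be positive")
        if self.n_null < 100:
            raise HMMError("calibration needs at least 100 null sequences")


def sample_null_sequences(
    composition: np.ndarray,
    n: int,
    length: int,
    rng: np.random.Generator,
    dirichlet_concentration: float | None = 50.0,
) -> list[str]:
    """Draw i.i.d. null sequences from a (possibly overdispersed) background.

    When ``dirichlet_concentration`` is set, each sequence gets its own
    composition drawn from Dirichlet(concentration * smoothed background),
    mimicking the compositional variability of real short proteins (and
    of the decoy generator).  ``None`` uses the fixed composition.
    """
    comp = np.asarray(composition, dtype=float)
    comp = comp / comp.sum()
    seqs = []
    for _ in range(n):
        if dirichlet_concentration is not None:
            alpha = dirichlet_concentration * (0.9 * comp + 0.1 / 20.0)
            p = rng.dirichlet(alpha)
        else:
            p = comp
        idx = rng.choice(20, size=length, p=p)
        seqs.append("".join(ALPHABET[i] for i in idx))
    return seqs


def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sd*sqrt(6)),
    mu = mean - gamma/lambda.

    Appropriate when the scores genuinely follow a Gumbel law.  Glocal
    forward null scores do not — their bulk is lighter-tailed — so the
    default calibration uses :func:`fit_gumbel_tail` instead.
    """
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise HMMError("null scores have zero variance; cannot calibrate")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = scores.mean() - EULER_GAMMA / lam
    return mu, lam


def fit_gumbel_tail(
    scores: np.ndarray, tail_fraction: float | None = None
) -> tuple[float, float]:
    """Censored Gumbel fit from the exponential upper tail.

    Exceedances over the (1 - tail_fraction) quantile ``u`` are fitted
    with a maximum-likelihood exponential rate ``lambda``; the matching
    Gumbel location is ``mu = u + ln(tail_fraction) / lambda`` so that
    the Gumbel survival ``exp(-lambda (s - mu))`` reproduces the
    empirical exceedance probability at and beyond ``u``.  Glocal
    forward scores of i.i.d. sequences have an approximately exponential
    far tail but a lighter bulk, so this censored fit calibrates the
    small-E regime far better than whole-sample moments.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.std(ddof=1) == 0:
        raise HMMError("null scores have zero variance; cannot calibrate")
    if tail_fraction is None:
        # default 2.5%, widened so at least ~20 exceedances remain
        tail_fraction = max(0.025, 20.0 / len(scores))
    u = float(np.quantile(scores, 1.0 - tail_fraction))
    exc = scores[scores > u] - u
    if len(exc) < 5 or exc.mean() == 0:
        raise HMMError("too few tail exceedances to calibrate; increase n_null")
    lam = 1.0 / float(exc.mean())
    mu = u + math.log(tail_fraction) / lam
    return mu, lam


def calibrate_null(
    hmm: ProfileHMM,
    db_composition: np.ndarray,
    n_null: int,
    seq_length: int,
    rng: np.random.Generator,
    dirichlet_concentration: float | None = 50.0,
    method: str = "tail",
) -> NullCalibration:
    """Score ``n_null`` background sequences and fit the Gumbel null.

    ``method`` is ``"tail"`` (censored exponential-tail fit, the
    default) or ``"moments"`` (whole-sample method of moments).
    """
    if n_null < 100:
        raise HMMError("n_null must be >= 100")
    seqs = sample_null_sequences(
        db_composition, n_null, seq_length, rng, dirichlet_concentration
    )
    scores = forward_scores(hmm, seqs)
    if method == "tail":
        mu, lam = fit_gumbel_tail(scores)
    elif method == "moments":
        mu, lam = fit_gumbel_moments(scores)
    else:
        raise HMMError(f"unknown calibration method {method!r}")
    return NullCalibration(gumbel_mu=mu, gumbel_lambda=lam, n_null=n_null)


def evalue(cal: NullCalibration, bit_score: float, db_size: int) -> float:
    """E = db_size * P(null >= score) under the fitted Gumbel."""
    z = cal.gumbel_lambda * (bit_score - cal.gumbel_mu)
    # 1 - exp(-exp(-z)), computed stably
    tail = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
    return db_size * tail


# ---------------------------------------------------------------------------
# Iterative search


@dataclass(frozen=True)
class SearchHit:
    sequence_id: str
    bit_score: float
    e_value: float
    iteration: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise HMMError("negative E-value")


def db_composition(records: Sequence[SeqRecord]) -> np.ndarray:
    """Pooled amino-acid frequencies of a database (X ignored),
    background-smoothed so no letter has zero frequency."""
    counts = np.zeros(20)
    for rec in records:
        for ch in rec.sequence:
            if ch != "X":
                counts[AA_INDEX[ch]] += 1
    counts += 1.0  # smoothing; also covers an empty database
    return counts / counts.sum()


def iterative_search(
    seed_msa: Sequence[tuple[str, str]],
    db: Sequence[SeqRecord],
    e_threshold: float = 1e-5,
    max_len: int = 100,
    n_iterations: int = 2,
    calibration_n: int = 1000,
    rng: np.random.Generator | int | None = 0,
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
) -> list[SearchHit]:
    """Two-round iterative profile-HMM mining of a short-protein database.

    Round 1 builds the model from the seed alignment, restricts the
    database to proteins strictly under ``max_len`` residues, calibrates
    a Gumbel null at the median database length, scores everything and
    keeps hits with E below ``e_threshold``.  Round 2 projects the round-1
    hits onto the model's match columns via their Viterbi paths, appends
    them to the (equally projected) seed rows, rebuilds and recalibrates,
    and rescores the database.  Hits are reported once each, tagged with
    the round of first discovery.
    """
    if not seed_msa:
        raise HMMError("empty seed alignment")
    if n_iterations < 1:
        raise HMMError("n_iterations must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    filtered = [rec for rec in db if len(rec.sequence) < max_len]
    if not filtered:
        warnings.warn(
            "no database sequences pass the length filter; empty result",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    comp = db_composition(filtered)
    cal_length = int(np.median([len(r.sequence) for r in filtered]))

    hits: dict[str, SearchHit] = {}
    msa = list(seed_msa)
    model = build_hmm(msa, occupancy_threshold, pseudocount_weight)
    for it in range(1, n_iterations + 1):
        if it > 1:
            new_ids = [h for h in hits if hits[h].iteration == it - 1]
            if not new_ids:
                break
            by_id = {rec.id: rec for rec in filtered}
            # project seed rows and hits onto round-1 match columns
            proj_rows = [
                (rid, _project_row(model, row)) for rid, row in msa
            ]
            for hid in new_ids:
                _, path = viterbi_align(model, by_id[hid])
                proj_rows.append((hid, path_to_match_row(model, by_id[hid], path)))
            msa = proj_rows
            model = build_hmm(msa, occupancy_threshold, pseudocount_weight)
        cal = calibrate_null(model, comp, calibration_n, cal_length, rng)
        scores = forward_scores(model, filtered)
        for rec, score in zip(filtered, scores):
            ev = evalue(cal, float(score), len(filtered))
            if ev < e_threshold and rec.id not in hits:
                hits[rec.id] = SearchHit(
                    sequence_id=rec.id,
                    bit_score=float(score),
                    e_value=ev,
                    iteration=it,
                )
    return sorted(hits.values(), key=lambda h: (h.iteration, h.e_value, h.sequence_id))


def _project_row(model: ProfileHMM, row: str) -> str:
    """Project one original alignment row onto the model's match columns.

    Assumes the model was built from this alignment, so match columns are
    the occupied ones; recompute the match-column mask from the model
    length by re-deriving occupancy is not possible here, so the row is
    aligned to the model by Viterbi on its degapped sequence.
    """
    seq = row.replace("-", "").replace(".", "")
    _, path = viterbi_align(model, seq)
    return path_to_match_row(model, seq, path)


def write_hits_tsv(hits: Sequence[SearchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tbit_score\te_value\titeration\n")
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.bit_score:.4f}\t{h.e_value:.6g}\t{h.iteration}\n")


# ---------------------------------------------------------------------------
# Plain-text model serialization (versioned)

_FORMAT_VERSION = "aureomine-hmm/1"


def write_hmm(hmm: ProfileHMM, path: str | Path) -> None:
    """Serialize the model to a documented plain-text profile format.

    Layout: a versioned header; the alphabet; the background row; then
    one ``MATCH k``/``INSERT k``/``TRANS k`` row per node with
    full-precision probabilities.
    """
    M = hmm.model_length
    with open(path, "w") as fh:
        fh.write(f"#{_FORMAT_VERSION}\n")
        fh.write(f"LENGTH\t{M}\n")
        fh.write(f"PSEUDOCOUNT\t{hmm.pseudocount_weight!r}\n")
        fh.write("ALPHABET\t" + ALPHABET + "\n")
        fh.write("BACKGROUND\t" + "\t".join(repr(float(v)) for v in hmm.background) + "\n")
        for k in range(M):
            fh.write(
                f"MATCH\t{k + 1}\t"
                + "\t".join(repr(float(v)) for v in hmm.match_emissions[k])
                + "\n"
            )
        for k in range(M + 1):
            fh.write(
                f"INSERT\t{k}\t"
                + "\t".join(repr(float(v)) for v in hmm.insert_emissions[k])
                + "\n"
            )
        fh.write("# TRANS order: " + " ".join(TRANS_NAMES) + "\n")
        for k in range(M + 1):
            fh.write(
                f"TRANS\t{k}\t" + "\t".join(repr(float(v)) for v in hmm.transitions[k]) + "\n"
            )


def read_hmm(path: str | Path) -> ProfileHMM:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"#{_FORMAT_VERSION}":
            raise HMMError(f"unsupported model format header {header!r}")
        fields: dict[str, list[list[str]]] = {}
        meta: dict[str, str] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            key = parts[0]
            if key in {"LENGTH", "PSEUDOCOUNT", "ALPHABET"}:
                meta[key] = parts[1]
            elif key == "BACKGROUND":
                meta["BACKGROUND"] = parts[1:]
            else:
                fields.setdefault(key, []).append(parts[1:])
    M = int(meta["LENGTH"])
    match = np.array(
        [[float(v) for v in row[1:]] for row in sorted(fields["MATCH"], key=lambda r: int(r[0]))]
    )
    insert = np.array(
        [[float(v) for v in row[1:]] for row in sorted(fields["INSERT"], key=lambda r: int(r[0]))]
    )
    trans = np.array(
        [[float(v) for v in row[1:]] for row in sorted(fields["TRANS"], key=lambda r: int(r[0]))]
    )
    return ProfileHMM(
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        background=np.array([float(v) for v in meta["BACKGROUND"]]),
        pseudocount_weight=float(meta["PSEUDOCOUNT"]),
    )
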