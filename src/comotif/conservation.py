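"""Phylogenetic footprinting of orthologous promoters.

The workflow mirrors classic conservation masking: each non-reference
species' promoter is locally aligned to the mouse promoter with the
Smith-Waterman-Gotoh affine-gap algorithm; species passing a score and
consensus-length filter are stacked into a reference-centred star
alignment; an iterative leave-one-out refinement polishes the alignment;
finally, reference positions whose column disagrees across species are
replaced by ``N`` so downstream motif discovery only sees conserved
sequence.

Scoring conventions
-------------------
Pairwise alignment is affine: a gap of length L costs
``gap_open + (L-1)*gap_extend`` (both negative, ``gap_open`` being the
cost of the first gap position).  The multiple-alignment sum-of-pairs
(SP) objective uses linear gap costs (``gap_open`` per gap-vs-base
column, 0 for gap-vs-gap) so that refinement monotonicity and the small
exact oracles used in testing share one well-defined objective.  ``N``
scores as a mismatch against everything and never counts as agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import GAP_CODE, N, decode, encode
from .promoter_io import OrthologueGroup, REFERENCE_SPECIES

logger = logging.getLogger(__name__)

_NEG = -1e30

try:  # optional JIT; the pure-python fallback is exact but slow
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass
class AlignmentParams:
    """Affine-gap scoring parameters (EMBOSS-water-like defaults)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass
class PairwiseAlignment:
    score: float
    aligned_a: str
    aligned_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def consensus_length(self) -> int:
        """Number of alignment columns of the local alignment."""
        return len(self.aligned_a)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows, reference species first."""

    species: list[str]
    rows: list[str]
    params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_for(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def sp_score(self) -> float:
        return sum_of_pairs(self.rows, self.params)


@dataclass
class MaskedConsensus:
    gene_id: str
    sequence: str
    retained_species: list[str]
    fraction_masked: float


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            if ai == bj and ai < 4:
                s = match
            else:
                s = mismatch
            prev = 0.0
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            M[i, j] = s + prev
            xo = M[i - 1, j] + gap_open
            xe = X[i - 1, j] + gap_extend
            X[i, j] = xo if xo > xe else xe
            yo = M[i, j - 1] + gap_open
            ye = Y[i, j - 1] + gap_extend
            Y[i, j] = yo if yo > ye else ye
    return M, X, Y


def _gotoh_fill_py(a, b, match, mismatch, gap_open, gap_extend):
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    for i in range(1, n + 1):
        ai = a[i - 1]
        sub_row = np.where((b == ai) & (ai < 4), match, mismatch)
        for j in range(1, m + 1):
            prev = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = sub_row[j - 1] + prev
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return M, X, Y


def sw_gotoh(a: str, b: str, params: AlignmentParams | None = None) -> PairwiseAlignment:
    """Optimal local alignment under affine gap penalties.

    Returns score 0 with an empty alignment when no positive-scoring local
    alignment exists.  ``N`` mismatches every base including ``N``.
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ca, cb = encode(a), encode(b)
    fill = _gotoh_fill if _HAVE_NUMBA else _gotoh_fill_py
    M, X, Y = fill(ca, cb, params.match, params.mismatch, params.gap_open, params.gap_extend)
    best = float(M.max())
    if best <= 0:
        return PairwiseAlignment(0.0, "", "", 0, 0, 0, 0)
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    a_end, b_end = int(i), int(j)
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-6
    state = "M"
    while True:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            vals = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i -= 1
            j -= 1
            top = max(0.0, *vals)
            if top <= eps:
                break
            if abs(vals[0] - top) <= eps:
                state = "M"
            elif abs(vals[1] - top) <= eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":  # gap in b, consume a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            if abs(M[i - 1, j] + params.gap_open - X[i, j]) <= eps:
                state = "M"
            i -= 1
        else:  # gap in a, consume b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            if abs(M[i, j - 1] + params.gap_open - Y[i, j]) <= eps:
                state = "M"
            j -= 1
    return PairwiseAlignment(
        best, "".join(reversed(out_a)), "".join(reversed(out_b)), int(i), a_end, int(j), b_end
    )


def filter_species(
    group: OrthologueGroup,
    params: AlignmentParams | None = None,
    min_score: float = 200.0,
    min_len: int = 500,
    max_len: int = 1000,
    reference: str = REFERENCE_SPECIES,
) -> list[str]:
    """Select species whose promoter aligns well enough to the reference.

    A species is retained iff its local alignment to the reference scores
    strictly more than ``min_score`` and spans ``min_len``..``max_len``
    alignment columns (inclusive).  The reference itself is always first in
    the returned list.
    """
    params = params or AlignmentParams()
    ref = group.require_reference(reference)
    retained = [reference]
    for species in sorted(group.members):
        if species == reference:
            continue
        aln = sw_gotoh(ref.sequence, group.members[species].sequence, params)
        if aln.score > min_score and min_len <= aln.consensus_length <= max_len:
            retained.append(species)
    return retained


def sum_of_pairs(rows: list[str], params: AlignmentParams | None = None) -> float:
    """Linear-gap sum-of-pairs score of a gapped row set.

    Base-vs-base columns score match/mismatch (``N`` mismatches all);
    base-vs-gap scores ``gap_open``; gap-vs-gap scores 0.
    """
    params = params or AlignmentParams()
    if len(rows) < 2:
        return 0.0
    mat = np.vstack([encode(r.replace("-", chr(ord("A") - 1))) for r in rows])
    # encode() maps unknown chars to N; recover explicit gap codes instead
    for k, row in enumerate(rows):
        gaps = np.frombuffer(row.encode(), dtype=np.uint8) == ord("-")
        mat[k, gaps] = GAP_CODE
    total = 0.0
    m = len(rows)
    for p in range(m):
        for q in range(p + 1, m):
            r1, r2 = mat[p], mat[q]
            both_base = (r1 < GAP_CODE) & (r2 < GAP_CODE)
            matches = both_base & (r1 == r2) & (r1 < N)
            n_match = int(matches.sum())
            n_mismatch = int(both_base.sum()) - n_match
            one_gap = (r1 == GAP_CODE) ^ (r2 == GAP_CODE)
            total += (
                params.match * n_match
                + params.mismatch * n_mismatch
                + params.gap_open * int(one_gap.sum())
            )
    return total


def progressive_msa(
    group: OrthologueGroup,
    retained: list[str],
    params: AlignmentParams | None = None,
    reference: str = REFERENCE_SPECIES,
) -> MultipleAlignment:
    """Reference-centred star alignment of the retained species.

    Each species is pairwise-aligned to the reference with ``sw_gotoh``
    and the pairwise gaps are merged into a growing master alignment
    ("once a gap, always a gap").  Only the locally aligned region of each
    non-reference species contributes; its unaligned flanks are dropped.
    A single retained species yields the trivial one-row alignment.
    """
    params = params or AlignmentParams()
    if not retained:
        raise ValueError("need at least one retained species")
    if retained[0] != reference:
        retained = [reference] + [s for s in retained if s != reference]
    ref_seq = group.require_reference(reference).sequence
    # master state: cols_refpos[c] = reference position or -1 for insertions
    cols_refpos: list[int] = list(range(len(ref_seq)))
    rows: dict[str, list[str]] = {reference: list(ref_seq)}
    for species in retained[1:]:
        other = group.members[species].sequence
        aln = sw_gotoh(ref_seq, other, params)
        row = ["-"] * len(cols_refpos)
        rows[species] = row
        if not aln.aligned_a:
            continue
        col_of_ref = {rp: c for c, rp in enumerate(cols_refpos) if rp >= 0}
        refpos = aln.a_start
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                col = col_of_ref[refpos]
                if cb != "-":
                    row[col] = cb
                refpos += 1
            else:
                # insertion relative to the reference: new all-gap column
                idx = col_of_ref[refpos] if refpos < len(ref_seq) else len(cols_refpos)
                cols_refpos.insert(idx, -1)
                for r in rows.values():
                    r.insert(idx, "-")
                row[idx] = cb
                for rp in col_of_ref:
                    if col_of_ref[rp] >= idx:
                        col_of_ref[rp] += 1
    ordered = [s for s in retained if s in rows]
    return MultipleAlignment(ordered, ["".join(rows[s]) for s in ordered], params)


def _drop_all_gap_columns(rows: list[list[str]]) -> None:
    ncols = len(rows[0])
    keep = [c for c in range(ncols) if any(r[c] != "-" for r in rows)]
    for k, r in enumerate(rows):
        rows[k][:] = [r[c] for c in keep]


def _profile_align(seq: str, prof_rows: list[str], params: AlignmentParams):
    """Global linear-gap alignment of one sequence against a profile.

    Returns (score, ops) where ops is a list over result columns of
    ('D', j, ch) diagonal into profile column j, ('L', j) profile column j
    with a gap in the sequence, or ('U', ch) a freshly inserted column.
    """
    m = len(prof_rows)
    C = len(prof_rows[0]) if prof_rows else 0
    prof = np.vstack([encode(r.replace("-", "X")) for r in prof_rows]) if m else np.zeros((0, 0), np.int8)
    for k, r in enumerate(prof_rows):
        gaps = np.frombuffer(r.encode(), dtype=np.uint8) == ord("-")
        prof[k, gaps] = GAP_CODE
    cnt = np.zeros((4, C))
    for x in range(4):
        cnt[x] = (prof == x).sum(axis=0)
    nbase = (prof < GAP_CODE).sum(axis=0).astype(float)  # bases incl. N
    ngap = m - nbase
    # score of seq char x against profile column j
    S = np.zeros((5, C))
    for x in range(4):
        S[x] = params.match * cnt[x] + params.mismatch * (nbase - cnt[x]) + params.gap_open * ngap
    S[4] = params.mismatch * nbase + params.gap_open * ngap  # N mismatches all
    gd = params.gap_open * nbase  # seq gap vs column j
    gi = params.gap_open * m  # new inserted column
    codes = encode(seq)
    L = len(codes)
    D = np.zeros((L + 1, C + 1))
    cg = np.concatenate([[0.0], np.cumsum(gd)])
    D[0, :] = cg
    D[:, 0] = np.arange(L + 1) * gi
    for i in range(1, L + 1):
        tmp = np.empty(C + 1)
        tmp[0] = D[i, 0]
        tmp[1:] = np.maximum(D[i - 1, :-1] + S[codes[i - 1]], D[i - 1, 1:] + gi)
        D[i] = np.maximum.accumulate(tmp - cg) + cg
    ops: list[tuple] = []
    i, j = L, C
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(D[i, j] - (D[i - 1, j - 1] + S[codes[i - 1], j - 1])) <= eps:
            ops.append(("D", j - 1, seq[i - 1]))
            i -= 1
            j -= 1
        elif i > 0 and abs(D[i, j] - (D[i - 1, j] + gi)) <= eps:
            ops.append(("U", seq[i - 1]))
            i -= 1
        else:
            ops.append(("L", j - 1))
            j -= 1
    ops.reverse()
    return float(D[L, C]), ops


def refine_msa(
    msa: MultipleAlignment, params: AlignmentParams | None = None, max_rounds: int = 10
) -> MultipleAlignment:
    """Iterative leave-one-out refinement of a multiple alignment.

    Each round realigns every row, in order, against the profile of the
    remaining rows with an exact linear-gap DP; a realignment is accepted
    only if it improves the sum-of-pairs score, so the SP score is
    non-decreasing and the procedure stops at a fixed point or after
    ``max_rounds`` rounds.
    """
    params = params or msa.params or AlignmentParams()
    species = list(msa.species)
    rows = [list(r) for r in msa.rows]
    best_sp = sum_of_pairs(["".join(r) for r in rows], params)
    for _ in range(max_rounds):
        improved = False
        for k in range(len(rows)):
            seq = "".join(ch for ch in rows[k] if ch != "-")
            if not seq:
                continue
            others = [rows[i] for i in range(len(rows)) if i != k]
            others = [list(r) for r in others]
            _drop_all_gap_columns(others)
            prof_rows = ["".join(r) for r in others]
            _, ops = _profile_align(seq, prof_rows, params)
            new_rows_other = [[] for _ in others]
            new_row_self: list[str] = []
            for op in ops:
                if op[0] == "D":
                    _, j, ch = op
                    for t, r in enumerate(others):
                        new_rows_other[t].append(r[j])
                    new_row_self.append(ch)
                elif op[0] == "L":
                    j = op[1]
                    for t, r in enumerate(others):
                        new_rows_other[t].append(r[j])
                    new_row_self.append("-")
                else:  # 'U'
                    for t in range(len(others)):
                        new_rows_other[t].append("-")
                    new_row_self.append(op[1])
            candidate = []
            oi = 0
            for i in range(len(rows)):
                if i == k:
                    candidate.append(new_row_self)
                else:
                    candidate.append(new_rows_other[oi])
                    oi += 1
            _drop_all_gap_columns(candidate)
            sp = sum_of_pairs(["".join(r) for r in candidate], params)
            if sp > best_sp + 1e-9:
                rows = candidate
                best_sp = sp
                improved = True
        if not improved:
            break
    return MultipleAlignment(species, ["".join(r) for r in rows], params)


def mask_nonconserved(
    msa: MultipleAlignment,
    reference: str = REFERENCE_SPECIES,
    min_agree_frac: float = 0.5,
    min_run: int = 6,
    gene_id: str = "",
) -> MaskedConsensus:
    """Mask reference positions that are not conserved across the alignment.

    A reference position is kept when, in its column, the fraction of
    non-reference non-gap rows carrying the same base is at least
    ``min_agree_frac`` (``N`` never counts as agreement but does count as a
    covering row).  Kept runs shorter than ``min_run`` are masked as well.
    Columns where the reference has a gap are skipped, so the output has
    exactly the reference promoter's length.
    """
    ref_row = msa.row_for(reference)
    other_rows = [r for s, r in zip(msa.species, msa.rows) if s != reference]
    ref_len = sum(1 for ch in ref_row if ch != "-")
    if not other_rows:
        logger.warning("mask_nonconserved: single-row alignment, nothing masked")
        seq = ref_row.replace("-", "")
        return MaskedConsensus(gene_id, seq, list(msa.species), 0.0)
    keep = np.zeros(ref_len, dtype=bool)
    ref_bases: list[str] = []
    pos = 0
    for c, ch in enumerate(ref_row):
        if ch == "-":
            continue
        ref_bases.append(ch)
        if ch != "N":
            covering = 0
            agreeing = 0
            for r in other_rows:
                oc = r[c]
                if oc == "-":
                    continue
                covering += 1
                if oc == ch and oc != "N":
                    agreeing += 1
            if covering > 0 and agreeing / covering >= min_agree_frac:
                keep[pos] = True
        pos += 1
    # run-length rule: kept runs shorter than min_run are masked
    out = list("".join(ref_bases))
    i = 0
    n_kept = 0
    while i < ref_len:
        if not keep[i]:
            out[i] = "N"
            i += 1
            continue
        j = i
        while j < ref_len and keep[j]:
            j += 1
        if j - i < min_run:
            for t in range(i, j):
                out[t] = "N"
        else:
            n_kept += j - i
        i = j
    masked_seq = "".join(out)
    frac = 1.0 - n_kept / ref_len if ref_len else 0.0
    return MaskedConsensus(gene_id, masked_seq, list(msa.species), frac)


def mask_group(
    group: OrthologueGroup,
    params: AlignmentParams | None = None,
    min_score: float = 200.0,
    min_len: int = 500,
    max_len: int = 1000,
    min_agree_frac: float = 0.5,
    min_run: int = 6,
    refine_rounds: int = 2,
    reference: str = REFERENCE_SPECIES,
) -> MaskedConsensus:
    """Full conservation pipeline for one orthologue group.

    filter -> star alignment -> refinement -> masking.  Groups where no
    non-reference species survives the filter are returned unmasked with a
    warning (no cross-species evidence either way).
    """
    params = params or AlignmentParams()
    retained = filter_species(group, params, min_score, min_len, max_len, reference)
    msa = progressive_msa(group, retained, params, reference)
    if refine_rounds > 0 and len(retained) > 2:
        msa = refine_msa(msa, params, max_rounds=refine_rounds)
    return mask_nonconserved(msa, reference, min_agree_frac, min_run, group.gene_id)
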