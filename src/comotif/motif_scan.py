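"""Locating motifs in (masked) promoters.

Two complementary search modes are provided:

* **PWM mode** — log-odds scanning of both strands with a per-sequence
  p-value computed from the exact null distribution of the single-window
  score (dynamic programming over a discretized score lattice under the
  background model), corrected for the number of scanned windows as
  ``1 - (1 - p1)^m``, and an E-value ``p * n_sequences``.  This mirrors
  best-hit filtering in MAST-style searches, simplified to one motif at a
  time.  Windows containing ``N`` are skipped.

* **String mode** — consensus / bracketed-consensus matching with a
  width-dependent maximum substitution budget (the Weeder-locator
  schedule).  ``N`` in the sequence counts as a mismatch.  Hits on the
  minus strand are reported in forward coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import BASES, encode
from .motif_models import PWM, MotifModel

_SCORE_BINS = 1000  # lattice resolution: 1e-3 of the log-odds range


@dataclass
class MotifHit:
    seq_id: str
    position: int  # 0-based forward-strand start
    strand: str
    width: int
    mismatches: int | None = None
    score: float | None = None

    @property
    def end(self) -> int:
        return self.position + self.width


@dataclass
class SequenceScan:
    best_score: float | None
    p_value: float
    e_value: float
    n_windows: int


@dataclass
class ScanResult:
    motif_id: str
    per_sequence: dict[str, SequenceScan]
    hits: list[MotifHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PWM scanning with exact null score distribution

def _lattice(pwm: PWM, background: np.ndarray) -> tuple[np.ndarray, float]:
    lo = pwm.log_odds(background)
    rng = float(lo.max(axis=1).sum() - lo.min(axis=1).sum())
    delta = max(rng, 1e-9) / _SCORE_BINS
    K = np.rint(lo / delta).astype(np.int64)
    return K, delta


def _null_tail(K: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact distribution of the integer lattice score of a random window.

    Returns (probabilities, offset) where ``probabilities[s - offset]`` is
    the chance of lattice score ``s`` under the background model.
    """
    # column-by-column convolution over the 4 letters
    cur = np.zeros(1)
    cur[0] = 1.0
    cur_off = 0
    for j in range(K.shape[0]):
        kj = K[j]
        new_off = cur_off + int(kj.min())
        new = np.zeros(len(cur) + int(kj.max() - kj.min()))
        for b in range(4):
            shift = int(kj[b]) - int(kj.min())
            new[shift : shift + len(cur)] += cur * background[b]
        cur = new
        cur_off = new_off
    return cur, cur_off


def _window_scores(codes: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer lattice scores of all forward and reverse windows."""
    w = K.shape[0]
    if len(codes) < w:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    W = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(W == 4).any(axis=1)
    K5 = np.column_stack([K, np.full(w, np.iinfo(np.int32).min, dtype=np.int64)])
    idx = np.arange(w)[None, :]
    s_f = K5[idx, W].sum(axis=1)
    flipped = W[:, ::-1]
    W_rc = np.where(flipped == 4, 4, 3 - flipped)
    s_r = K5[idx, W_rc].sum(axis=1)
    s_f[~valid] = np.iinfo(np.int64).min
    s_r[~valid] = np.iinfo(np.int64).min
    return s_f, s_r


def pwm_scan_evalue(
    pwm: PWM | MotifModel,
    sequences: dict[str, str],
    background: np.ndarray | None = None,
    motif_id: str | None = None,
) -> ScanResult:
    """Best-hit E-value scan of a PWM over a set of sequences.

    For each sequence the best log-odds score over all N-free windows on
    both strands is converted to a p-value via the exact null score
    distribution and the number of windows scanned; the E-value is the
    p-value times the number of sequences scanned.  Sequences shorter
    than the motif (or fully masked) get p-value 1 and no best score.
    """
    if isinstance(pwm, MotifModel):
        motif_id = motif_id or pwm.motif_id
        pwm = pwm.pwm
    bg = np.asarray(background, float) if background is not None else pwm.background
    K, delta = _lattice(pwm, bg)
    w = K.shape[0]
    if sequences and all(len(s) < w for s in sequences.values()):
        raise ValueError("motif is wider than every sequence")
    dist, off = _null_tail(K, bg)
    tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])  # tail[s-off] = P(S >= s)
    n_seq = len(sequences)
    per_seq: dict[str, SequenceScan] = {}
    hits: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        codes = encode(seq.upper())
        s_f, s_r = _window_scores(codes, K)
        valid_f = s_f > np.iinfo(np.int64).min
        m = int(valid_f.sum()) * 2
        if m == 0:
            per_seq[seq_id] = SequenceScan(None, 1.0, float(n_seq), 0)
            continue
        best = int(max(s_f.max(), s_r.max()))
        idx = int(np.clip(best - off, 0, len(tail) - 1))
        p1 = float(tail[idx]) if best >= off else 1.0
        p1 = min(p1, 1.0)
        p_seq = 1.0 - (1.0 - p1) ** m
        per_seq[seq_id] = SequenceScan(best * delta, p_seq, p_seq * n_seq, m)
        strand, pos = ("+", int(s_f.argmax())) if s_f.max() >= s_r.max() else ("-", int(s_r.argmax()))
        hits.append(MotifHit(seq_id, pos, strand, w, score=best * delta))
    return ScanResult(motif_id or "pwm", per_seq, hits)


# ---------------------------------------------------------------------------
# String matching under the substitution schedule

_SCHEDULE = {6: 1, 8: 1, 10: 2, 12: 2, 14: 3, 16: 3, 18: 4}


def substitution_budget(width: int) -> int:
    """Maximum substitutions allowed per hit as a function of motif width.

    Listed widths: 6,8 -> 1; 10,12 -> 2; 14,16 -> 3; 18 -> 4.  Unlisted
    widths inherit the schedule of the nearest lower listed width; widths
    below 6 allow no substitutions.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    lower = [k for k in _SCHEDULE if k <= width]
    if not lower:
        return 0
    return _SCHEDULE[max(lower)]


_BRACKET_RE = re.compile(r"\[([ACGT]+)\]|([ACGT])", re.IGNORECASE)


def parse_motif_pattern(motif: str) -> list[frozenset[str]]:
    """Parse a plain or bracketed consensus into per-position letter sets."""
    sets: list[frozenset[str]] = []
    pos = 0
    for m in _BRACKET_RE.finditer(motif):
        if m.start() != pos:
            raise ValueError(f"cannot parse motif pattern {motif!r}")
        pos = m.end()
        letters = (m.group(1) or m.group(2)).upper()
        sets.append(frozenset(letters))
    if pos != len(motif):
        raise ValueError(f"cannot parse motif pattern {motif!r}")
    return sets


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp_pattern(sets: list[frozenset[str]]) -> list[frozenset[str]]:
    return [frozenset(_COMP[ch] for ch in s) for s in reversed(sets)]


def _allowed_matrix(sets: list[frozenset[str]]) -> np.ndarray:
    allowed = np.zeros((len(sets), 5), dtype=bool)
    for j, s in enumerate(sets):
        for ch in s:
            allowed[j, BASES.index(ch)] = True
    return allowed  # column 4 (N) stays False: N never matches


def locate_with_substitutions(
    motif: str | MotifModel,
    sequence: str,
    budget: int | None = None,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[MotifHit]:
    """All offsets where the motif matches with at most ``budget`` mismatches.

    ``motif`` may be a plain consensus, a bracketed degenerate consensus,
    or a MotifModel (its ambiguous consensus is used).  ``budget`` defaults
    to the width schedule.  Overlapping hits are all reported; minus-strand
    hits carry forward-strand start coordinates.
    """
    if isinstance(motif, MotifModel):
        pattern = motif.ambiguous_consensus or motif.consensus
    else:
        pattern = motif
    sets = parse_motif_pattern(pattern)
    w = len(sets)
    if budget is None:
        budget = substitution_budget(w)
    codes = encode(sequence.upper())
    if len(codes) < w:
        return []
    W = np.lib.stride_tricks.sliding_window_view(codes, w)
    idx = np.arange(w)[None, :]
    hits: list[MotifHit] = []
    patterns = [("+", _allowed_matrix(sets))]
    if both_strands:
        patterns.append(("-", _allowed_matrix(_revcomp_pattern(sets))))
    for strand, allowed in patterns:
        mism = (~allowed[idx, W]).sum(axis=1)
        for pos in np.nonzero(mism <= budget)[0]:
            hits.append(MotifHit(seq_id, int(pos), strand, w, mismatches=int(mism[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def select_mafb_binding_genes(
    scans: dict[str, dict[str, dict[str, tuple[float, int]]]],
    conserved_species: tuple[str, ...] = ("mouse", "human"),
    e_threshold: float = 21.0,
    reference: str = "mouse",
) -> list[str]:
    """Genes whose promoters carry a MafB motif conserved across species.

    ``scans[species][gene][motif_id] = (e_value, n_hits)``.  A gene is
    kept iff the minimum E-value over MafB motifs in the reference species
    is strictly below ``e_threshold`` and every species in
    ``conserved_species`` has at least one hit of some MafB motif.
    Missing scans raise ``KeyError`` naming the gene.
    """
    if reference not in scans:
        raise KeyError(f"no scans for reference species {reference!r}")
    kept: list[str] = []
    for gene in sorted(scans[reference]):
        evals = [e for e, _ in scans[reference][gene].values()]
        if not evals or min(evals) >= e_threshold:
            continue
        conserved = True
        for sp in conserved_species:
            if sp not in scans or gene not in scans[sp]:
                raise KeyError(f"gene {gene!r}: missing scan for species {sp!r}")
            if not any(n > 0 for _, n in scans[sp][gene].values()):
                conserved = False
                break
        if conserved:
            kept.append(gene)
    return kept


def write_hits_bed(hits: list[MotifHit], motif_id: str, path) -> None:
    """BED-like TSV: seq_id, start, end, motif_id, mismatches-or-score, strand."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.seq_id, h.position, h.strand)):
            value = h.mismatches if h.mismatches is not None else f"{h.score:.4f}"
            fh.write(f"{h.seq_id}\t{h.position}\t{h.end}\t{motif_id}\t{value}\t{h.strand}\n")
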