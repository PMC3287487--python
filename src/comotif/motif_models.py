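"""De novo motif discovery with a ZOOPS EM finder.

The model is the classic "zero or one occurrence per sequence" mixture:
each sequence either contains no site (probability ``1-gamma``) or exactly
one site drawn uniformly over all valid start positions on either strand,
with site letters emitted by a position weight matrix (PWM) and all other
letters by a background multinomial.  EM alternates site-posterior
computation (E) with PWM / site-prior re-estimation (M); the log
likelihood is checked to be non-decreasing at every iteration.

Seeding is deterministic: candidate width-mers from the input are ranked
by their exact occurrence count on both strands, the top ``seed_pool``
seeds are scored with a single EM iteration, and the best ``n_refine``
are run to convergence; ties break lexicographically on the consensus, so
results are reproducible without a random seed.  ``seed_pool=None``
evaluates every distinct width-mer (practical only for small inputs).

The final model is reported in the orientation of the majority of its
sites' strands (lexicographically smaller consensus on a tie).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._alphabet import BASES, encode, revcomp

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.25
MAFB_WIDTHS = (8, 9, 10, 11)
DISCOVERY_WIDTHS = (6, 8, 10, 12, 14, 16, 18)


@dataclass
class PWM:
    """Position weight matrix: per-column probabilities over A,C,G,T."""

    probs: np.ndarray  # (width, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("PWM needs shape (width, 4) with width >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be positive (apply a pseudocount)")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def consensus(self) -> str:
        return "".join(BASES[int(i)] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background.copy(), self.pseudocount)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = self.background if background is None else np.asarray(background, float)
        return np.log(self.probs) - np.log(bg)[None, :]


@dataclass
class MotifModel:
    """A discovered (or known) motif with its PWM and site list."""

    motif_id: str
    pwm: PWM
    consensus: str
    ambiguous_consensus: str
    sites: list[tuple[str, int, str]] = field(default_factory=list)  # (seq_id, offset, strand)
    score: float = 0.0
    is_mafb: bool = False

    def __post_init__(self) -> None:
        if len(self.consensus) != self.pwm.width:
            raise ValueError("consensus length must equal PWM width")


def ambiguous_consensus(pwm: PWM, include_threshold: float = 0.2) -> str:
    """Bracketed degenerate consensus.

    Per column, every letter with probability >= ``include_threshold`` is
    listed in decreasing-probability order (ties alphabetical); a single
    qualifying letter is emitted bare, multiple letters in brackets.  If no
    letter qualifies the single most probable letter is emitted.
    """
    parts = []
    for col in pwm.probs:
        order = sorted(range(4), key=lambda i: (-col[i], BASES[i]))
        chosen = [i for i in order if col[i] >= include_threshold]
        if not chosen:
            chosen = [order[0]]
        letters = "".join(BASES[i] for i in chosen)
        parts.append(letters if len(letters) == 1 else f"[{letters}]")
    return "".join(parts)


class _SeqData:
    """Per-sequence window codes for EM (forward and reverse-complement)."""

    def __init__(self, seq_id: str, seq: str, width: int):
        self.seq_id = seq_id
        codes = encode(seq)
        self.length = len(codes)
        if self.length >= width:
            W = np.lib.stride_tricks.sliding_window_view(codes, width)
            self.W = np.ascontiguousarray(W)
        else:
            self.W = np.zeros((0, width), dtype=codes.dtype)
        flipped = self.W[:, ::-1]
        self.W_rc = np.where(flipped == 4, 4, 3 - flipped).astype(self.W.dtype)
        self.valid = ~(self.W == 4).any(axis=1)
        self.m = self.W.shape[0]
        self.n_valid = int(self.valid.sum())


def _estimate_background(seqs: list[str]) -> np.ndarray:
    counts = np.full(4, 1.0)
    for s in seqs:
        c = encode(s)
        counts += np.bincount(c[c < 4], minlength=4)
    return counts / counts.sum()


def _window_logratio(data: _SeqData, logratio5: np.ndarray, revcomp_ok: bool):
    w = logratio5.shape[0]
    idx = np.arange(w)[None, :]
    s_f = logratio5[idx, data.W].sum(axis=1)
    s_f[~data.valid] = -np.inf
    if revcomp_ok:
        s_r = logratio5[idx, data.W_rc].sum(axis=1)
        s_r[~data.valid] = -np.inf
    else:
        s_r = np.full_like(s_f, -np.inf)
    return s_f, s_r


def _em(
    datas: list[_SeqData],
    init_probs: np.ndarray,
    background: np.ndarray,
    revcomp_ok: bool,
    pseudocount: float,
    gamma0: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """Run ZOOPS EM to convergence; returns (probs, gamma, loglik, posteriors).

    ``loglik`` is the log likelihood ratio against the background-only
    model (the background term is constant and cancels).
    """
    probs = init_probs.copy()
    gamma = gamma0
    w = probs.shape[0]
    log_bg = np.log(background)
    prev_ll = -np.inf
    prev_pen = -np.inf
    post: list[tuple[np.ndarray, np.ndarray, float]] = []
    n_strands = 2 if revcomp_ok else 1
    for _ in range(max_iter):
        logratio = np.log(probs) - log_bg[None, :]
        logratio5 = np.column_stack([logratio, np.full(w, -1e30)])
        ll = 0.0
        post = []
        counts = np.zeros((w, 5))  # 5th column absorbs N codes (always weight 0)
        counts[:, :4] = pseudocount
        gamma_sum = 0.0
        n_seq = 0
        for data in datas:
            if data.n_valid == 0:
                post.append((np.zeros(data.m), np.zeros(data.m), 1.0))
                continue
            n_seq += 1
            s_f, s_r = _window_logratio(data, logratio5, revcomp_ok)
            denom = n_strands * data.n_valid
            r_f = np.exp(s_f) * (gamma / denom)
            r_r = np.exp(s_r) * (gamma / denom)
            z0w = 1.0 - gamma
            norm = z0w + r_f.sum() + r_r.sum()
            ll += np.log(norm)
            p_f = r_f / norm
            p_r = r_r / norm
            z0 = z0w / norm
            post.append((p_f, p_r, z0))
            gamma_sum += 1.0 - z0
            for j in range(w):
                np.add.at(counts[j], data.W[:, j], p_f)
                np.add.at(counts[j], data.W_rc[:, j], p_r)
        # With pseudocounts the M-step is a Dirichlet-MAP update, so the
        # monotone EM objective is the likelihood plus the Dirichlet prior
        # term, not the raw likelihood.
        penalized = ll + pseudocount * float(np.log(probs).sum())
        if penalized < prev_pen - 1e-6 * (abs(prev_pen) + 1.0):
            raise AssertionError("EM objective decreased")
        prev_pen = penalized
        counts = counts[:, :4]
        probs = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(gamma_sum / max(n_seq, 1), 1e-6, 1.0 - 1e-6))
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            prev_ll = ll
            break
        prev_ll = ll
    return probs, gamma, float(prev_ll), post


def _seed_pwm(word: str, background: np.ndarray, match_p: float = 0.7) -> np.ndarray:
    codes = encode(word)
    probs = np.full((len(word), 4), (1.0 - match_p) / 3.0)
    for j, c in enumerate(codes):
        probs[j, c] = match_p
    return probs


def discover_motif_zoops(
    sequences: list[str],
    width: int,
    revcomp_ok: bool = True,
    seq_ids: list[str] | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed_pool: int | None = 100,
    n_refine: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
    motif_id: str | None = None,
) -> MotifModel:
    """Discover the single best ZOOPS motif of the given width.

    Raises ``ValueError`` when any sequence is shorter than ``width`` or
    fewer than two sequences are supplied.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if min(len(s) for s in sequences) < width:
        raise ValueError("width exceeds the shortest sequence")
    ids = seq_ids if seq_ids is not None else [str(i) for i in range(len(sequences))]
    bg = _estimate_background(sequences) if background is None else np.asarray(background, float)
    datas = [_SeqData(i, s.upper(), width) for i, s in zip(ids, sequences)]
    if all(d.n_valid == 0 for d in datas):
        raise ValueError("no scannable (N-free) window of the requested width")

    # --- deterministic seeding -------------------------------------------
    word_counts: Counter[str] = Counter()
    for data, s in zip(datas, sequences):
        su = s.upper()
        for p in np.nonzero(data.valid)[0]:
            word_counts[su[p : p + width]] += 1
    def both_strand_count(word: str) -> int:
        return word_counts[word] + word_counts[revcomp(word)] if revcomp_ok else word_counts[word]

    candidates = sorted(word_counts, key=lambda w_: (-both_strand_count(w_), w_))
    if seed_pool is not None:
        candidates = candidates[:seed_pool]
    scored: list[tuple[float, str]] = []
    for word in candidates:
        probs0 = _seed_pwm(word, bg)
        _, _, ll1, _ = _em(datas, probs0, bg, revcomp_ok, pseudocount, max_iter=1)
        scored.append((ll1, word))
    scored.sort(key=lambda t: (-t[0], t[1]))
    best = None
    for ll1, word in scored[:n_refine]:
        probs0 = _seed_pwm(word, bg)
        probs, gamma, ll, post = _em(
            datas, probs0, bg, revcomp_ok, pseudocount, tol=tol, max_iter=max_iter
        )
        cons = "".join(BASES[i] for i in probs.argmax(axis=1))
        key = (-ll, cons)
        if best is None or key < best[0]:
            best = (key, probs, gamma, ll, post)
    assert best is not None
    _, probs, gamma, ll, post = best

    # --- site calls and canonical orientation ----------------------------
    sites: list[tuple[str, int, str]] = []
    for data, (p_f, p_r, z0) in zip(datas, post):
        if 1.0 - z0 <= 0.5 or data.m == 0:
            continue
        best_f = int(p_f.argmax()) if p_f.size else 0
        best_r = int(p_r.argmax()) if p_r.size else 0
        if p_r.size and p_r[best_r] > p_f[best_f]:
            sites.append((data.seq_id, best_r, "-"))
        else:
            sites.append((data.seq_id, best_f, "+"))
    n_minus = sum(1 for s in sites if s[2] == "-")
    pwm = PWM(probs, bg, pseudocount)
    flip = False
    if 2 * n_minus > len(sites):
        flip = True
    elif 2 * n_minus == len(sites) and sites:
        flip = pwm.reverse_complement().consensus() < pwm.consensus()
    if flip:
        pwm = pwm.reverse_complement()
        sites = [(sid, off, "-" if st == "+" else "+") for sid, off, st in sites]
    cons = pwm.consensus()
    return MotifModel(
        motif_id=motif_id or f"{width}-1",
        pwm=pwm,
        consensus=cons,
        ambiguous_consensus=ambiguous_consensus(pwm),
        sites=sites,
        score=ll,
    )


def discover_motif_set(
    sequences: list[str],
    widths: tuple[int, ...] = DISCOVERY_WIDTHS,
    per_width: int = 10,
    seq_ids: list[str] | None = None,
    **kwargs,
) -> list[MotifModel]:
    """Iterative multi-width discovery with site masking.

    For each width, motifs are discovered one at a time; after each
    discovery the called sites are replaced with ``N`` so the next rank
    finds a different signal.  Motif ids follow the ``width-rank`` naming
    convention (``"10-3"`` is the third-ranked width-10 motif).  At most
    ``per_width * len(widths)`` motifs are returned.
    """
    ids = seq_ids if seq_ids is not None else [str(i) for i in range(len(sequences))]
    motifs: list[MotifModel] = []
    for width in widths:
        work = [s.upper() for s in sequences]
        for rank in range(1, per_width + 1):
            try:
                model = discover_motif_zoops(
                    work, width, seq_ids=ids, motif_id=f"{width}-{rank}", **kwargs
                )
            except ValueError:
                break
            motifs.append(model)
            if not model.sites:
                break
            by_id = {sid: k for k, sid in enumerate(ids)}
            for sid, off, _strand in model.sites:
                k = by_id[sid]
                s = work[k]
                work[k] = s[:off] + "N" * width + s[off + width :]
    return motifs


# ---------------------------------------------------------------------------
# Known MafB binding sequences (biochemically confirmed MARE-carrying sites)

def mafb_binding_sequences() -> list[str]:
    """The nine biochemically confirmed MafB binding sequences (bundled)."""
    text = resources.files("comotif.data").joinpath("mafb_sites.fasta").read_text()
    seqs = []
    cur: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if cur:
                seqs.append("".join(cur))
                cur = []
        elif line.strip():
            cur.append(line.strip().upper())
    if cur:
        seqs.append("".join(cur))
    return seqs


def extract_mafb_motifs(
    binding_sequences: list[str] | None = None,
    widths: tuple[int, ...] = MAFB_WIDTHS,
    **kwargs,
) -> list[MotifModel]:
    """Build one MafB motif model per width from the binding sequences.

    The AT-rich extension sits ~3 nt upstream of the 6-bp MARE core, hence
    the default widths 8..11.  Models are tagged ``is_mafb=True`` so
    downstream merge rules leave them alone.
    """
    seqs = binding_sequences if binding_sequences is not None else mafb_binding_sequences()
    kwargs.setdefault("seed_pool", None)  # small input: exhaustive seeding
    motifs = []
    for width in widths:
        m = discover_motif_zoops(seqs, width, motif_id=f"mafb-{width}", **kwargs)
        m.is_mafb = True
        motifs.append(m)
    return motifs


# ---------------------------------------------------------------------------
# Motif text format: one block per motif

def write_motifs(motifs: list[MotifModel], path: str | Path) -> None:
    lines: list[str] = []
    for m in motifs:
        lines.append(f">{m.motif_id}\twidth={m.pwm.width}\tscore={m.score:.6g}\tmafb={int(m.is_mafb)}")
        lines.append(f"consensus\t{m.consensus}")
        lines.append(f"ambiguous\t{m.ambiguous_consensus}")
        for b, base in enumerate(BASES):
            row = "\t".join(f"{p:.6f}" for p in m.pwm.probs[:, b])
            lines.append(f"{base}\t{row}")
        bgl = "\t".join(f"{p:.6f}" for p in m.pwm.background)
        lines.append(f"background\t{bgl}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_motifs(path: str | Path) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    block: dict = {}

    def flush():
        if not block:
            return
        probs = np.column_stack([block[b] for b in BASES])
        probs = probs / probs.sum(axis=1, keepdims=True)
        pwm = PWM(probs, np.asarray(block.get("background", [0.25] * 4)))
        motifs.append(
            MotifModel(
                motif_id=block["id"],
                pwm=pwm,
                consensus=block["consensus"],
                ambiguous_consensus=block["ambiguous"],
                score=block.get("score", 0.0),
                is_mafb=block.get("mafb", False),
            )
        )

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            block = {"id": line[1:].split("\t")[0]}
            for tok in line.split("\t")[1:]:
                k, _, v = tok.partition("=")
                if k == "score":
                    block["score"] = float(v)
                elif k == "mafb":
                    block["mafb"] = bool(int(v))
        else:
            key, *vals = line.split("\t")
            if key in ("consensus", "ambiguous"):
                block[key] = vals[0]
            elif key in BASES or key == "background":
                block[key] = np.array([float(v) for v in vals])
    flush()
    return motifs
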