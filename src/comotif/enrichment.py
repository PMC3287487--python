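"""Over-representation scoring and the binary occurrence matrix.

The Over-Representation Index (ORI) combines two signals: how much more
frequently a motif occurs in the down-regulated promoters than in the
non-regulated ones (group-size-normalised occurrence-rate ratio) and how
evenly those occurrences spread across the down-regulated promoters
(fraction of down-regulated promoters carrying at least one occurrence).
A score above 1 indicates over-representation; a high score indicates the
motif is present in most down-regulated promoters rather than piled into
a few.

    ORI = ((Patt_p / S_p) / (max(Patt_np, 1) / S_np)) * (N_p / N_promoter)

where ``Patt_p``/``Patt_np`` are total occurrence counts in the
down-regulated / non-regulated promoter groups, ``S_p``/``S_np`` the
numbers of promoters scanned in each group, ``N_p`` the number of
down-regulated promoters containing the motif and ``N_promoter`` the
total number of down-regulated promoters.  The ``max(.,1)`` pseudocount
keeps a motif absent from the non-regulated group finite; a "+1
smoothing" variant is selectable.

Occurrence matrices use the {1 = absent, 2 = present} coding in all I/O
for fidelity with the downstream log-linear analysis inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._alphabet import revcomp
from .motif_models import MotifModel
from .motif_scan import locate_with_substitutions, substitution_budget

logger = logging.getLogger(__name__)

ABSENT, PRESENT = 1, 2


@dataclass
class ORIInputs:
    patt_p: int
    patt_np: int
    n_p: int
    n_promoter: int
    s_p: int
    s_np: int

    def __post_init__(self) -> None:
        vals = (self.patt_p, self.patt_np, self.n_p, self.n_promoter, self.s_p, self.s_np)
        if any(v < 0 for v in vals):
            raise ValueError("ORI inputs must be non-negative")
        if self.n_p > self.n_promoter:
            raise ValueError("n_p cannot exceed n_promoter")
        if self.n_p > 0 and self.patt_p < self.n_p:
            # holds for raw hit counts; normalized counts may break it
            logger.warning(
                "patt_p (%s) < n_p (%s): inputs look normalized rather than raw",
                self.patt_p,
                self.n_p,
            )


@dataclass
class OccurrenceMatrix:
    """Genes x motifs presence table with {1,2} coding and group labels."""

    values: pd.DataFrame  # int entries in {1, 2}
    groups: pd.Series  # per-gene label: "down" | "nonreg"

    def __post_init__(self) -> None:
        bad = ~self.values.isin([ABSENT, PRESENT]).all(axis=None)
        if bad:
            raise ValueError("occurrence matrix entries must be 1 (absent) or 2 (present)")
        if self.values.isna().any(axis=None):
            raise ValueError("occurrence matrix has missing cells")
        self.groups = self.groups.reindex(self.values.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.values.columns)

    def down_genes(self) -> list[str]:
        return list(self.groups[self.groups == "down"].index)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "OccurrenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
        groups = df.pop("group")
        return cls(df.astype(int), groups)


def count_occurrences(
    motif: MotifModel | str, promoters: dict[str, str], budget: int | None = None
) -> tuple[int, int]:
    """Total hit count and number of promoters with >= 1 hit.

    Hits are counted on both strands with the width substitution schedule
    (unless ``budget`` overrides it).
    """
    if not promoters:
        raise ValueError("no promoters to scan")
    patt = 0
    n_with = 0
    for gene, seq in promoters.items():
        hits = locate_with_substitutions(motif, seq, budget=budget, seq_id=gene)
        patt += len(hits)
        n_with += bool(hits)
    return patt, n_with


def compute_ori(inputs: ORIInputs, variant: str = "max1") -> float:
    """Evaluate the ORI score; see the module docstring for the formula."""
    if min(inputs.s_p, inputs.s_np, inputs.n_promoter) <= 0:
        raise ValueError("s_p, s_np and n_promoter must be positive")
    if variant == "max1":
        denom = max(inputs.patt_np, 1) / inputs.s_np
        rate_p = inputs.patt_p / inputs.s_p
    elif variant == "plus1":
        denom = (inputs.patt_np + 1) / inputs.s_np
        rate_p = (inputs.patt_p + 1) / inputs.s_p
    else:
        raise ValueError(f"unknown ORI variant {variant!r}")
    return (rate_p / denom) * (inputs.n_p / inputs.n_promoter)


def score_motifs(
    motifs: list[MotifModel],
    down_promoters: dict[str, str],
    nonreg_promoters: dict[str, str],
    variant: str = "max1",
) -> pd.DataFrame:
    """ORI table for a motif list: one row per motif with counts and score."""
    rows = []
    for m in motifs:
        budget = substitution_budget(m.pwm.width)
        patt_p, n_p = count_occurrences(m, down_promoters, budget)
        patt_np, _ = count_occurrences(m, nonreg_promoters, budget)
        inputs = ORIInputs(
            patt_p=patt_p,
            patt_np=patt_np,
            n_p=n_p,
            n_promoter=len(down_promoters),
            s_p=len(down_promoters),
            s_np=len(nonreg_promoters),
        )
        rows.append(
            {
                "motif_id": m.motif_id,
                "width": m.pwm.width,
                "consensus": m.consensus,
                "is_mafb": m.is_mafb,
                "patt_p": patt_p,
                "patt_np": patt_np,
                "n_p": n_p,
                "n_promoter": len(down_promoters),
                "ori": compute_ori(inputs, variant),
            }
        )
    return pd.DataFrame(rows)


def rank_candidates(ori_table: pd.DataFrame, top_k: int = 10) -> list[str]:
    """Top-k motif ids by descending ORI.

    Ties break by (width ascending, motif_id lexicographic) and are
    logged.  If fewer motifs than ``top_k`` are available all are
    returned with a warning.
    """
    if len(ori_table) < top_k:
        logger.warning("only %d motifs available for top_k=%d", len(ori_table), top_k)
    ranked = ori_table.sort_values(
        ["ori", "width", "motif_id"], ascending=[False, True, True], kind="mergesort"
    )
    chosen = ranked.head(top_k)
    if len(ranked) > top_k:
        cutoff = chosen["ori"].iloc[-1]
        ties = ranked[ranked["ori"] == cutoff]
        if len(ties) > (chosen["ori"] == cutoff).sum():
            logger.info(
                "ORI tie at %.6g broken by (width, motif_id): %s",
                cutoff,
                ", ".join(ties["motif_id"]),
            )
    return list(chosen["motif_id"])


def build_occurrence_matrix(
    candidates: list[MotifModel],
    promoters: dict[str, str],
    groups: dict[str, str],
) -> OccurrenceMatrix:
    """Presence (2) / absence (1) of each candidate in every promoter."""
    data = {}
    genes = sorted(promoters)
    for m in candidates:
        budget = substitution_budget(m.pwm.width)
        col = []
        for gene in genes:
            hits = locate_with_substitutions(m, promoters[gene], budget=budget, seq_id=gene)
            col.append(PRESENT if hits else ABSENT)
        data[m.motif_id] = col
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene"), dtype=int)
    group_s = pd.Series({g: groups[g] for g in genes}, name="group")
    return OccurrenceMatrix(values, group_s)


def _related_consensi(a: str, b: str) -> bool:
    """True when two consensi are reverse complements or substrings."""
    rb = revcomp(b)
    return a == rb or a in b or b in a or a in rb or rb in a


def merge_equivalent_motifs(
    matrix: OccurrenceMatrix, candidates: list[MotifModel]
) -> tuple[OccurrenceMatrix, dict[str, list[str]]]:
    """Merge columns carrying the same signal through related sequences.

    Two columns merge when their occurrence vectors are identical AND
    their consensi are reverse complements or one is a substring of the
    other (or of its reverse complement).  MafB-tagged motifs are never
    merged.  Returns the reduced matrix and a map representative ->
    merged member ids (representative included).
    """
    by_id = {m.motif_id: m for m in candidates}
    order = [c for c in matrix.values.columns]
    merged: dict[str, list[str]] = {}
    used: set[str] = set()
    for i, a in enumerate(order):
        if a in used:
            continue
        members = [a]
        used.add(a)
        if not by_id[a].is_mafb:
            for b in order[i + 1 :]:
                if b in used or by_id[b].is_mafb:
                    continue
                if matrix.values[a].equals(matrix.values[b]) and _related_consensi(
                    by_id[a].consensus, by_id[b].consensus
                ):
                    members.append(b)
                    used.add(b)
        merged[a] = members
    values = matrix.values[[rep for rep in merged]].copy()
    return OccurrenceMatrix(values, matrix.groups.copy()), merged


def write_ori_table(ori_table: pd.DataFrame, path) -> None:
    ori_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
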