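"""Promoter sequence and expression-table I/O.

Promoter FASTA dialect
----------------------
Each record header encodes ``gene_id|species|tss_index`` where
``tss_index`` is the 0-based position of the transcription start site
within the record sequence.  Promoters exported from TSS databases are
usually pre-windowed to -2000/+300 around the TSS, so a missing third
field defaults to ``tss_index = 2000``.

Expression tables are two-signal TSV files (``gene_id``, ``wt_signal``,
``ko_signal``); gene classification follows knockout/wild-type signal
ratios: down-regulated below 0.5, non-regulated at 1.0 (with an optional
tolerance, since real array ratios never hit 1.0 exactly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import normalize

logger = logging.getLogger(__name__)

DEFAULT_TSS_INDEX = 2000
REFERENCE_SPECIES = "mouse"


class FastaHeaderError(ValueError):
    """Raised when a promoter FASTA header does not follow the dialect."""


@dataclass
class PromoterRecord:
    """One species' promoter sequence for one gene.

    ``sequence`` is upper-case over ``ACGTN``; ``tss_index`` is the 0-based
    position of the transcription start site within ``sequence``.
    """

    gene_id: str
    species: str
    sequence: str
    tss_index: int = DEFAULT_TSS_INDEX

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}/{self.species}: empty sequence")
        if not (0 <= self.tss_index < len(self.sequence)):
            raise ValueError(
                f"{self.gene_id}/{self.species}: tss_index {self.tss_index} "
                f"outside sequence of length {len(self.sequence)}"
            )

    @property
    def fasta_id(self) -> str:
        return f"{self.gene_id}|{self.species}|{self.tss_index}"


@dataclass
class OrthologueGroup:
    """Orthologous promoters for one gene, keyed by species."""

    gene_id: str
    members: dict[str, PromoterRecord] = field(default_factory=dict)

    def require_reference(self, reference: str = REFERENCE_SPECIES) -> PromoterRecord:
        if reference not in self.members:
            raise KeyError(f"group {self.gene_id} lacks reference species {reference!r}")
        return self.members[reference]


@dataclass
class ExpressionRecord:
    gene_id: str
    wt_signal: float
    ko_signal: float


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoter records from FASTA under the ``gene|species|tss`` dialect.

    Sequences are upper-cased and non-ACGTN characters become ``N`` (the
    number of substitutions is logged).  An empty file yields an empty list.
    """
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    total_subs = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 2:
            gene_id, species = parts
            tss = DEFAULT_TSS_INDEX
        elif len(parts) == 3:
            gene_id, species = parts[0], parts[1]
            try:
                tss = int(parts[2])
            except ValueError as exc:
                raise FastaHeaderError(
                    f"record {rec.id!r}: third header field must be an integer TSS index"
                ) from exc
        else:
            raise FastaHeaderError(
                f"record {rec.id!r}: expected 'gene|species[|tss]' header"
            )
        if rec.id in seen:
            raise FastaHeaderError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq, n_sub = normalize(str(rec.seq))
        total_subs += n_sub
        if len(seq) <= tss:
            # Pre-windowed records shorter than the default window keep a
            # clamped TSS so short test sequences remain usable.
            tss = max(0, len(seq) - 1) if len(parts) == 2 else tss
        records.append(PromoterRecord(gene_id, species, seq, tss))
    if total_subs:
        logger.info("read_fasta(%s): substituted %d non-ACGTN characters with N", path, total_subs)
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.fasta_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def extract_promoter_window(
    record: PromoterRecord, upstream: int = 2000, downstream: int = 300
) -> str:
    """Return the promoter window ``[tss-upstream, tss+downstream)``.

    Half-open and 0-based: a full-length window has ``upstream+downstream``
    nucleotides; bounds are clipped to the sequence, so truncated promoters
    yield shorter (possibly empty) windows rather than errors.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    start = max(0, record.tss_index - upstream)
    end = min(len(record.sequence), record.tss_index + downstream)
    return record.sequence[start:end] if end > start else ""


def classify_genes(
    records: Sequence[ExpressionRecord],
    down_threshold: float = 0.5,
    nonreg_value: float = 1.0,
    nonreg_tol: float = 0.0,
    manual_down: Iterable[str] = (),
) -> tuple[set[str], set[str]]:
    """Split genes into down-regulated and non-regulated sets by KO/WT ratio.

    A gene is down-regulated when ``ko/wt < down_threshold`` (under half of
    wild-type expression at the default) and non-regulated when
    ``|ko/wt - nonreg_value| <= nonreg_tol``.  ``manual_down`` forces genes
    into the down-regulated set regardless of their ratio (a hook for genes
    known to be mis-measured on the array).  Records with ``wt_signal <= 0``
    are excluded with a warning.
    """
    down: set[str] = set()
    nonreg: set[str] = set()
    for rec in records:
        if rec.wt_signal <= 0:
            logger.warning("gene %s: non-positive wild-type signal, excluded", rec.gene_id)
            continue
        ratio = rec.ko_signal / rec.wt_signal
        if ratio < down_threshold:
            down.add(rec.gene_id)
        elif abs(ratio - nonreg_value) <= nonreg_tol:
            nonreg.add(rec.gene_id)
    down.update(manual_down)
    nonreg -= down
    return down, nonreg


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene_id, wt_signal, ko_signal."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "wt_signal", "ko_signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    return [
        ExpressionRecord(str(r.gene_id), float(r.wt_signal), float(r.ko_signal))
        for r in df.itertuples(index=False)
    ]


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.wt_signal, r.ko_signal) for r in records],
        columns=["gene_id", "wt_signal", "ko_signal"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_orthologue_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV mapping gene_id, species -> fasta_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "species", "fasta_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"orthologue table needs columns {sorted(required)}")
    return df


def group_orthologues(
    records: Sequence[PromoterRecord],
    table: pd.DataFrame | None = None,
    reference: str = REFERENCE_SPECIES,
) -> list[OrthologueGroup]:
    """Assemble orthologue groups from promoter records.

    Without a table, records sharing a ``gene_id`` form a group (one record
    per species).  With an orthologue table, the table's (gene_id, species,
    fasta_id) rows define membership, so cross-named orthologues can be
    grouped.  Groups lacking the reference species are dropped with a
    warning.
    """
    if table is None:
        by_gene: dict[str, dict[str, PromoterRecord]] = {}
        for rec in records:
            members = by_gene.setdefault(rec.gene_id, {})
            if rec.species in members:
                raise ValueError(
                    f"gene {rec.gene_id}: duplicate species {rec.species!r}"
                )
            members[rec.species] = rec
        groups = [OrthologueGroup(g, m) for g, m in by_gene.items()]
    else:
        by_id = {r.fasta_id: r for r in records}
        by_gene = {}
        for row in table.itertuples(index=False):
            rec = by_id.get(row.fasta_id)
            if rec is None:
                raise KeyError(f"orthologue table refers to unknown record {row.fasta_id!r}")
            members = by_gene.setdefault(row.gene_id, {})
            members[row.species] = rec
        groups = [OrthologueGroup(g, m) for g, m in by_gene.items()]
    kept = []
    for grp in groups:
        if reference not in grp.members:
            logger.warning("gene %s: no %s promoter, group dropped", grp.gene_id, reference)
            continue
        kept.append(grp)
    kept.sort(key=lambda g: g.gene_id)
    return kept
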