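"""End-to-end orchestration of the three-step analysis.

Step 1 — classify genes from the expression table, mask non-conserved
promoter positions across orthologues, extract the MafB motif models
from the nine confirmed binding sequences and select the MafB binding
gene set (E-value below threshold in mouse, hit conserved in mouse and
human).  Step 2 — discover a multi-width motif set in the masked
promoters of that gene set and rank all motifs (discovered + MafB) by
ORI against the non-regulated promoters.  Step 3 — build the binary
occurrence matrix of the top candidates over every gene, merge
equivalent columns, fit the log-linear graphical model by backward
elimination and emit the independence graph, motif combinations and the
star table.

Every artifact carries the config hash in a header comment; reruns with
the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import conservation, enrichment, lgm, motif_models, motif_scan, promoter_io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their study-default constants."""

    promoters_fasta: str = ""
    orthologues_tsv: str = ""
    expression_tsv: str = ""
    outdir: str = "comotif_run"
    seed: int = 0
    # Step 1
    upstream: int = 2000
    downstream: int = 300
    down_threshold: float = 0.5
    nonreg_value: float = 1.0
    nonreg_tol: float = 0.0
    manual_down: list[str] = field(default_factory=list)
    min_align_score: float = 200.0
    min_consensus_len: int = 500
    max_consensus_len: int = 1000
    min_agree_frac: float = 0.5
    min_conserved_run: int = 6
    refine_rounds: int = 2
    mafb_widths: tuple[int, ...] = (8, 9, 10, 11)
    e_threshold: float = 21.0
    conserved_species: tuple[str, ...] = ("mouse", "human")
    # Step 2
    widths: tuple[int, ...] = (6, 8, 10, 12, 14, 16, 18)
    per_width: int = 10
    seed_pool: int | None = 100
    top_k: int = 10
    ori_variant: str = "max1"
    # Step 3
    alpha: float = 0.001
    full_model: str = "saturated"

    def config_hash(self) -> str:
        # the output location does not affect the analysis, so reruns into
        # different directories stay byte-identical
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _timed(report: RunReport, stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: failed after %.1fs", stage, dt)
                return False
            logger.info("stage %s: done in %.1fs", stage, dt)
            return True

    return _Timer()


def run_full(config: PipelineConfig) -> RunReport:
    """Execute the full Step 1 -> Step 3 analysis and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.config_hash(), config.seed)
    header = f"# comotif config={report.config_hash} seed={config.seed}\n"

    # ---- stage: classify -------------------------------------------------
    with _timed(report, "classify"):
        try:
            expression = promoter_io.read_expression_table(config.expression_tsv)
            down, nonreg = promoter_io.classify_genes(
                expression,
                config.down_threshold,
                config.nonreg_value,
                config.nonreg_tol,
                config.manual_down,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("classify", str(exc)) from exc
        report.stages["classify"] = {
            "n_expression": len(expression),
            "n_down": len(down),
            "n_nonreg": len(nonreg),
        }

    # ---- stage: mask -----------------------------------------------------
    with _timed(report, "mask"):
        try:
            records = promoter_io.read_fasta(config.promoters_fasta)
            table = (
                promoter_io.read_orthologue_table(config.orthologues_tsv)
                if config.orthologues_tsv
                else None
            )
            groups = promoter_io.group_orthologues(records, table)
            groups = [g for g in groups if g.gene_id in down | nonreg]
            windows = {
                g.gene_id: {
                    sp: promoter_io.PromoterRecord(
                        g.gene_id,
                        sp,
                        promoter_io.extract_promoter_window(
                            rec, config.upstream, config.downstream
                        ),
                        min(rec.tss_index, config.upstream),
                    )
                    for sp, rec in g.members.items()
                }
                for g in groups
            }
            params = conservation.AlignmentParams()
            masked: dict[str, conservation.MaskedConsensus] = {}
            for g in groups:
                grp = promoter_io.OrthologueGroup(g.gene_id, windows[g.gene_id])
                masked[g.gene_id] = conservation.mask_group(
                    grp,
                    params,
                    config.min_align_score,
                    config.min_consensus_len,
                    config.max_consensus_len,
                    config.min_agree_frac,
                    config.min_conserved_run,
                    config.refine_rounds,
                )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("mask", str(exc)) from exc
        masked_records = [
            promoter_io.PromoterRecord(
                g, "mouse", m.sequence, min(config.upstream, max(0, len(m.sequence) - 1))
            )
            for g, m in sorted(masked.items())
            if m.sequence
        ]
        promoter_io.write_fasta(masked_records, outdir / "masked.fasta")
        with open(outdir / "masking_stats.tsv", "w") as fh:
            fh.write(header)
            fh.write("gene_id\tfraction_masked\tretained_species\n")
            for g, m in sorted(masked.items()):
                fh.write(f"{g}\t{m.fraction_masked:.4f}\t{','.join(m.retained_species)}\n")
        report.stages["mask"] = {
            "n_groups": len(groups),
            "mean_fraction_masked": (
                sum(m.fraction_masked for m in masked.values()) / len(masked) if masked else 0.0
            ),
        }

    # ---- stage: mafb motifs + binding gene set ---------------------------
    with _timed(report, "mafb_select"):
        try:
            mafb = motif_models.extract_mafb_motifs(widths=config.mafb_widths)
            motif_models.write_motifs(mafb, outdir / "mafb_motifs.txt")
            down_masked = {g: masked[g].sequence for g in sorted(down) if g in masked}
            scans: dict[str, dict[str, dict[str, tuple[float, int]]]] = {}
            # E-values from PWM scans of the masked mouse promoters
            mouse_scans: dict[str, dict[str, tuple[float, int]]] = {g: {} for g in down_masked}
            for m in mafb:
                if down_masked:
                    sr = motif_scan.pwm_scan_evalue(m, down_masked)
                    for g, s in sr.per_sequence.items():
                        n_hits = sum(1 for h in sr.hits if h.seq_id == g)
                        mouse_scans[g][m.motif_id] = (s.e_value, n_hits)
            scans["mouse"] = mouse_scans
            # conservation requirement: string-mode hits in each species' window
            for sp in config.conserved_species:
                if sp == "mouse":
                    # hits on the conserved (masked) mouse promoter
                    sp_scans = {}
                    for g, seq in down_masked.items():
                        sp_scans[g] = {
                            m.motif_id: (
                                mouse_scans[g][m.motif_id][0],
                                len(motif_scan.locate_with_substitutions(m, seq, seq_id=g)),
                            )
                            for m in mafb
                        }
                    scans["mouse"] = {
                        g: {
                            mid: (mouse_scans[g][mid][0], sp_scans[g][mid][1])
                            for mid in mouse_scans[g]
                        }
                        for g in down_masked
                    }
                    continue
                sp_scans = {}
                for g in down_masked:
                    rec = windows.get(g, {}).get(sp)
                    if rec is None:
                        sp_scans[g] = {m.motif_id: (float("inf"), 0) for m in mafb}
                        continue
                    sp_scans[g] = {
                        m.motif_id: (
                            float("inf"),
                            len(motif_scan.locate_with_substitutions(m, rec.sequence, seq_id=g)),
                        )
                        for m in mafb
                    }
                scans[sp] = sp_scans
            mafb_genes = motif_scan.select_mafb_binding_genes(
                scans, config.conserved_species, config.e_threshold
            )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("mafb_select", str(exc)) from exc
        (outdir / "mafb_genes.txt").write_text("".join(f"{g}\n" for g in mafb_genes))
        report.stages["mafb_select"] = {
            "n_down_masked": len(down_masked),
            "n_mafb_genes": len(mafb_genes),
        }

    # ---- stage: motif discovery -----------------------------------------
    with _timed(report, "motifs"):
        try:
            target_seqs = [masked[g].sequence for g in mafb_genes]
            if len(target_seqs) < 2:
                raise StageError("motifs", "fewer than two MafB binding genes; cannot discover motifs")
            discovered = motif_models.discover_motif_set(
                target_seqs,
                widths=config.widths,
                per_width=config.per_width,
                seq_ids=mafb_genes,
                seed_pool=config.seed_pool,
            )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("motifs", str(exc)) from exc
        motif_models.write_motifs(discovered, outdir / "motifs.txt")
        report.stages["motifs"] = {"n_discovered": len(discovered)}

    # ---- stage: ORI ranking ----------------------------------------------
    with _timed(report, "ori"):
        try:
            all_motifs = discovered + mafb
            down_proms = {g: masked[g].sequence for g in mafb_genes}
            nonreg_proms = {g: masked[g].sequence for g in sorted(nonreg) if g in masked}
            ori_table = enrichment.score_motifs(
                all_motifs, down_proms, nonreg_proms, config.ori_variant
            )
            candidates_ids = enrichment.rank_candidates(ori_table, config.top_k)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("ori", str(exc)) from exc
        enrichment.write_ori_table(ori_table, outdir / "ori.tsv")
        report.stages["ori"] = {"n_scored": len(ori_table), "n_candidates": len(candidates_ids)}

    # ---- stage: LGM ------------------------------------------------------
    with _timed(report, "lgm"):
        try:
            by_id = {m.motif_id: m for m in all_motifs}
            candidates = [by_id[c] for c in candidates_ids]
            all_proms = {**down_proms, **nonreg_proms}
            group_labels = {g: ("down" if g in down_proms else "nonreg") for g in all_proms}
            occ = enrichment.build_occurrence_matrix(candidates, all_proms, group_labels)
            merged, merge_map = enrichment.merge_equivalent_motifs(occ, candidates)
            btab = lgm.tabulate(merged)
            graph, trace = lgm.backward_eliminate(
                btab, config.alpha, config.full_model
            )
            combos = lgm.extract_combinations(graph)
            stars = lgm.star_table(merged, combos)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("lgm", str(exc)) from exc
        occ.to_tsv(outdir / "occurrence.tsv")
        merged.to_tsv(outdir / "occurrence_merged.tsv")
        (outdir / "merge_map.json").write_text(
            json.dumps(merge_map, indent=2, sort_keys=True) + "\n"
        )
        graph.to_json(outdir / "graph.json")
        graph.to_dot(outdir / "graph.dot")
        trace.to_tsv(outdir / "trace.tsv")
        lgm.write_star_table(stars, outdir / "star_table.tsv")
        report.stages["lgm"] = {
            "k_motifs": btab.k,
            "n_genes": int(btab.n),
            "n_edges": len(graph.edges),
            "final_deviance": trace.final_deviance,
            "final_df": trace.final_df,
            "final_p_vs_fm": trace.final_p_vs_fm,
        }

    report.to_json(outdir / "report.json")
    return report
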