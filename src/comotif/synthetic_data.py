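"""Synthetic study inputs with known ground truth.

The generator emulates the experimental design end to end: a two-signal
expression table separating down-regulated from non-regulated genes,
multi-species promoters of the -2000/+300 window around the TSS with a
conserved core, and motif instances planted inside the core whose
per-gene presence/absence in the down-regulated group follows an exactly
enumerated log-linear joint distribution (so graphical-model inference
has a known truth to recover).  Non-regulated genes receive presences
from an independence model so the group contrast is controllable.

All randomness flows from ``SimulationConfig.seed``; outputs are
bit-for-bit reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._alphabet import BASES, encode
from .motif_models import PWM
from .promoter_io import (
    ExpressionRecord,
    PromoterRecord,
    write_expression_table,
    write_fasta,
)

SPECIES_POOL = ["mouse", "human", "rat", "bovine", "dog", "chimp", "horse"]
MAX_K = 12  # exact enumeration bound for the joint presence distribution


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions this generator emulates: 18
    down-regulated target genes against 211 non-regulated genes, 4
    mammalian species, and 2300-nt promoter windows (-2000/+300 around
    the TSS).  ``planted_edges`` are pairwise interaction coefficients of
    the log-linear presence model on the natural-log scale.
    """

    seed: int = 0
    k_motifs: int = 3
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    main_effects: list[float] | float = 0.0
    n_down: int = 18
    n_nonreg: int = 211
    n_species: int = 4
    promoter_length: int = 2300
    conserved_core_length: int = 800
    gc_fraction: float = 0.5
    site_mutation_prob: float = 0.05
    species_substitution_prob: float = 0.3
    nonreg_presence_prob: float = 0.2
    motif_width: int = 10
    sites_per_presence: int = 1
    motif_consensi: list[str] | None = None

    def __post_init__(self) -> None:
        if self.k_motifs > MAX_K:
            raise ValueError(f"k_motifs must be <= {MAX_K} (exact enumeration bound)")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        for p in (self.site_mutation_prob, self.species_substitution_prob, self.nonreg_presence_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for i, j, _ in self.planted_edges:
            if not (0 <= i < self.k_motifs and 0 <= j < self.k_motifs and i != j):
                raise ValueError("planted edge endpoints must be distinct motif indices")

    def main_effect_vector(self) -> np.ndarray:
        if isinstance(self.main_effects, (int, float)):
            return np.full(self.k_motifs, float(self.main_effects))
        v = np.asarray(self.main_effects, dtype=float)
        if v.shape != (self.k_motifs,):
            raise ValueError("main_effects must be scalar or length k_motifs")
        return v

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthBundle:
    presence: np.ndarray  # (n_down + n_nonreg, k) 0/1
    gene_ids: list[str]
    group_labels: list[str]
    consensi: list[str]
    planted_edges: list[tuple[int, int, float]]
    placements: dict[str, list[dict]]  # gene -> [{motif, offset, strand}]

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "group_labels": self.group_labels,
            "presence": self.presence.astype(int).tolist(),
            "consensi": self.consensi,
            "planted_edges": [[int(i), int(j), float(c)] for i, j, c in self.planted_edges],
            "placements": self.placements,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def enumerate_joint(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint distribution of the k-motif presence vector.

    P(x) is proportional to exp(sum_i main_i x_i + sum_(i,j) coef_ij x_i x_j)
    over the 2^k binary states.  Returns (states, probabilities) with
    states ordered by cell index (motif 0 = least significant bit).
    """
    k = config.k_motifs
    states = np.array(list(itertools.product([0, 1], repeat=k)))[:, ::-1]
    main = config.main_effect_vector()
    energy = states @ main
    for i, j, coef in config.planted_edges:
        energy = energy + coef * states[:, i] * states[:, j]
    energy -= energy.max()
    probs = np.exp(energy)
    probs /= probs.sum()
    return states, probs


def sample_presence_patterns(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample down-group presence patterns from the exact joint distribution."""
    rng = rng if rng is not None else config.rng()
    states, probs = enumerate_joint(config)
    idx = rng.choice(len(states), size=config.n_down, p=probs)
    return states[idx].astype(np.int8)


def _random_consensus(rng: np.random.Generator, width: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=width))


def planted_pwm(consensus: str, mutation_prob: float, background=None) -> PWM:
    """PWM implied by a consensus and a per-site mutation probability."""
    w = len(consensus)
    codes = encode(consensus)
    probs = np.full((w, 4), max(mutation_prob, 3e-4) / 3.0)
    for j, c in enumerate(codes):
        probs[j, c] = 1.0 - max(mutation_prob, 3e-4)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(probs, bg)


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def plant_motifs(
    presence: np.ndarray,
    pwms: list[PWM],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gene_ids: list[str] | None = None,
    group_labels: list[str] | None = None,
) -> tuple[list[PromoterRecord], TruthBundle]:
    """Emit multi-species promoters with planted motif instances.

    Per gene: an i.i.d. background reference (mouse) promoter; one site
    per present motif (or ``sites_per_presence``) sampled from the motif's
    PWM at a random non-overlapping offset inside the conserved core;
    orthologous species copy the reference with per-site substitution
    probability ``species_substitution_prob`` outside the core and
    ``site_mutation_prob`` inside it.
    """
    rng = rng if rng is not None else config.rng()
    n_genes, k = presence.shape
    if len(pwms) != k:
        raise ValueError("need one PWM per motif")
    L = config.promoter_length
    core_len = min(config.conserved_core_length, L)
    core_start = (L - core_len) // 2
    tss = max(0, L - min(300, max(1, L // 8)))
    species = SPECIES_POOL[: config.n_species]
    bg = _background_probs(config.gc_fraction)
    ids = gene_ids if gene_ids is not None else [f"g{i:04d}" for i in range(n_genes)]
    labels = group_labels if group_labels is not None else ["down"] * n_genes
    records: list[PromoterRecord] = []
    placements: dict[str, list[dict]] = {}
    total_site_len = int(presence.sum(axis=1).max() if n_genes else 0)
    widths = [p.width for p in pwms]
    if core_len < config.sites_per_presence * total_site_len * (max(widths) if widths else 0):
        raise ValueError("conserved core too small for the requested sites")
    for gi in range(n_genes):
        ref = rng.choice(4, size=L, p=bg).astype(np.int8)
        taken: list[tuple[int, int]] = []
        placements[ids[gi]] = []
        for mi in range(k):
            if not presence[gi, mi]:
                continue
            w = pwms[mi].width
            for _ in range(config.sites_per_presence):
                offset = None
                for _try in range(200):
                    cand = int(rng.integers(core_start, core_start + core_len - w + 1))
                    if all(cand + w <= s or cand >= e for s, e in taken):
                        offset = cand
                        break
                if offset is None:
                    raise ValueError("conserved core too small for the requested sites")
                taken.append((offset, offset + w))
                site = np.array(
                    [rng.choice(4, p=pwms[mi].probs[j]) for j in range(w)], dtype=np.int8
                )
                ref[offset : offset + w] = site
                placements[ids[gi]].append({"motif": mi, "offset": offset, "strand": "+"})
        ref_seq = "".join(BASES[c] for c in ref)
        records.append(PromoterRecord(ids[gi], species[0], ref_seq, tss))
        for sp in species[1:]:
            copy = ref.copy()
            outside = np.ones(L, dtype=bool)
            outside[core_start : core_start + core_len] = False
            mut_out = outside & (rng.random(L) < config.species_substitution_prob)
            mut_in = ~outside & (rng.random(L) < config.site_mutation_prob)
            for mask in (mut_out, mut_in):
                pos = np.nonzero(mask)[0]
                if pos.size:
                    shifts = rng.integers(1, 4, size=pos.size)
                    copy[pos] = (copy[pos] + shifts) % 4
            records.append(PromoterRecord(ids[gi], sp, "".join(BASES[c] for c in copy), tss))
    consensi = [p.consensus() for p in pwms]
    truth = TruthBundle(
        presence=presence.copy(),
        gene_ids=list(ids),
        group_labels=list(labels),
        consensi=consensi,
        planted_edges=list(config.planted_edges),
        placements=placements,
    )
    return records, truth


def generate_expression_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ExpressionRecord]:
    """Expression records reproducing the classification contrast.

    Down-regulated genes get KO/WT ratios uniform in (0.05, 0.5) with
    wild-type signals log-uniform in the down-group's magnitude band;
    non-regulated genes get a ratio of exactly 1.0.
    """
    rng = rng if rng is not None else config.rng()
    records: list[ExpressionRecord] = []
    for i in range(config.n_down):
        wt = float(10 ** rng.uniform(np.log10(494), np.log10(169099)))
        ratio = float(rng.uniform(0.05, 0.5))
        records.append(ExpressionRecord(f"down{i:03d}", wt, wt * ratio))
    for i in range(config.n_nonreg):
        wt = float(10 ** rng.uniform(np.log10(471), np.log10(229536)))
        records.append(ExpressionRecord(f"nonreg{i:03d}", wt, wt))
    return records


def end_to_end_fixture(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write a self-contained run directory: FASTA + TSV inputs + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    expression = generate_expression_table(config, rng)
    write_expression_table(expression, outdir / "expression.tsv")
    consensi = (
        list(config.motif_consensi)
        if config.motif_consensi
        else [_random_consensus(rng, config.motif_width) for _ in range(config.k_motifs)]
    )
    if len(consensi) != config.k_motifs:
        raise ValueError("motif_consensi must have length k_motifs")
    pwms = [planted_pwm(c, config.site_mutation_prob) for c in consensi]
    down_presence = sample_presence_patterns(config, rng)
    nonreg_presence = (
        rng.random((config.n_nonreg, config.k_motifs)) < config.nonreg_presence_prob
    ).astype(np.int8)
    presence = np.vstack([down_presence, nonreg_presence])
    gene_ids = [r.gene_id for r in expression]
    labels = ["down"] * config.n_down + ["nonreg"] * config.n_nonreg
    records, truth = plant_motifs(
        presence, pwms, config, rng, gene_ids=gene_ids, group_labels=labels
    )
    write_fasta(records, outdir / "promoters.fasta")
    with open(outdir / "orthologues.tsv", "w") as fh:
        fh.write("gene_id\tspecies\tfasta_id\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.species}\t{r.fasta_id}\n")
    truth.to_json(outdir / "truth.json")
    (outdir / "config.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True, default=list) + "\n"
    )
    return outdir
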