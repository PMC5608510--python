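"""Synthetic study generator with planted ground truth.

Emulates the data shapes of the real study — a miniature genome with gene
annotation and AR-binding-site-like peak intervals, published-style
androgen-regulated gene lists, and a knockdown × treatment expression matrix
(each siRNA condition crossed with androgen/vehicle, 3 biological replicates
per cell) — while planting per-(gene, coregulator) dependence classes and
effect sizes so every downstream stage can be scored against truth.

Intensities are generated multiplicatively, 2^(baseline + effects + noise),
so the additive effect model is exact after the pipeline's log2 transform.
All randomness derives from a single master seed; per-stage substreams are
spawned as SeedSequence(seed, spawn_key=(k,)) with k = 0 (annotation/peaks),
1 (expression), 2 (regulated lists), 3 (motif sequences), so stages can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dependence import CATEGORIES, classify_effects
from .differential import ExpressionStudy
from .genomic import DEFAULT_WINDOW, GeneAnnotation, PeakSet
from .motifs import BASES, PWM

_STAGE_ANNOTATION = 0
_STAGE_EXPRESSION = 1
_STAGE_LISTS = 2
_STAGE_SEQUENCES = 3


def _default_chrom_lengths() -> dict[str, int]:
    return {"chr1": 30_000_000, "chr2": 30_000_000, "chr3": 30_000_000}


def _default_class_fractions() -> dict[str, float]:
    # mid-range mix: per-coregulator affected fractions in the real study span
    # 0-57% with direction-consistent (co) changes dominating flipped (op) ones
    return {"co+": 0.08, "co-": 0.12, "op+": 0.03, "op-": 0.02, "unaffected": 0.75}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Effects are on the log2 scale: ``effect_log2fc`` is the planted androgen
    response under control siRNA, ``delta_log2fc`` the planted knockdown-
    induced change in that response, ``noise_sd`` the residual SD.
    """

    n_genes: int = 2000
    n_coregulators: int = 6
    chrom_lengths: Mapping[str, int] = field(default_factory=_default_chrom_lengths)
    reps_per_condition: int = 3
    effect_log2fc: float = 2.0
    delta_log2fc: float = 1.5
    noise_sd: float = 0.25
    class_fractions: Mapping[str, float] = field(default_factory=_default_class_fractions)
    baseline_log2: float = 8.0
    seed: int = 0
    # peak/annotation geometry
    peak_fraction: float = 0.9  # fraction of genes receiving a nearby true peak
    decoy_fraction: float = 0.2  # decoy peaks per gene
    n_decoy_peaks: int | None = None  # explicit decoy count (overrides decoy_fraction)
    window: int = DEFAULT_WINDOW
    peak_halfwidth: int = 150
    gene_region_frac: float = 0.4  # chromosome fraction holding gene territories
    multi_tss_fraction: float = 0.0  # fraction of genes given a second TSS
    # expression extras
    regulated_fraction: float = 0.9  # genes with a nonzero androgen response
    up_fraction: float = 0.55  # of regulated genes, fraction androgen-induced
    baseline_gene_sd: float = 1.0  # between-gene spread of baseline intensity

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("zero-length chromosome in chrom_lengths")
        if self.reps_per_condition < 2:
            raise ValueError("reps_per_condition must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        fr = dict(self.class_fractions)
        if set(fr) != set(CATEGORIES):
            raise ValueError(f"class_fractions must have keys {CATEGORIES}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be >= 0")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        affected = {k: v for k, v in fr.items() if k != "unaffected" and v > 0}
        if affected and self.effect_log2fc - self.delta_log2fc <= 0 and (
            fr.get("co-", 0) > 0 or fr.get("op-", 0) > 0
        ):
            raise ValueError(
                "effect_log2fc must exceed delta_log2fc when magnitude-decreased "
                "classes are planted (otherwise the planted sign relation breaks)"
            )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects: per-gene androgen response and per-pair classes.

    ``genes`` is indexed by gene_id with columns control_log2fc, regulated;
    ``pairs`` has one row per (gene, coregulator): category, kd_log2fc.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame

    def pair_categories(self) -> pd.DataFrame:
        """Wide genes × coregulators matrix of planted category labels."""
        return self.pairs.pivot(index="gene", columns="coregulator", values="category")

    def write_tsv(self, genes_path, pairs_path) -> None:
        self.genes.to_csv(genes_path, sep="\t", index_label="gene_id")
        self.pairs.to_csv(pairs_path, sep="\t", index=False)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_annotation_and_peaks(config: SimConfig) -> tuple[GeneAnnotation, PeakSet]:
    """Simulate gene annotation plus ARBS-like peaks.

    Genes live in a per-chromosome "gene territory" ([0, gene_region_frac*L));
    a ``peak_fraction`` of genes receives a true peak whose midpoint lies
    within ``window`` of its TSS, while decoy peaks are placed beyond
    gene_region_frac*L + window, i.e. outside the assignment window of every
    TSS by construction (emulating gene deserts). Truth is carried in peak
    names: ``arbs_<gene_id>`` vs ``decoy_<i>``.
    """
    rng = config.rng(_STAGE_ANNOTATION)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    hw = config.peak_halfwidth

    n_decoys = (
        config.n_decoy_peaks
        if config.n_decoy_peaks is not None
        else int(round(config.decoy_fraction * config.n_genes))
    )
    if n_decoys:
        for c, L in config.chrom_lengths.items():
            lo = int(config.gene_region_frac * L) + config.window + hw
            if lo >= L - hw:
                raise ValueError(
                    f"chromosome {c} too short to host decoy peaks beyond the "
                    f"gene territory plus window"
                )

    gene_rows = {}
    peak_rows = []
    ids = _gene_ids(config.n_genes)
    for gid in ids:
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom, L = chroms[ci], int(lengths[ci])
        region_hi = max(int(config.gene_region_frac * L), 200_000)
        body_len = int(rng.integers(5_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(body_len + 1, region_hi - body_len - 1))
        if strand == "+":
            body = (tss, tss + body_len)
        else:
            body = (tss - body_len + 1, tss + 1)
        exons = _split_exons(body, rng)
        tss_list = [tss]
        if rng.random() < config.multi_tss_fraction:
            # an alternative start within the gene body, respecting strand
            shift = int(rng.integers(500, max(501, body_len // 2)))
            tss_list.append(tss + shift if strand == "+" else tss - shift)
        gene_rows[gid] = {
            "chrom": chrom,
            "strand": strand,
            "tss": tuple(sorted(tss_list)),
            "exons": exons,
        }
        if rng.random() < config.peak_fraction:
            offset = int(rng.integers(-config.window, config.window + 1))
            mid = min(max(tss + offset, hw), L - hw)
            peak_rows.append((chrom, mid - hw, mid + hw, f"arbs_{gid}", 0.0, "."))

    for i in range(n_decoys):
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom, L = chroms[ci], int(lengths[ci])
        lo = int(config.gene_region_frac * L) + config.window + hw
        mid = int(rng.integers(lo, L - hw))
        peak_rows.append((chrom, mid - hw, mid + hw, f"decoy_{i}", 0.0, "."))

    annotation = GeneAnnotation(
        pd.DataFrame.from_dict(gene_rows, orient="index")[["chrom", "strand", "tss", "exons"]]
        if gene_rows
        else pd.DataFrame(columns=["chrom", "strand", "tss", "exons"])
    )
    peaks = PeakSet(
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        if peak_rows
        else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    )
    return annotation, peaks


def _split_exons(body: tuple[int, int], rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """Split a gene body into 2-5 exons separated by introns."""
    start, end = body
    n_exons = int(rng.integers(2, 6))
    cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * n_exons - 2, replace=False))
    bounds = [start, *cuts.tolist(), end]
    exons = tuple(
        (int(bounds[i]), int(bounds[i + 1])) for i in range(0, len(bounds) - 1, 2)
    )
    return exons


def _planted_kd_effect(c1: float, category: str, delta: float) -> float:
    """Androgen response under knockdown implied by the planted class.

    co-classes keep the sign of c1 and move its magnitude by ±delta; op-classes
    flip the sign (and also move the magnitude by ±delta).
    """
    if category == "unaffected":
        return c1
    sign = np.sign(c1) if c1 != 0 else 1.0
    mag = abs(c1) + (delta if category.endswith("+") else -delta)
    if category.startswith("op"):
        sign = -sign
    return float(sign * mag)


def simulate_expression(
    config: SimConfig, coregulator_names: Sequence[str]
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate the knockdown × treatment intensity matrix with planted truth.

    One sample per (siRNA in {control} ∪ coregulators) × (androgen, vehicle)
    × replicate. log2 intensity = gene baseline + planted effect + N(0, σ);
    the matrix is returned on the raw intensity scale (2^log2), matching what
    the real pipeline ingests before its log2 step.
    """
    names = list(coregulator_names)
    if not names:
        raise ValueError("coregulator_names must be nonempty")
    if len(names) != len(set(names)):
        raise ValueError("duplicate coregulator names")
    if "control" in names:
        raise ValueError("'control' is reserved for the control siRNA")

    rng = config.rng(_STAGE_EXPRESSION)
    n = config.n_genes
    ids = _gene_ids(n)

    regulated = rng.random(n) < config.regulated_fraction
    sign = np.where(rng.random(n) < config.up_fraction, 1.0, -1.0)
    control_fc = np.where(regulated, sign * config.effect_log2fc, 0.0)

    cats = list(CATEGORIES)
    probs = np.array([config.class_fractions[c] for c in cats])
    probs = probs / probs.sum()
    pair_rows = []
    kd = np.empty((n, len(names)))
    for j, coreg in enumerate(names):
        drawn = rng.choice(len(cats), size=n, p=probs)
        for i in range(n):
            category = cats[drawn[i]] if regulated[i] else "unaffected"
            kd[i, j] = _planted_kd_effect(control_fc[i], category, config.delta_log2fc)
            if category != "unaffected":
                planted = classify_effects(control_fc[i], kd[i, j])
                if planted != category:  # pragma: no cover - guarded by config validation
                    raise RuntimeError(
                        f"planted class {category} inconsistent with effects "
                        f"({control_fc[i]}, {kd[i, j]}) -> {planted}"
                    )
            pair_rows.append((ids[i], coreg, category, kd[i, j]))

    baseline = config.baseline_log2 + rng.normal(0.0, config.baseline_gene_sd, size=n)

    sample_ids, design_rows, columns = [], [], []
    for sirna in ["control", *names]:
        j = None if sirna == "control" else names.index(sirna)
        for treatment in ("androgen", "vehicle"):
            for rep in range(1, config.reps_per_condition + 1):
                sid = f"{sirna}_{treatment}_r{rep}"
                sample_ids.append(sid)
                design_rows.append((sirna, treatment, rep))
                effect = np.zeros(n)
                if treatment == "androgen":
                    effect = control_fc if j is None else kd[:, j]
                noise = (
                    rng.normal(0.0, config.noise_sd, size=n)
                    if config.noise_sd > 0
                    else np.zeros(n)
                )
                columns.append(baseline + effect + noise)

    log2_matrix = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((n, 0)),
        index=ids,
        columns=sample_ids,
    )
    design = pd.DataFrame(
        design_rows, index=pd.Index(sample_ids, name="sample_id"),
        columns=["sirna", "treatment", "replicate"],
    )
    study = ExpressionStudy(np.exp2(log2_matrix), design, log_transformed=False)
    truth = GroundTruth(
        pd.DataFrame(
            {"control_log2fc": control_fc, "regulated": regulated}, index=ids
        ),
        pd.DataFrame(pair_rows, columns=["gene", "coregulator", "category", "kd_log2fc"]),
    )
    return study, truth


def simulate_regulated_lists(
    truth: GroundTruth,
    config: SimConfig,
    n_lists: int = 3,
    coverage: float = 0.8,
    false_fraction: float = 0.05,
) -> list[list[str]]:
    """Published-style androgen-regulated gene lists for target cross-matching.

    Each list samples ``coverage`` of the truly regulated genes and adds a
    small fraction of unregulated genes (imperfect published records).
    """
    rng = config.rng(_STAGE_LISTS)
    genes = truth.genes.index.to_numpy()
    reg = truth.genes["regulated"].to_numpy(dtype=bool)
    lists = []
    for _ in range(n_lists):
        take = rng.random(len(genes)) < np.where(reg, coverage, false_fraction)
        lists.append([str(g) for g in genes[take]])
    return lists


# --- synthetic motif study -------------------------------------------------

#: ARE-like palindromic consensus used as the shared "AR motif" in simulations.
AR_CONSENSUS = "AGAACANNNTGTTCT"


def synthetic_pwm_library(n_signature_motifs: int, rng: np.random.Generator) -> list[PWM]:
    """A small synthetic PWM library: one ARE-like motif plus random 8-mers."""
    pwms = [PWM.from_consensus("ARE_synthetic", AR_CONSENSUS, p_match=0.9)]
    for i in range(n_signature_motifs):
        consensus = "".join(rng.choice(list(BASES), size=8))
        pwms.append(PWM.from_consensus(f"TF{i:02d}_synthetic", consensus, p_match=0.9))
    return pwms


def simulate_motif_dataset(
    config: SimConfig,
    signatures: Sequence[str],
    n_fg_per_signature: int = 30,
    n_bg: int = 200,
    seq_length: int = 200,
    ar_rate: float = 0.8,
    sig_rate: float = 0.7,
) -> tuple[dict[str, list[str]], list[str], list[PWM], dict[str, list[str]]]:
    """Per-signature ARBS-like sequences with planted motif structure.

    Every signature's foreground carries the shared ARE-like motif at
    ``ar_rate``; signature k additionally carries its own private motif at
    ``sig_rate`` (selective by construction). One extra motif is planted in
    three signatures (non-selective control) and one is never planted.
    Returns (foreground sets, background, PWM library, planted-truth map of
    signature -> motif ids planted there).
    """
    rng = config.rng(_STAGE_SEQUENCES)
    sigs = list(signatures)
    pwms = synthetic_pwm_library(len(sigs) + 2, rng)
    are = pwms[0]
    private = pwms[1 : 1 + len(sigs)]
    broad = pwms[1 + len(sigs)]  # planted in up to 3 signatures
    absent = pwms[2 + len(sigs)]  # never planted

    def consensus_of(pwm: PWM) -> str:
        return "".join(
            BASES[i] if p[i] > 0.5 else rng.choice(list(BASES))
            for p in pwm.probs
            for i in [int(np.argmax(p))]
        )

    def random_seq(length: int) -> list[str]:
        return list(rng.choice(list(BASES), size=length))

    def plant(seq: list[str], pwm: PWM) -> None:
        site = consensus_of(pwm)
        pos = int(rng.integers(0, len(seq) - len(site)))
        seq[pos : pos + len(site)] = list(site)

    truth: dict[str, list[str]] = {s: [] for s in sigs}
    fg: dict[str, list[str]] = {}
    for k, sig in enumerate(sigs):
        seqs = []
        planted_here = [are.motif_id, private[k].motif_id]
        if k < 3:
            planted_here.append(broad.motif_id)
        truth[sig] = planted_here
        for _ in range(n_fg_per_signature):
            seq = random_seq(seq_length)
            if rng.random() < ar_rate:
                plant(seq, are)
            if rng.random() < sig_rate:
                plant(seq, private[k])
            if k < 3 and rng.random() < sig_rate:
                plant(seq, broad)
            seqs.append("".join(seq))
        fg[sig] = seqs
    bg = ["".join(random_seq(seq_length)) for _ in range(n_bg)]
    _ = absent  # kept in the library precisely because it is planted nowhere
    return fg, bg, pwms, truth
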