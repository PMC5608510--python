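"""End-to-end orchestration of the synthetic coregulator-dependence study.

Stages run in order — simulate → targets → de → classify → overlap → motifs —
each reading its inputs from the run directory (so toggled-off stages can be
satisfied by cached artifacts) and writing TSV outputs plus a JSON manifest
with per-file checksums. Re-running with an identical configuration
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dependence import classify_study, summarize_calls, write_calls_tsv
from .differential import ExpressionStudy, call_de, fit_contrast, write_contrast_tsv
from .genomic import (
    GeneAnnotation,
    PeakSet,
    assign_peaks_to_tss,
    categorize_peak_locations,
    nominate_targets,
    read_gene_list,
    write_gene_list,
)
from .motifs import motif_enrichment, selective_motifs, write_fasta
from .setstats import (
    SignedGeneSet,
    cluster_genes,
    combine_pairs,
    effect_correlation,
    pairwise_overlap_matrix,
)
from .simulate import (
    SimConfig,
    simulate_annotation_and_peaks,
    simulate_expression,
    simulate_motif_dataset,
    simulate_regulated_lists,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "targets", "de", "classify", "overlap", "motifs")


@dataclass
class RunConfig:
    """Pipeline configuration: output location, stage toggles, thresholds."""

    outdir: str = "coregdep_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    # thresholds (the study's published analysis settings)
    window: int = 300_000
    pad: int = 1000
    fdr: float = 0.05
    min_abs_log2fc: float = 1.0  # 2-fold on the log2 scale
    min_delta: float = 1.0
    min_lists: int = 1
    r_min: float = 0.25
    alphas: tuple[float, ...] = (0.05, 0.01)
    max_signatures: int = 2
    score_min_frac: float = 0.8
    moderation: str = "eb"
    # simulator overrides (field name -> value), applied on top of SimConfig defaults
    sim: dict[str, Any] = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alphas"] = list(self.alphas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        if "stages" in d:
            bad = sorted(set(d["stages"]) - set(STAGES))
            if bad:
                raise ValueError(f"unknown stages: {bad}")
            d["stages"] = {s: bool(d["stages"].get(s, True)) for s in STAGES}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(outdir: Path, stage: str, filename: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires missing artifact {filename!r} "
            f"(produced by an earlier stage that did not run)"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim_config()
    coregs = [f"coreg{i:02d}" for i in range(sim_cfg.n_coregulators)]
    logger.info(
        "thresholds: window=%d bp, fold-change>=%.1fx, FDR<%g, r>=%g, "
        "<=%d signatures, pad=%d bp",
        config.window, 2**config.min_abs_log2fc, config.fdr, config.r_min,
        config.max_signatures, config.pad,
    )

    manifest: dict = {
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], params: dict | None = None) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params or {},
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            }
        )
        logger.info("stage %s complete (%d outputs)", stage, len(outputs))

    if config.stages.get("simulate", True):
        annotation, peaks = simulate_annotation_and_peaks(sim_cfg)
        study, truth = simulate_expression(sim_cfg, coregs)
        lists = simulate_regulated_lists(truth, sim_cfg)
        outs = []
        annotation.write_tsv(outdir / "annotation.tsv"); outs.append(outdir / "annotation.tsv")
        peaks.write_bed(outdir / "peaks.bed"); outs.append(outdir / "peaks.bed")
        study.matrix.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
        outs.append(outdir / "expression.tsv")
        study.design.to_csv(outdir / "design.tsv", sep="\t")
        outs.append(outdir / "design.tsv")
        truth.write_tsv(outdir / "truth_genes.tsv", outdir / "truth_pairs.tsv")
        outs += [outdir / "truth_genes.tsv", outdir / "truth_pairs.tsv"]
        for i, lst in enumerate(lists):
            p = outdir / f"regulated_list_{i}.txt"
            write_gene_list(lst, p)
            outs.append(p)
        record("simulate", outs, {"n_genes": sim_cfg.n_genes, "seed": sim_cfg.seed})

    if config.stages.get("targets", True):
        annotation = GeneAnnotation.read_tsv(_require(outdir, "targets", "annotation.tsv"))
        peaks = PeakSet.read_bed(_require(outdir, "targets", "peaks.bed"))
        lists = []
        i = 0
        while (outdir / f"regulated_list_{i}.txt").exists():
            lists.append(read_gene_list(outdir / f"regulated_list_{i}.txt"))
            i += 1
        if not lists:
            _require(outdir, "targets", "regulated_list_0.txt")
        assignments = assign_peaks_to_tss(peaks, annotation, config.window)
        targets = sorted(nominate_targets(assignments, lists, config.min_lists))
        cats = categorize_peak_locations(peaks, annotation)
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        write_gene_list(targets, outdir / "targets.txt")
        pd.Series(cats.counts, name="count").rename_axis("category").to_csv(
            outdir / "peak_categories.tsv", sep="\t"
        )
        record(
            "targets",
            [outdir / "assignments.tsv", outdir / "targets.txt", outdir / "peak_categories.tsv"],
            {"window": config.window, "min_lists": config.min_lists},
        )

    if config.stages.get("de", True):
        study = _load_study(outdir, "de")
        log2 = study.log2()
        res = fit_contrast(
            log2,
            log2.samples("control", "androgen"),
            log2.samples("control", "vehicle"),
            config.moderation,
        )
        calls = call_de(res, config.fdr, config.min_abs_log2fc)
        write_contrast_tsv(res, outdir / "de_control.tsv")
        calls.rename("sign").to_csv(outdir / "de_calls.tsv", sep="\t", index_label="gene")
        record("de", [outdir / "de_control.tsv", outdir / "de_calls.tsv"],
               {"fdr": config.fdr, "min_abs_log2fc": config.min_abs_log2fc})

    if config.stages.get("classify", True):
        study = _load_study(outdir, "classify")
        panel = _analysis_panel(outdir, "classify")
        coregs_present = sorted(set(study.design["sirna"]) - {"control"})
        calls = classify_study(
            study,
            coregs_present,
            panel=panel,
            moderation=config.moderation,
            fdr_max=config.fdr,
            min_abs_delta_log2=config.min_delta,
            min_regulated_abs_log2fc=config.min_abs_log2fc,
        )
        summary = summarize_calls(calls, panel_size=len(panel) if panel else None)
        write_calls_tsv(calls, outdir / "calls.tsv")
        summary.to_csv(outdir / "summary.tsv", sep="\t")
        record("classify", [outdir / "calls.tsv", outdir / "summary.tsv"],
               {"fdr": config.fdr, "min_delta": config.min_delta, "panel_size": len(panel)})

    if config.stages.get("overlap", True):
        calls = pd.read_csv(_require(outdir, "overlap", "calls.tsv"), sep="\t")
        panel = _analysis_panel(outdir, "overlap")
        sets = [
            SignedGeneSet.from_calls(calls, c)
            for c in sorted(calls["coregulator"].unique())
        ]
        nonempty = [s for s in sets if len(s) > 0]
        outs = []
        if len(nonempty) >= 2:
            ov = pairwise_overlap_matrix(nonempty, panel, config.alphas)
            ov.counts.to_csv(outdir / "overlap_counts.tsv", sep="\t")
            ov.p_values.to_csv(outdir / "overlap_pvalues.tsv", sep="\t")
            pd.Series(
                {"n_pairs": ov.n_pairs, **{f"n_sig_p<{a:g}": k for a, k in ov.n_significant.items()}},
                name="value",
            ).rename_axis("statistic").to_csv(outdir / "overlap_summary.tsv", sep="\t")
            outs += [
                outdir / "overlap_counts.tsv",
                outdir / "overlap_pvalues.tsv",
                outdir / "overlap_summary.tsv",
            ]
        delta = calls.pivot(index="gene", columns="coregulator", values="c3_log2fc")
        if delta.shape[1] >= 2 and delta.shape[0] >= 3:
            corr = effect_correlation(delta)
            corr.to_csv(outdir / "correlation.tsv", sep="\t")
            outs.append(outdir / "correlation.tsv")
            merged = combine_pairs(corr, nonempty, config.r_min)
            with open(outdir / "combined_sets.tsv", "w") as fh:
                fh.write("pair\tr\tn_members\tmembers\n")
                for la, lb, r, ms in merged:
                    fh.write(f"{la}|{lb}\t{r:.4f}\t{len(ms)}\t{','.join(sorted(ms.members))}\n")
            outs.append(outdir / "combined_sets.tsv")
        affected = calls[calls["category"] != "unaffected"]
        if affected["gene"].nunique() >= 2:
            sign_matrix = (
                affected.assign(
                    sign=np.where(affected["category"].str.endswith("+"), 1, -1)
                )
                .pivot(index="gene", columns="coregulator", values="sign")
                .fillna(0)
                .astype(int)
            )
            if sign_matrix.shape[0] >= 2 and (sign_matrix.std(axis=1) > 0).sum() >= 2:
                clust = cluster_genes(sign_matrix)
                with open(outdir / "gene_clusters.nwk", "w") as fh:
                    fh.write(clust.newick + "\n")
                write_gene_list(clust.leaf_order, outdir / "cluster_leaf_order.txt")
                outs += [outdir / "gene_clusters.nwk", outdir / "cluster_leaf_order.txt"]
        record("overlap", outs, {"alphas": list(config.alphas), "r_min": config.r_min})

    if config.stages.get("motifs", True):
        calls = pd.read_csv(_require(outdir, "motifs", "calls.tsv"), sep="\t")
        signatures = sorted(calls["coregulator"].unique())
        fg, bg, pwms, planted = simulate_motif_dataset(sim_cfg, signatures)
        for sig, seqs in fg.items():
            write_fasta({f"{sig}_arbs_{i}": s for i, s in enumerate(seqs)},
                        outdir / f"sequences_{sig}.fa")
        write_fasta({f"bg_{i}": s for i, s in enumerate(bg)}, outdir / "sequences_bg.fa")
        records = motif_enrichment(fg, bg, pwms, alpha=config.fdr)
        sel = selective_motifs(records, config.max_signatures)
        records.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        with open(outdir / "selective_motifs.tsv", "w") as fh:
            fh.write("motif\tsignatures\n")
            for motif, sigs in sorted(sel.items()):
                fh.write(f"{motif}\t{','.join(sigs)}\n")
        with open(outdir / "motif_truth.json", "w") as fh:
            json.dump(planted, fh, indent=1, sort_keys=True)
        outs = [
            outdir / "motif_enrichment.tsv",
            outdir / "selective_motifs.tsv",
            outdir / "motif_truth.json",
            outdir / "sequences_bg.fa",
        ] + [outdir / f"sequences_{sig}.fa" for sig in signatures]
        record("motifs", outs, {"max_signatures": config.max_signatures, "alpha": config.fdr})

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _load_study(outdir: Path, stage: str) -> ExpressionStudy:
    matrix = pd.read_csv(_require(outdir, stage, "expression.tsv"), sep="\t", index_col=0)
    design = pd.read_csv(_require(outdir, stage, "design.tsv"), sep="\t", index_col=0)
    return ExpressionStudy(matrix, design, log_transformed=False)


def _analysis_panel(outdir: Path, stage: str) -> list[str]:
    """The analysis panel: nominated target genes that are androgen-regulated.

    Mirrors the study's construction of its direct-target panel (peak-linked,
    cross-matched, and differentially expressed under androgen).
    """
    targets = set(read_gene_list(_require(outdir, stage, "targets.txt")))
    de = pd.read_csv(_require(outdir, stage, "de_calls.tsv"), sep="\t")
    regulated = set(de["gene"].astype(str))
    return sorted(targets & regulated)


def render_summary(
    calls: pd.DataFrame | None,
    overlaps=None,
    enrichments: pd.DataFrame | None = None,
    panel_size: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Figure-style summary tables from completed-run outputs.

    Returns per-coregulator dependence category counts, the pairwise overlap
    count matrix (symmetric, set sizes on the diagonal), and per-signature
    counts of overrepresented motifs. Empty inputs yield empty, well-formed
    tables.
    """
    tables: dict[str, pd.DataFrame] = {}
    if calls is None or calls.empty:
        tables["dependence_counts"] = summarize_calls(pd.DataFrame(columns=["gene", "coregulator", "category"]))
    else:
        tables["dependence_counts"] = summarize_calls(calls, panel_size)
    if overlaps is not None:
        tables["overlap_counts"] = overlaps.counts
        tables["overlap_pvalues"] = overlaps.p_values
    else:
        tables["overlap_counts"] = pd.DataFrame()
        tables["overlap_pvalues"] = pd.DataFrame()
    if enrichments is None or enrichments.empty:
        tables["motif_counts"] = pd.DataFrame(columns=["n_enriched"]).rename_axis("signature")
    else:
        tables["motif_counts"] = (
            enrichments.groupby("signature")["enriched"].sum().astype(int).to_frame("n_enriched")
        )
    return tables
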