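"""Three-contrast knockdown design and four-way coregulator-dependence calls.

For each coregulator knockdown, three per-gene comparisons are made:

  c1  androgen response under control siRNA
      (control siRNA + androgen) vs (control siRNA + vehicle)
  c2  androgen response under the coregulator siRNA
      (siX + androgen) vs (siX + vehicle)
  c3  the interaction: c2 − c1, tested as a difference-of-differences
      contrast in the four-cell linear model with its own moderated test.

A gene is AFFECTED by the knockdown when the interaction passes the dual
FDR + fold-change rule and the gene is androgen-regulated in at least one of
the two conditions. Affected genes get a four-way label:

  prefix  "co" — direction of androgen regulation preserved (sign(c1)=sign(c2))
          "op" — direction flipped (sign(c1)=−sign(c2))
  suffix  "+"  — magnitude of androgen regulation increased (|c2| > |c1|)
          "−"  — magnitude decreased (|c2| < |c1|)

All other (gene, coregulator) pairs are "unaffected".
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .differential import ExpressionStudy, bh_adjust, fit_linear_contrast

CATEGORIES = ("co+", "co-", "op+", "op-", "unaffected")

CONTROL_SIRNA = "control"
TREATMENTS = ("androgen", "vehicle")


def androgen_response_pair(
    study: ExpressionStudy,
    coregulator: str,
    control: str = CONTROL_SIRNA,
    treatments: tuple[str, str] = TREATMENTS,
    moderation: str = "eb",
) -> pd.DataFrame:
    """Per-gene c1/c2/c3 effects and FDRs for one coregulator knockdown.

    p-values are BH-adjusted across genes within each of the three
    comparisons separately. Returns a DataFrame indexed by gene with columns
    {c}_log2fc, {c}_p, {c}_fdr for c in c1, c2, c3.
    """
    study = study.log2()
    androgen, vehicle = treatments
    cells = {
        (control, androgen): study.samples(control, androgen),
        (control, vehicle): study.samples(control, vehicle),
        (coregulator, androgen): study.samples(coregulator, androgen),
        (coregulator, vehicle): study.samples(coregulator, vehicle),
    }
    for cell, ids in cells.items():
        if not ids:
            raise ValueError(f"design cell missing: sirna={cell[0]!r}, treatment={cell[1]!r}")

    c1 = fit_linear_contrast(
        study.matrix,
        [cells[(control, androgen)], cells[(control, vehicle)]],
        [1.0, -1.0],
        moderation,
    )
    c2 = fit_linear_contrast(
        study.matrix,
        [cells[(coregulator, androgen)], cells[(coregulator, vehicle)]],
        [1.0, -1.0],
        moderation,
    )
    # interaction: (siX,A − siX,V) − (ctrl,A − ctrl,V), pooled 4-cell variance
    c3 = fit_linear_contrast(
        study.matrix,
        [
            cells[(coregulator, androgen)],
            cells[(coregulator, vehicle)],
            cells[(control, androgen)],
            cells[(control, vehicle)],
        ],
        [1.0, -1.0, -1.0, 1.0],
        moderation,
    )
    out = pd.DataFrame(index=study.matrix.index)
    for name, res in (("c1", c1), ("c2", c2), ("c3", c3)):
        out[f"{name}_log2fc"] = res["log2fc"]
        out[f"{name}_p"] = res["p_value"]
        out[f"{name}_fdr"] = res["fdr"]
    return out


def classify_effects(c1: float, c2: float) -> str:
    """Four-way label from the two androgen-response effects (no gating).

    Ties |c2| == |c1| take "+"; a zero sign in c1 or c2 cannot be a strict
    flip, so "op" requires sign(c1) == −sign(c2) with both nonzero.
    """
    suffix = "+" if abs(c2) >= abs(c1) else "-"
    prefix = "op" if (c1 * c2) < 0 else "co"
    return prefix + suffix


def classify_dependence(
    pair: pd.DataFrame,
    fdr_max: float = 0.05,
    min_abs_delta_log2: float = 1.0,
    min_regulated_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Label every gene of a c1/c2/c3 response table.

    AFFECTED requires the interaction to pass the dual rule
    (c3_fdr < fdr_max AND |c3_log2fc| >= min_abs_delta_log2) and the gene to
    be androgen-regulated in at least one condition
    (max(|c1|, |c2|) >= min_regulated_abs_log2fc). Affected genes are labeled
    by :func:`classify_effects`; everything else is "unaffected".

    Returns the input table plus a ``category`` column.
    """
    if fdr_max <= 0 or min_abs_delta_log2 <= 0 or min_regulated_abs_log2fc <= 0:
        raise ValueError("thresholds must be > 0")
    c1 = pair["c1_log2fc"].to_numpy(dtype=float)
    c2 = pair["c2_log2fc"].to_numpy(dtype=float)
    c3 = pair["c3_log2fc"].to_numpy(dtype=float)
    fdr3 = pair["c3_fdr"].to_numpy(dtype=float)
    affected = (
        (fdr3 < fdr_max)
        & (np.abs(c3) >= min_abs_delta_log2)
        & (np.maximum(np.abs(c1), np.abs(c2)) >= min_regulated_abs_log2fc)
    )
    labels = np.where(
        affected,
        [classify_effects(a, b) for a, b in zip(c1, c2)],
        "unaffected",
    )
    out = pair.copy()
    out["category"] = labels
    return out


def classify_study(
    study: ExpressionStudy,
    coregulators: Sequence[str],
    panel: Sequence[str] | None = None,
    control: str = CONTROL_SIRNA,
    treatments: tuple[str, str] = TREATMENTS,
    moderation: str = "eb",
    fdr_max: float = 0.05,
    min_abs_delta_log2: float = 1.0,
    min_regulated_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Run the three-contrast design and classification for many coregulators.

    Returns a long-format table with columns gene, coregulator, category, and
    the c1/c2/c3 effects and FDRs; optionally restricted to a gene ``panel``.
    """
    frames = []
    for coreg in coregulators:
        pair = androgen_response_pair(study, coreg, control, treatments, moderation)
        if panel is not None:
            pair = pair.loc[pair.index.intersection(list(panel))]
            # re-adjust within the analysis panel
            for c in ("c1", "c2", "c3"):
                pair[f"{c}_fdr"] = bh_adjust(pair[f"{c}_p"].to_numpy())
        calls = classify_dependence(
            pair, fdr_max, min_abs_delta_log2, min_regulated_abs_log2fc
        )
        calls = calls.reset_index(names="gene")
        calls.insert(1, "coregulator", coreg)
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def summarize_calls(calls: pd.DataFrame, panel_size: int | None = None) -> pd.DataFrame:
    """Per-coregulator category counts and affected fraction.

    ``panel_size`` defaults to the number of distinct genes in the table.
    The affected fraction is reported both exactly and rounded to a whole
    percent (half-up), e.g. 258 affected of a 452-gene panel -> 57.
    """
    cols = ["co+", "co-", "op+", "op-", "affected", "panel", "affected_pct"]
    if calls.empty:
        return pd.DataFrame(columns=cols).rename_axis("coregulator")
    if panel_size is None:
        panel_size = calls["gene"].nunique()
    rows = {}
    for coreg, sub in calls.groupby("coregulator", sort=True):
        counts = sub["category"].value_counts()
        per_cat = {c: int(counts.get(c, 0)) for c in CATEGORIES if c != "unaffected"}
        affected = sum(per_cat.values())
        rows[coreg] = {
            **per_cat,
            "affected": affected,
            "panel": panel_size,
            "affected_pct": int(np.floor(100.0 * affected / panel_size + 0.5))
            if panel_size
            else 0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[cols].rename_axis("coregulator")


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    cols = [
        "gene", "coregulator", "category",
        "c1_log2fc", "c2_log2fc", "c3_log2fc",
        "c1_fdr", "c2_fdr", "c3_fdr",
    ]
    calls[cols].to_csv(path, sep="\t", index=False)
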