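import numpy as np
import pandas as pd
import pytest

from coregdep import ExpressionStudy, GeneAnnotation


@pytest.fixture
def small_annotation() -> GeneAnnotation:
    """Three genes on two chromosomes with known promoter/exon/intron layout."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+"],
            "tss": [(100_000,), (400_000,), (50_000, 70_000)],
            "exons": [
                ((100_000, 101_000), (105_000, 106_500)),
                ((390_000, 392_000), (395_000, 400_001)),
                ((50_000, 52_000), (60_000, 61_000), (69_000, 75_000)),
            ],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return GeneAnnotation(df)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """Noise-free 2-gene study: planted c1=+2 for both; coregX plants c2=+3.5
    for gene g1 (co+) and c2=+2 for g2 (unaffected)."""
    cells = {
        ("control", "vehicle"): {"g1": 8.0, "g2": 8.0},
        ("control", "androgen"): {"g1": 10.0, "g2": 10.0},
        ("coregX", "vehicle"): {"g1": 8.0, "g2": 8.0},
        ("coregX", "androgen"): {"g1": 11.5, "g2": 10.0},
    }
    cols, design_rows, ids = [], [], []
    for (sirna, trt), means in cells.items():
        for rep in (1, 2, 3):
            ids.append(f"{sirna}_{trt}_r{rep}")
            design_rows.append((sirna, trt, rep))
            cols.append([means["g1"], means["g2"]])
    matrix = pd.DataFrame(
        np.array(cols).T, index=["g1", "g2"], columns=ids
    )
    design = pd.DataFrame(
        design_rows,
        index=pd.Index(ids, name="sample_id"),
        columns=["sirna", "treatment", "replicate"],
    )
    return ExpressionStudy(np.exp2(matrix), design, log_transformed=False)
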