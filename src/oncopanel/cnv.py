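"""Per-gene copy-number calling against a pseudonormal baseline.

With no matched normal DNA, the copy-number baseline for a cell-line
panel is a *pseudonormal*: the per-gene arithmetic mean of the
(library-size scaled) capture depths across all panel lines.  Each line
is compared to that baseline on the log2 scale and the ratio is bucketed
into categorical calls (homozygous deletion / loss / neutral / gain /
amplification).

Because the queried line itself contributes to the baseline, a private
aberration in one of n lines attenuates its own ratio by a factor of
about (n-1)/n + c/(2n); with 22 lines the shift is at most ~1/22 on the
linear scale and the default thresholds absorb it.

No segmentation is applied: calls are per gene.  Sex-chromosome genes are
flagged in output but no ploidy correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import DepthMatrix

__all__ = [
    "CNVThresholds",
    "CNVCategory",
    "scale_depths",
    "pseudonormal",
    "log2_ratio",
    "call_cnv",
    "cnv_pipeline",
]

LOG2_CLAMP = 8.0
SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class CNVThresholds:
    """log2-ratio breakpoints for categorical calls, plus the pseudocount.

    Defaults (-1.3 / -0.4 / 0.4 / 1.0) are conventional exome-CNV cutoffs:
    a single-copy loss in a diploid background sits near log2(1/2) = -1 and
    a single-copy gain near log2(3/2) ~ 0.58.
    """

    t_homdel: float = -1.3
    t_loss: float = -0.4
    t_gain: float = 0.4
    t_amp: float = 1.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t_homdel < self.t_loss < 0 < self.t_gain < self.t_amp):
            raise ValueError(
                "thresholds must satisfy t_homdel < t_loss < 0 < t_gain < t_amp; got "
                f"{self.t_homdel}, {self.t_loss}, {self.t_gain}, {self.t_amp}"
            )
        if self.epsilon < 0:
            raise ValueError("pseudocount must be >= 0")


class CNVCategory:
    HOMDEL = "homozygous_deletion"
    LOSS = "loss"
    NEUTRAL = "neutral"
    GAIN = "gain"
    AMP = "amplification"
    ORDER = (HOMDEL, LOSS, NEUTRAL, GAIN, AMP)


def scale_depths(matrix: DepthMatrix) -> DepthMatrix:
    """Equalize per-line medians (library-size normalization).

    Each line is multiplied by (grand median of per-line medians) / (its
    own median), so downstream log2 ratios are invariant to per-line
    multiplicative depth differences.
    """
    medians = matrix.depths.median(axis=0)
    zero = medians[medians <= 0]
    if not zero.empty:
        raise ValueError(f"line(s) with non-positive median depth: {list(zero.index)}")
    target = float(np.median(medians.to_numpy()))
    return DepthMatrix(matrix.depths * (target / medians))


def pseudonormal(matrix: DepthMatrix) -> pd.Series:
    """Per-gene baseline: arithmetic mean depth over all lines (the
    queried line included)."""
    return matrix.depths.mean(axis=1)


def log2_ratio(
    matrix: DepthMatrix, baseline: pd.Series, epsilon: float = 1.0
) -> pd.DataFrame:
    """log2((depth + eps) / (baseline + eps)), clamped to [-8, 8]."""
    depths = matrix.depths
    base = baseline.reindex(depths.index)
    if epsilon == 0.0 and ((depths.to_numpy() == 0).any() or (base.to_numpy() == 0).any()):
        raise ValueError("epsilon must be > 0 when any depth or baseline is zero")
    ratios = np.log2(depths.add(epsilon).div(base + epsilon, axis=0))
    return ratios.clip(lower=-LOG2_CLAMP, upper=LOG2_CLAMP)


def call_cnv(ratios: pd.DataFrame, thresholds: CNVThresholds = CNVThresholds()) -> pd.DataFrame:
    """Bucket log2 ratios into categorical calls.

    Returns a long-form table (gene, line, log2_ratio, category, clamped).
    """
    t = thresholds
    long = ratios.stack().rename("log2_ratio").rename_axis(["gene", "line"]).reset_index()
    r = long["log2_ratio"].to_numpy()
    category = np.full(len(long), CNVCategory.NEUTRAL, dtype=object)
    category[r <= t.t_homdel] = CNVCategory.HOMDEL
    category[(r > t.t_homdel) & (r <= t.t_loss)] = CNVCategory.LOSS
    category[(r >= t.t_gain) & (r < t.t_amp)] = CNVCategory.GAIN
    category[r >= t.t_amp] = CNVCategory.AMP
    long["category"] = category
    long["clamped"] = np.abs(r) >= LOG2_CLAMP
    return long


def cnv_pipeline(
    matrix: DepthMatrix,
    thresholds: CNVThresholds = CNVThresholds(),
    gene_chroms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """scale -> pseudonormal -> log2 ratio -> categorical calls.

    ``gene_chroms`` optionally maps genes to chromosomes so sex-chromosome
    genes can be flagged.
    """
    scaled = scale_depths(matrix)
    baseline = pseudonormal(scaled)
    ratios = log2_ratio(scaled, baseline, thresholds.epsilon)
    calls = call_cnv(ratios, thresholds)
    if gene_chroms:
        calls["sex_chrom"] = calls["gene"].map(
            lambda g: gene_chroms.get(g, "") in SEX_CHROMS
        )
    return calls
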