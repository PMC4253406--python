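"""Two-class differential expression for panel RNA-seq counts.

Two stages mirror the two contrasts the pipeline supports:

* a negative-binomial exact test on read counts (normal vs cancer style
  contrast): library sizes are equalized, a single common dispersion phi
  is estimated by maximizing the summed per-gene conditional NB
  log-likelihood on a grid, and each gene is tested conditionally on its
  total count with a minimum-likelihood two-sided p-value;
* a moderated t-test on log-CPM (HPV+ vs HPV- style contrast): gene-wise
  residual variances are shrunk toward a prior (d0, s0^2) estimated by
  matching the marginal distribution of log s_g^2 to a scaled log-F
  (moment matching via digamma/trigamma), and the moderated statistic is
  referred to t with d0 + d degrees of freedom.

Benjamini-Hochberg FDR and fold-change/significance gating produce the
final up/down calls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .panel_io import CountMatrix

__all__ = [
    "DEThresholds",
    "DEMode",
    "cpm",
    "log_cpm",
    "equalize_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_test",
    "nb_de_table",
    "moderated_t",
    "moderated_t_table",
    "bh_fdr",
    "call_de",
]

_PHI_GRID = np.logspace(np.log10(1e-6), np.log10(5.0), 200)


@dataclass(frozen=True)
class DEThresholds:
    """Gates for declaring a gene differentially expressed.

    ``fc_min`` bounds the linear fold change (default 2, i.e. |log2FC| >= 1);
    ``fdr_max`` applies to BH q-values in the NB stage (default 0.01) and
    ``p_max`` to raw p-values in the moderated-t stage (default 0.05).
    """

    fc_min: float = 2.0
    fdr_max: float = 0.01
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        for name, value in (("fdr_max", self.fdr_max), ("p_max", self.p_max)):
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


class DEMode(str, enum.Enum):
    NB_FDR = "nb_fdr"
    MODT_P = "modt_p"


# ---------------------------------------------------------------------------
# normalization


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million; every column sums to 1e6."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    libsizes = df.sum(axis=0)
    if (libsizes == 0).any():
        raise ValueError(f"zero library size: {list(libsizes[libsizes == 0].index)}")
    return df.div(libsizes, axis=1) * 1e6


def log_cpm(counts: CountMatrix | pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a prior count: log2((y + prior)/(N + 2*prior) * 1e6)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    libsizes = df.sum(axis=0)
    if (libsizes == 0).any():
        raise ValueError(f"zero library size: {list(libsizes[libsizes == 0].index)}")
    return np.log2((df + prior).div(libsizes + 2 * prior, axis=1) * 1e6)


def equalize_library_sizes(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale every sample's counts to the geometric-mean library size.

    Scaled counts are rounded back to integers (exact tests need integer
    sums); the per-sample factors applied are returned alongside.
    """
    libsizes = df.sum(axis=0)
    if (libsizes == 0).any():
        raise ValueError("cannot equalize a sample with zero library size")
    target = float(np.exp(np.mean(np.log(libsizes.to_numpy(dtype=float)))))
    factors = target / libsizes
    equalized = df.mul(factors, axis=1).round().astype(np.int64)
    return equalized, factors


# ---------------------------------------------------------------------------
# NB dispersion and exact test


def _group_masks(groups: pd.Series) -> dict[str, np.ndarray]:
    return {g: (groups == g).to_numpy() for g in sorted(groups.unique())}


def _conditional_loglik(y: np.ndarray, phi: float) -> float:
    """Summed conditional NB log-likelihood for one group (genes × samples).

    Conditional on each gene's group total z, with equal library sizes and
    n samples: sum_i lgamma(y_i + r) - n*lgamma(r) + lgamma(n r) - lgamma(z + n r),
    where r = 1/phi.  Terms free of phi are dropped.
    """
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        special.gammaln(y + r).sum()
        - y.shape[0] * n * special.gammaln(r)
        + y.shape[0] * special.gammaln(n * r)
        - special.gammaln(z + n * r).sum()
    )
    return float(ll)


def estimate_common_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups: pd.Series | None = None,
    grid: np.ndarray = _PHI_GRID,
) -> float:
    """Single dispersion maximizing the summed conditional log-likelihood.

    Library sizes are equalized first; only groups with >= 2 samples
    contribute.  For Poisson data the estimate collapses to the grid
    minimum (~1e-6).
    """
    if isinstance(counts, CountMatrix):
        df, groups = counts.counts, counts.groups
    else:
        df = counts
    if groups is None:
        raise ValueError("group labels are required")
    groups = groups.loc[list(df.columns)]
    if (df.to_numpy() == 0).all():
        raise ValueError("all-zero count matrix")
    equalized, _ = equalize_library_sizes(df)
    values = equalized.to_numpy()
    blocks = [values[:, mask] for mask in _group_masks(groups).values() if mask.sum() >= 2]
    if not blocks:
        raise ValueError("no group has >= 2 samples; dispersion is not estimable")
    lls = [sum(_conditional_loglik(b, phi) for b in blocks) for phi in grid]
    return float(grid[int(np.argmax(lls))])


def nb_exact_test(
    gene_counts: np.ndarray | pd.Series,
    groups: pd.Series | np.ndarray,
    phi: float,
) -> float:
    """Two-sided NB exact p for one gene, conditional on the total.

    With equalized library sizes the two group sums are NB(n_i/phi, p);
    conditional on z = s1 + s2 the split follows a negative-hypergeometric
    law.  The two-sided p sums the probabilities of all splits no more
    probable than the observed one (ties counted once).  At phi = 0 the
    conditional law is Binomial(z, n1/(n1+n2)).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    y = np.asarray(gene_counts, dtype=np.int64)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {list(labels)}")
    n1 = int((g == labels[0]).sum())
    n2 = int((g == labels[1]).sum())
    s1 = int(y[g == labels[0]].sum())
    z = int(y.sum())
    if z == 0:
        return 1.0
    s = np.arange(z + 1)
    if phi == 0.0:
        logpmf = stats.binom.logpmf(s, z, n1 / (n1 + n2))
    else:
        r = 1.0 / phi
        logpmf = (
            special.gammaln(s + n1 * r)
            - special.gammaln(s + 1)
            + special.gammaln(z - s + n2 * r)
            - special.gammaln(z - s + 1)
        )
        logpmf -= special.logsumexp(logpmf)
    obs = logpmf[s1]
    keep = logpmf <= obs + 1e-10
    p = float(np.exp(special.logsumexp(logpmf[keep])))
    return min(p, 1.0)


def nb_de_table(
    counts: CountMatrix,
    group_order: tuple[str, str] | None = None,
    phi: float | None = None,
) -> pd.DataFrame:
    """Full NB stage: equalize, estimate dispersion, test every gene.

    Returns a per-gene table with log2_fold_change (group2 over group1 of
    mean CPM, with a half-count prior), p, and BH q.
    """
    groups = counts.groups
    if group_order is None:
        names = sorted(groups.unique())
        if len(names) != 2:
            raise ValueError(f"exactly two groups required, got {names}")
        group_order = (names[0], names[1])
    g1, g2 = group_order
    if phi is None:
        phi = estimate_common_dispersion(counts.counts, groups)
    equalized, _ = equalize_library_sizes(counts.counts)
    gvec = groups.to_numpy()
    pvals = np.array(
        [nb_exact_test(row, gvec, phi) for row in equalized.to_numpy()]
    )
    cpm_mat = cpm(counts.counts)
    prior_cpm = 0.5 / float(counts.counts.sum(axis=0).mean()) * 1e6
    mean1 = cpm_mat.loc[:, gvec == g1].mean(axis=1) + prior_cpm
    mean2 = cpm_mat.loc[:, gvec == g2].mean(axis=1) + prior_cpm
    table = pd.DataFrame(
        {
            "log2_fold_change": np.log2(mean2 / mean1),
            "p": pvals,
            "q": bh_fdr(pvals),
        },
        index=counts.counts.index.rename("gene"),
    )
    table.attrs["phi"] = phi
    table.attrs["contrast"] = f"{g2} vs {g1}"
    return table


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_log_f_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Estimate (d0, s0^2) by moment matching on log s_g^2.

    Under s_g^2 ~ s0^2 * F(d, d0), e_g = log s_g^2 - digamma(d/2) + log(d/2)
    has mean log s0^2 - digamma(d0/2) + log(d0/2)... rearranged, the excess
    of var(e) over trigamma(d/2) identifies d0, and the mean identifies s0^2.
    Returns d0 = inf when there is no excess variance.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    emean = float(np.mean(e))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    log_expr: pd.DataFrame,
    groups: pd.Series,
    group_order: tuple[str, str] | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene.

    ``d0_override`` forces the prior degrees of freedom: 0 recovers the
    ordinary t statistic, inf complete pooling to s0^2.
    """
    if group_order is None:
        names = sorted(groups.unique())
        if len(names) != 2:
            raise ValueError(f"exactly two groups required, got {names}")
        group_order = (names[0], names[1])
    g1, g2 = group_order
    gvec = groups.loc[list(log_expr.columns)].to_numpy()
    x1 = log_expr.loc[:, gvec == g1].to_numpy(dtype=float)
    x2 = log_expr.loc[:, gvec == g2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    if n1 < 2 or n2 < 2 or d == 0:
        raise ValueError(
            "moderated t needs >= 2 samples per group for variance estimation; "
            "use the NB exact-test stage for unreplicated designs"
        )
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = _fit_log_f_prior(s2, d)
    else:
        d0, s0_sq = _fit_log_f_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0.0:
        s2_post = s2
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = (mean2 - mean1) / se
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    out = pd.DataFrame(
        {
            "log2_fold_change": mean2 - mean1,
            "t": t_stat,
            "p": p,
            "df_total": df_total,
            "s2_posterior": s2_post,
        },
        index=log_expr.index.rename("gene"),
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["contrast"] = f"{g2} vs {g1}"
    return out


def moderated_t_table(
    counts: CountMatrix,
    group_order: tuple[str, str] | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Moderated t on log-CPM, with BH q-values appended."""
    table = moderated_t(log_cpm(counts.counts, prior), counts.groups, group_order)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# FDR and gating


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values with monotonicity enforcement."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN p-values are not allowed")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr.copy()
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


def call_de(
    results: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
    mode: DEMode | str = DEMode.NB_FDR,
) -> tuple[list[str], list[str], dict[str, int]]:
    """Gate a result table into up/down gene lists.

    ``nb_fdr`` mode gates on BH q < fdr_max, ``modt_p`` on raw p < p_max;
    both additionally require |log2FC| >= log2(fc_min).  A ``direction``
    column (up/down/ns) is added to ``results`` in place.
    """
    mode = DEMode(mode)
    log_fc_min = np.log2(thresholds.fc_min)
    lfc = results["log2_fold_change"].to_numpy()
    if mode is DEMode.NB_FDR:
        sig = results["q"].to_numpy() < thresholds.fdr_max
    else:
        sig = results["p"].to_numpy() < thresholds.p_max
    up_mask = sig & (lfc >= log_fc_min)
    down_mask = sig & (lfc <= -log_fc_min)
    direction = np.where(up_mask, "up", np.where(down_mask, "down", "ns"))
    results["direction"] = direction
    up = list(results.index[up_mask])
    down = list(results.index[down_mask])
    counts = {"total": len(up) + len(down), "up": len(up), "down": len(down)}
    return up, down, counts
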