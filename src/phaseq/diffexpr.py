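"""Replicate-aware significance gating, categorisation, ratios, clustering.

Genes are gated by a per-gene one-way fixed-effects ANOVA of RPKM values
across conditions (technical replicates as observations), at raw P < 0.05 by
default — no multiple-testing correction, matching the original analysis; a
Benjamini-Hochberg FDR option is available but off by default. Expression
categories use the study's thresholds (RPKM < 250 silent-or-weak, > 20,000
high). Samples are clustered by average linkage on 1 - Pearson correlation
over log2(RPKM + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quant import RPKMMatrix

DEFAULT_ALPHA = 0.05
WEAK_MAX_RPKM = 250.0
HIGH_MIN_RPKM = 20_000.0
LOG2_PSEUDO = 1.0


class DesignError(ValueError):
    """Replicate/condition structure unusable for the requested analysis."""


def _as_frame(
    rpkm: RPKMMatrix | pd.DataFrame, design: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accept either an RPKMMatrix or a plain gene x sample frame + design."""
    if isinstance(rpkm, RPKMMatrix):
        return rpkm.rpkm, rpkm.design
    if design is None:
        raise DesignError("a design table is required with a plain RPKM frame")
    missing = set(rpkm.columns) - set(design.index)
    if missing:
        raise DesignError(f"samples missing from design: {sorted(missing)}")
    return rpkm, design.loc[list(rpkm.columns)]


def condition_means(
    rpkm: RPKMMatrix | pd.DataFrame, design: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean RPKM per gene per condition over replicates."""
    df, design = _as_frame(rpkm, design)
    return df.T.groupby(design["condition"]).mean().T


# ---------------------------------------------------------------------------
# Per-gene ANOVA
# ---------------------------------------------------------------------------

def anova_per_gene(
    rpkm: RPKMMatrix | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    design: pd.DataFrame | None = None,
    *,
    fdr: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA of RPKM across conditions, per gene.

    Returns a frame indexed by gene with columns ``F_statistic``,
    ``p_value``, ``significant`` and one ``mean_<condition>`` column per
    condition. Genes with zero variance everywhere get p = 1 (never
    significant): a constitutively flat gene is not evidence of change.
    With ``fdr=True`` significance is gated on Benjamini-Hochberg adjusted
    p-values instead of raw ones.
    """
    df, design = _as_frame(rpkm, design)
    cond_of = design["condition"]
    conditions = list(dict.fromkeys(cond_of))
    if len(conditions) < 2:
        raise DesignError("ANOVA needs at least 2 conditions")
    groups = {c: list(design.index[cond_of == c]) for c in conditions}
    for c, samples in groups.items():
        if len(samples) < 2:
            raise DesignError(f"condition {c!r} has < 2 replicates")

    X = df.to_numpy(dtype=float)  # genes x samples
    n_total = X.shape[1]
    k = len(conditions)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    means = {}
    col_idx = {s: i for i, s in enumerate(df.columns)}
    for c in conditions:
        idx = [col_idx[s] for s in groups[c]]
        sub = X[:, idx]
        m = sub.mean(axis=1)
        means[c] = m
        ssb += len(idx) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_between) / (ssw / df_within)
    p = stats.f.sf(F, df_between, df_within)
    # SSW == 0: either flat everywhere (no evidence, p=1) or perfect
    # separation (F -> inf, p -> 0).
    flat = (ssw == 0) & (ssb == 0)
    sep = (ssw == 0) & (ssb > 0)
    F = np.where(flat, 0.0, F)
    p = np.where(flat, 1.0, np.where(sep, 0.0, p))

    result = pd.DataFrame({"F_statistic": F, "p_value": p}, index=df.index)
    if fdr:
        result["p_adjusted"] = stats.false_discovery_control(result["p_value"])
        result["significant"] = result["p_adjusted"] < alpha
    else:
        result["significant"] = result["p_value"] < alpha
    for c in conditions:
        result[f"mean_{c}"] = means[c]
    return result


# ---------------------------------------------------------------------------
# Expression categories
# ---------------------------------------------------------------------------

def classify_expression(
    rpkm: RPKMMatrix | pd.DataFrame,
    weak_max: float = WEAK_MAX_RPKM,
    high_min: float = HIGH_MIN_RPKM,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label each gene in each condition by its mean-RPKM expression band.

    Strictly below ``weak_max`` -> ``silent_or_weak``; strictly above
    ``high_min`` -> ``high``; otherwise ``moderate`` (both thresholds are
    strict, so a gene exactly at 250 is moderate). The boolean column
    ``high_in_any`` flags genes high in at least one condition.
    """
    if not weak_max < high_min:
        raise ValueError("need weak_max < high_min")
    means = condition_means(rpkm, design)
    labels = pd.DataFrame("moderate", index=means.index, columns=means.columns)
    labels = labels.mask(means < weak_max, "silent_or_weak")
    labels = labels.mask(means > high_min, "high")
    labels["high_in_any"] = (means > high_min).any(axis=1)
    return labels


# ---------------------------------------------------------------------------
# Ratio tables
# ---------------------------------------------------------------------------

def expression_ratios(
    rpkm: RPKMMatrix | pd.DataFrame,
    cond_numerator: str,
    cond_denominator: str,
    pseudo: float = 0.0,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fold-change table between two conditions, on replicate-mean RPKM.

    ``pseudo`` is added to both means before dividing; with the default of
    0, genes whose denominator mean is 0 are skipped rather than reported as
    infinite. Sorted by descending ratio.
    """
    means = condition_means(rpkm, design)
    for c in (cond_numerator, cond_denominator):
        if c not in means.columns:
            raise KeyError(f"unknown condition {c!r}")
    num = means[cond_numerator] + pseudo
    den = means[cond_denominator] + pseudo
    if pseudo == 0:
        keep = den > 0
        num, den = num[keep], den[keep]
    ratio = num / den
    with np.errstate(divide="ignore"):
        log2_ratio = np.log2(ratio)
    table = pd.DataFrame(
        {
            f"mean_{cond_numerator}": num - pseudo,
            f"mean_{cond_denominator}": den - pseudo,
            "ratio": ratio,
            "log2_ratio": log2_ratio,
            "direction": np.where(ratio > 1, "up",
                                  np.where(ratio < 1, "down", "unchanged")),
        }
    )
    return table.sort_values("ratio", ascending=False)


def log2_matrix(
    rpkm: RPKMMatrix | pd.DataFrame,
    pseudo: float = LOG2_PSEUDO,
    significant: pd.Series | None = None,
) -> pd.DataFrame:
    """log2(RPKM + pseudo), gene x sample; optionally significant genes only.

    ``significant`` is a boolean Series (e.g. from :func:`anova_per_gene`);
    non-significant genes are excluded at export, mirroring heatmaps that
    omit genes with P above the gate.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    df = rpkm.rpkm if isinstance(rpkm, RPKMMatrix) else rpkm
    mat = np.log2(df + pseudo)
    if significant is not None:
        mat = mat.loc[significant.reindex(mat.index, fill_value=False)]
    return mat


# ---------------------------------------------------------------------------
# Sample clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    samples: list[str]
    linkage: np.ndarray
    newick: str
    nearest_pair: tuple[str, str]
    cophenetic: pd.DataFrame

    def partner_of(self, sample: str) -> str:
        """The sample that joins ``sample`` at the smallest cophenetic height."""
        col = self.cophenetic[sample].drop(sample)
        return str(col.idxmin())


def cluster_samples(log2_mat: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of sample columns on 1 - Pearson correlation.

    Returns the linkage, a newick string of the sample dendrogram, the first
    pair to merge, and the cophenetic distance matrix. A constant input has
    all-zero distances; the resulting order is arbitrary but stable, and a
    warning is issued.
    """
    samples = list(log2_mat.columns)
    if len(samples) < 3:
        raise DesignError("clustering needs at least 3 samples")
    X = log2_mat.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=1)
    if (sd == 0).all():
        warnings.warn("constant matrix: all inter-sample distances are zero",
                      stacklevel=2)
        dist = np.zeros((len(samples), len(samples)))
    else:
        corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    coph = squareform(hierarchy.cophenet(Z))
    coph_df = pd.DataFrame(coph, index=samples, columns=samples)
    i, j = int(Z[0, 0]), int(Z[0, 1])
    tree = hierarchy.to_tree(Z)
    return ClusterResult(samples, Z, _newick(tree, samples),
                         (samples[min(i, j)], samples[max(i, j)]), coph_df)


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.6g}"
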