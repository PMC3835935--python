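"""Expression statistics: NB differential expression with BH FDR, Wallenius
gene-set enrichment, Fisher's exact test, stromal/epithelial signature
scoring, and qPCR expression ratios.

The differential-expression engine is a conditional negative-binomial exact
test with moment-based, shrunken per-gene dispersions.  For each gene the
group sums (on library-size-equalized pseudo-counts) are conditioned on
their total; the two-sided p-value sums the conditional probability of every
outcome as or more extreme — i.e. no more probable — than the one observed.
At dispersion zero this reduces exactly to the conditional binomial
(Poisson) test.  Genes at Benjamini-Hochberg FDR < 0.05 are flagged as
differentially expressed.

Gene-set enrichment uses the Wallenius non-central hypergeometric
distribution, whose odds parameter is the mean selection weight of in-set
genes over that of out-of-set genes; with uniform weights it collapses to
the central hypergeometric (one-sided Fisher) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, hypergeom, nchypergeom_wallenius
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

__all__ = [
    "bh_adjust",
    "estimate_dispersion",
    "nb_exact_test",
    "differential_expression",
    "read_gmt",
    "wallenius_enrichment",
    "fisher_exact",
    "SignatureDefinition",
    "DEFAULT_SIGNATURE",
    "stromal_score",
    "QpcrMeasurement",
    "qpcr_ratio",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _equalize_libraries(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Scale each sample's counts to the geometric-mean library size."""
    totals = totals[counts.columns].astype(float)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    common = float(np.exp(np.log(totals).mean()))
    return counts * (common / totals)


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups,
    prior_df: float = 20.0,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments with shrinkage.

    Within each group the raw estimate is (var - mean) / mean^2, pooled
    across groups with degree-of-freedom weights, then shrunk toward the
    all-gene common dispersion (the mean raw estimate, floored at 0 — the
    mean rather than the median, because the raw estimator's sampling
    distribution is right-skewed and the median systematically
    underestimates the truth) with weight prior_df / (prior_df +
    residual_df).  Library sizes are equalized first when a
    :class:`CountMatrix` is given.
    """
    if isinstance(counts, CountMatrix):
        mat = _equalize_libraries(counts.counts, counts.library_totals)
    else:
        mat = counts.astype(float)
    groups = np.asarray(groups)
    if groups.size != mat.shape[1]:
        raise ValueError("groups must label every sample")
    labels = pd.unique(groups)
    num = np.zeros(mat.shape[0])
    df_total = 0
    single_only = True
    for g in labels:
        sub = mat.loc[:, groups == g].to_numpy()
        n = sub.shape[1]
        if n < 2:
            continue
        single_only = False
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / np.square(m), np.nan)
        num += np.nan_to_num(phi) * (n - 1)
        df_total += n - 1
    if single_only:
        import warnings

        warnings.warn("no group has >= 2 samples; returning common dispersion 0")
        return pd.Series(0.0, index=mat.index)
    raw = num / df_total
    common = max(float(np.nanmean(raw)), 0.0)
    w = prior_df / (prior_df + df_total)
    shrunk = np.clip((1 - w) * raw + w * common, 0.0, None)
    return pd.Series(shrunk, index=mat.index)


def nb_exact_test(
    counts_A,
    counts_B,
    dispersion: float,
    totals_A=None,
    totals_B=None,
) -> float:
    """Two-sided conditional NB exact test for equality of group means.

    Group sums (after optional library-size equalization) are conditioned on
    the pooled total; the p-value sums the probability of every split no
    more probable than the observed one.  ``dispersion=0`` gives the
    conditional binomial (Poisson limit).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.atleast_1d(np.asarray(counts_A, dtype=float))
    b = np.atleast_1d(np.asarray(counts_B, dtype=float))
    if totals_A is not None or totals_B is not None:
        ta = np.atleast_1d(np.asarray(totals_A, dtype=float))
        tb = np.atleast_1d(np.asarray(totals_B, dtype=float))
        allt = np.concatenate([ta, tb])
        if (allt <= 0).any():
            raise ValueError("library totals must be positive")
        common = float(np.exp(np.log(allt).mean()))
        a = a * (common / ta)
        b = b * (common / tb)
    s_a = int(round(a.sum()))
    s_b = int(round(b.sum()))
    return _conditional_nb_p(s_a, s_b, len(a), len(b), dispersion)


def _conditional_nb_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    total = s_a + s_b
    if total == 0:
        return 1.0
    k = np.arange(total + 1)  # candidate group-B sums
    if phi == 0:
        logp = binom.logpmf(k, total, n_b / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(k + r_b)
            - gammaln(k + 1)
            + gammaln(total - k + r_a)
            - gammaln(total - k + 1)
        )
        logp -= logsumexp(logp)
    p_obs = logp[s_b]
    p = float(np.exp(logsumexp(logp[logp <= p_obs + 1e-10])))
    return min(p, 1.0)


def _median_ratio_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to asymmetric DE).

    Ratios are taken against the per-gene geometric mean over genes
    expressed in every sample; factors are scaled to geometric mean 1.
    Falls back to column totals when fewer than 10 genes qualify.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.sum() < 10:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.log(totals).mean())
        return pd.Series(sf, index=counts.columns)
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - ref, axis=0))
    sf /= np.exp(np.log(sf).mean())
    return pd.Series(sf, index=counts.columns)


def differential_expression(
    matrix: CountMatrix,
    groups,
    alpha: float = 0.05,
    prior_df: float = 20.0,
    lfc_offset: float = 0.5,
    normalization: str = "median_ratio",
) -> pd.DataFrame:
    """Per-gene NB exact test between two groups with BH FDR.

    For testing, samples are put on a common scale by median-of-ratios size
    factors (``normalization="median_ratio"``, the default), which stay
    calibrated when differential expression is concentrated in one
    direction; ``"totals"`` uses the stated library totals instead.
    Reported ``log_fold_change`` is log2 of group-B over group-A mean CPM
    (library-total based), offset by ``lfc_offset`` to avoid log of zero.
    Returns columns ``log_fold_change``, ``p_value``, ``fdr`` and ``is_de``
    (fdr < ``alpha``).
    """
    if matrix.counts.empty:
        raise ValueError("empty count matrix")
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("differential expression requires exactly two groups")
    if normalization == "median_ratio":
        sf = _median_ratio_factors(matrix.counts)
        pseudo = matrix.counts / sf
    elif normalization == "totals":
        pseudo = _equalize_libraries(matrix.counts, matrix.library_totals)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    in_a = groups == labels[0]
    in_b = groups == labels[1]
    disp = estimate_dispersion(pseudo, groups, prior_df=prior_df)
    sums_a = pseudo.loc[:, in_a].sum(axis=1).round().astype(int)
    sums_b = pseudo.loc[:, in_b].sum(axis=1).round().astype(int)
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    pvals = np.array(
        [
            _conditional_nb_p(sa, sb, n_a, n_b, phi)
            for sa, sb, phi in zip(sums_a, sums_b, disp)
        ]
    )
    cpm = matrix.cpm()
    mean_a = cpm.loc[:, in_a].mean(axis=1)
    mean_b = cpm.loc[:, in_b].mean(axis=1)
    lfc = np.log2((mean_b + lfc_offset) / (mean_a + lfc_offset))
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log_fold_change": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "is_de": fdr < alpha,
        },
        index=matrix.counts.index,
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {line[:60]!r}")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def wallenius_enrichment(
    de_flags: pd.Series,
    gene_sets: dict[str, set[str]],
    bias_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Over/under-representation of gene sets among DE genes.

    ``de_flags`` is a boolean Series over the gene universe.  The Wallenius
    odds parameter for a set is the mean bias weight of its members divided
    by the mean weight of non-members; with no (or uniform) weights the test
    is the central hypergeometric.  Returns one row per set with
    ``n_in_set``, ``n_de_in_set``, ``odds``, ``p_over``, ``p_under``.
    """
    universe = pd.Index(de_flags.index)
    N = len(universe)
    n_de = int(de_flags.sum())
    if bias_weights is not None:
        bias_weights = bias_weights.reindex(universe)
        if bias_weights.isna().any() or (bias_weights <= 0).any():
            raise ValueError("bias weights must be positive for every gene")
    rows = []
    for set_id, members in gene_sets.items():
        in_set = universe.isin(members)
        K = int(in_set.sum())
        k = int(de_flags[in_set].sum()) if K else 0
        if N == 0 or n_de == 0 or K == 0 or K == N:
            rows.append((set_id, K, k, 1.0, 1.0, 1.0))
            continue
        if bias_weights is None:
            odds = 1.0
        else:
            w = bias_weights.to_numpy()
            odds = float(w[in_set].mean() / w[~in_set].mean())
        if odds == 1.0:
            dist = hypergeom(N, K, n_de)
        else:
            dist = nchypergeom_wallenius(N, K, n_de, odds)
        p_over = float(min(dist.sf(k - 1), 1.0))
        p_under = float(min(dist.cdf(k), 1.0))
        rows.append((set_id, K, k, odds, p_over, p_under))
    return pd.DataFrame(
        rows,
        columns=["set_id", "n_in_set", "n_de_in_set", "odds", "p_over", "p_under"],
    ).set_index("set_id")


def fisher_exact(table) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Two-tailed by the minimum-likelihood convention: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    return float(_scipy_fisher(t, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class SignatureDefinition:
    """Marker genes separating stromal from epithelial expression programs."""

    stromal_genes: tuple[str, ...] = (
        "FN1", "VIM", "CD248", "COL1A2", "COL6A2", "COL6A3",
        "MMP2", "MMP9", "PECAM1", "CD3D", "CD3E", "CD3G",
    )
    epithelial_genes: tuple[str, ...] = ("EPCAM", "CEACAM5", "CDH1")
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if set(self.stromal_genes) & set(self.epithelial_genes):
            raise ValueError("stromal and epithelial gene lists must be disjoint")


DEFAULT_SIGNATURE = SignatureDefinition()


def stromal_score(
    sample_expression: pd.Series,
    signature: SignatureDefinition = DEFAULT_SIGNATURE,
) -> tuple[float, str]:
    """Score a xenograft's human transcriptome as carcinoma- or stroma-like.

    ``sample_expression`` must be log-scale expression indexed by gene
    symbol.  The score is mean(stromal markers) - mean(epithelial markers);
    a score above the signature threshold calls the sample a stromal
    xenograft (SX), otherwise a carcinoma xenograft (CX).
    """
    stromal = [g for g in signature.stromal_genes if g in sample_expression.index]
    epithelial = [g for g in signature.epithelial_genes if g in sample_expression.index]
    if not stromal or not epithelial:
        raise ValueError("expression lacks genes from one of the signature lists")
    score = float(
        sample_expression.loc[stromal].mean()
        - sample_expression.loc[epithelial].mean()
    )
    call = "SX" if score > signature.threshold else "CX"
    return score, call


@dataclass
class QpcrMeasurement:
    """One qPCR N0 estimate (starting concentration, arbitrary units)."""

    gene_id: str
    n0: float | None
    detectable: bool = True

    def __post_init__(self) -> None:
        if self.detectable and (self.n0 is None or self.n0 <= 0):
            raise ValueError("detectable measurements need a positive N0")


@dataclass
class QpcrRatio:
    ratio: float
    flag: str | None  # None, "down", "up", or "indeterminate"


def qpcr_ratio(
    target_a: QpcrMeasurement,
    target_b: QpcrMeasurement,
    gapdh_a: QpcrMeasurement,
    gapdh_b: QpcrMeasurement,
    floor: float,
) -> QpcrRatio:
    """GAPDH-normalized expression ratio between two samples.

    ratio = (N0_target,a / N0_GAPDH,a) / (N0_target,b / N0_GAPDH,b).  An
    undetectable target N0 is replaced by ``floor`` and the substitution
    direction flagged ("down" when the numerator was undetectable, "up" for
    the denominator, "indeterminate" when both were).  Undetectable GAPDH is
    an error: the normalizer cannot be imputed.
    """
    if not (gapdh_a.detectable and gapdh_b.detectable):
        raise ValueError("GAPDH must be detectable in both samples")
    if floor <= 0:
        raise ValueError("floor must be positive")
    na = target_a.n0 if target_a.detectable else floor
    nb = target_b.n0 if target_b.detectable else floor
    if not target_a.detectable and not target_b.detectable:
        flag = "indeterminate"
    elif not target_a.detectable:
        flag = "down"
    elif not target_b.detectable:
        flag = "up"
    else:
        flag = None
    ratio = (na / gapdh_a.n0) / (nb / gapdh_b.n0)
    return QpcrRatio(ratio=float(ratio), flag=flag)
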