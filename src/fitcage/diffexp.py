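"""Count-based differential expression for CAGE promoters.

Implements the standard bulk count-DE toolchain on a promoters x samples
matrix: TMM (trimmed mean of M-values) scaling factors, a common
negative-binomial dispersion estimated by conditional maximum likelihood on
library-equalized counts, the exact conditional NB test for two-group
contrasts, and Benjamini-Hochberg FDR control — together with the
promoter-set logic used to define torpor-specific transcription:

* reversible: significantly up Pre->Mid AND down Mid->Post (or the mirror),
  both at FDR < 0.05;
* hypometabolic: significantly changed toward the torpid (Mid) state in both
  the HiT->Mid and Fed->Mid contrasts, same direction;
* torpor-specific: direction-matched intersection of the two;
* deprivation-specific: single-contrast Mid->Dep split by sign.

No tagwise empirical-Bayes dispersion shrinkage is applied: a single common
dispersion is shared by all promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "PromoterSets",
    "tmm_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "classify_reversible",
    "classify_hypometabolic",
    "torpor_specific",
    "deprivation_specific",
    "rank_by_total_fc",
    "mds_embed",
]


@dataclass
class CountMatrix:
    """Promoters x samples raw tag counts with library sizes and TMM factors.

    ``effective_lib`` (library size x normalization factor) is the scale on
    which all DE computations run.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns).astype(float)
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        self.norm_factors = self.norm_factors.reindex(self.counts.columns).astype(float)
        if (self.norm_factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    @property
    def effective_lib(self) -> pd.Series:
        return self.library_sizes * self.norm_factors

    def with_tmm(self) -> "CountMatrix":
        return CountMatrix(
            self.counts, self.library_sizes, tmm_factors(self.counts, self.library_sizes)
        )


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (geometric mean 1).

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the across-sample mean. For every sample, M (log2 count-
    fraction ratio vs reference) and A (average log2 abundance) are computed
    over promoters expressed in both; the most extreme 30% of M and 5% of A
    are trimmed, and the factor is 2**(precision-weighted mean M), with
    weights from the asymptotic binomial variance of M.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns).astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if (counts.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero count")

    y = counts.to_numpy(dtype=float)
    lib = library_sizes.to_numpy()
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed promoter with the reference"
            )
        pj, pr = yj[ok] / nj, yr[ok] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        v = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = m.size
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
        lo_a, hi_a = np.floor(n * abundance_trim) + 1, n + 1 - (np.floor(n * abundance_trim) + 1)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            keep = np.ones(n, dtype=bool)
        w = 1.0 / v[keep]
        factors[j] = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _equalize_counts(counts: pd.DataFrame, effective_lib: pd.Series) -> np.ndarray:
    """Rescale each sample's counts to the geometric-mean effective library
    size and round to integers (pseudo-counts for the conditional tests)."""
    lib = effective_lib.reindex(counts.columns).to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(lib)))
    scaled = counts.to_numpy(dtype=float) * (common / lib)
    return np.rint(scaled)


def estimate_dispersion(
    matrix: CountMatrix,
    groups: pd.Series,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are scaled to a common effective library size, then the
    conditional log-likelihood of each promoter's within-group counts given
    their group sum (which is free of the mean under equal library sizes) is
    summed over promoters and groups and maximized over the dispersion phi
    (variance = mu + phi*mu^2).
    """
    groups = groups.reindex(matrix.counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    y = _equalize_counts(matrix.counts, matrix.effective_lib)
    if y.sum() == 0:
        raise ValueError("all-zero count matrix")

    group_cols = [np.flatnonzero((groups == g).to_numpy()) for g in groups.unique()]
    group_cols = [c for c in group_cols if len(c) >= 1]

    def neg_cll(log10_phi: float) -> float:
        r = 1.0 / (10.0**log10_phi)
        total = 0.0
        for cols in group_cols:
            if len(cols) < 2:
                continue
            yg = y[:, cols]
            n = len(cols)
            z = yg.sum(axis=1)
            ll = (
                gammaln(yg + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(z + n * r)
            )
            total += ll.sum()
        return -total

    res = minimize_scalar(
        neg_cll,
        bounds=(np.log10(bounds[0]), np.log10(bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    phi = float(10.0**res.x)
    # the bounded optimum sitting on the lower edge means "Poisson-like"
    return max(phi, 0.0)


def _exact_nb_pvalue(a: float, b: float, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional test of equal means.

    Conditions on the pooled total t = a + b over equalized libraries: under
    the null the group-A sum follows (phi>0) the ratio of two NB masses —
    a beta-binomial-like pmf — or (phi->0) Binomial(t, n_a/(n_a+n_b)).
    The p-value is the total mass of splits no more probable than observed.
    """
    t = a + b
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi < 1e-8:
        logpmf = binom.logpmf(x, t, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logpmf = (
            gammaln(x + r_a)
            - gammaln(x + 1)
            + gammaln(t - x + r_b)
            - gammaln(t - x + 1)
        )
        logpmf -= logsumexp(logpmf)
    obs = logpmf[int(a)]
    return float(np.exp(logsumexp(logpmf[logpmf <= obs + 1e-10])))


def nb_exact_test(
    matrix: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    phi: float,
) -> pd.DataFrame:
    """Per-promoter exact conditional NB test of B vs A.

    Returns a DataFrame indexed by promoter with ``logfc`` (log2 of B over A
    mean equalized counts, prior count 0.5 on each), ``pvalue`` and ``fdr``
    (Benjamini-Hochberg). logFC > 0 means higher in B.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    cols = list(group_a) + list(group_b)
    sub = CountMatrix(
        matrix.counts[cols],
        matrix.library_sizes[cols],
        matrix.norm_factors[cols],
    )
    y = _equalize_counts(sub.counts, sub.effective_lib)
    n_a, n_b = len(group_a), len(group_b)
    a_sum = y[:, :n_a].sum(axis=1)
    b_sum = y[:, n_a:].sum(axis=1)

    pvals = np.array(
        [_exact_nb_pvalue(a, b, n_a, n_b, phi) for a, b in zip(a_sum, b_sum)]
    )
    logfc = np.log2((b_sum / n_b + 0.5) / (a_sum / n_a + 0.5))
    return pd.DataFrame(
        {"logfc": logfc, "pvalue": np.minimum(pvals, 1.0), "fdr": bh_adjust(np.minimum(pvals, 1.0))},
        index=matrix.counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PromoterSets:
    """Named promoter sets from the study's classification logic."""

    reversible_up: set = field(default_factory=set)
    reversible_down: set = field(default_factory=set)
    hypometabolic_up: set = field(default_factory=set)
    hypometabolic_down: set = field(default_factory=set)
    torpor_specific_up: set = field(default_factory=set)
    torpor_specific_down: set = field(default_factory=set)
    deprivation_up: set = field(default_factory=set)
    deprivation_down: set = field(default_factory=set)


def _check_universe(*de_results: pd.DataFrame) -> None:
    base = set(de_results[0].index)
    for de in de_results[1:]:
        if set(de.index) != base:
            raise ValueError("DE results cover different promoter universes")


def classify_reversible(
    de_pre_mid: pd.DataFrame, de_mid_post: pd.DataFrame, fdr: float = 0.05
) -> tuple[set, set]:
    """Promoters significantly up Pre->Mid and down Mid->Post (and mirror).

    Both contrasts must clear the FDR threshold with the required logFC sign.
    """
    _check_universe(de_pre_mid, de_mid_post)
    up = set(
        de_pre_mid.index[
            (de_pre_mid["fdr"] < fdr)
            & (de_pre_mid["logfc"] > 0)
            & (de_mid_post["fdr"] < fdr)
            & (de_mid_post["logfc"] < 0)
        ]
    )
    down = set(
        de_pre_mid.index[
            (de_pre_mid["fdr"] < fdr)
            & (de_pre_mid["logfc"] < 0)
            & (de_mid_post["fdr"] < fdr)
            & (de_mid_post["logfc"] > 0)
        ]
    )
    return up, down


def classify_hypometabolic(
    de_hit_mid: pd.DataFrame, de_fed_mid: pd.DataFrame, fdr: float = 0.05
) -> tuple[set, set]:
    """Promoters changed toward the torpid state in both HiT->Mid and
    Fed->Mid contrasts (same direction, both FDR-significant)."""
    _check_universe(de_hit_mid, de_fed_mid)
    up = set(
        de_hit_mid.index[
            (de_hit_mid["fdr"] < fdr)
            & (de_hit_mid["logfc"] > 0)
            & (de_fed_mid["fdr"] < fdr)
            & (de_fed_mid["logfc"] > 0)
        ]
    )
    down = set(
        de_hit_mid.index[
            (de_hit_mid["fdr"] < fdr)
            & (de_hit_mid["logfc"] < 0)
            & (de_fed_mid["fdr"] < fdr)
            & (de_fed_mid["logfc"] < 0)
        ]
    )
    return up, down


def torpor_specific(
    reversible: tuple[set, set], hypometabolic: tuple[set, set]
) -> tuple[set, set]:
    """Direction-matched intersection of reversible and hypometabolic sets."""
    return reversible[0] & hypometabolic[0], reversible[1] & hypometabolic[1]


def deprivation_specific(
    de_mid_dep: pd.DataFrame,
    fdr: float = 0.05,
    torpor_sets: tuple[set, set] | None = None,
) -> dict:
    """Single-contrast Mid->Dep split by logFC sign.

    Returns the up/down sets plus (when ``torpor_sets`` is given) their
    overlap with the torpor-specific sets — the logic that singled out the
    Atf3 promoter in the study design this mirrors.
    """
    sig = de_mid_dep["fdr"] < fdr
    up = set(de_mid_dep.index[sig & (de_mid_dep["logfc"] > 0)])
    down = set(de_mid_dep.index[sig & (de_mid_dep["logfc"] < 0)])
    out = {"up": up, "down": down}
    if torpor_sets is not None:
        out["overlap_torpor_up"] = up & torpor_sets[0]
        out["overlap_torpor_down"] = down & torpor_sets[1]
    return out


def rank_by_total_fc(
    promoters: set, de_first: pd.DataFrame, de_second: pd.DataFrame
) -> pd.DataFrame:
    """Rank promoters by total fold change |logFC1| + |logFC2|, descending.

    Ties break on promoter id (ascending) for a stable order.
    """
    ids = sorted(promoters)
    score = de_first.loc[ids, "logfc"].abs() + de_second.loc[ids, "logfc"].abs()
    out = pd.DataFrame(
        {
            "promoter": ids,
            "logfc_first": de_first.loc[ids, "logfc"].to_numpy(),
            "logfc_second": de_second.loc[ids, "logfc"].to_numpy(),
            "total_fc": score.to_numpy(),
        }
    )
    return (
        out.sort_values(["total_fc", "promoter"], ascending=[False, True])
        .reset_index(drop=True)
    )


def mds_embed(matrix: CountMatrix, top: int = 500, prior: float = 0.5) -> pd.DataFrame:
    """2-D classical MDS of samples on leading-logFC distances.

    The distance between two samples is the root-mean-square of the ``top``
    largest absolute pairwise log2 fold changes (log2 CPM with a prior
    count), embedded by double-centering + eigendecomposition. Coordinates
    are unique up to rotation/reflection.
    """
    lib = matrix.effective_lib.to_numpy(dtype=float)
    logcpm = np.log2((matrix.counts.to_numpy(dtype=float) + prior) / (lib + 2 * prior) * 1e6)
    n = logcpm.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (logcpm[:, i] - logcpm[:, j]) ** 2
            k = min(top, diff2.size)
            lead = np.partition(diff2, diff2.size - k)[diff2.size - k:]
            d[i, j] = d[j, i] = np.sqrt(lead.mean())
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (d**2) @ j_mat
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(coords, index=matrix.counts.columns, columns=["dim1", "dim2"])
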