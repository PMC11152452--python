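"""Isolation by distance and by ecology for inversion frequencies.

Inversion karyotype frequencies are treated as a single biallelic locus per
chromosome; pairwise Weir-Cockerham F_ST (negatives clipped to 0), geographic
great-circle distance and absolute environmental differences enter a multiple
regression on distance matrices (MRM): OLS on the vectorized lower triangles
with Mantel-type significance from jointly permuting the rows/columns of the
response matrix.  Because collinear SNPs experience the same demography, the
same MRM fitted to per-SNP allele-frequency distance matrices yields a null
distribution of coefficients against which the inversion's coefficient is
ranked (Bonferroni-corrected over the chromosomes tested).  A slope contrast
between inversion and collinear F_ST against distance tests whether the
inversion's cline is steeper than the neutral background.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "great_circle_km",
    "single_locus_fst",
    "DistanceMatrixSet",
    "DistanceMatrixRegression",
    "MrmResults",
    "snp_null_test",
    "slope_contrast",
    "abs_diff_matrix",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if not -360.0 <= lon <= 360.0:
            raise ValueError("longitude out of range")
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def single_locus_fst(
    geno_a: tuple[int, int, int], geno_b: tuple[int, int, int], clip: bool = True
) -> float:
    """Weir-Cockerham theta-hat for one biallelic locus and two populations.

    ``geno_a``/``geno_b`` are genotype counts (hom-ref, het, hom-alt) — for an
    inversion locus, (AA, AD, DD).  Negative estimates are clipped to 0
    (``clip=False`` returns the raw value).  NaN if a population has < 2
    samples.
    """
    counts = np.array([geno_a, geno_b], dtype=float)
    n = counts.sum(axis=1)
    if (n < 2).any():
        return math.nan
    r = 2
    p = (counts[:, 2] + 0.5 * counts[:, 1]) / n  # alt-allele frequency
    h = counts[:, 1] / n  # observed heterozygote frequency
    n_bar = n.mean()
    n_c = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    p_bar = (n * p).sum() / n.sum()
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / n.sum()
    a = (n_bar / n_c) * (
        s2
        - 1.0 / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    if denom == 0:
        theta = 0.0
    else:
        theta = a / denom
    return max(theta, 0.0) if clip else theta


# ----------------------------------------------------------------- matrices -


def _check_square(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return m


def abs_diff_matrix(values) -> np.ndarray:
    """|x_i - x_j| matrix from a per-population vector (e.g. allele freq, temp)."""
    v = np.asarray(values, dtype=float)
    return np.abs(v[:, None] - v[None, :])


@dataclass
class DistanceMatrixSet:
    """Aligned symmetric population x population matrices for the MRM."""

    labels: list[str]
    matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.labels)
        for name, m in self.matrices.items():
            m = _check_square(m, name)
            if m.shape[0] != k:
                raise ValueError(f"{name} size does not match label count")
            self.matrices[name] = m

    def add(self, name: str, matrix: np.ndarray) -> None:
        m = _check_square(matrix, name)
        if m.shape[0] != len(self.labels):
            raise ValueError(f"{name} size does not match label count")
        self.matrices[name] = m

    def geo_from_coords(self, lat, lon, name: str = "geo_km") -> None:
        k = len(self.labels)
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                m[i, j] = m[j, i] = great_circle_km(lat[i], lon[i], lat[j], lon[j])
        self.matrices[name] = m


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


# ---------------------------------------------------------------------- MRM -


@dataclass
class MrmResults:
    """Results of a fitted distance-matrix regression.

    ``params`` includes the intercept; permutation p-values are two-sided for
    coefficients and one-sided (upper) for R^2.  ``relative_importance``
    holds LMG variance shares (mean R^2 increment over all predictor
    orderings), which sum to the total R^2.
    """

    params: pd.Series
    r_squared: float
    perm_pvalues: pd.Series
    r_squared_pvalue: float
    vif: pd.Series
    relative_importance: pd.Series
    n_populations: int
    n_pairs: int
    n_permutations: int

    def summary(self) -> str:
        lines = [
            "Multiple regression on distance matrices",
            f"  populations: {self.n_populations}  pairs: {self.n_pairs}  "
            f"permutations: {self.n_permutations}",
            f"  R^2 = {self.r_squared:.4f}  (perm p = {self.r_squared_pvalue:.4g})",
            f"  {'predictor':<16}{'coef':>12}{'perm p':>10}{'VIF':>8}{'R2 share':>10}",
        ]
        for name in self.params.index:
            coef = self.params[name]
            p = self.perm_pvalues.get(name, math.nan)
            v = self.vif.get(name, math.nan)
            share = self.relative_importance.get(name, math.nan)
            lines.append(
                f"  {name:<16}{coef:>12.5g}{p:>10.4g}{v:>8.3g}{share:>10.4g}"
            )
        return "\n".join(lines)


class DistanceMatrixRegression:
    """MRM model: a response distance matrix regressed on predictor matrices.

    OLS (with intercept) on the vectorized lower triangles.  ``fit`` returns
    an :class:`MrmResults`; significance comes from jointly permuting the
    rows and columns of the response matrix (standard Mantel scheme).
    """

    def __init__(self, response: np.ndarray, predictors: dict[str, np.ndarray]):
        self.response = _check_square(response, "response")
        k = self.response.shape[0]
        if k < 4:
            raise ValueError("need >= 4 populations")
        if not predictors:
            raise ValueError("need at least one predictor matrix")
        self.predictor_names = list(predictors)
        self.predictors = {}
        for name, m in predictors.items():
            m = _check_square(m, name)
            if m.shape[0] != k:
                raise ValueError(f"predictor {name} size mismatch")
            self.predictors[name] = m
        self.k = k
        self._X = np.column_stack(
            [np.ones(k * (k - 1) // 2)]
            + [_lower_triangle(self.predictors[n]) for n in self.predictor_names]
        )
        rank = np.linalg.matrix_rank(self._X)
        if rank < self._X.shape[1]:
            corr = np.corrcoef(self._X[:, 1:].T)
            pairs = [
                (self.predictor_names[i], self.predictor_names[j])
                for i in range(len(self.predictor_names))
                for j in range(i + 1, len(self.predictor_names))
                if abs(corr[i, j]) > 0.999
            ]
            raise ValueError(f"rank-deficient predictors; collinear pairs: {pairs}")

    @classmethod
    def from_matrix_set(
        cls, dset: DistanceMatrixSet, response: str, predictors: list[str]
    ) -> "DistanceMatrixRegression":
        return cls(
            dset.matrices[response], {p: dset.matrices[p] for p in predictors}
        )

    # internals ------------------------------------------------------------

    @staticmethod
    def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 0.0
        return beta, r2

    def _r2_subset(self, y: np.ndarray, subset: tuple[int, ...]) -> float:
        cols = [0] + [1 + i for i in subset]
        _, r2 = self._ols(self._X[:, cols], y)
        return r2

    def fit(self, n_permutations: int = 999, seed: int = 0) -> MrmResults:
        y = _lower_triangle(self.response)
        beta, r2 = self._ols(self._X, y)

        rng = np.random.default_rng(seed)
        hits = np.zeros(len(beta))
        r2_hits = 0
        idx = np.arange(self.k)
        for _ in range(n_permutations):
            perm = rng.permutation(idx)
            yp = _lower_triangle(self.response[np.ix_(perm, perm)])
            bp, r2p = self._ols(self._X, yp)
            hits += np.abs(bp) >= np.abs(beta)
            r2_hits += r2p >= r2
        pvals = (1.0 + hits) / (1.0 + n_permutations)
        r2_p = (1.0 + r2_hits) / (1.0 + n_permutations)

        # VIF per predictor (regress each on the others)
        names = self.predictor_names
        vif = {}
        for i, name in enumerate(names):
            if len(names) == 1:
                vif[name] = 1.0
                continue
            others = [j for j in range(len(names)) if j != i]
            cols = [0] + [1 + j for j in others]
            _, r2_i = self._ols(self._X[:, cols], self._X[:, 1 + i])
            vif[name] = 1.0 / (1.0 - r2_i) if r2_i < 1 else math.inf

        # LMG relative importance: mean R^2 increment over all orderings
        p = len(names)
        shares = np.zeros(p)
        r2_cache: dict[tuple[int, ...], float] = {(): 0.0}

        def r2_of(subset: frozenset) -> float:
            key = tuple(sorted(subset))
            if key not in r2_cache:
                r2_cache[key] = self._r2_subset(y, key)
            return r2_cache[key]

        orderings = list(itertools.permutations(range(p)))
        for order in orderings:
            seen: frozenset = frozenset()
            for i in order:
                with_i = seen | {i}
                shares[i] += r2_of(with_i) - r2_of(seen)
                seen = with_i
        shares /= len(orderings)

        param_index = ["intercept"] + names
        return MrmResults(
            params=pd.Series(beta, index=param_index),
            r_squared=r2,
            perm_pvalues=pd.Series(pvals, index=param_index),
            r_squared_pvalue=r2_p,
            vif=pd.Series(vif),
            relative_importance=pd.Series(shares, index=names),
            n_populations=self.k,
            n_pairs=len(y),
            n_permutations=n_permutations,
        )


# --------------------------------------------------------------- SNP null ---


def snp_null_test(
    inversion_freqs: np.ndarray,
    snp_freq_table: np.ndarray,
    predictors: dict[str, np.ndarray],
    n_chromosome_tests: int = 4,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Rank the inversion's MRM coefficients in a per-SNP null distribution.

    Fits the same MRM (response: |delta frequency| matrix) to the inversion
    frequencies and to every null SNP (rows of ``snp_freq_table``, one SNP per
    row, one population per column, pre-filtered here to overall minor allele
    frequency > ``maf_min``).  The two-sided empirical p-value of each
    predictor is (1 + #{|beta_null| >= |beta_inv|}) / (1 + n_snps), then
    Bonferroni-multiplied by ``n_chromosome_tests`` and capped at 1.

    Returns a DataFrame indexed by predictor with beta_inversion, p_empirical,
    p_adjusted and the null coefficient distribution summary.
    """
    snp_freq_table = np.atleast_2d(np.asarray(snp_freq_table, dtype=float))
    if snp_freq_table.size == 0:
        raise ValueError("empty SNP null set")
    overall = snp_freq_table.mean(axis=1)
    keep = np.minimum(overall, 1 - overall) > maf_min
    snps = snp_freq_table[keep]
    if snps.shape[0] == 0:
        raise ValueError("no null SNPs pass the MAF filter")
    if snps.shape[0] < 100:
        warnings.warn(
            f"only {snps.shape[0]} null SNPs; >= 100 recommended", stacklevel=2
        )

    names = list(predictors)

    def betas_for(freqs: np.ndarray) -> np.ndarray:
        model = DistanceMatrixRegression(abs_diff_matrix(freqs), predictors)
        beta, _ = model._ols(model._X, _lower_triangle(model.response))
        return beta[1:]

    beta_inv = betas_for(np.asarray(inversion_freqs, dtype=float))
    null_betas = np.array([betas_for(row) for row in snps])

    n_null = null_betas.shape[0]
    p_emp = (1.0 + (np.abs(null_betas) >= np.abs(beta_inv)).sum(axis=0)) / (
        1.0 + n_null
    )
    p_adj = np.minimum(p_emp * n_chromosome_tests, 1.0)
    return pd.DataFrame(
        {
            "beta_inversion": beta_inv,
            "p_empirical": p_emp,
            "p_adjusted": p_adj,
            "null_mean": null_betas.mean(axis=0),
            "null_sd": null_betas.std(axis=0, ddof=1) if n_null > 1 else np.nan,
            "n_null_snps": n_null,
        },
        index=names,
    )


# ---------------------------------------------------------- slope contrast --


def slope_contrast(
    fst_inversion: np.ndarray,
    fst_collinear: np.ndarray,
    distance: np.ndarray,
) -> dict:
    """Interaction of distance x region (inversion vs collinear) on F_ST.

    Stacks the vectorized pairs of both F_ST matrices and fits
    F_ST ~ distance * is_inversion by OLS; the interaction coefficient
    estimates how much steeper the inversion's distance slope is.  Population
    pairs are not independent data points, so the returned p-value is
    anti-conservative (``caveat_nonindependence`` flags this).
    """
    fi = _lower_triangle(_check_square(fst_inversion, "fst_inversion"))
    fc = _lower_triangle(_check_square(fst_collinear, "fst_collinear"))
    d = _lower_triangle(_check_square(distance, "distance"))
    if not (len(fi) == len(fc) == len(d)):
        raise ValueError("matrices must cover the same population pairs")
    y = np.concatenate([fi, fc])
    dist = np.concatenate([d, d])
    is_inv = np.concatenate([np.ones(len(fi)), np.zeros(len(fc))])
    X = sm.add_constant(
        np.column_stack([dist, is_inv, dist * is_inv]), has_constant="add"
    )
    res = sm.OLS(y, X).fit()
    return {
        "interaction": float(res.params[3]),
        "interaction_p": float(res.pvalues[3]),
        "slope_collinear": float(res.params[1]),
        "slope_inversion": float(res.params[1] + res.params[3]),
        "caveat_nonindependence": True,
    }
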