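"""Unfolded site-frequency spectrum and SFS-based neutrality statistics.

The unfolded SFS tallies derived-allele counts (polarized by an ancestral
state, here from an outgroup genome) into classes xi_1 .. xi_{n-1} for n
sampled chromosomes.  From it the theta estimators

    theta_W = S / a_n                      (Watterson)
    theta_pi = sum i(n-i) xi_i * 2/(n(n-1))  (mean pairwise)
    theta_H = sum i^2 xi_i * 2/(n(n-1))      (Fay & Wu)
    theta_L = sum i xi_i / (n-1)             (Zeng)

feed the standard neutrality tests: Tajima's D, Fu & Li's D and F (using the
derived-singleton count), Fay & Wu's H in the normalized form of Zeng et al.
(2006), and Zeng's E.  Variance constants follow Tajima (1989), Fu & Li
(1993) with the Simonsen et al. (1995) corrections, and Zeng et al. (2006).

Groups are homokaryotype subsets (heterokaryotypes excluded) or populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeTable

__all__ = ["UnfoldedSFS", "unfolded_sfs", "neutrality_stats"]


@dataclass
class UnfoldedSFS:
    """Derived-allele frequency spectrum for n chromosomes.

    ``xi[i-1]`` counts sites with derived-allele count i (i = 1..n-1);
    ``accessible_sites`` is the per-site scaling denominator;
    ``skipped_sites`` counts sites dropped for missing data or an ancestral
    allele matching neither VCF allele.
    """

    n: int
    xi: np.ndarray
    accessible_sites: int = 0
    skipped_sites: int = 0

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=np.int64)
        if self.n < 2:
            raise ValueError("need n >= 2 chromosomes")
        if len(self.xi) != self.n - 1:
            raise ValueError("xi must have length n-1")
        if (self.xi < 0).any():
            raise ValueError("xi must be non-negative")

    @property
    def S(self) -> int:
        return int(self.xi.sum())


def unfolded_sfs(
    table: GenotypeTable,
    ancestral: np.ndarray,
    sample_ids=None,
) -> UnfoldedSFS:
    """Tally derived-allele counts into an unfolded SFS.

    ``ancestral`` gives the per-site ancestral allele as 0 (VCF REF) or
    1 (VCF ALT); any other value marks the site unpolarizable.  Sites with a
    missing genotype in the group, or with an unusable ancestral state, are
    skipped and counted.  n is fixed at twice the group size.
    """
    ids = table.sample_ids if sample_ids is None else list(sample_ids)
    sub = table.take_samples(ids)
    anc = np.asarray(ancestral)
    if len(anc) != sub.n_sites:
        raise ValueError("ancestral-state array must match site count")
    n = 2 * len(ids)
    alt, n_chrom = sub.allele_counts()
    complete = n_chrom == n
    polarizable = (anc == 0) | (anc == 1)
    use = complete & polarizable
    derived = np.where(anc == 0, alt, n - alt)[use]
    seg = (derived > 0) & (derived < n)
    xi = np.bincount(derived[seg], minlength=n)[1:n]
    return UnfoldedSFS(
        n=n,
        xi=xi,
        accessible_sites=int(use.sum()),
        skipped_sites=int((~use).sum()),
    )


# ------------------------------------------------------------- statistics ---


def _harmonics(n: int) -> tuple[float, float]:
    a_n = sum(1.0 / i for i in range(1, n))
    b_n = sum(1.0 / i**2 for i in range(1, n))
    return a_n, b_n


def neutrality_stats(sfs: UnfoldedSFS) -> dict[str, float]:
    """Theta estimators and SFS neutrality tests from an unfolded SFS.

    Returns tajimas_d, fu_li_d, fu_li_f, fay_wu_h_normalized, zeng_e and the
    four theta estimators (per locus; divide by accessible_sites for
    per-site values).  All statistics are NaN when S = 0.
    """
    n = sfs.n
    if n < 4:
        raise ValueError("need n >= 4 chromosomes")
    S = sfs.S
    nan = float("nan")
    if S == 0:
        return {
            k: nan
            for k in (
                "tajimas_d",
                "fu_li_d",
                "fu_li_f",
                "fay_wu_h_normalized",
                "zeng_e",
                "theta_w",
                "theta_pi",
                "theta_h",
                "theta_l",
            )
        }

    i = np.arange(1, n)
    xi = sfs.xi.astype(float)
    a_n, b_n = _harmonics(n)
    comb2 = n * (n - 1) / 2.0

    theta_w = S / a_n
    theta_pi = float((i * (n - i) * xi).sum() / comb2)
    theta_h = float((i**2 * xi).sum() / comb2)
    theta_l = float((i * xi).sum() / (n - 1))
    xi1 = float(xi[0])

    # Tajima's D (Tajima 1989)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a_n
    c2 = b2 - (n + 2) / (a_n * n) + b_n / a_n**2
    e1 = c1 / a_n
    e2 = c2 / (a_n**2 + b_n)
    var_d = e1 * S + e2 * S * (S - 1)
    tajd = (theta_pi - theta_w) / math.sqrt(var_d) if var_d > 0 else nan

    # Fu & Li's D and F, unfolded (Fu & Li 1993; Simonsen et al. 1995)
    c_n = 2.0 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a_n**2 / (b_n + a_n**2)) * (c_n - (n + 1) / (n - 1))
    u_d = a_n - 1.0 - v_d
    var_fld = u_d * S + v_d * S**2
    fld = (S - a_n * xi1) / math.sqrt(var_fld) if var_fld > 0 else nan

    a_n1 = a_n + 1.0 / n  # a_{n+1}
    v_f = (
        c_n + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)
    ) / (a_n**2 + b_n)
    u_f = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * ((n + 1) / (n - 1) ** 2) * (a_n1 - 2.0 * n / (n + 1))
    ) / a_n - v_f
    var_flf = u_f * S + v_f * S**2
    flf = (theta_pi - xi1) / math.sqrt(var_flf) if var_flf > 0 else nan

    # theta and theta^2 moment estimators shared by the Zeng et al. variances
    theta_hat = theta_w
    theta2_hat = S * (S - 1) / (a_n**2 + b_n)

    # Fay & Wu's H, normalized (Zeng et al. 2006, eq. 11-12)
    b_n1 = b_n + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    var_h = (
        (n - 2) / (6.0 * (n - 1)) * theta_hat
        + (
            18.0 * n**2 * (3.0 * n + 2.0) * b_n1
            - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
        )
        / (9.0 * n * (n - 1) ** 2)
        * theta2_hat
    )
    fwh = (theta_pi - theta_l) / math.sqrt(var_h) if var_h > 0 else nan

    # Zeng's E (Zeng et al. 2006, eq. 13-14)
    var_e = (
        (n / (2.0 * (n - 1)) - 1.0 / a_n) * theta_hat
        + (
            b_n / a_n**2
            + 2.0 * (n / (n - 1)) ** 2 * b_n
            - 2.0 * (n * b_n - n + 1.0) / ((n - 1) * a_n)
            - (3.0 * n + 1.0) / (n - 1)
        )
        * theta2_hat
    )
    ze = (theta_l - theta_w) / math.sqrt(var_e) if var_e > 0 else nan

    return {
        "tajimas_d": tajd,
        "fu_li_d": fld,
        "fu_li_f": flf,
        "fay_wu_h_normalized": fwh,
        "zeng_e": ze,
        "theta_w": theta_w,
        "theta_pi": theta_pi,
        "theta_h": theta_h,
        "theta_l": theta_l,
    }
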