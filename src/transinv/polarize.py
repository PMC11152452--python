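"""Ancestral/derived arrangement assignment and distance trees.

A derived inversion originates as a single haplotype and therefore passes
through a severe bottleneck: barring homoplasy and gene conversion it should
share no segregating variation with an outgroup that split before the
inversion arose, whereas the ancestral arrangement retains polymorphism from
the common ancestor.  Polarity is therefore decided by counting, in
non-overlapping windows of 50 SNPs, how many variants segregating in each
homokaryotype class are also present in the outgroup, and testing the
per-window difference with a sign test.  Neighbor-joining trees over
homokaryotype groups provide the trans-species evidence: built from d_xy in
the inverted region, groups cluster by arrangement rather than by population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from skbio import DistanceMatrix
from skbio.tree import nj

from .genotypes import GenotypeTable

__all__ = ["SharingProfile", "outgroup_sharing", "neighbor_joining_tree"]


@dataclass
class SharingProfile:
    """Per-window outgroup-shared-variant counts for the two arrangements.

    ``shared_1``/``shared_2`` count, per non-overlapping window of
    ``window_snps`` segregating sites, the variants segregating in the
    arrangement-1 (resp. arrangement-2) homokaryotype class that are also
    non-reference in the outgroup.  ``polarity`` is "1" or "2" naming the
    arrangement inferred ancestral, or "unpolarized" when the sign test over
    windows is not decisive.
    """

    window_snps: int
    shared_1: np.ndarray
    shared_2: np.ndarray
    total_1: int
    total_2: int
    polarity: str
    p_value: float


def _segregating(alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    return (n >= 4) & (alt > 0) & (alt < n)


def outgroup_sharing(
    table: GenotypeTable,
    class_1_ids,
    class_2_ids,
    outgroup: GenotypeTable,
    window_snps: int = 50,
    alpha: float = 0.05,
) -> SharingProfile:
    """Count outgroup-shared variants per homokaryotype class and decide polarity.

    A site is "shared" for a class when it segregates (0 < freq < 1) in that
    class and the outgroup carries the alternate allele (segregating or
    fixed).  Windows are consecutive blocks of ``window_snps`` sites that
    segregate in at least one class.  The arrangement with significantly
    higher sharing (paired sign test across windows, p < alpha) is called
    ancestral; ties or non-significance yield "unpolarized".
    """
    if table.n_sites != outgroup.n_sites or not np.array_equal(table.pos, outgroup.pos):
        raise ValueError("ingroup and outgroup tables must share site coordinates")
    g1, g2 = list(class_1_ids), list(class_2_ids)
    if 2 * len(g1) < 4 or 2 * len(g2) < 4:
        raise ValueError("each homokaryotype class needs >= 4 chromosomes")

    a1, n1 = table.allele_counts(g1)
    a2, n2 = table.allele_counts(g2)
    ao, no = outgroup.allele_counts()
    seg1 = _segregating(a1, n1)
    seg2 = _segregating(a2, n2)
    out_has_alt = (no > 0) & (ao > 0)

    informative = np.flatnonzero(seg1 | seg2)
    shared1_site = (seg1 & out_has_alt)[informative]
    shared2_site = (seg2 & out_has_alt)[informative]

    n_windows = max(1, len(informative) // window_snps) if len(informative) else 0
    s1 = np.zeros(n_windows, dtype=int)
    s2 = np.zeros(n_windows, dtype=int)
    for w in range(n_windows):
        sl = slice(w * window_snps, (w + 1) * window_snps)
        s1[w] = shared1_site[sl].sum()
        s2[w] = shared2_site[sl].sum()

    total1, total2 = int(shared1_site.sum()), int(shared2_site.sum())
    diff = s1 - s2
    nonzero = diff != 0
    if nonzero.sum() == 0:
        polarity, p = "unpolarized", 1.0
    else:
        wins1 = int((diff > 0).sum())
        test = binomtest(wins1, int(nonzero.sum()), 0.5, alternative="two-sided")
        p = float(test.pvalue)
        if p < alpha and total1 != total2:
            polarity = "1" if total1 > total2 else "2"
        else:
            polarity = "unpolarized"
    return SharingProfile(
        window_snps=window_snps,
        shared_1=s1,
        shared_2=s2,
        total_1=total1,
        total_2=total2,
        polarity=polarity,
        p_value=p,
    )


def neighbor_joining_tree(distances: np.ndarray, labels) -> str:
    """Saitou-Nei neighbor joining on a symmetric distance matrix -> Newick.

    Used on collinear d_xy over populations (species-tree proxy) and on
    inverted-region d_xy over homokaryotype groups, where clustering by
    arrangement across populations is the trans-species signature.
    """
    d = np.asarray(distances, dtype=float)
    labels = list(labels)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] != len(labels):
        raise ValueError("label count must match matrix size")
    if d.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    tree = nj(DistanceMatrix(d, ids=labels))
    return str(tree).strip()
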