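"""Inversion detection, genotyping and validation from genotype dosages.

Detection scans a chromosome in sliding windows (default 10 kb with 2 kb
step) of Hudson/Bhatia F_ST between a population pair; a candidate inversion
span runs from the first to the last window exceeding a threshold, and the
collinear remainder of the chromosome is taken outside the span extended by a
buffer.  Genotyping projects the samples onto PC1 of the dosage matrix inside
the span, where an inversion separates the two homokaryotype classes with
heterokaryotypes in between; a deterministic 1-D k-means (k=3, centers
initialized at min/median/max) turns the trimodal PC1 distribution into
AA/AD/DD calls.  Validation checks the two classic signatures of a
polymorphic inversion: elevated heterozygosity and more negative F_IS in
heterokaryotypes inside the span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "FstWindow",
    "InversionSpan",
    "KaryotypeCalls",
    "hudson_fst_components",
    "windowed_fst",
    "call_inversion_span",
    "karyotype_by_pca",
    "heterozygosity_contrast",
    "hwe_deviation_fis",
]


@dataclass
class FstWindow:
    chrom: str
    start: int  # 0-based half-open, bp
    end: int
    n_sites: int
    fst: float  # NaN when the window has no informative site


@dataclass
class InversionSpan:
    chrom: str
    start: int
    end: int
    threshold: float
    buffer_bp: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("span start must precede end")

    def collinear(self, chrom_length: int) -> list[tuple[int, int]]:
        """Chromosome minus the span extended by the buffer on both sides."""
        out = []
        lo = max(0, self.start - self.buffer_bp)
        hi = min(chrom_length, self.end + self.buffer_bp)
        if lo > 0:
            out.append((0, lo))
        if hi < chrom_length:
            out.append((hi, chrom_length))
        return out


@dataclass
class KaryotypeCalls:
    """Per-sample AA/AD/DD assignment with PC1 scores and cluster centers."""

    genotype: pd.Series  # values in {"AA", "AD", "DD", "unassigned"}
    pc1: pd.Series
    centers: np.ndarray  # ordered along PC1: AA, AD, DD centers
    polarized: bool = False  # polarity provisional until outgroup polarization
    diagnostic: str = "ok"
    truth_note: str = field(default="", repr=False)

    def samples_with(self, *genotypes: str) -> list[str]:
        return list(self.genotype.index[self.genotype.isin(genotypes)])

    @property
    def heterokaryotypes(self) -> list[str]:
        return self.samples_with("AD")

    @property
    def homokaryotypes(self) -> list[str]:
        return self.samples_with("AA", "DD")

    def swap_polarity(self) -> None:
        """Relabel AA <-> DD (used when outgroup polarization flips the call)."""
        self.genotype = self.genotype.map(
            {"AA": "DD", "DD": "AA", "AD": "AD", "unassigned": "unassigned"}
        )
        self.centers = self.centers[::-1].copy()


# ------------------------------------------------------------------- F_ST ---


def hudson_fst_components(
    alt_a: np.ndarray, n_a: np.ndarray, alt_b: np.ndarray, n_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson/Bhatia F_ST numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    with allele counts in chromosomes; sites with n < 2 in either sample are
    returned as NaN and should be excluded from ratio-of-averages sums.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt_a / n_a
        p2 = alt_b / n_b
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n_a - 1)
            - p2 * (1 - p2) / (n_b - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n_a < 2) | (n_b < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def windowed_fst(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    chrom: str | None = None,
    window_bp: int = 10_000,
    step_bp: int = 2_000,
    chrom_length: int | None = None,
) -> list[FstWindow]:
    """Sliding-window Hudson F_ST between two populations.

    Windows combine per-site numerators and denominators as a ratio of
    averages (sum of numerators over sum of denominators).  Windows with no
    informative site carry NaN.  The final window may be truncated at
    ``chrom_length`` (default: last site position + 1).
    """
    if chrom is None:
        chroms = pd.unique(table.chrom)
        if len(chroms) != 1:
            raise ValueError("multiple chromosomes in table; pass chrom=")
        chrom = chroms[0]
    sub = table.restrict(chrom)
    ids_a = sub.population_samples(pop_a)
    ids_b = sub.population_samples(pop_b)
    alt_a, n_a = sub.allele_counts(ids_a)
    alt_b, n_b = sub.allele_counts(ids_b)
    num, den = hudson_fst_components(alt_a, n_a, alt_b, n_b)
    informative = ~np.isnan(den) & (den > 0)

    length = int(chrom_length if chrom_length is not None else (sub.pos.max() + 1 if sub.n_sites else 0))
    out: list[FstWindow] = []
    start = 0
    while start < length:
        end = min(start + window_bp, length)
        lo = np.searchsorted(sub.pos, start, side="left")
        hi = np.searchsorted(sub.pos, end, side="left")
        sl = slice(lo, hi)
        m = informative[sl]
        n_sites = int(m.sum())
        if n_sites:
            fst = float(num[sl][m].sum() / den[sl][m].sum())
            fst = min(fst, 1.0)
        else:
            fst = math.nan
        out.append(FstWindow(chrom, start, end, n_sites, fst))
        if end >= length:
            break
        start += step_bp
    return out


def call_inversion_span(
    windows: list[FstWindow], threshold: float, buffer_bp: int
) -> InversionSpan | None:
    """Span = [start of first, end of last] window with F_ST > threshold.

    Returns None (a no-call, not an error) when no window exceeds the
    threshold.  The collinear complement is available from the span itself.
    """
    if buffer_bp < 0:
        raise ValueError("buffer must be non-negative")
    above = [w for w in windows if not math.isnan(w.fst) and w.fst > threshold]
    if not above:
        return None
    chroms = {w.chrom for w in windows}
    if len(chroms) != 1:
        raise ValueError("windows span multiple chromosomes")
    return InversionSpan(
        chrom=above[0].chrom,
        start=min(w.start for w in above),
        end=max(w.end for w in above),
        threshold=threshold,
        buffer_bp=buffer_bp,
    )


# ------------------------------------------------------------- karyotyping --


def _kmeans_1d(x: np.ndarray, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means, k=3, centers seeded at min/median/max."""
    centers = np.array([x.min(), np.median(x), x.max()], dtype=float)
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        new_labels = d.argmin(axis=1)
        new_centers = centers.copy()
        for k in range(3):
            if (new_labels == k).any():
                new_centers[k] = x[new_labels == k].mean()
        if (new_labels == labels).all() and np.allclose(new_centers, centers):
            break
        labels, centers = new_labels, new_centers
    order = np.argsort(centers)
    remap = np.empty(3, dtype=int)
    remap[order] = np.arange(3)
    return remap[labels], centers[order]


def karyotype_by_pca(
    table: GenotypeTable,
    maf_min: float = 0.01,
    unassign_frac: float | None = 0.45,
    min_separation: float = 2.0,
) -> KaryotypeCalls:
    """Genotype samples for the inversion from PC1 of the span's dosages.

    The dosage matrix (mean-imputed for missing calls, centered, scaled) is
    projected on its first principal component; inside an inversion the three
    karyotype classes form three clusters along PC1 which a deterministic
    1-D k-means separates.  Cluster order along PC1 maps to AA/AD/DD with the
    majority homokaryotype labeled A (polarity provisional until outgroup
    polarization); the PC1 sign is canonicalized so the majority homokaryotype
    cluster has the negative center.

    A sample farther than ``unassign_frac`` x (adjacent center gap) from every
    center is left "unassigned".  Two degeneracy checks guard against calling
    an inversion where there is none: (i) an empty cluster, or an
    adjacent-center gap below ``min_separation`` x the mean within-cluster
    spread, rejects non-trimodal PC1 distributions; (ii) plain population
    structure can also produce three separated PC1 clusters, so the middle
    cluster must additionally be heterozygous at sites strongly
    differentiated between the outer clusters (mean heterozygosity > 0.6
    where the outer-cluster frequency difference exceeds 0.5) — true
    heterokaryotypes carry one haplotype from each arrangement pool there,
    whereas an intermediate population shows at most 2pq = 0.5.
    """
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples for karyotyping")
    d = table.dosages.astype(float)
    d[table.dosages == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = ~np.isnan(p) & (maf > maf_min)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites after MAF filter")
    d = d[:, keep]
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    d -= col_mean
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    d /= sd
    # PC1 via SVD of the centered/scaled matrix
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    pc1 = d @ vt[0]

    labels, centers = _kmeans_1d(pc1)
    counts = np.bincount(labels, minlength=3)
    gaps = np.diff(centers)
    spread = np.array(
        [pc1[labels == k].std() if counts[k] > 1 else 0.0 for k in range(3)]
    )
    mean_spread = spread[counts > 1].mean() if (counts > 1).any() else 0.0

    index = table.samples.index

    def _degenerate(reason: str) -> KaryotypeCalls:
        return KaryotypeCalls(
            genotype=pd.Series("unassigned", index=index),
            pc1=pd.Series(pc1, index=index),
            centers=centers,
            diagnostic=f"no-inversion: {reason}",
        )

    if (counts == 0).any() or (
        mean_spread > 0 and gaps.min() < min_separation * mean_spread
    ):
        return _degenerate("PC1 clustering degenerate")

    # heterokaryotype check: raw (unimputed) dosages at outer-cluster-
    # differentiated sites; d was overwritten, so recompute from the table
    raw = table.dosages.astype(float)
    raw[table.dosages == MISSING] = np.nan
    raw = raw[:, keep]
    with np.errstate(invalid="ignore"):
        p_low = np.nanmean(raw[labels == 0], axis=0) / 2.0
        p_high = np.nanmean(raw[labels == 2], axis=0) / 2.0
    diag_sites = np.abs(p_low - p_high) > 0.5
    if diag_sites.sum() < 10:
        return _degenerate("too few arrangement-diagnostic sites")
    mid = raw[np.ix_(labels == 1, diag_sites)]
    mid_het = np.nanmean(mid == 1.0)
    if not mid_het > 0.6:
        return _degenerate(
            f"middle cluster not heterozygous at diagnostic sites (het={mid_het:.2f})"
        )

    # canonical sign: majority homokaryotype cluster gets the negative center
    majority_low = counts[0] >= counts[2]
    if not majority_low:
        pc1 = -pc1
        labels = 2 - labels
        centers = -centers[::-1]
        counts = counts[::-1]
        gaps = np.diff(centers)

    names = np.array(["AA", "AD", "DD"])
    geno = names[labels].astype(object)
    if unassign_frac is not None:
        dist = np.abs(pc1[:, None] - centers[None, :])
        cutoff = np.array([gaps[0], min(gaps), gaps[1]]) * unassign_frac
        far = (dist > cutoff[None, :]).all(axis=1)
        geno[far] = "unassigned"

    return KaryotypeCalls(
        genotype=pd.Series(geno, index=index),
        pc1=pd.Series(pc1, index=index),
        centers=centers,
    )


# -------------------------------------------------------------- validation --


def _het_proportion(table: GenotypeTable, ids) -> np.ndarray:
    pos_idx = table.samples.index.get_indexer(list(ids))
    d = table.dosages[pos_idx, :]
    called = (d != MISSING).sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, het / called, np.nan)


def heterozygosity_contrast(
    table: GenotypeTable,
    calls: KaryotypeCalls,
    span: InversionSpan,
    chrom_length: int,
    n_permutations: int = 999,
    seed: int = 0,
    males_only: bool = False,
) -> dict:
    """Heterozygosity excess of heterokaryotypes inside the inversion.

    Per sample, the proportion of heterozygous calls among non-missing sites
    is computed inside the span and over the collinear remainder; the
    contrast is mean(AD inside-outside) - mean(homokaryotype inside-outside),
    with a one-sided permutation p-value over karyotype labels.  For Z-linked
    spans pass ``males_only=True`` to drop females (single Z).
    """
    samples = table.samples
    keep = samples.index
    if males_only:
        keep = samples.index[samples["sex"] == "M"]
    geno = calls.genotype.loc[keep]
    het_ids = list(geno.index[geno == "AD"])
    hom_ids = list(geno.index[geno.isin(["AA", "DD"])])
    if not het_ids or not hom_ids:
        return {"contrast": math.nan, "p_value": math.nan, "n_het": len(het_ids), "n_hom": len(hom_ids)}

    inside = table.restrict(span.chrom, span.start, span.end)
    parts = span.collinear(chrom_length)
    masks = np.zeros(table.n_sites, dtype=bool)
    for lo, hi in parts:
        masks |= (table.chrom == span.chrom) & (table.pos >= lo) & (table.pos < hi)
    outside = table.take_sites(masks)

    ids = het_ids + hom_ids
    diff = _het_proportion(inside, ids) - _het_proportion(outside, ids)
    is_het = np.array([True] * len(het_ids) + [False] * len(hom_ids))
    observed = float(np.nanmean(diff[is_het]) - np.nanmean(diff[~is_het]))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(is_het)
        stat = np.nanmean(diff[perm]) - np.nanmean(diff[~perm])
        if stat >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return {"contrast": observed, "p_value": p, "n_het": len(het_ids), "n_hom": len(hom_ids)}


def hwe_deviation_fis(table: GenotypeTable, sample_ids=None) -> float:
    """Mean per-site F_IS = 1 - H_obs/H_exp over polymorphic sites.

    H_exp uses the sample-size-corrected 2*p*q*(2n)/(2n-1); monomorphic sites
    are skipped; NaN when every site is monomorphic.  Negative values mark
    heterozygote excess, the signature of heterokaryotype groups inside an
    inversion.
    """
    ids = table.sample_ids if sample_ids is None else list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples for F_IS")
    sub = table.take_samples(ids)
    alt, n_chrom = sub.allele_counts()
    het, n_called = sub.heterozygote_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_chrom
        poly = (n_chrom >= 4) & (alt > 0) & (alt < n_chrom)
        h_obs = het / n_called
        h_exp = 2.0 * p * (1 - p) * n_chrom / (n_chrom - 1)
        fis = 1.0 - h_obs / h_exp
    if not poly.any():
        return math.nan
    return float(np.nanmean(fis[poly]))
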