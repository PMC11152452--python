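"""Readers/writers for the formats the pipeline touches, plus run configuration.

VCF input goes through cyvcf2 and keeps only biallelic SNPs (skips logged);
positions become 0-based internally and 1-based again on output.  TSV outputs
carry a provenance comment (tool version, seed, config hash) so a run can be
reproduced from its artifacts.  BED output is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import __version__
from .genotypes import MISSING, GenotypeTable
from .scan import InversionSpan

log = logging.getLogger("transinv")

__all__ = [
    "RunConfig",
    "read_vcf",
    "write_vcf",
    "read_samples",
    "read_env",
    "write_bed",
    "write_tsv",
    "read_tsv",
    "provenance_line",
]


@dataclass
class RunConfig:
    """Analysis constants with documented defaults.

    F_ST thresholds and buffers are per target region and in practice are
    chosen post hoc per chromosome (typical megabase-scale values:
    thresholds 0.39-0.94, buffers 0.5-1 Mb); override per dataset.
    """

    window_bp: int = 10_000
    step_bp: int = 2_000
    fst_threshold: float = 0.5
    buffer_bp: int = 500_000
    maf_min: float = 0.01
    polarize_window_snps: int = 50
    n_permutations: int = 999
    mu_per_site_year: float = 2.45e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.window_bp, self.step_bp) <= 0 or self.buffer_bp < 0:
            raise ValueError("window/step must be positive, buffer non-negative")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.mu_per_site_year <= 0:
            raise ValueError("mutation rate must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(config: RunConfig | None = None, seed: int | None = None) -> str:
    parts = [f"#transinv\tversion={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config.digest()}")
    return "\t".join(parts)


def parse_provenance(path) -> dict[str, str]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("#transinv"):
        return {}
    return dict(p.split("=", 1) for p in first.split("\t")[1:])


# ----------------------------------------------------------------- samples --


def read_samples(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, population[, species, region, latitude, longitude, sex]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})
    if "sample" not in df.columns or "population" not in df.columns:
        raise ValueError("sample sheet needs 'sample' and 'population' columns")
    if df["sample"].duplicated().any():
        dupes = df["sample"][df["sample"].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if df["population"].isna().any() or (df["population"].astype(str) == "").any():
        raise ValueError("populations must be non-empty")
    return df.set_index("sample")


def read_env(path) -> pd.DataFrame:
    """Environment table: population, precipitation, temperature (TSV or CSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    need = {"population", "precipitation", "temperature"}
    if not need <= set(df.columns):
        raise ValueError(f"environment table needs columns {sorted(need)}")
    return df.set_index("population")


# --------------------------------------------------------------------- VCF --


def read_vcf(path, samples: pd.DataFrame | None = None, region: str | None = None) -> GenotypeTable:
    """Load biallelic SNPs from a VCF into a GenotypeTable.

    Multiallelic and non-SNP records are skipped (counts logged).  ``samples``
    is a sample sheet indexed by sample id; every VCF sample must appear in
    it.  ``region`` is "chrom" or "chrom:start-end" in 1-based coordinates,
    applied while streaming (works on uncompressed, unindexed VCF).
    """
    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    if samples is not None:
        unknown = [s for s in vcf_samples if s not in samples.index]
        if unknown:
            raise ValueError(f"VCF samples missing from sample sheet: {unknown}")
        meta = samples.loc[vcf_samples].copy()
    else:
        meta = pd.DataFrame({"population": "pop0"}, index=pd.Index(vcf_samples, name="sample"))

    want_chrom, lo, hi = None, None, None
    if region:
        if ":" in region:
            want_chrom, rng = region.split(":", 1)
            a, b = rng.split("-")
            lo, hi = int(a), int(b)
        else:
            want_chrom = region

    chroms, positions, rows = [], [], []
    skipped = {"multiallelic": 0, "non_snp": 0, "outside_region": 0}
    for v in vcf:
        if want_chrom is not None:
            if v.CHROM != want_chrom or (lo is not None and not (lo <= v.POS <= hi)):
                skipped["outside_region"] += 1
                continue
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not v.is_snp:
            skipped["non_snp"] += 1
            continue
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)  # to 0-based
        rows.append(g)
    vcf.close()
    log.info(
        "read_vcf: kept %d sites, skipped %s", len(positions),
        {k: n for k, n in skipped.items() if n},
    )
    if positions:
        dosages = np.column_stack(rows) if rows else np.empty((len(meta), 0), np.int8)
    else:
        dosages = np.empty((len(meta), 0), dtype=np.int8)
    return GenotypeTable(dosages, np.array(chroms, dtype=object), np.array(positions), meta)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as a minimal uncompressed VCF (GT only)."""
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source=transinv {__version__}\n")
    for c in pd.unique(table.chrom):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(table.sample_ids) + "\n")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    d = table.dosages
    for j in range(table.n_sites):
        cols = [
            str(table.chrom[j]), str(table.pos[j] + 1), ".", "A", "T", ".", "PASS", ".", "GT",
        ]
        cols.extend(gt_str[int(d[i, j])] for i in range(table.n_samples))
        buf.write("\t".join(cols) + "\n")
    Path(path).write_text(buf.getvalue())


# ------------------------------------------------------------------ tables --


def write_bed(spans: list[InversionSpan] | InversionSpan, path) -> None:
    """0-based half-open BED lines, one per span."""
    if isinstance(spans, InversionSpan):
        spans = [spans]
    lines = [f"{s.chrom}\t{s.start}\t{s.end}" for s in spans]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tsv(df: pd.DataFrame, path, config: RunConfig | None = None, seed: int | None = None) -> None:
    """TSV with header and a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(provenance_line(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=df.index.name is not None)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
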