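"""Per-sample mitogene-pool summary statistics.

Computes, for one pooled egg or hatchling sample: mitogenome copy number
from the mtDNA:chromosomal coverage ratio, heteroplasmy burden per
mitogenome and per cell, MAF summaries, the Ts/Tv substitution spectrum,
the frequency-weighted dN/dS ratio, the Grantham-based genetic-load ratio,
and the per-region HP-site table.

The frequency-weighted dN/dS used here is the raw ratio of summed minor
allele frequencies at nonsynonymous vs synonymous coding sites (no
per-site opportunity normalization); a Nei-Gojobori-style site-normalized
variant is available behind ``normalize_sites=True``. Undefined ratios
(zero denominators, empty site lists) are reported as NaN markers, never
raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .mito_model import (
    ACCEPTED_LOF_LABELS,
    BASES,
    MitoAnnotation,
    NONSYNONYMOUS_EFFECTS,
    translate_codon,
    _coding_sequence,
)

UNDEFINED = float("nan")


@dataclass
class CoverageSummary:
    """Mean sequencing depth per nuclear chromosome and for the mitogenome."""

    chrom_depths: np.ndarray
    mt_depth: float

    def __post_init__(self) -> None:
        self.chrom_depths = np.asarray(self.chrom_depths, dtype=float)
        if (self.chrom_depths <= 0).any() or self.mt_depth <= 0:
            raise ValueError("all depths must be positive")

    @property
    def chrom_mean(self) -> float:
        return float(self.chrom_depths.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chromosome": f"chr{i + 1}", "mean_depth": d}
            for i, d in enumerate(self.chrom_depths)
        ]
        rows.append({"chromosome": "MT", "mean_depth": self.mt_depth})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "CoverageSummary":
        df = pd.read_csv(path, sep="\t")
        mt = df[df["chromosome"] == "MT"]["mean_depth"]
        if mt.empty:
            raise ValueError("coverage table has no MT row")
        chrom = df[df["chromosome"] != "MT"]["mean_depth"].to_numpy()
        return cls(chrom_depths=chrom, mt_depth=float(mt.iloc[0]))


@dataclass
class PoolSample:
    """A pooled egg or hatchling sample with its filtered, annotated HP sites."""

    sample_id: str
    tissue: str  # egg | hatchling
    pool_size: int
    nuclear_ploidy: int
    hp_sites: pd.DataFrame
    coverage: CoverageSummary
    female_id: str | None = None

    def __post_init__(self) -> None:
        expected = {"egg": 1, "hatchling": 2}
        if self.tissue not in expected:
            raise ValueError(f"tissue must be egg or hatchling, got {self.tissue!r}")
        if self.nuclear_ploidy != expected[self.tissue]:
            raise ValueError(
                f"{self.tissue} samples must have nuclear ploidy "
                f"{expected[self.tissue]}, got {self.nuclear_ploidy}"
            )


def copy_number(coverage: CoverageSummary, nuclear_ploidy: int) -> float:
    """Mitogenome copies per cell from the coverage ratio.

    copies = ploidy * mt_depth / chromosomal_mean_depth; for haploid eggs
    this is the plain depth ratio, for diploid somatic cells it is doubled.
    """
    denom = coverage.chrom_mean
    if denom <= 0:
        raise ValueError("chromosomal mean depth must be positive")
    return nuclear_ploidy * coverage.mt_depth / denom


def hp_burden(hp_sites: pd.DataFrame, copies_per_cell: float) -> tuple[float, float]:
    """Heteroplasmy burden: (per mitogenome, per cell).

    The per-mitogenome burden is the summed MAF over HP sites — the
    expected number of heteroplasmic substitutions carried by a single
    mtDNA copy; per cell scales by the copy number.
    """
    per_mito = float(hp_sites["maf"].sum()) if len(hp_sites) else 0.0
    return per_mito, per_mito * copies_per_cell


def spectrum_summary(hp_sites: pd.DataFrame) -> dict:
    """Ts/Tv substitution spectrum: counts, percentages, and Tv/Ts ratio.

    With no transitions the ratio is an undefined (NaN) marker; with no
    sites percentages are undefined too.
    """
    n = len(hp_sites)
    ts = int((hp_sites["ts_tv"] == "Ts").sum()) if n else 0
    tv = int((hp_sites["ts_tv"] == "Tv").sum()) if n else 0
    return {
        "ts_count": ts,
        "tv_count": tv,
        "ts_pct": 100.0 * ts / n if n else UNDEFINED,
        "tv_pct": 100.0 * tv / n if n else UNDEFINED,
        "tv_ts_ratio": tv / ts if ts else UNDEFINED,
    }


def dnds(
    hp_sites: pd.DataFrame,
    normalize_sites: bool = False,
    reference: str | None = None,
    annotation: MitoAnnotation | None = None,
) -> tuple[float, float, float]:
    """Frequency-weighted dN/dS over coding HP sites.

    dN is the summed MAF over nonsynonymous sites (missense and
    loss-of-function classes), dS the summed MAF over synonymous sites;
    the ratio is NaN when dS is zero. With ``normalize_sites=True`` the
    sums are divided by the Nei-Gojobori potential nonsynonymous and
    synonymous site counts of the reference CDS (requires ``reference``
    and ``annotation``).
    """
    if len(hp_sites):
        nonsyn = hp_sites["effect"].isin(NONSYNONYMOUS_EFFECTS)
        syn = hp_sites["effect"] == "synonymous"
        dn = float(hp_sites.loc[nonsyn, "maf"].sum())
        ds = float(hp_sites.loc[syn, "maf"].sum())
    else:
        dn = ds = 0.0
    if normalize_sites:
        if reference is None or annotation is None:
            raise ValueError("normalize_sites requires reference and annotation")
        n_sites, s_sites = potential_sites(reference, annotation)
        dn, ds = dn / n_sites, ds / s_sites
    ratio = dn / ds if ds > 0 else UNDEFINED
    return dn, ds, ratio


def potential_sites(reference: str, annotation: MitoAnnotation) -> tuple[float, float]:
    """Nei-Gojobori potential (nonsynonymous, synonymous) site counts over
    all complete reference codons of all CDS features."""
    n_sites = s_sites = 0.0
    for parts in annotation.cds_groups().values():
        cds = _coding_sequence(reference, parts)
        table_id = parts[0].table_id
        for idx in range(len(cds) // 3):
            codon = cds[idx * 3 : idx * 3 + 3]
            aa = translate_codon(codon, table_id)
            if aa == "*":
                continue
            for within in range(3):
                syn_frac = sum(
                    translate_codon(
                        codon[:within] + b + codon[within + 1 :], table_id
                    ) == aa
                    for b in BASES
                    if b != codon[within]
                ) / 3.0
                s_sites += syn_frac
                n_sites += 1.0 - syn_frac
    return n_sites, s_sites


def genetic_load(hp_sites: pd.DataFrame, grantham_threshold: float = 150.0) -> dict:
    """Genetic-load accounting over annotated HP sites.

    Load sites are loss-of-function effects plus missense changes with
    Grantham score strictly above the threshold; the load ratio divides by
    ALL HP sites (noncoding included). Splice LOF labels from imported
    annotations are counted if present but never produced by this package.
    """
    n = len(hp_sites)
    if n:
        lof = hp_sites["effect"].isin(ACCEPTED_LOF_LABELS)
        deleterious = (hp_sites["effect"] == "missense") & (
            hp_sites["grantham"] > grantham_threshold
        )
        n_lof = int(lof.sum())
        n_del = int(deleterious.sum())
    else:
        n_lof = n_del = 0
    total = n_lof + n_del
    return {
        "n_lof": n_lof,
        "n_deleterious_missense": n_del,
        "total_load_count": total,
        "load_ratio": total / n if n else UNDEFINED,
    }


def region_table(hp_sites: pd.DataFrame) -> pd.DataFrame:
    """Per-region HP-site table: count, proportion of HP sites (%), and
    mean MAF (%); proportions sum to 100 over all observed regions."""
    if hp_sites.empty:
        return pd.DataFrame(columns=["region", "count", "proportion_pct", "mean_maf_pct"])
    grp = hp_sites.groupby("region", sort=True)
    out = pd.DataFrame(
        {
            "count": grp.size(),
            "mean_maf_pct": grp["maf"].mean() * 100.0,
        }
    )
    out["proportion_pct"] = 100.0 * out["count"] / len(hp_sites)
    out = out.sort_values(["count", "region"], ascending=[False, True]).reset_index()
    return out[["region", "count", "proportion_pct", "mean_maf_pct"]]


@dataclass
class PoolMetrics:
    """All per-sample summary statistics."""

    sample_id: str
    tissue: str
    copies_per_cell: float
    hp_site_count: int
    hp_per_mitogenome: float
    hp_per_cell: float
    maf_mean: float
    maf_min: float
    maf_max: float
    ts_count: int
    tv_count: int
    ts_pct: float
    tv_pct: float
    tv_ts_ratio: float
    dN: float
    dS: float
    dnds: float
    n_lof: int
    n_deleterious_missense: int
    total_load_count: int
    load_ratio: float
    regions: pd.DataFrame = field(repr=False)
    female_id: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "regions"}
        return d


def compute_metrics(sample: PoolSample, grantham_threshold: float = 150.0) -> PoolMetrics:
    """Assemble every summary statistic for one pooled sample."""
    sites = sample.hp_sites
    copies = copy_number(sample.coverage, sample.nuclear_ploidy)
    per_mito, per_cell = hp_burden(sites, copies)
    spectrum = spectrum_summary(sites)
    dn, ds, ratio = dnds(sites)
    load = genetic_load(sites, grantham_threshold)
    mafs = sites["maf"] if len(sites) else pd.Series(dtype=float)
    return PoolMetrics(
        sample_id=sample.sample_id,
        tissue=sample.tissue,
        female_id=sample.female_id,
        copies_per_cell=copies,
        hp_site_count=len(sites),
        hp_per_mitogenome=per_mito,
        hp_per_cell=per_cell,
        maf_mean=float(mafs.mean()) if len(mafs) else UNDEFINED,
        maf_min=float(mafs.min()) if len(mafs) else UNDEFINED,
        maf_max=float(mafs.max()) if len(mafs) else UNDEFINED,
        ts_count=spectrum["ts_count"],
        tv_count=spectrum["tv_count"],
        ts_pct=spectrum["ts_pct"],
        tv_pct=spectrum["tv_pct"],
        tv_ts_ratio=spectrum["tv_ts_ratio"],
        dN=dn,
        dS=ds,
        dnds=ratio,
        n_lof=load["n_lof"],
        n_deleterious_missense=load["n_deleterious_missense"],
        total_load_count=load["total_load_count"],
        load_ratio=load["load_ratio"],
        regions=region_table(sites),
    )


def metrics_frame(metrics: Iterable[PoolMetrics]) -> pd.DataFrame:
    """One metrics row per sample."""
    return pd.DataFrame([m.to_dict() for m in metrics])
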