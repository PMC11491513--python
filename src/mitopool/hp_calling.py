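"""Heteroplasmic-site calling and filtering.

Converts per-site allele counts (pileup-derived TSV or VCF) into candidate
minor-allele variants with an exact binomial sequencing-error p-value, then
applies the five-criterion heteroplasmy filter: allele base quality,
mapping quality, minor allele frequency, p-value, and depth strictly above
the per-sample median depth of candidate sites.

Site tables are pandas DataFrames. Allele-count tables carry columns
``position, ref, A, C, G, T, depth, bq_A, bq_C, bq_G, bq_T, map_qual``
(a single ``base_qual`` column is accepted in site-mean quality mode);
variant tables carry ``position, ref, alt, alt_count, depth, maf, p_value,
base_qual, map_qual`` plus, after annotation, ``ts_tv, region, effect,
gene, aa_change, grantham, is_load``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mito_model import (
    BASES,
    LOF_EFFECTS,
    GranthamModel,
    DEFAULT_GRANTHAM,
    MitoAnnotation,
    classify_substitution,
    effect_calls,
    EFFECT_SEVERITY,
)

logger = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "position", "ref", "A", "C", "G", "T", "depth",
    "bq_A", "bq_C", "bq_G", "bq_T", "map_qual",
]
VARIANT_COLUMNS = [
    "position", "ref", "alt", "alt_count", "depth", "maf", "p_value",
    "base_qual", "map_qual",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the heteroplasmy filter.

    All inequalities are strict, matching the filtering criteria: base
    quality > 20, mapping quality > 30, MAF > 0.1%, p-value < 0.05, and
    depth > per-sample median depth over candidate sites. ``error_rate``
    parameterizes the binomial sequencing-error null for the minor-allele
    p-value. ``quality_mode`` selects whether base quality is judged on the
    minor allele's reads ("allele") or on the site mean ("site").
    """

    min_base_quality: float = 20.0
    min_mapping_quality: float = 30.0
    min_maf: float = 0.001
    max_p: float = 0.05
    error_rate: float = 0.001
    quality_mode: str = "allele"

    def __post_init__(self) -> None:
        if not (0 < self.min_maf < 0.5):
            raise ValueError("min_maf must be in (0, 0.5)")
        for name in ("min_base_quality", "min_mapping_quality", "max_p", "error_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.quality_mode not in ("allele", "site"):
            raise ValueError("quality_mode must be 'allele' or 'site'")

    def with_(self, **kw) -> "FilterConfig":
        return replace(self, **kw)


def call_candidates(counts: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Derive candidate heteroplasmic variants from per-site allele counts.

    At each site the most frequent non-reference allele becomes the
    candidate minor allele; sites with no non-reference reads are omitted.
    When the non-reference allele exceeds 50% of reads the site is treated
    as a consensus difference: the minor allele is re-derived from the
    remaining bases (which may be the reference itself), and sites whose
    minor-allele count is zero (fixed differences) are dropped, so MAF is
    always oriented into (0, 0.5]. The p-value is the one-sided exact
    binomial tail P(X >= alt_count | depth, error_rate).
    """
    config = config or FilterConfig()
    if counts.empty:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    bad_ref = ~counts["ref"].isin(BASES)
    if bad_ref.any():
        pos = counts.loc[bad_ref, "position"].iloc[0]
        raise ValueError(f"reference base not in ACGT at position {pos}")

    n_zero = int((counts["depth"] <= 0).sum())
    if n_zero:
        logger.info("skipping %d zero-depth sites", n_zero)
    df = counts[counts["depth"] > 0].reset_index(drop=True)

    mat = df[list(BASES)].to_numpy(dtype=np.int64)
    depth = df["depth"].to_numpy(dtype=np.int64)
    ref_idx = np.array([BASES.index(b) for b in df["ref"]])
    rows = np.arange(len(df))

    nonref = mat.copy()
    nonref[rows, ref_idx] = -1
    major_idx = nonref.argmax(axis=1)
    major_count = nonref[rows, major_idx]

    # Default orientation: minor allele is the top non-reference allele.
    minor_idx = major_idx.copy()
    minor_count = major_count.copy()

    # Consensus differences: major non-reference allele above 50%.
    swap = major_count * 2 > depth
    if swap.any():
        rest = mat.copy()
        rest[rows[swap], major_idx[swap]] = -1
        rest[rows[~swap]] = -1  # ignore non-swapped rows
        minor_idx[swap] = rest[swap].argmax(axis=1)
        minor_count[swap] = rest[rows[swap], minor_idx[swap]]

    keep = minor_count > 0
    if not keep.any():
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    df = df.loc[keep].reset_index(drop=True)
    depth, minor_idx, minor_count = depth[keep], minor_idx[keep], minor_count[keep]
    major_idx, ref_idx, swap = major_idx[keep], ref_idx[keep], swap[keep]

    # Reported alt allele: the non-reference allele involved. For consensus
    # differences whose minor allele is the reference itself, that is the
    # major (near-fixed) allele; MAF always refers to the minor fraction.
    alt_idx = np.where(swap & (minor_idx == ref_idx), major_idx, minor_idx)
    maf = minor_count / depth
    p_value = stats.binom.sf(minor_count - 1, depth, config.error_rate)

    if config.quality_mode == "site" or "bq_A" not in df.columns:
        base_qual = df["base_qual"].to_numpy(dtype=float)
    else:
        bq = df[[f"bq_{b}" for b in BASES]].to_numpy(dtype=float)
        base_qual = bq[np.arange(len(df)), minor_idx]

    out = pd.DataFrame(
        {
            "position": df["position"].to_numpy(),
            "ref": df["ref"].to_numpy(),
            "alt": np.array(BASES)[alt_idx],
            "alt_count": minor_count,
            "depth": depth,
            "maf": maf,
            "p_value": p_value,
            "base_qual": base_qual,
            "map_qual": df["map_qual"].to_numpy(dtype=float),
        }
    )
    return out.sort_values("position", ignore_index=True)


def filter_hp_sites(
    candidates: pd.DataFrame,
    config: FilterConfig | None = None,
    median_depth: float | None = None,
) -> pd.DataFrame:
    """Apply the five-criterion heteroplasmy filter to candidate variants.

    ``median_depth`` freezes the depth cutoff (used for idempotent
    re-filtering); by default it is the median depth over the candidate
    set itself (even count: mean of the central pair). Returns surviving
    sites sorted by position, with the applied median recorded in
    ``result.attrs["median_depth"]``.
    """
    config = config or FilterConfig()
    if candidates.empty:
        logger.info("no candidate sites to filter")
        out = candidates.copy()
        out.attrs["median_depth"] = float("nan")
        return out
    med = float(np.median(candidates["depth"])) if median_depth is None else float(median_depth)
    mask = (
        (candidates["base_qual"] > config.min_base_quality)
        & (candidates["map_qual"] > config.min_mapping_quality)
        & (candidates["maf"] > config.min_maf)
        & (candidates["p_value"] < config.max_p)
        & (candidates["depth"] > med)
    )
    out = candidates.loc[mask].sort_values("position", ignore_index=True)
    out.attrs["median_depth"] = med
    return out


def annotate_sites(
    hp_sites: pd.DataFrame,
    annotation: MitoAnnotation,
    reference: str,
    model: GranthamModel | None = None,
) -> pd.DataFrame:
    """Annotate filtered HP sites with substitution class, region, coding
    effect, Grantham score (missense only), and the genetic-load flag.

    A site is a load site iff its effect is loss-of-function or it is a
    missense change with Grantham score strictly above the model threshold.
    """
    model = model or DEFAULT_GRANTHAM
    out = hp_sites.copy()
    ts_tv, regions, effects, genes, aa_changes, grantham, is_load = (
        [], [], [], [], [], [], [])
    for row in hp_sites.itertuples(index=False):
        try:
            calls = effect_calls(row.position, row.ref, row.alt, annotation, reference)
        except ValueError as exc:
            raise ValueError(f"site {row.position} {row.ref}>{row.alt}: {exc}") from exc
        ts_tv.append(classify_substitution(row.ref, row.alt))
        regions.append(annotation.region_of(row.position))
        if calls:
            best = max(calls, key=lambda c: EFFECT_SEVERITY[c.effect])
            effects.append(best.effect)
            genes.append(best.feature)
            aa_changes.append(f"{best.ref_aa}>{best.alt_aa}")
            if best.effect == "missense":
                g = model.distance(best.ref_aa, best.alt_aa)
                grantham.append(float(g))
                is_load.append(g > model.deleterious_threshold)
            else:
                grantham.append(np.nan)
                is_load.append(best.effect in LOF_EFFECTS)
        else:
            effects.append("noncoding")
            genes.append(None)
            aa_changes.append(None)
            grantham.append(np.nan)
            is_load.append(False)
    out["ts_tv"] = ts_tv
    out["region"] = regions
    out["effect"] = effects
    out["gene"] = genes
    out["aa_change"] = aa_changes
    out["grantham"] = grantham
    out["is_load"] = is_load
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pileup_tsv(path) -> pd.DataFrame:
    """Read a per-site allele-count table (tab-separated)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"position", "ref", "A", "C", "G", "T", "depth"} - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_sites_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_vcf(path, default_base_quality: float = 37.0, default_map_quality: float = 60.0) -> pd.DataFrame:
    """Read a minimal single-sample VCF with AD/DP into an allele-count table.

    Only SNP records are used. Per-allele base qualities default to
    ``default_base_quality`` unless an INFO/BQ value is present; mapping
    quality comes from INFO/MQ when present.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.ref is None or len(rec.ref) != 1:
                continue
            alts = [a for a in (rec.alts or []) if a is not None and len(a) == 1]
            sample = rec.samples[0] if rec.samples else None
            ad = sample.get("AD") if sample else None
            if ad is None:
                continue
            counts = dict.fromkeys(BASES, 0)
            counts[rec.ref] = int(ad[0])
            for alt, c in zip(alts, ad[1:]):
                counts[alt] = int(c)
            depth = sum(counts.values())
            info_keys = set(rec.info.keys())
            bq = float(rec.info["BQ"]) if "BQ" in info_keys else default_base_quality
            mq = float(rec.info["MQ"]) if "MQ" in info_keys else default_map_quality
            rows.append(
                {
                    "position": rec.pos, "ref": rec.ref,
                    **counts, "depth": depth,
                    **{f"bq_{b}": bq for b in BASES},
                    "map_qual": mq,
                }
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_hp_vcf(df: pd.DataFrame, path, contig: str = "MT", contig_length: int | None = None) -> None:
    """Write annotated HP sites as an uncompressed VCF with INFO keys
    MAF, TSTV, EFF, GRT, LOAD."""
    import pysam

    header = pysam.VariantHeader()
    length = int(contig_length or (int(df["position"].max()) if len(df) else 1))
    header.contigs.add(contig, length=length)
    header.info.add("MAF", 1, "Float", "Minor allele frequency")
    header.info.add("TSTV", 1, "String", "Substitution class (Ts/Tv)")
    header.info.add("EFF", 1, "String", "Coding effect")
    header.info.add("GRT", 1, "Float", "Grantham score (missense)")
    header.info.add("LOAD", 0, "Flag", "Genetic load site")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=contig, start=int(row.position) - 1,
                alleles=(row.ref, row.alt), qual=None,
            )
            rec.info["MAF"] = float(row.maf)
            if hasattr(row, "ts_tv"):
                rec.info["TSTV"] = row.ts_tv
            if hasattr(row, "effect"):
                rec.info["EFF"] = row.effect
            if hasattr(row, "grantham") and not pd.isna(row.grantham):
                rec.info["GRT"] = float(row.grantham)
            if hasattr(row, "is_load") and bool(row.is_load):
                rec.info["LOAD"] = True
            out.write(rec)


def containment_report(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Set-containment between two variant tables keyed on (position, alt).

    Mirrors cross-caller concordance checks: what fraction of A's variants
    are contained in B.
    """
    keys_a = set(zip(table_a["position"], table_a["alt"]))
    keys_b = set(zip(table_b["position"], table_b["alt"]))
    shared = keys_a & keys_b
    return {
        "n_a": len(keys_a),
        "n_b": len(keys_b),
        "n_shared": len(shared),
        "fraction_a_in_b": len(shared) / len(keys_a) if keys_a else float("nan"),
    }
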