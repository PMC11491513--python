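"""Paired egg-vs-hatchling statistics and end-to-end pipeline orchestration.

Eggs and hatchlings from the same female are paired observations; every
pool-level metric is compared across females with a paired-samples t-test
on the per-female differences, with a Shapiro-Wilk normality p-value
reported alongside (advisory, never gating). ``run_pipeline`` composes the
full analysis — NUMT masking, candidate calling, filtering, annotation,
metrics, paired comparison — over a synthetic multi-female study or over
user-supplied allele-count tables, as a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .hp_calling import (
    FilterConfig,
    annotate_sites,
    call_candidates,
    filter_hp_sites,
    read_pileup_tsv,
    write_sites_tsv,
)
from .numt_screen import find_numts, mask_sites
from .pool_metrics import PoolSample, compute_metrics, metrics_frame
from .synthetic_pool import (
    PoolProfile,
    generate_reference,
    read_fasta,
    simulate_coverage,
    simulate_pool,
    write_fasta,
)

logger = logging.getLogger(__name__)

#: Metrics compared between eggs and hatchlings in the paired report.
PAIRED_METRICS = [
    "hp_per_cell",
    "hp_per_mitogenome",
    "maf_mean",
    "ts_pct",
    "tv_pct",
    "tv_ts_ratio",
    "dnds",
    "load_ratio",
    "lof_fraction",
    "deleterious_missense_fraction",
]


@dataclass
class PairedMetricSet:
    """Per-female egg and hatchling values of one metric, paired by female."""

    metric: str
    egg: np.ndarray
    hatchling: np.ndarray
    female_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.egg = np.asarray(self.egg, dtype=float)
        self.hatchling = np.asarray(self.hatchling, dtype=float)
        if self.egg.shape != self.hatchling.shape:
            raise ValueError("egg and hatchling vectors must have equal length")
        if self.egg.size < 2:
            raise ValueError("paired test requires at least 2 females")


@dataclass
class PairedTestResult:
    metric: str
    n_pairs: int
    mean_egg: float
    sd_egg: float
    mean_hatchling: float
    sd_hatchling: float
    t_abs: float
    df: int
    p_value: float
    normality_p: float


def paired_test(metric_set: PairedMetricSet) -> PairedTestResult:
    """Paired-samples t-test on per-female differences.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n-1 and a two-sided p-value;
    |t| is reported. Shapiro-Wilk on the differences (n >= 3) is attached
    as an advisory normality p-value. All-zero differences are the defined
    null limit (t=0, p=1); constant nonzero differences have no finite t
    and raise a degenerate-pairing error.
    """
    d = metric_set.egg - metric_set.hatchling
    if np.isnan(d).any():
        raise ValueError(f"metric {metric_set.metric}: NaN in paired values")
    n = d.size
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if float(d.mean()) == 0.0:
            t_abs, p = 0.0, 1.0
        else:
            raise ValueError(
                f"degenerate pairing for {metric_set.metric}: "
                "differences are constant and nonzero"
            )
    else:
        t_stat, p = stats.ttest_rel(metric_set.egg, metric_set.hatchling)
        t_abs = abs(float(t_stat))
        p = float(p)
    if n >= 3 and sd_d > 0:
        normality_p = float(stats.shapiro(d).pvalue)
    else:
        normality_p = float("nan")
    return PairedTestResult(
        metric=metric_set.metric,
        n_pairs=n,
        mean_egg=float(metric_set.egg.mean()),
        sd_egg=float(metric_set.egg.std(ddof=1)),
        mean_hatchling=float(metric_set.hatchling.mean()),
        sd_hatchling=float(metric_set.hatchling.std(ddof=1)),
        t_abs=t_abs,
        df=n - 1,
        p_value=p,
        normality_p=normality_p,
    )


def paired_table(metrics: pd.DataFrame, metric_names: list[str] | None = None) -> pd.DataFrame:
    """Paired egg-vs-hatchling test for every metric, one row per metric.

    ``metrics`` must carry columns female_id, tissue, and the metric
    columns; derived fractions (lof_fraction, deleterious_missense_fraction)
    are computed on the fly when absent. Metrics whose pairing is
    degenerate or undefined are reported with NaN statistics rather than
    dropped.
    """
    metric_names = metric_names or PAIRED_METRICS
    df = metrics.copy()
    if "lof_fraction" not in df.columns:
        df["lof_fraction"] = df["n_lof"] / df["hp_site_count"]
    if "deleterious_missense_fraction" not in df.columns:
        df["deleterious_missense_fraction"] = (
            df["n_deleterious_missense"] / df["hp_site_count"]
        )
    eggs = df[df["tissue"] == "egg"].set_index("female_id")
    hats = df[df["tissue"] == "hatchling"].set_index("female_id")
    females = sorted(set(eggs.index) & set(hats.index))
    rows = []
    for name in metric_names:
        ms = PairedMetricSet(
            metric=name,
            egg=eggs.loc[females, name].to_numpy(),
            hatchling=hats.loc[females, name].to_numpy(),
            female_ids=list(females),
        )
        try:
            res = paired_test(ms)
            rows.append(res.__dict__)
        except ValueError as exc:
            logger.warning("paired test skipped for %s: %s", name, exc)
            rows.append(
                {
                    "metric": name, "n_pairs": len(females),
                    "mean_egg": float(np.mean(ms.egg)),
                    "sd_egg": float(np.std(ms.egg, ddof=1)),
                    "mean_hatchling": float(np.mean(ms.hatchling)),
                    "sd_hatchling": float(np.std(ms.hatchling, ddof=1)),
                    "t_abs": float("nan"), "df": len(females) - 1,
                    "p_value": float("nan"), "normality_p": float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def pool_recovery(
    reference: str,
    annotation,
    profile: PoolProfile,
    seeds,
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Parameter-recovery study: simulate, call, filter, annotate one pool
    per seed and summarize what the pipeline recovered.

    Returns one row per replicate with the filtered-site count, recovered
    Ts/Tv percentages, and recovered mean/min/max MAF (in %).
    """
    fcfg = filter_config or FilterConfig()
    rows = []
    for s in seeds:
        _, counts = simulate_pool(reference, annotation, profile, seed=int(s))
        hp = filter_hp_sites(call_candidates(counts, fcfg), fcfg)
        annotated = annotate_sites(hp, annotation, reference)
        from .pool_metrics import spectrum_summary

        spec = spectrum_summary(annotated)
        rows.append(
            {
                "seed": int(s),
                "n_sites": len(annotated),
                "ts_pct": spec["ts_pct"],
                "tv_pct": spec["tv_pct"],
                "maf_mean_pct": float(annotated["maf"].mean()) * 100.0,
                "maf_min_pct": float(annotated["maf"].min()) * 100.0,
                "maf_max_pct": float(annotated["maf"].max()) * 100.0,
            }
        )
    return pd.DataFrame(rows)


DEFAULT_CONFIG: dict = {
    "n_females": 6,
    "seed": 0,
    "reference": {"length": 16615, "n_cds": 13},
    "egg": {},        # PoolProfile.egg overrides
    "hatchling": {},  # PoolProfile.hatchling overrides
    "filters": {},    # FilterConfig overrides
    "numt": {"enabled": False, "nuclear_fasta": None,
             "min_seed": 20, "min_length": 25, "min_identity": 0.9},
    "copy_number": {
        "egg_copies_range": [1374.8, 2414.91],
        "hatchling_copies_range": [25.04, 207.10],
        "chrom_depth_mean": 4.0,
        "noise_cv": 0.02,
    },
    "samples": None,  # optional: list of real-input sample dicts
    "out_dir": None,
}


def _merged_config(config: dict | str | Path | None) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_pipeline(config: dict | str | Path | None = None, seed: int | None = None) -> dict:
    """Run the full analysis and return the report bundle.

    The bundle maps ``reference`` (sequence), ``annotation``, ``metrics``
    (one row per sample), ``paired`` (one row per compared metric),
    ``samples`` (sample_id -> annotated HP table), ``numt_hits`` and
    ``log`` (seeds, versions, thresholds). Identical (config, seed) give
    identical outputs; results are also written to ``out_dir`` when set.
    """
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    master = np.random.default_rng(cfg["seed"])

    fcfg = FilterConfig(**cfg["filters"])
    ref_cfg = cfg["reference"]
    ref_seed = int(ref_cfg.get("seed", master.integers(2**31)))
    reference, annotation = generate_reference(
        length=int(ref_cfg.get("length", 16615)),
        n_cds=int(ref_cfg.get("n_cds", 13)),
        seed=ref_seed,
    )

    numt_cfg = cfg["numt"]
    hits = []
    if numt_cfg.get("enabled") and numt_cfg.get("nuclear_fasta"):
        nuclear = read_fasta(numt_cfg["nuclear_fasta"])
        hits = find_numts(
            nuclear, reference,
            min_seed=int(numt_cfg.get("min_seed", 20)),
            min_length=int(numt_cfg.get("min_length", 25)),
            min_identity=float(numt_cfg.get("min_identity", 0.9)),
        )
        logger.info("NUMT screen: %d hits", len(hits))

    cn = cfg["copy_number"]
    samples: list[PoolSample] = []
    hp_tables: dict[str, pd.DataFrame] = {}
    if cfg["samples"]:
        sample_specs = cfg["samples"]
        for spec in sample_specs:
            counts = read_pileup_tsv(spec["counts_tsv"])
            sample = _process_sample(
                counts, spec["sample_id"], spec["tissue"], spec["female_id"],
                annotation, reference, fcfg, hits,
                coverage=simulate_coverage(
                    float(spec.get("copies_per_cell", 1000.0)),
                    1 if spec["tissue"] == "egg" else 2,
                    chrom_depth_mean=float(cn["chrom_depth_mean"]),
                    noise_cv=0.0,
                ),
                pool_size=int(spec.get("pool_size", 0)),
            )
            samples.append(sample)
            hp_tables[sample.sample_id] = sample.hp_sites
    else:
        egg_profile = PoolProfile.egg(**cfg["egg"])
        hat_profile = PoolProfile.hatchling(**cfg["hatchling"])
        for i in range(int(cfg["n_females"])):
            female = f"F{i + 1}"
            for profile, lo_hi in (
                (egg_profile, cn["egg_copies_range"]),
                (hat_profile, cn["hatchling_copies_range"]),
            ):
                sid = f"{female}_{profile.tissue}"
                pool_seed = int(master.integers(2**31))
                cov_seed = int(master.integers(2**31))
                copies = float(master.uniform(*lo_hi))
                _, counts = simulate_pool(reference, annotation, profile, seed=pool_seed)
                coverage = simulate_coverage(
                    copies, profile.nuclear_ploidy,
                    chrom_depth_mean=float(cn["chrom_depth_mean"]),
                    noise_cv=float(cn["noise_cv"]), seed=cov_seed,
                )
                sample = _process_sample(
                    counts, sid, profile.tissue, female,
                    annotation, reference, fcfg, hits,
                    coverage=coverage, pool_size=profile.pool_size,
                )
                samples.append(sample)
                hp_tables[sid] = sample.hp_sites

    metrics = metrics_frame([compute_metrics(s) for s in samples])
    metrics["lof_fraction"] = metrics["n_lof"] / metrics["hp_site_count"]
    metrics["deleterious_missense_fraction"] = (
        metrics["n_deleterious_missense"] / metrics["hp_site_count"]
    )
    paired = paired_table(metrics) if metrics["female_id"].nunique() >= 2 else pd.DataFrame()

    bundle = {
        "reference": reference,
        "annotation": annotation,
        "metrics": metrics,
        "paired": paired,
        "samples": hp_tables,
        "numt_hits": hits,
        "log": {
            "package_version": __version__,
            "seed": cfg["seed"],
            "reference_seed": ref_seed,
            "filters": fcfg.__dict__,
            "n_females": cfg["n_females"],
            "numt_enabled": bool(numt_cfg.get("enabled")),
        },
    }
    if cfg.get("out_dir"):
        _write_bundle(bundle, Path(cfg["out_dir"]))
    return bundle


def _process_sample(
    counts, sample_id, tissue, female_id, annotation, reference, fcfg, hits,
    coverage, pool_size,
) -> PoolSample:
    """One sample through the stage chain: call -> mask -> filter -> annotate.

    Masking precedes the median-depth filter so NUMT intervals cannot skew
    the per-sample candidate depth median.
    """
    candidates = call_candidates(counts, fcfg)
    if hits:
        candidates, masked = mask_sites(candidates, hits)
        logger.info("%s: masked %d candidate sites in NUMT intervals",
                    sample_id, len(masked))
    filtered = filter_hp_sites(candidates, fcfg)
    annotated = annotate_sites(filtered, annotation, reference)
    return PoolSample(
        sample_id=sample_id,
        tissue=tissue,
        female_id=female_id,
        pool_size=pool_size,
        nuclear_ploidy=1 if tissue == "egg" else 2,
        hp_sites=annotated,
        coverage=coverage,
    )


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle["reference"], out_dir / "reference.fasta")
    bundle["annotation"].to_tsv(out_dir / "features.tsv")
    bundle["metrics"].to_csv(out_dir / "metrics.tsv", sep="\t", index=False,
                             float_format="%.6g")
    if len(bundle["paired"]):
        bundle["paired"].to_csv(out_dir / "paired_tests.tsv", sep="\t",
                                index=False, float_format="%.6g")
    sample_dir = out_dir / "hp_sites"
    sample_dir.mkdir(exist_ok=True)
    for sid, table in bundle["samples"].items():
        write_sites_tsv(table, sample_dir / f"{sid}.tsv")
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(bundle["log"], fh, indent=2, sort_keys=True)
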