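"""Synthetic mitogene-pool data generator.

Generates random circular reference mitogenomes with valid in-frame CDS
features, pooled-sample allele-count tables with planted heteroplasmic
sites, coverage summaries, and exact "fixed-spectrum" fixtures, so every
pipeline stage is testable without sequencing data.

The stochastic generator emulates the statistical structure of pooled
mtDNA resequencing: egg pools (500 haploid cells, ~7,800x mitogenome
depth, transversion-dominated low-frequency spectrum) and hatchling pools
(100 diploid-soma individuals, ~2,500x depth, transition-dominated
spectrum with broader minor-allele frequencies). True-site MAFs are drawn
log-uniformly by default; observed minor-allele counts are binomial in
the true MAF; background miscall reads arrive at ``error_rate`` split
evenly over the three non-reference alleles and carry low base quality,
while reads supporting the planted allele carry high base quality (the
planted allele receives no extra miscall reads — miscalls toward it are
considered absorbed in the drawn MAF, keeping the observed MAF an
unbiased binomial draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mito_model import (
    BASES,
    GranthamModel,
    DEFAULT_GRANTHAM,
    Feature,
    MitoAnnotation,
    TRANSITIONS,
    TRANSVERSIONS,
    _codon_table,
    _coding_sequence,
    annotate_effect,
    classify_substitution,
    translate_codon,
)
from .hp_calling import COUNT_COLUMNS
from .pool_metrics import CoverageSummary

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical vertebrate mitochondrial protein gene names, genome order.
MT_GENE_NAMES = [
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
]

FIXTURE_CLASSES = (
    "noncoding", "synonymous", "missense_benign", "missense_deleterious", "lof",
)


# ---------------------------------------------------------------------------
# MAF distribution helpers
# ---------------------------------------------------------------------------

def loguniform_mean(low: float, high: float) -> float:
    """Mean of the log-uniform distribution on [low, high]."""
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    return (high - low) / np.log(high / low)


def loguniform_high_for_mean(low: float, mean: float) -> float:
    """Upper bound of a log-uniform distribution with given lower bound and
    mean (used to pin the generator's MAF distribution to a target mean)."""
    if mean <= low:
        raise ValueError("mean must exceed the lower bound")
    return brentq(lambda hi: loguniform_mean(low, hi) - mean, low * (1 + 1e-9), low * 1e6)


# ---------------------------------------------------------------------------
# Pool profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolProfile:
    """Generator settings for one pooled sample.

    Defaults for :meth:`egg` and :meth:`hatchling` encode the study
    conditions this package models: egg pools of 500 haploid cells at
    ~7,800x mtDNA depth with a transversion fraction of 95.23% and MAFs
    log-uniform on [0.21%, 1.3%]; hatchling pools of 100 diploid-soma
    individuals at ~2,500x depth (central in the 853-4,565x range such
    pools are sequenced at),
    transversion fraction 14.62% (the complement of the 85.38% transition
    share), MAFs log-uniform on [0.21%, 37.18%].
    """

    tissue: str
    n_true_sites: int
    maf_low: float
    maf_high: float
    tv_fraction: float
    depth_mean: float
    pool_size: int
    nuclear_ploidy: int
    maf_family: str = "loguniform"  # loguniform | uniform | fixed
    depth_cv: float = 0.05
    error_rate: float = 0.001
    sampling: str = "binomial"  # binomial | exact
    effect_mix: Mapping[str, float] | None = None
    load_fraction: float | None = None
    true_base_quality: float = 37.0
    error_base_quality: float = 16.0
    map_quality: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_true_sites < 0:
            raise ValueError("n_true_sites must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.tv_fraction <= 1:
            raise ValueError("tv_fraction must be in [0, 1]")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.maf_family not in ("loguniform", "uniform", "fixed"):
            raise ValueError(f"unknown maf_family {self.maf_family!r}")
        if self.sampling not in ("binomial", "exact"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")

    def with_(self, **kw) -> "PoolProfile":
        return replace(self, **kw)

    @classmethod
    def egg(cls, **overrides) -> "PoolProfile":
        base = dict(
            tissue="egg", n_true_sites=170, maf_low=0.0021, maf_high=0.013,
            tv_fraction=0.9523, depth_mean=7800.0, pool_size=500,
            nuclear_ploidy=1,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def hatchling(cls, **overrides) -> "PoolProfile":
        base = dict(
            tissue="hatchling", n_true_sites=65, maf_low=0.0021,
            maf_high=0.3718, tv_fraction=0.1462, depth_mean=2500.0,
            pool_size=100, nuclear_ploidy=2,
        )
        base.update(overrides)
        return cls(**base)

    def draw_mafs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.maf_family == "loguniform":
            return np.exp(rng.uniform(np.log(self.maf_low), np.log(self.maf_high), n))
        if self.maf_family == "uniform":
            return rng.uniform(self.maf_low, self.maf_high, n)
        return np.full(n, self.maf_low)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def generate_reference(
    length: int = 16615,
    n_cds: int = 13,
    seed: int = 0,
    control_length: int | None = None,
    rrna_length: int | None = None,
    trna_length: int = 70,
    gap: int = 15,
) -> tuple[str, MitoAnnotation]:
    """Random circular mitogenome with valid, non-overlapping features.

    Layout: control region ("D-loop"), two tRNAs, one rRNA ("rrnL"), then
    ``n_cds`` protein genes separated by short intergenic gaps; any slack
    remains intergenic at the end. Each CDS starts with ATG or ATA, has no
    internal table-2 stop codon, and ends with a complete TAA/TAG stop.
    The last CDS (ND6 at full gene count, as in real vertebrate
    mitogenomes) is placed on the minus strand. Deterministic under
    ``seed``.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if n_cds < 1:
        raise ValueError("n_cds must be >= 1")
    rng = np.random.default_rng(seed)
    # non-coding feature sizes scale with the genome (mitogenome-like
    # proportions at full size: ~930 bp control region, ~1,700 bp rrnL)
    if control_length is None:
        control_length = max(60, round(0.056 * length))
    if rrna_length is None:
        rrna_length = max(100, round(0.102 * length))
    trna_length = min(trna_length, max(30, length // 60))
    n_feats = 4 + n_cds
    fixed = control_length + 2 * trna_length + rrna_length + gap * n_feats
    cds_budget = length - fixed
    per_cds = (cds_budget // n_cds) // 3 * 3
    if per_cds < 30:
        raise ValueError(
            f"cannot pack {n_cds} CDS features into length {length}; "
            "reduce n_cds or feature lengths"
        )

    table = _codon_table(2)
    sense_codons = sorted(
        c for c in table.forward_table if set(c) <= set(BASES)
    )
    stop_choices = ["TAA", "TAG"]
    start_choices = ["ATG", "ATA"]

    def random_bases(n: int) -> str:
        return "".join(rng.choice(list(BASES), n))

    def random_cds(n_codons: int) -> str:
        start = start_choices[rng.integers(len(start_choices))]
        internal = rng.choice(sense_codons, n_codons - 2)
        stop = stop_choices[rng.integers(len(stop_choices))]
        return start + "".join(internal) + stop

    names = list(MT_GENE_NAMES[:n_cds])
    names += [f"CDS{i}" for i in range(len(names) + 1, n_cds + 1)]
    # ND6 is the one minus-strand protein gene of vertebrate mitogenomes
    minus_name = "ND6" if "ND6" in names else None

    chunks: list[str] = []
    features: list[Feature] = []
    cursor = 1

    def emit(seq: str, feature: Feature | None = None) -> None:
        nonlocal cursor
        chunks.append(seq)
        if feature is not None:
            features.append(feature)
        cursor += len(seq)

    emit(random_bases(control_length),
         Feature("D-loop", "control", cursor, cursor + control_length - 1))
    emit(random_bases(gap))
    emit(random_bases(trna_length),
         Feature("trnF", "tRNA", cursor, cursor + trna_length - 1))
    emit(random_bases(gap))
    emit(random_bases(rrna_length),
         Feature("rrnL", "rRNA", cursor, cursor + rrna_length - 1))
    emit(random_bases(gap))
    emit(random_bases(trna_length),
         Feature("trnV", "tRNA", cursor, cursor + trna_length - 1))
    emit(random_bases(gap))
    for name in names:
        coding = random_cds(per_cds // 3)
        strand = "-" if name == minus_name else "+"
        segment = coding if strand == "+" else _revcomp_str(coding)
        emit(segment,
             Feature(name, "CDS", cursor, cursor + per_cds - 1, strand=strand))
        emit(random_bases(gap))
    if cursor <= length:
        emit(random_bases(length - cursor + 1))
    sequence = "".join(chunks)
    assert len(sequence) == length
    return sequence, MitoAnnotation(genome_length=length, features=features)


def _revcomp_str(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Effect catalogue (shared by targeted placement and fixed fixtures)
# ---------------------------------------------------------------------------

def effect_catalogue(
    reference: str,
    annotation: MitoAnnotation,
    model: GranthamModel | None = None,
) -> pd.DataFrame:
    """Every single-base substitution of the genome with its coding effect.

    Returns a DataFrame (position, ref, alt, effect, grantham, klass) where
    ``klass`` is one of noncoding / synonymous / missense_benign /
    missense_deleterious / lof. Positions covered by more than one CDS
    group are excluded so that each row's class is unambiguous.
    """
    model = model or DEFAULT_GRANTHAM
    length = annotation.genome_length
    coverage = np.zeros(length + 1, dtype=int)
    groups = annotation.cds_groups()
    for parts in groups.values():
        for part in parts:
            coverage[part.start : part.end + 1] += 1

    rows: list[tuple] = []
    for name, parts in groups.items():
        cds = _coding_sequence(reference, parts)
        strand = parts[0].strand
        table_id = parts[0].table_id
        table = _codon_table(table_id)
        genome_pos: list[int] = []
        for part in parts:
            rng_ = range(part.start, part.end + 1)
            genome_pos.extend(rng_ if strand == "+" else reversed(rng_))
        n_codons = len(cds) // 3
        for idx in range(n_codons):
            old_codon = cds[idx * 3 : idx * 3 + 3]
            old_aa = translate_codon(old_codon, table_id)
            for within in range(3):
                off = idx * 3 + within
                pos = genome_pos[off]
                if coverage[pos] > 1:
                    continue
                ref_base = reference[pos - 1].upper()
                for coding_alt in BASES:
                    if coding_alt == old_codon[within]:
                        continue
                    new_codon = (
                        old_codon[:within] + coding_alt + old_codon[within + 1 :]
                    )
                    new_aa = translate_codon(new_codon, table_id)
                    if new_aa == old_aa:
                        effect, klass, score = "synonymous", "synonymous", np.nan
                    elif new_aa == "*":
                        effect, klass, score = "stop_gained", "lof", np.nan
                    elif old_aa == "*":
                        effect, klass, score = "stop_lost", "lof", np.nan
                    elif idx == 0 and new_codon not in table.start_codons:
                        effect, klass, score = "start_lost", "lof", np.nan
                    else:
                        score = float(model.distance(old_aa, new_aa))
                        effect = "missense"
                        klass = (
                            "missense_deleterious"
                            if score > model.deleterious_threshold
                            else "missense_benign"
                        )
                    genome_alt = coding_alt if strand == "+" else _COMPLEMENT[coding_alt]
                    rows.append((pos, ref_base, genome_alt, effect, score, klass))
    for pos in np.flatnonzero(coverage[1:] == 0) + 1:
        ref_base = reference[pos - 1].upper()
        if ref_base not in BASES:
            continue
        for alt in BASES:
            if alt != ref_base:
                rows.append((int(pos), ref_base, alt, "noncoding", np.nan, "noncoding"))
    cat = pd.DataFrame(
        rows, columns=["position", "ref", "alt", "effect", "grantham", "klass"]
    )
    return cat.sort_values(["position", "alt"], ignore_index=True)


# ---------------------------------------------------------------------------
# Stochastic pool simulation
# ---------------------------------------------------------------------------

def simulate_pool(
    reference: str,
    annotation: MitoAnnotation,
    profile: PoolProfile,
    seed: int | None = None,
    catalogue: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one pooled sample: (truth table, allele-count table).

    Plants ``profile.n_true_sites`` heteroplasmic sites at distinct
    positions; each site's alternate allele realizes a transition draw
    (probability 1 - tv_fraction) or a transversion draw, its true MAF
    comes from the profile's MAF distribution, and the observed
    minor-allele count is binomial(depth, MAF) at a per-site depth drawn
    as round(normal(depth_mean, depth_cv)). Background miscall reads at
    ``error_rate`` (split over the three non-reference alleles, low base
    quality) are added at all genome positions. With targeted placement
    (``effect_mix`` or ``load_fraction``) site positions and alleles come
    from the effect catalogue, overriding the Ts/Tv draw for those sites.
    Deterministic under ``seed`` (falling back to ``profile.seed``).
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    length = annotation.genome_length
    n = profile.n_true_sites
    if n > length:
        raise ValueError("n_true_sites exceeds usable positions")
    ref_arr = np.array(list(reference.upper()))

    if profile.effect_mix is not None or profile.load_fraction is not None:
        positions, alts = _targeted_placement(
            reference, annotation, profile, rng, catalogue
        )
    else:
        positions = np.sort(rng.choice(length, size=n, replace=False)) + 1
        refs = ref_arr[positions - 1]
        is_tv = rng.random(n) < profile.tv_fraction
        alts = np.empty(n, dtype="<U1")
        pick = rng.integers(2, size=n)
        for i, (r, tv) in enumerate(zip(refs, is_tv)):
            alts[i] = TRANSVERSIONS[r][pick[i]] if tv else TRANSITIONS[r]

    refs = ref_arr[positions - 1]
    mafs = profile.draw_mafs(n, rng)

    depth = np.maximum(
        1,
        np.round(
            rng.normal(profile.depth_mean, profile.depth_cv * profile.depth_mean, length)
        ),
    ).astype(np.int64)
    true_depth = depth[positions - 1]
    if profile.sampling == "binomial":
        alt_counts = rng.binomial(true_depth, mafs)
    else:
        alt_counts = np.round(mafs * true_depth).astype(np.int64)

    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.array([base_idx[b] for b in ref_arr])
    alt_idx = np.array([base_idx[b] for b in alts]) if n else np.empty(0, dtype=int)

    # background miscalls on every non-reference allele slot
    counts = np.zeros((length, 4), dtype=np.int64)
    err = rng.binomial(
        np.repeat(depth[:, None], 3, axis=1), profile.error_rate / 3.0
    )
    slot_alleles = np.argsort(
        np.eye(4, dtype=int)[ref_idx], axis=1, kind="stable"
    )[:, :3]  # the 3 non-ref allele indices per position
    np.put_along_axis(counts, slot_alleles, err, axis=1)
    if n:
        counts[positions - 1, alt_idx] = alt_counts  # planted allele: pure binomial draw

    nonref_total = counts.sum(axis=1)
    ref_counts = np.maximum(depth - nonref_total, 0)
    counts[np.arange(length), ref_idx] = ref_counts
    depth = counts.sum(axis=1)  # invariant: depth == sum of the four counts

    bq = np.zeros((length, 4))
    err_mask = counts > 0
    bq[err_mask] = np.clip(
        rng.normal(profile.error_base_quality, 1.0, int(err_mask.sum())), 2.0, None
    )
    bq[np.arange(length), ref_idx] = rng.normal(profile.true_base_quality, 0.3, length)
    if n:
        has_alt = alt_counts > 0
        bq[(positions - 1)[has_alt], alt_idx[has_alt]] = rng.normal(
            profile.true_base_quality, 0.5, int(has_alt.sum())
        )
    bq[counts == 0] = 0.0
    map_qual = rng.normal(profile.map_quality, 1.0, length)

    counts_df = pd.DataFrame(
        {
            "position": np.arange(1, length + 1),
            "ref": ref_arr,
            **{b: counts[:, i] for i, b in enumerate(BASES)},
            "depth": depth,
            **{f"bq_{b}": np.round(bq[:, i], 2) for i, b in enumerate(BASES)},
            "map_qual": np.round(map_qual, 2),
        }
    )[COUNT_COLUMNS]

    truth_rows = []
    for pos, r, a, m in zip(positions, refs, alts, mafs):
        truth_rows.append(
            {
                "position": int(pos),
                "ref": r,
                "alt": a,
                "true_maf": float(m),
                "ts_tv": classify_substitution(r, a),
                "region": annotation.region_of(int(pos)),
                "effect": annotate_effect(int(pos), r, a, annotation, reference),
            }
        )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["position", "ref", "alt", "true_maf", "ts_tv", "region", "effect"],
    )
    return truth_df, counts_df


def _targeted_placement(
    reference: str,
    annotation: MitoAnnotation,
    profile: PoolProfile,
    rng: np.random.Generator,
    catalogue: pd.DataFrame | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Choose site positions/alleles realizing effect_mix or load_fraction."""
    cat = catalogue if catalogue is not None else effect_catalogue(reference, annotation)
    n = profile.n_true_sites
    quotas: dict[str, int] = {}
    if profile.load_fraction is not None:
        n_load = int(round(n * profile.load_fraction))
        quotas = {"load": n_load, "nonload": n - n_load}
        buckets = {
            "load": cat[cat["klass"].isin(["lof", "missense_deleterious"])],
            "nonload": cat[~cat["klass"].isin(["lof", "missense_deleterious"])],
        }
    else:
        mix = dict(profile.effect_mix)
        alias = {"missense": ["missense_benign", "missense_deleterious"]}
        buckets = {}
        for key, frac in mix.items():
            klasses = alias.get(key, [key])
            buckets[key] = cat[cat["klass"].isin(klasses)]
            quotas[key] = int(round(n * frac))
        # rounding slack goes to the largest quota
        slack = n - sum(quotas.values())
        if slack and quotas:
            quotas[max(quotas, key=quotas.get)] += slack
    chosen_pos: list[int] = []
    chosen_alt: list[str] = []
    used: set[int] = set()
    for key, want in quotas.items():
        pool = buckets[key].drop_duplicates("position")
        pool = pool[~pool["position"].isin(used)]
        if len(pool) < want:
            raise ValueError(f"infeasible placement request for class '{key}'")
        take = pool.iloc[np.sort(rng.choice(len(pool), size=want, replace=False))]
        chosen_pos.extend(int(p) for p in take["position"])
        chosen_alt.extend(take["alt"])
        used.update(take["position"])
    order = np.argsort(chosen_pos)
    return np.array(chosen_pos)[order], np.array(chosen_alt, dtype="<U1")[order]


# ---------------------------------------------------------------------------
# Fixed-spectrum fixtures
# ---------------------------------------------------------------------------

def fixed_spectrum_fixture(
    reference: str,
    annotation: MitoAnnotation,
    class_counts: Mapping[str, int],
    class_mafs: Mapping[str, float | Sequence[float]],
    depth: int = 1_000_000,
    model: GranthamModel | None = None,
    catalogue: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Deterministic allele-count fixture with exact effect-class counts.

    ``class_counts`` maps class names (noncoding, synonymous,
    missense_benign, missense_deleterious, lof) to requested site counts;
    ``class_mafs`` gives a scalar MAF or per-site MAF list per class.
    Planted minor-allele counts are rounded to the nearest read at
    ``depth`` (chosen so the rounding error is < 1e-6); no background
    noise is added, so post-annotation class counts equal the request
    exactly.
    """
    model = model or DEFAULT_GRANTHAM
    unknown = set(class_counts) - set(FIXTURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown fixture classes: {sorted(unknown)}")
    cat = catalogue if catalogue is not None else effect_catalogue(reference, annotation, model)
    used: set[int] = set()
    rows = []
    for klass in FIXTURE_CLASSES:
        want = int(class_counts.get(klass, 0))
        if want == 0:
            continue
        mafs = class_mafs.get(klass)
        if mafs is None:
            raise ValueError(f"no MAFs supplied for class '{klass}'")
        mafs = [float(mafs)] * want if np.isscalar(mafs) else [float(m) for m in mafs]
        if len(mafs) != want:
            raise ValueError(
                f"class '{klass}': {want} sites requested but {len(mafs)} MAFs given"
            )
        pool = cat[cat["klass"] == klass].drop_duplicates("position")
        pool = pool[~pool["position"].isin(used)]
        if len(pool) < want:
            raise ValueError(
                f"infeasible class request: only {len(pool)} placements "
                f"available for class '{klass}', {want} requested"
            )
        take = pool.iloc[:want]
        used.update(take["position"])
        for (row, maf) in zip(take.itertuples(index=False), mafs):
            if not 0 < maf <= 0.5:
                raise ValueError(f"MAF {maf} outside (0, 0.5]")
            alt_count = int(round(maf * depth))
            if alt_count < 1 or abs(alt_count / depth - maf) >= 1e-6:
                raise ValueError(
                    f"depth {depth} cannot represent MAF {maf} exactly enough; "
                    "increase depth"
                )
            rows.append((row.position, row.ref, row.alt, alt_count))
    out_rows = []
    for pos, ref, alt, alt_count in sorted(rows):
        counts = dict.fromkeys(BASES, 0)
        counts[alt] = alt_count
        counts[ref] = depth - alt_count
        bq = {f"bq_{b}": (37.0 if counts[b] else 0.0) for b in BASES}
        out_rows.append(
            {"position": pos, "ref": ref, **counts, "depth": depth, **bq, "map_qual": 60.0}
        )
    return pd.DataFrame(out_rows, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    true_copies_per_cell: float,
    nuclear_ploidy: int,
    chrom_depth_mean: float = 4.0,
    noise_cv: float = 0.02,
    seed: int | None = None,
    n_chromosomes: int = 24,
) -> CoverageSummary:
    """Coverage summary consistent with a known mitogenome copy number.

    Per-chromosome depths are normal(chrom_depth_mean, noise_cv * mean)
    truncated positive (depth is flat across chromosomes up to noise); the
    mt depth is true_copies * chrom_depth_mean / ploidy, perturbed by the
    same relative noise, so :func:`pool_metrics.copy_number` recovers the
    truth within a few multiples of noise_cv.
    """
    if true_copies_per_cell <= 0 or chrom_depth_mean <= 0:
        raise ValueError("inputs must be positive")
    rng = np.random.default_rng(seed)
    chrom = rng.normal(chrom_depth_mean, noise_cv * chrom_depth_mean, n_chromosomes)
    chrom = np.maximum(chrom, 1e-6)
    mt_clean = true_copies_per_cell * chrom_depth_mean / nuclear_ploidy
    mt = max(mt_clean * (1 + rng.normal(0, noise_cv)), 1e-6)
    return CoverageSummary(chrom_depths=chrom, mt_depth=float(mt))


# ---------------------------------------------------------------------------
# FASTA / table output helpers
# ---------------------------------------------------------------------------

def write_fasta(sequence: str, path, name: str = "mt_synthetic") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
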