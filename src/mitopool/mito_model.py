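"""Reference mitogenome model.

Holds the circular mitogenome representation (typed features with reading
frames), the vertebrate mitochondrial genetic code, variant-effect
annotation, transition/transversion classification, and the Grantham
amino-acid distance model used for deleteriousness scoring.

Coordinates are 1-based inclusive throughout, matching the convention of
mitogenome annotation tables. Origin-spanning (wrap-around) features are
represented as two sub-intervals sharing a name and ordered by ``part``;
codon reconstruction joins the parts in coding order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Transition partner of each base.
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: The two transversion partners of each base.
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

#: Loss-of-function effect classes this package can produce. Splice classes
#: cannot occur on an intron-less mitogenome; they are accepted as input
#: labels from imported annotations but never generated here.
LOF_EFFECTS = frozenset({"stop_gained", "stop_lost", "start_lost"})
ACCEPTED_LOF_LABELS = LOF_EFFECTS | {
    "splice_acceptor_variant",
    "splice_donor_variant",
}
NONSYNONYMOUS_EFFECTS = ACCEPTED_LOF_LABELS | {"missense"}

#: Severity ranking used when a position lies in overlapping CDS features.
EFFECT_SEVERITY = {
    "stop_gained": 5,
    "stop_lost": 4,
    "start_lost": 3,
    "missense": 2,
    "synonymous": 1,
    "noncoding": 0,
}

_FTYPE_PRECEDENCE = {"CDS": 0, "rRNA": 1, "tRNA": 2, "control": 3}


# ---------------------------------------------------------------------------
# Features and annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One typed interval on the mitogenome (1-based inclusive).

    ``part`` orders the sub-intervals of an origin-spanning feature in
    coding order; single-interval features use ``part=0``.
    """

    name: str
    ftype: str  # CDS | rRNA | tRNA | control
    start: int
    end: int
    strand: str = "+"
    table_id: int = 2
    incomplete_terminal: bool = False
    part: int = 0

    def __post_init__(self) -> None:
        if self.ftype not in _FTYPE_PRECEDENCE:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"feature {self.name}: require 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class MitoAnnotation:
    """Circular mitogenome length plus its typed features.

    Features tile positions without requiring full coverage; positions
    covered by no feature are labelled ``"intergenic"``.
    """

    genome_length: int
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.name} extends past genome end "
                    f"({f.end} > {self.genome_length})"
                )

    # -- queries ----------------------------------------------------------

    def features_at(self, position: int) -> list[Feature]:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside genome (1..{self.genome_length})"
            )
        return [f for f in self.features if f.contains(position)]

    def region_of(self, position: int) -> str:
        """Region label at a position.

        Overlapping features are broken by type precedence
        (CDS > rRNA > tRNA > control) then lexicographic name; positions in
        no feature are ``"intergenic"``.
        """
        hits = self.features_at(position)
        if not hits:
            return "intergenic"
        hits.sort(key=lambda f: (_FTYPE_PRECEDENCE[f.ftype], f.name))
        return hits[0].name

    def cds_groups(self) -> dict[str, list[Feature]]:
        """CDS features grouped by name, parts in coding order."""
        groups: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.ftype == "CDS":
                groups.setdefault(f.name, []).append(f)
        for parts in groups.values():
            parts.sort(key=lambda f: f.part)
        return groups

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": f.name,
                    "ftype": f.ftype,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "table_id": f.table_id,
                    "incomplete_terminal": f.incomplete_terminal,
                    "part": f.part,
                }
                for f in self.features
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome_length: int, circular: bool = True) -> "MitoAnnotation":
        df = pd.read_csv(path, sep="\t")
        feats = [
            Feature(
                name=str(r["name"]),
                ftype=str(r["ftype"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r.get("strand", "+")),
                table_id=int(r.get("table_id", 2)),
                incomplete_terminal=bool(r.get("incomplete_terminal", False)),
                part=int(r.get("part", 0)),
            )
            for _, r in df.iterrows()
        ]
        return cls(genome_length=genome_length, features=feats, circular=circular)

    @classmethod
    def from_gff3(cls, path, genome_length: int, circular: bool = True) -> "MitoAnnotation":
        """Minimal GFF3 reader mapping gene-level records to features.

        Recognised GFF types: CDS, rRNA, tRNA, D_loop/region->control.
        Feature name is taken from the Name= or ID= attribute.
        """
        type_map = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
                    "D_loop": "control", "region": "control"}
        feats = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9 or cols[2] not in type_map:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                name = attrs.get("Name", attrs.get("ID", cols[2]))
                frame = cols[7]
                feats.append(
                    Feature(
                        name=name,
                        ftype=type_map[cols[2]],
                        start=int(cols[3]),
                        end=int(cols[4]),
                        strand=cols[6] if cols[6] in "+-" else "+",
                        table_id=int(attrs.get("transl_table", 2)),
                        incomplete_terminal=frame not in ("0", "."),
                    )
                )
        return cls(genome_length=genome_length, features=feats, circular=circular)


def region_of(position: int, annotation: MitoAnnotation) -> str:
    """Region label of a position (see :meth:`MitoAnnotation.region_of`)."""
    return annotation.region_of(position)


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

def _codon_table(table_id: int) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unsupported translation table {table_id}") from exc


def translate_codon(codon: str, table_id: int = 2) -> str:
    """Translate one codon; returns a one-letter residue or ``"*"`` for stop.

    Table 2 (vertebrate mitochondrial) deviations from the standard code are
    honored: TGA->Trp, ATA->Met, AGA/AGG->stop.
    """
    codon = str(codon).upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon: {codon!r}")
    table = _codon_table(table_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a base substitution as transition (Ts) or transversion (Tv)."""
    ref, alt = str(ref).upper(), str(alt).upper()
    for b in (ref, alt):
        if b not in BASES:
            raise ValueError(f"invalid base: {b!r}")
    if ref == alt:
        raise ValueError("not a substitution: ref equals alt")
    same_class = (ref in PURINES) == (alt in PURINES)
    return "Ts" if same_class else "Tv"


# ---------------------------------------------------------------------------
# Variant-effect annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectCall:
    """One per-feature effect call for a variant."""

    effect: str
    feature: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def _coding_offset(parts: list[Feature], position: int) -> int | None:
    """Offset of a genome position within the concatenated coding sequence."""
    offset = 0
    for part in parts:
        if part.contains(position):
            if part.strand == "+":
                return offset + (position - part.start)
            return offset + (part.end - position)
        offset += len(part)
    return None


def _coding_sequence(reference: str, parts: list[Feature]) -> str:
    chunks = []
    for part in parts:
        seg = reference[part.start - 1 : part.end]
        if part.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        chunks.append(seg)
    return "".join(chunks).upper()


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def effect_calls(
    position: int,
    ref: str,
    alt: str,
    annotation: MitoAnnotation,
    reference: str,
) -> list[EffectCall]:
    """All per-feature effect calls for a substitution, one per CDS group
    containing the position; empty if the position is non-coding."""
    ref, alt = str(ref).upper(), str(alt).upper()
    if not 1 <= position <= annotation.genome_length:
        raise ValueError(f"position {position} outside genome")
    genome_base = reference[position - 1].upper()
    if genome_base != ref:
        raise ValueError(
            f"reference mismatch at {position}: expected {genome_base}, got {ref}"
        )
    calls: list[EffectCall] = []
    for name, parts in annotation.cds_groups().items():
        offset = _coding_offset(parts, position)
        if offset is None:
            continue
        cds = _coding_sequence(reference, parts)
        incomplete = (len(cds) % 3 != 0) or any(p.incomplete_terminal for p in parts)
        codon_idx, within = divmod(offset, 3)
        if codon_idx * 3 + 3 > len(cds):
            logger.warning(
                "position %d falls in the incomplete terminal codon of %s; "
                "treated as noncoding", position, name,
            )
            continue
        if incomplete and codon_idx == len(cds) // 3:
            logger.warning(
                "position %d in incomplete terminal codon of %s", position, name
            )
            continue
        table_id = parts[0].table_id
        strand = parts[0].strand
        coding_alt = alt if strand == "+" else _COMPLEMENT[alt]
        old_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        new_codon = (
            old_codon[:within] + coding_alt + old_codon[within + 1 :]
        )
        old_aa = translate_codon(old_codon, table_id)
        new_aa = translate_codon(new_codon, table_id)
        table = _codon_table(table_id)
        if new_aa == old_aa:
            effect = "synonymous"
        elif new_aa == "*":
            effect = "stop_gained"
        elif old_aa == "*":
            effect = "stop_lost"
        elif codon_idx == 0 and new_codon not in table.start_codons:
            effect = "start_lost"
        else:
            effect = "missense"
        calls.append(EffectCall(effect, name, old_aa, new_aa))
    return calls


def annotate_effect(
    position: int,
    ref: str,
    alt: str,
    annotation: MitoAnnotation,
    reference: str,
) -> str:
    """Most severe effect of a substitution across all CDS features at the
    position; ``"noncoding"`` outside CDS.

    Severity order: stop_gained > stop_lost > start_lost > missense >
    synonymous.
    """
    calls = effect_calls(position, ref, alt, annotation, reference)
    if not calls:
        return "noncoding"
    return max(calls, key=lambda c: EFFECT_SEVERITY[c.effect]).effect


# ---------------------------------------------------------------------------
# Grantham distance
# ---------------------------------------------------------------------------

#: Grantham's amino-acid property table: composition (c), polarity (p),
#: molecular volume (v).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

AMINO_ACIDS = tuple(sorted(GRANTHAM_PROPERTIES))


@dataclass
class GranthamModel:
    """Grantham (1974) physicochemical distance between amino acids.

    D(i,j) = rho * [alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2
                    + gamma*(v_i-v_j)^2]^(1/2)

    ``rho`` normalizes the mean over the 190 unordered pairs to 100
    (computed exactly from the property table when not supplied), and the
    integer matrix is the formula rounded to the nearest unit, so the
    formula and the embedded matrix agree on every pair by construction.
    Missense changes scoring strictly above ``deleterious_threshold`` are
    flagged deleterious.
    """

    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: float | None = None
    deleterious_threshold: float = 150.0
    properties: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    matrix: dict[frozenset, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pairs = list(itertools.combinations(sorted(self.properties), 2))
        raw = {frozenset(p): self._raw(*p) for p in pairs}
        if self.rho is None:
            self.rho = 100.0 * len(pairs) / sum(raw.values())
        self.matrix = {k: round(self.rho * v) for k, v in raw.items()}

    def _raw(self, a: str, b: str) -> float:
        ca, pa, va = self.properties[a]
        cb, pb, vb = self.properties[b]
        return math.sqrt(
            self.alpha * (ca - cb) ** 2
            + self.beta * (pa - pb) ** 2
            + self.gamma * (va - vb) ** 2
        )

    def formula_distance(self, aa1: str, aa2: str) -> float:
        """Unrounded formula distance (test oracle for the matrix)."""
        self._check(aa1), self._check(aa2)
        if aa1 == aa2:
            return 0.0
        return self.rho * self._raw(aa1, aa2)

    def distance(self, aa1: str, aa2: str) -> int:
        self._check(aa1), self._check(aa2)
        if aa1 == aa2:
            return 0
        return self.matrix[frozenset((aa1, aa2))]

    def is_deleterious(self, aa1: str, aa2: str) -> bool:
        return self.distance(aa1, aa2) > self.deleterious_threshold

    def _check(self, aa: str) -> None:
        if aa not in self.properties:
            raise ValueError(
                f"not scoreable: {aa!r} is not a standard amino acid "
                "(stop changes are routed to LOF, not Grantham)"
            )


#: Shared default model (vertebrate-agnostic; the matrix is organism-free).
DEFAULT_GRANTHAM = GranthamModel()


def grantham_distance(aa1: str, aa2: str, model: GranthamModel | None = None) -> int:
    """Grantham distance between two standard amino acids (symmetric,
    zero on the diagonal, off-diagonal values in [5, 215])."""
    return (model or DEFAULT_GRANTHAM).distance(aa1, aa2)
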