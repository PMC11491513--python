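"""NUMT screening: mt <-> nuclear homology detection and site masking.

Nuclear-embedded mitochondrial segments (NUMTs) masquerade as low-frequency
heteroplasmy when nuclear reads co-align to the mitogenome. This module
finds mt/nuclear homologous intervals with a desk-scale exact-seed,
ungapped-extension matcher and removes HP sites falling inside matched
mitogenome intervals.

Coordinates are 1-based inclusive. Minus-strand hits follow the convention
of reporting the nuclear interval in reversed order (nuc_start > nuc_end).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

VALID = set("ACGT")


@dataclass(frozen=True)
class NumtHit:
    """One mt/nuclear homology interval.

    ``length`` is the inclusive mt-interval length (end - start + 1);
    strand is ``-`` iff nuc_start > nuc_end.
    """

    mt_start: int
    mt_end: int
    nuc_start: int
    nuc_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.mt_end - self.mt_start + 1


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= VALID:  # N-runs never seed
            index.setdefault(kmer, []).append(i)
    return index


def _extend(nuc: str, mt: str, i: int, j: int, k: int, min_identity: float) -> tuple[int, int, int, int, float]:
    """Greedy ungapped extension of an exact seed (0-based anchors i, j).

    Extends one base at a time on each side while running identity stays at
    or above ``min_identity``, stopping at two consecutive mismatches; the
    extension is trimmed back to the last matching base so hits end on
    matches. Returns (nuc_lo, mt_lo, length, matches, identity).
    """
    matches = k
    length = k
    # right extension
    step = mismatch_run = 0
    best_right, best_right_matches = 0, matches
    cur = matches
    while i + k + step < len(nuc) and j + k + step < len(mt):
        eq = nuc[i + k + step] == mt[j + k + step]
        cur += eq
        step += 1
        mismatch_run = 0 if eq else mismatch_run + 1
        if mismatch_run >= 2 or cur / (length + step) < min_identity:
            break
        if eq:
            best_right, best_right_matches = step, cur
    length += best_right
    matches = best_right_matches
    # left extension
    step = mismatch_run = 0
    best_left, best_left_matches = 0, matches
    cur = matches
    while i - step - 1 >= 0 and j - step - 1 >= 0:
        eq = nuc[i - step - 1] == mt[j - step - 1]
        cur += eq
        step += 1
        mismatch_run = 0 if eq else mismatch_run + 1
        if mismatch_run >= 2 or cur / (length + step) < min_identity:
            break
        if eq:
            best_left, best_left_matches = step, cur
    length += best_left
    matches = best_left_matches
    nuc_lo = i - best_left
    mt_lo = j - best_left
    return nuc_lo, mt_lo, length, matches, matches / length


def find_numts(
    nuclear_seq: str,
    mt_seq: str,
    min_seed: int = 20,
    min_length: int = 25,
    min_identity: float = 0.9,
) -> list[NumtHit]:
    """Find mt/nuclear homologous segments on both strands.

    Maximal ungapped matches are seeded by exact ``min_seed``-mers of the
    mitogenome, extended while identity stays >= ``min_identity``;
    overlapping/contained hits are merged and hits shorter than
    ``min_length`` are dropped. Hits are reported with 1-based inclusive
    coordinates; minus-strand hits have nuc_start > nuc_end.
    """
    if min_seed < 11:
        raise ValueError("min_seed must be >= 11")
    nuclear_seq = str(nuclear_seq).upper()
    mt_seq = str(mt_seq).upper()
    if not nuclear_seq or not mt_seq:
        return []
    index = _seed_index(mt_seq, min_seed)
    n = len(nuclear_seq)
    raw: set[tuple[int, int, int, int, str, float]] = set()
    for strand in "+-":
        nuc = nuclear_seq if strand == "+" else _revcomp(nuclear_seq)
        # furthest nuclear index already covered per diagonal: seeds inside
        # an extended hit need no re-extension
        covered: dict[int, int] = {}
        for i in range(len(nuc) - min_seed + 1):
            kmer = nuc[i : i + min_seed]
            for j in index.get(kmer, ()):
                diag = i - j
                if covered.get(diag, -1) >= i + min_seed:
                    continue
                nuc_lo, mt_lo, length, _, ident = _extend(
                    nuc, mt_seq, i, j, min_seed, min_identity
                )
                covered[diag] = max(covered.get(diag, -1), nuc_lo + length)
                mt_start, mt_end = mt_lo + 1, mt_lo + length
                if strand == "+":
                    nuc_start, nuc_end = nuc_lo + 1, nuc_lo + length
                else:
                    # map back from the reverse-complemented scan
                    nuc_start = n - nuc_lo        # larger coordinate first
                    nuc_end = n - (nuc_lo + length - 1)
                raw.add((mt_start, mt_end, nuc_start, nuc_end, strand, ident))
    merged = _merge_hits(raw)
    hits = [
        NumtHit(*h)
        for h in merged
        if (h[1] - h[0] + 1) >= min_length and h[5] >= min_identity
    ]
    hits.sort(key=lambda h: (h.mt_start, h.mt_end, h.strand))
    return hits


def _merge_hits(raw: set) -> list[tuple]:
    """Merge same-strand, same-diagonal overlapping hits; drop hits whose
    mt and nuclear intervals are both contained in another hit."""
    by_diag: dict[tuple, list] = {}
    for mt_s, mt_e, nuc_s, nuc_e, strand, ident in raw:
        diag = (strand, min(nuc_s, nuc_e) - mt_s if strand == "+" else max(nuc_s, nuc_e) + mt_s)
        by_diag.setdefault(diag, []).append([mt_s, mt_e, nuc_s, nuc_e, strand, ident])
    merged: list[tuple] = []
    for (strand, _), group in by_diag.items():
        group.sort(key=lambda h: h[0])
        cur = group[0]
        for nxt in group[1:]:
            if nxt[0] <= cur[1] + 1:  # overlapping/adjacent on mt, same diagonal
                w1, w2 = cur[1] - cur[0] + 1, nxt[1] - nxt[0] + 1
                cur[1] = max(cur[1], nxt[1])
                if strand == "+":
                    cur[2], cur[3] = min(cur[2], nxt[2]), max(cur[3], nxt[3])
                else:
                    cur[2], cur[3] = max(cur[2], nxt[2]), min(cur[3], nxt[3])
                cur[5] = (cur[5] * w1 + nxt[5] * w2) / (w1 + w2)
            else:
                merged.append(tuple(cur))
                cur = nxt
        merged.append(tuple(cur))
    # containment removal (both axes)
    out = []
    for h in merged:
        contained = any(
            g is not h
            and g[4] == h[4]
            and g[0] <= h[0] and h[1] <= g[1]
            and min(g[2], g[3]) <= min(h[2], h[3])
            and max(h[2], h[3]) <= max(g[2], g[3])
            and (g[1] - g[0]) > (h[1] - h[0])
            for g in merged
        )
        if not contained:
            out.append(h)
    return out


def mask_sites(hp_sites: pd.DataFrame, hits: list[NumtHit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition HP sites into (kept, masked) by NUMT mt-interval containment.

    A site is masked iff its position lies in any hit's inclusive
    [mt_start, mt_end]; the partition is exact (|kept| + |masked| = input).
    """
    if hp_sites.empty or not hits:
        return hp_sites.copy(), hp_sites.iloc[0:0].copy()
    pos = hp_sites["position"]
    masked = pd.Series(False, index=hp_sites.index)
    for h in hits:
        masked |= (pos >= h.mt_start) & (pos <= h.mt_end)
    return (
        hp_sites.loc[~masked].reset_index(drop=True),
        hp_sites.loc[masked].reset_index(drop=True),
    )


def hits_to_frame(hits: list[NumtHit]) -> pd.DataFrame:
    """Hit table mirroring the usual NUMT report columns."""
    return pd.DataFrame(
        [
            {
                "mt_start": h.mt_start,
                "mt_end": h.mt_end,
                "nuc_start": h.nuc_start,
                "nuc_end": h.nuc_end,
                "strand": h.strand,
                "identity": h.identity,
                "length_bp": h.length,
            }
            for h in hits
        ]
    )


def write_hits_tsv(hits: list[NumtHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_hits_bed(hits: list[NumtHit], path, chrom: str = "MT") -> None:
    """Write mt intervals as BED (0-based half-open) for masking interop."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{chrom}\t{h.mt_start - 1}\t{h.mt_end}\tnumt\t0\t{h.strand}\n")
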