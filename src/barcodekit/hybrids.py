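"""Hybrid diagnosis and infraspecific haplotype analysis.

An F1 hybrid carries, at every nuclear site where its two parent species
differ, the IUPAC two-base code of the parental pair (A/G -> R and so on),
because both parental alleles are present and Sanger consensus calls the
double peak as an ambiguity code.  The chloroplast is maternally inherited,
so the hybrid's plastid sequence identifies the seed parent.

Parental species are represented by strict-majority consensus sequences
over their conspecific individuals; columns without a majority base are
excluded from the diagnostics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seq_io import PAIR_TO_CODE, MarkerAlignment

BASES = set("ACGT")


def consensus(sequences: Sequence[str]) -> str:
    """Strict-majority consensus; columns without a majority become ``N``."""
    if not sequences:
        raise ValueError("consensus of zero sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("unequal sequence lengths")
    out = []
    for col in range(L):
        counts = Counter(s[col] for s in sequences)
        base, k = counts.most_common(1)[0]
        out.append(base if 2 * k > len(sequences) else "N")
    return "".join(out)


def species_consensuses(aln: MarkerAlignment, species_of: Dict[str, str]) -> Dict[str, str]:
    """Per-species consensus over all conspecific sequences in the alignment."""
    groups: Dict[str, List[str]] = {}
    for sid, seq in aln.sequences.items():
        sp = species_of.get(sid)
        if sp is not None:
            groups.setdefault(sp, []).append(seq)
    return {sp: consensus(seqs) for sp, seqs in groups.items()}


@dataclass
class DiagnosticSite:
    column: int  # 1-based alignment column
    parent1_base: str
    parent2_base: str
    hybrid_base: str
    is_heterozygous_match: bool


def diagnostic_sites(parent1: str, parent2: str, hybrid: str) -> List[DiagnosticSite]:
    """Columns where the parents carry different unambiguous bases.

    A column is a heterozygous match when the putative hybrid carries
    exactly the two-base IUPAC code of the parental base pair.
    """
    if not (len(parent1) == len(parent2) == len(hybrid)):
        raise ValueError("unequal sequence lengths")
    sites = []
    for col, (b1, b2, h) in enumerate(zip(parent1, parent2, hybrid), start=1):
        if b1 in BASES and b2 in BASES and b1 != b2:
            expected = PAIR_TO_CODE[frozenset((b1, b2))]
            sites.append(
                DiagnosticSite(
                    column=col,
                    parent1_base=b1,
                    parent2_base=b2,
                    hybrid_base=h,
                    is_heterozygous_match=(h == expected),
                )
            )
    return sites


@dataclass
class HybridCall:
    hybrid_id: str
    parent_pair: Optional[Tuple[str, str]]  # alphabetical; None if no call
    n_diagnostic: int
    n_heterozygous: int
    fraction: float
    maternal_parent: Optional[str] = None
    unresolved: bool = False
    tied_pairs: List[Tuple[str, str]] = field(default_factory=list)
    best_pair: Optional[Tuple[str, str]] = None  # top candidate even when below threshold


def infer_parent_pair(
    hybrid_id: str,
    hybrid_seq: str,
    candidates: Dict[str, str],
    min_sites: int = 3,
    call_threshold: float = 0.8,
) -> HybridCall:
    """Best-supported parental species pair for a putative hybrid.

    Scans all candidate pairs with at least ``min_sites`` diagnostic
    columns and picks the one maximizing the heterozygous fraction; a call
    requires that fraction >= ``call_threshold``.  Ties between pairs are
    reported as unresolved (no call).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate parent species")
    best: List[Tuple[Tuple[str, str], int, int, float]] = []
    for sp1, sp2 in combinations(sorted(candidates), 2):
        sites = diagnostic_sites(candidates[sp1], candidates[sp2], hybrid_seq)
        n_diag = len(sites)
        if n_diag < min_sites:
            continue
        n_het = sum(s.is_heterozygous_match for s in sites)
        frac = n_het / n_diag
        best.append(((sp1, sp2), n_diag, n_het, frac))
    if not best:
        return HybridCall(hybrid_id, None, 0, 0, 0.0, unresolved=False)
    best.sort(key=lambda t: (-t[3], t[0]))
    top = best[0]
    tied = [b for b in best if abs(b[3] - top[3]) < 1e-12]
    if top[3] < call_threshold:
        return HybridCall(
            hybrid_id, None, top[1], top[2], top[3],
            unresolved=False, best_pair=top[0],
        )
    if len(tied) > 1:
        return HybridCall(
            hybrid_id, None, top[1], top[2], top[3],
            unresolved=True, tied_pairs=[b[0] for b in tied], best_pair=top[0],
        )
    return HybridCall(hybrid_id, top[0], top[1], top[2], top[3], best_pair=top[0])


def maternal_parent(
    hybrid_cp: str,
    parent1: str,
    parent1_cp: str,
    parent2: str,
    parent2_cp: str,
) -> Optional[str]:
    """Maternal parent from chloroplast similarity.

    The parent whose plastid consensus differs from the hybrid's plastid at
    fewer comparable sites wins, by a margin of at least one substitution;
    an equidistant hybrid is unresolved (None).
    """

    def _mismatches(a: str, b: str) -> int:
        if len(a) != len(b):
            raise ValueError("unequal sequence lengths")
        return sum(
            1 for x, y in zip(a, b) if x in BASES and y in BASES and x != y
        )

    m1 = _mismatches(hybrid_cp, parent1_cp)
    m2 = _mismatches(hybrid_cp, parent2_cp)
    if m1 + 1 <= m2:
        return parent1
    if m2 + 1 <= m1:
        return parent2
    return None


@dataclass
class HaplotypeTable:
    """Variant columns and the haplotype index of each individual."""

    variants: pd.DataFrame  # kind (snv/indel), marker, start, end
    assignment: Dict[str, int]
    n_haplotypes: int
    n_snv: int
    n_indel: int


def haplotype_collapse(alignments: Sequence[MarkerAlignment]) -> HaplotypeTable:
    """Collapse individuals into haplotypes over the variants of >=1 markers.

    SNVs are single columns with two or more distinct unambiguous bases;
    an indel is a maximal run of columns where at least one individual has
    a gap, counted as one variant event regardless of its width.  Only
    individuals present in every supplied alignment are used.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    shared = set(alignments[0].sequences)
    for aln in alignments[1:]:
        shared &= set(aln.sequences)
    if not shared:
        raise ValueError("no individuals shared across alignments")
    ids = sorted(shared)

    var_rows = []
    states: Dict[str, List[str]] = {sid: [] for sid in ids}
    for aln in alignments:
        seqs = [aln.sequences[sid] for sid in ids]
        L = aln.length
        has_gap = [any(s[c] == "-" for s in seqs) for c in range(L)]
        # Maximal gap-containing runs are single indel events.
        c = 0
        in_indel = np.zeros(L, dtype=bool)
        while c < L:
            if has_gap[c]:
                start = c
                while c < L and has_gap[c]:
                    c += 1
                end = c - 1
                in_indel[start : end + 1] = True
                var_rows.append(
                    {"kind": "indel", "marker": aln.marker, "start": start + 1, "end": end + 1}
                )
                for sid, seq in zip(ids, seqs):
                    states[sid].append(seq[start : end + 1])
            else:
                c += 1
        for col in range(L):
            if in_indel[col]:
                continue
            bases = {s[col] for s in seqs} & BASES
            if len(bases) >= 2:
                var_rows.append(
                    {"kind": "snv", "marker": aln.marker, "start": col + 1, "end": col + 1}
                )
                for sid, seq in zip(ids, seqs):
                    states[sid].append(seq[col])

    keys: Dict[Tuple[str, ...], int] = {}
    assignment = {}
    for sid in ids:
        key = tuple(states[sid])
        if key not in keys:
            keys[key] = len(keys) + 1
        assignment[sid] = keys[key]
    variants = pd.DataFrame(var_rows, columns=["kind", "marker", "start", "end"])
    # Keep only variant indel events (invariant all-gap regions shared by
    # every individual are not variants).
    if not variants.empty:
        informative = []
        for _, row in variants.iterrows():
            if row["kind"] == "snv":
                informative.append(True)
            else:
                aln = next(a for a in alignments if a.marker == row["marker"])
                block = {aln.sequences[sid][row["start"] - 1 : row["end"]] for sid in ids}
                informative.append(len(block) > 1)
        variants = variants[np.array(informative, dtype=bool)].reset_index(drop=True)
    n_snv = int((variants["kind"] == "snv").sum()) if not variants.empty else 0
    n_indel = int((variants["kind"] == "indel").sum()) if not variants.empty else 0
    return HaplotypeTable(
        variants=variants,
        assignment=assignment,
        n_haplotypes=len(keys),
        n_snv=n_snv,
        n_indel=n_indel,
    )
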