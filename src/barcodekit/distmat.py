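"""Kimura 2-parameter distances, marker summaries and barcode-gap analysis.

The K2P distance between two aligned sequences is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with P and Q the transition and transversion proportions over comparable
sites.  Sites where either sequence carries a gap, ``N`` or an ambiguity
code are excluded (pairwise deletion, the common distance-matrix
convention).  A pair with fewer comparable sites
than ``min_overlap`` is MISSING (NaN); a saturated pair (argument of a log
non-positive) is flagged with an infinite sentinel and excluded from
min/max summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .seq_io import MarkerAlignment, SpecimenRecord

#: Sentinel for a saturated (undefined) distance.
SATURATED = np.inf

#: Default minimum number of comparable sites for a defined distance.
DEFAULT_MIN_OVERLAP = 50

_CODE = np.full(256, -1, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and every other symbol (gap, N, ambiguity) as -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def encode_alignment(aln: MarkerAlignment) -> Tuple[List[str], np.ndarray]:
    ids = aln.ids
    mat = np.vstack([encode_sequence(aln.sequences[i]) for i in ids]) if ids else np.empty((0, 0), np.int8)
    return ids, mat


def _k2p_from_counts(n_sites: int, n_ts: int, n_tv: int) -> float:
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return SATURATED
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_distance(a: str, b: str, min_overlap: int = 1) -> float:
    """K2P distance between two aligned sequences; NaN if overlap < min_overlap."""
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    ca, cb = encode_sequence(a), encode_sequence(b)
    valid = (ca >= 0) & (cb >= 0)
    n = int(valid.sum())
    if n < min_overlap:
        return np.nan
    va, vb = ca[valid], cb[valid]
    diff = va != vb
    # Purines (A=0, G=2) are even codes, pyrimidines (C=1, T=3) odd: a
    # substitution is a transition iff the parities agree.
    ts = diff & (((va ^ vb) & 1) == 0)
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return _k2p_from_counts(n, n_ts, n_tv)


def p_distance(a: str, b: str, min_overlap: int = 1) -> float:
    """Proportion of differing comparable sites (pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    ca, cb = encode_sequence(a), encode_sequence(b)
    valid = (ca >= 0) & (cb >= 0)
    n = int(valid.sum())
    if n < min_overlap:
        return np.nan
    return float((ca[valid] != cb[valid]).sum() / n)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair comparable-site counts.

    ``d`` uses NaN for MISSING pairs and +inf for saturated ones.
    """

    ids: List[str]
    d: np.ndarray
    overlap: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n) and self.overlap.shape == (n, n)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index_of(a), self.index_of(b)])

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.overlap[np.ix_(idx, idx)])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id1": self.ids[i],
                        "id2": self.ids[j],
                        "distance": self.d[i, j],
                        "overlap": int(self.overlap[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["id1", "id2", "distance", "overlap"])


def matrix_from_codes(
    ids: List[str], mat: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """K2P matrix from an encoded alignment (rows = sequences, -1 = excluded site).

    Vectorized via one-hot base-indicator matrix products, so bootstrap
    replicates over hundreds of sequences stay cheap.
    """
    n = len(ids)
    if n < 2:
        raise ValueError("pairwise_matrix needs at least 2 sequences")
    onehot = [(mat == b).astype(np.float32) for b in range(4)]  # A, C, G, T
    valid = (mat >= 0).astype(np.float32)
    overlap_f = valid @ valid.T
    same = sum(B @ B.T for B in onehot)
    A, C, G, T = onehot
    ts = A @ G.T + G @ A.T + C @ T.T + T @ C.T  # purine<->purine, pyrimidine<->pyrimidine
    tv = overlap_f - same - ts

    # The matmul counts are exact small integers in float32; divide in
    # float64 so matrix entries agree with the scalar k2p_distance path.
    ts64, tv64, ov64 = (x.astype(np.float64) for x in (ts, tv, overlap_f))
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts64 / ov64
        Q = tv64 / ov64
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    saturated = (w1 <= 0.0) | (w2 <= 0.0)
    d = np.where(saturated, SATURATED, d)
    overlap = np.rint(overlap_f).astype(int)
    d = np.where(overlap < min_overlap, np.nan, d).astype(float)
    np.fill_diagonal(d, 0.0)
    # Enforce exact symmetry; the counts are symmetric so this is a no-op
    # beyond guarding against accumulation-order effects.
    iu = np.triu_indices(n, k=1)
    d[(iu[1], iu[0])] = d[iu]
    return DistanceMatrix(list(ids), d, overlap)


def pairwise_matrix(aln: MarkerAlignment, min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs K2P matrix under pairwise deletion."""
    ids, mat = encode_alignment(aln)
    return matrix_from_codes(ids, mat, min_overlap=min_overlap)


def _species_map(specimens: Sequence[SpecimenRecord], exclude_hybrids: bool = True) -> Dict[str, str]:
    return {
        r.specimen_id: r.species
        for r in specimens
        if not (exclude_hybrids and r.group == "hybrid")
    }


def partition_distances(
    m: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    exclude_hybrids: bool = True,
) -> Tuple[List[float], List[float]]:
    """Split non-MISSING off-diagonal pairs into intra- and inter-specific lists.

    Hybrid-group specimens are excluded by default: a hybrid's distance to
    either parent species is neither intra- nor inter-specific in the usual
    sense.  Saturated pairs are retained (callers filter with np.isfinite
    where appropriate).
    """
    species = _species_map(specimens, exclude_hybrids)
    intra, inter = [], []
    n = len(m.ids)
    for i in range(n):
        si = species.get(m.ids[i])
        if si is None:
            continue
        for j in range(i + 1, n):
            sj = species.get(m.ids[j])
            if sj is None:
                continue
            dij = m.d[i, j]
            if np.isnan(dij):
                continue
            (intra if si == sj else inter).append(float(dij))
    return intra, inter


@dataclass
class MarkerSummary:
    """Per-marker characteristics table row."""

    marker: str
    n_sequences: int
    n_species: int
    n_species_valid: int
    pct_valid_conspecifics: float
    gc_content: float
    variable_sites: int
    gap_columns: int
    alignment_length: int
    max_intraspecific: float
    max_interspecific: float


def summarize_marker(
    aln: MarkerAlignment,
    specimens: Sequence[SpecimenRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MarkerSummary:
    """Alignment- and distance-level characteristics of one marker.

    GC content is computed as (G + C + S) over unambiguous non-gap bases
    (S = G-or-C, the only ambiguity that is unambiguously G/C); variable
    sites are columns with >= 2 distinct unambiguous bases; gap columns are
    columns with a gap in at least one sequence.  Hybrids are excluded from
    distance summaries and species counts.
    """
    ids, mat = encode_alignment(aln)
    raw = np.vstack(
        [np.frombuffer(aln.sequences[i].encode("ascii"), dtype=np.uint8) for i in ids]
    ) if ids else np.empty((0, 0), np.uint8)

    gc_num = int(np.isin(raw, [ord("G"), ord("C"), ord("S")]).sum())
    gc_den = gc_num + int(np.isin(raw, [ord("A"), ord("T")]).sum())
    gc = 100.0 * gc_num / gc_den if gc_den else np.nan

    n_var = 0
    for col in range(mat.shape[1]):
        states = np.unique(mat[:, col])
        if (states >= 0).sum() >= 2:
            n_var += 1
    gap_cols = int(((raw == ord("-")).any(axis=0)).sum()) if raw.size else 0

    species = _species_map(specimens)
    present = [sid for sid in ids if sid in species]
    sp_counts: Dict[str, int] = {}
    for sid in present:
        sp_counts[species[sid]] = sp_counts.get(species[sid], 0) + 1
    n_species = len(sp_counts)
    n_valid = sum(1 for c in sp_counts.values() if c >= 2)
    n_valid_seqs = sum(c for c in sp_counts.values() if c >= 2)
    pct_valid = 100.0 * n_valid_seqs / len(present) if present else np.nan

    if len(ids) >= 2:
        m = pairwise_matrix(aln, min_overlap=min_overlap)
        intra, inter = partition_distances(m, specimens)
        intra = [x for x in intra if np.isfinite(x)]
        inter = [x for x in inter if np.isfinite(x)]
    else:
        intra, inter = [], []

    return MarkerSummary(
        marker=aln.marker,
        n_sequences=len(ids),
        n_species=n_species,
        n_species_valid=n_valid,
        pct_valid_conspecifics=pct_valid,
        gc_content=gc,
        variable_sites=n_var,
        gap_columns=gap_cols,
        alignment_length=aln.length,
        max_intraspecific=max(intra) if intra else np.nan,
        max_interspecific=max(inter) if inter else np.nan,
    )


@dataclass
class GapTable:
    """Per-species barcode-gap verdicts.

    A species shows a barcode gap when its minimum distance to any other
    species strictly exceeds its maximum conspecific distance (the point
    lies above the 1:1 line of the max-intra vs min-inter scatter plot).
    """

    table: pd.DataFrame  # species, max_intra, min_inter, has_gap, counted
    percent_with_gap: float

    def species_row(self, species: str) -> pd.Series:
        return self.table.set_index("species").loc[species]


def barcode_gap(
    m: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
    exclude_hybrids: bool = True,
) -> GapTable:
    """Barcode-gap table over all species with at least one sequence.

    Species with a single sequence have UNDEFINED (NaN) max_intra and are
    excluded from the percentage denominator; saturated distances are
    excluded from both extrema.
    """
    species = _species_map(specimens, exclude_hybrids)
    sp_of = [species.get(i) for i in m.ids]
    all_species = sorted({s for s in sp_of if s is not None})
    if len(all_species) < 2:
        raise ValueError("barcode_gap needs at least 2 species")

    finite = np.where(np.isfinite(m.d), m.d, np.nan)
    rows = []
    n_gap = n_counted = 0
    for sp in all_species:
        idx = [i for i, s in enumerate(sp_of) if s == sp]
        other = [i for i, s in enumerate(sp_of) if s is not None and s != sp]
        if len(idx) >= 2:
            block = finite[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            vals = block[iu]
            max_intra = np.nanmax(vals) if np.isfinite(vals).any() else np.nan
        else:
            max_intra = np.nan
        cross = finite[np.ix_(idx, other)]
        min_inter = np.nanmin(cross) if np.isfinite(cross).any() else np.nan
        counted = np.isfinite(max_intra) and np.isfinite(min_inter)
        has_gap = bool(counted and min_inter > max_intra)
        if counted:
            n_counted += 1
            n_gap += has_gap
        rows.append(
            {
                "species": sp,
                "n_sequences": len(idx),
                "max_intra": max_intra,
                "min_inter": min_inter,
                "has_gap": has_gap,
                "counted": counted,
            }
        )
    pct = round(100.0 * n_gap / n_counted, 1) if n_counted else np.nan
    return GapTable(table=pd.DataFrame(rows), percent_with_gap=pct)
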