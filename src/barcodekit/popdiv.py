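"""Population genetic diversity from aligned barcode sequences.

Two per-site diversity estimators over a set of n conspecific sequences:

* Watterson's theta:  theta_w = S / (a_{n-1} * L)  with
  a_{n-1} = sum_{i=1}^{n-1} 1/i, S the number of segregating sites and L
  the number of columns where every sequence in the subset carries an
  unambiguous base (complete deletion within the subset).
* Nucleotide diversity pi: the mean over all unordered sequence pairs of
  the per-site p-distance (pairwise deletion).

For n = 2 the two estimators coincide exactly.  Intraspecific distances
can additionally be split into within- and between-population classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix, encode_alignment
from .seq_io import BarcodeDataset, MarkerAlignment, SpecimenRecord


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


def _subset_codes(aln: MarkerAlignment, ids: Optional[Sequence[str]] = None) -> np.ndarray:
    use = list(aln.sequences) if ids is None else list(ids)
    _, codes = encode_alignment(aln.subset(use))
    return codes


def segregating_sites(codes: np.ndarray) -> Tuple[int, int]:
    """(S, L): segregating-site count and usable length under complete deletion."""
    complete = (codes >= 0).all(axis=0)
    L = int(complete.sum())
    sub = codes[:, complete]
    S = int((sub != sub[0]).any(axis=0).sum())
    return S, L


def watterson_theta(aln: MarkerAlignment, ids: Optional[Sequence[str]] = None) -> float:
    """Per-site Watterson estimator over the given sequence subset."""
    codes = _subset_codes(aln, ids)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("watterson_theta needs at least 2 sequences")
    S, L = segregating_sites(codes)
    if L == 0:
        raise ValueError("no completely resolved columns in subset (L = 0)")
    return S / (harmonic_number(n - 1) * L)


def nucleotide_pi(aln: MarkerAlignment, ids: Optional[Sequence[str]] = None) -> float:
    """Per-site nucleotide diversity: mean pairwise p-distance (pairwise deletion)."""
    codes = _subset_codes(aln, ids)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("nucleotide_pi needs at least 2 sequences")
    valid = codes >= 0
    dists = []
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        nb = int(both.sum())
        if nb == 0:
            continue
        dists.append(float((codes[i][both] != codes[j][both]).sum() / nb))
    if not dists:
        raise ValueError("no comparable sites in any pair (L = 0)")
    return float(np.mean(dists))


@dataclass
class DiversityRecord:
    species: str
    population_id: str  # "ALL" for the species-wide estimate
    marker: str
    n: int
    L: int
    S: int
    theta_w: float
    pi: float


def diversity_table(
    dataset: BarcodeDataset,
    marker: str,
    min_n: int = 3,
    per_population: bool = True,
) -> pd.DataFrame:
    """Theta/pi per species (and per population) for one marker.

    Species (or populations) with fewer than ``min_n`` sequenced
    individuals are skipped; the study protocol computed diversity only for
    species with more than two individuals.  Hybrids are excluded.
    """
    aln = dataset.alignments[marker]
    meta = {r.specimen_id: r for r in dataset.specimens if r.group != "hybrid"}
    groups: Dict[Tuple[str, str], List[str]] = {}
    for sid in aln.sequences:
        rec = meta.get(sid)
        if rec is None:
            continue
        groups.setdefault((rec.species, "ALL"), []).append(sid)
        if per_population:
            groups.setdefault((rec.species, rec.population_id), []).append(sid)

    rows = []
    for (sp, pop), ids in sorted(groups.items()):
        if len(ids) < max(2, min_n):
            continue
        codes = _subset_codes(aln, ids)
        S, L = segregating_sites(codes)
        if L == 0:
            continue
        rows.append(
            DiversityRecord(
                species=sp,
                population_id=pop,
                marker=marker,
                n=len(ids),
                L=L,
                S=S,
                theta_w=S / (harmonic_number(len(ids) - 1) * L),
                pi=nucleotide_pi(aln, ids),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def population_distance_partition(
    m: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
) -> pd.DataFrame:
    """Within- vs between-population intraspecific distance pairs.

    Returns a long frame (species, class, id1, id2, distance) where class is
    ``within_pop`` or ``between_pop``; every non-MISSING intraspecific pair
    appears exactly once.  Hybrids are excluded.
    """
    meta = {r.specimen_id: r for r in specimens if r.group != "hybrid"}
    rows = []
    n = len(m.ids)
    for i in range(n):
        ri = meta.get(m.ids[i])
        if ri is None:
            continue
        for j in range(i + 1, n):
            rj = meta.get(m.ids[j])
            if rj is None or ri.species != rj.species:
                continue
            dij = m.d[i, j]
            if np.isnan(dij):
                continue
            rows.append(
                {
                    "species": ri.species,
                    "class": "within_pop" if ri.population_id == rj.population_id else "between_pop",
                    "id1": m.ids[i],
                    "id2": m.ids[j],
                    "distance": float(dij),
                }
            )
    return pd.DataFrame(rows, columns=["species", "class", "id1", "id2", "distance"])


def partition_summary(partition: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean/max distance for each population class."""
    if partition.empty:
        return pd.DataFrame(columns=["species", "class", "n_pairs", "mean", "max"])
    finite = partition[np.isfinite(partition["distance"])]
    out = (
        finite.groupby(["species", "class"])["distance"]
        .agg(n_pairs="size", mean="mean", max="max")
        .reset_index()
    )
    return out
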