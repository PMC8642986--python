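"""Marker-versus-marker divergence comparison by Wilcoxon signed-rank test.

The pairing unit is the species pair: for each unordered pair of species
sharing sequences in both markers, the summary divergence is the mean of
all interspecific sequence-pair K2P distances between the two species.
The signed-rank statistic uses midranks for tied absolute differences;
p-values come from exact sign enumeration for small N and from the normal
approximation with continuity and tie corrections otherwise.

The common-language effect size is W- / (W- + W+): 0 when the "after"
marker's divergences dominate, 1 when the "before" marker's do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .distmat import DistanceMatrix
from .seq_io import SpecimenRecord

#: Largest N for which the exact null distribution is enumerated (2^N terms).
EXACT_N_MAX = 25


def species_pair_divergence(
    m: DistanceMatrix,
    specimens: Sequence[SpecimenRecord],
) -> Dict[Tuple[str, str], float]:
    """Mean interspecific distance for every species pair with finite data."""
    species = {r.specimen_id: r.species for r in specimens if r.group != "hybrid"}
    sp_of = [species.get(i) for i in m.ids]
    by_pair: Dict[Tuple[str, str], List[float]] = {}
    n = len(m.ids)
    for i in range(n):
        if sp_of[i] is None:
            continue
        for j in range(i + 1, n):
            if sp_of[j] is None or sp_of[i] == sp_of[j]:
                continue
            dij = m.d[i, j]
            if not np.isfinite(dij):
                continue
            key = tuple(sorted((sp_of[i], sp_of[j])))
            by_pair.setdefault(key, []).append(float(dij))
    return {k: float(np.mean(v)) for k, v in sorted(by_pair.items())}


@dataclass
class MarkerComparison:
    marker_before: str
    marker_after: str
    n: int
    w_minus: float
    w_plus: float
    p_value: float
    cl_effect: float
    verdict: str  # "before>>after", "after>>before" or "ns"


def _exact_p(abs_ranks: np.ndarray, w_small: float) -> float:
    """Two-sided exact p: enumerate all 2^N sign assignments of the ranks."""
    n = len(abs_ranks)
    # Distribution of W+ over all sign vectors, built by convolution over
    # the (possibly tied, hence non-integer midrank) rank values.
    totals = {0.0: 1}
    for r in abs_ranks:
        new: Dict[float, int] = {}
        for w, c in totals.items():
            new[w] = new.get(w, 0) + c
            new[w + r] = new.get(w + r, 0) + c
        totals = new
    total = 2**n
    # Two-sided: P(W <= w_small) doubled, capped at 1, where w_small is
    # min(W+, W-); symmetric null makes this exact.
    p_le = sum(c for w, c in totals.items() if w <= w_small + 1e-9) / total
    return min(1.0, 2.0 * p_le)


def _approx_p(abs_ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(abs_ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # Tie correction: subtract sum(t^3 - t)/48 over tied groups.
    _, counts = np.unique(abs_ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return float(2.0 * norm.sf(max(z, 0.0)))


def wilcoxon_signed_rank(
    before: Sequence[float],
    after: Sequence[float],
    marker_before: str = "before",
    marker_after: str = "after",
    alpha: float = 0.05,
) -> MarkerComparison:
    """Paired signed-rank comparison of divergences between two markers.

    Zero differences are dropped before ranking.  Raises if no nonzero
    differences remain.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after must be paired (equal length)")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero paired differences (N = 0)")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_p(ranks, min(w_plus, w_minus))
    else:
        p = _approx_p(ranks, w_plus)
    cl = w_minus / (w_minus + w_plus)
    if p < alpha:
        verdict = f"{marker_before}>>{marker_after}" if w_minus > w_plus else f"{marker_after}>>{marker_before}"
    else:
        verdict = "ns"
    return MarkerComparison(
        marker_before=marker_before,
        marker_after=marker_after,
        n=n,
        w_minus=w_minus,
        w_plus=w_plus,
        p_value=p,
        cl_effect=cl,
        verdict=verdict,
    )


def compare_markers(
    matrices: Dict[str, DistanceMatrix],
    specimens: Sequence[SpecimenRecord],
    pairs: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """Run the signed-rank comparison for each (before, after) marker pair.

    Pairing is restricted to species pairs represented in both markers.
    """
    divergences = {
        mk: species_pair_divergence(m, specimens) for mk, m in matrices.items()
    }
    rows = []
    for before_mk, after_mk in pairs:
        db, da = divergences[before_mk], divergences[after_mk]
        shared = sorted(set(db) & set(da))
        cmp_res = wilcoxon_signed_rank(
            [db[k] for k in shared],
            [da[k] for k in shared],
            marker_before=before_mk,
            marker_after=after_mk,
        )
        rows.append(cmp_res.__dict__)
    return pd.DataFrame(rows)
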