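"""Multi-marker barcode construction by end-to-end concatenation.

With four markers the exhaustive enumeration yields 15 candidate barcodes:
the 4 single markers, 6 pairs, 4 triples and the full quadruple.  Marker
abbreviations follow the field convention I (ITS2), R (rbcL), M (matK),
T (trnH-psbA); combination names are abbreviation-joined, e.g. ``I+R+T``.

Concatenation is complete-case: a specimen missing any constituent marker
is dropped (gap-padding would silently mix pairwise-deletion semantics
across markers).  Pass ``pad_missing=True`` to keep such specimens with
all-gap blocks for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

from .seq_io import BarcodeDataset, MarkerAlignment

logger = logging.getLogger(__name__)

#: Canonical single-letter abbreviations for the study's markers.
ABBREV = {"ITS2": "I", "rbcL": "R", "matK": "M", "trnH-psbA": "T"}

#: Canonical ordering of abbreviations within a combination name.
CANONICAL_ORDER = ["I", "R", "M", "T"]


def _abbrev(marker: str) -> str:
    return ABBREV.get(marker, marker)


@dataclass(frozen=True)
class BarcodeSpec:
    """A named ordered subset of the available markers."""

    name: str
    markers: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("BarcodeSpec needs at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate markers in {self.markers}")


def spec_for(markers: Sequence[str]) -> BarcodeSpec:
    """Canonically ordered and named spec for a marker subset."""

    def sort_key(mk: str):
        ab = _abbrev(mk)
        return (CANONICAL_ORDER.index(ab) if ab in CANONICAL_ORDER else len(CANONICAL_ORDER), ab)

    ordered = tuple(sorted(markers, key=sort_key))
    name = "+".join(_abbrev(mk) for mk in ordered)
    return BarcodeSpec(name=name, markers=ordered)


def enumerate_barcodes(markers: Sequence[str]) -> List[BarcodeSpec]:
    """All non-empty marker subsets, singles first, then growing sizes."""
    if not markers:
        raise ValueError("need at least one marker")
    specs = []
    for k in range(1, len(markers) + 1):
        for combo in combinations(markers, k):
            specs.append(spec_for(combo))
    return specs


def concatenate(
    dataset: BarcodeDataset,
    spec: BarcodeSpec,
    pad_missing: bool = False,
) -> MarkerAlignment:
    """Join per-marker sequences of each specimen end-to-end in spec order.

    Returns an alignment named after the spec whose length is the sum of the
    constituent alignment lengths.  Single-marker specs return a copy of the
    original alignment.
    """
    alns = []
    for mk in spec.markers:
        if mk not in dataset.alignments:
            raise KeyError(f"marker {mk!r} not in dataset (have {dataset.markers})")
        alns.append(dataset.alignments[mk])

    if len(alns) == 1:
        return MarkerAlignment(spec.name, dict(alns[0].sequences))

    all_ids = [r.specimen_id for r in dataset.specimens]
    if pad_missing:
        keep = [i for i in all_ids if any(i in a.sequences for a in alns)]
    else:
        keep = [i for i in all_ids if all(i in a.sequences for a in alns)]
        dropped = [
            i for i in all_ids if any(i in a.sequences for a in alns) and i not in keep
        ]
        for sid in dropped:
            missing = [a.marker for a in alns if sid not in a.sequences]
            logger.info("concatenate %s: dropping %s (missing %s)", spec.name, sid, missing)
    if not keep:
        raise ValueError(f"no specimen has all markers of {spec.name}")

    seqs = {}
    for sid in keep:
        parts = [
            a.sequences.get(sid, "-" * a.length) for a in alns
        ]
        seqs[sid] = "".join(parts)
    return MarkerAlignment(spec.name, seqs)


def block_coordinates(spec: BarcodeSpec, dataset: BarcodeDataset) -> List[Dict]:
    """1-based inclusive column ranges of each marker block in the concatenate."""
    rows, start = [], 1
    for mk in spec.markers:
        L = dataset.alignments[mk].length
        rows.append({"marker": mk, "start": start, "end": start + L - 1})
        start += L
    return rows
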