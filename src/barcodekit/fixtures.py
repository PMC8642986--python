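"""Small hand-checked datasets with frozen expected verdicts.

Every fixture was constructed so its verdicts can be enumerated by hand
from the distance definitions (all mutations below are transitions unless
stated, so K2P distance is monotone in the mutation count and equal counts
give exact ties).  The expectations frozen here are those hand
enumerations; tests compare pipeline output against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .seq_io import BarcodeDataset, MarkerAlignment, SpecimenRecord

_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _mut(seq: str, positions: Sequence[int], kind: str = "ts") -> str:
    table = _TS if kind == "ts" else _TV
    chars = list(seq)
    for p in positions:
        chars[p] = table[chars[p]]
    return "".join(chars)


def _gap(seq: str, start: int, end: int) -> str:
    return seq[:start] + "-" * (end - start) + seq[end:]


def _dataset(
    marker_seqs: Dict[str, Dict[str, str]],
    species_of: Dict[str, str],
    groups: Dict[str, str] | None = None,
    sites: Dict[str, str] | None = None,
) -> BarcodeDataset:
    groups = groups or {}
    sites = sites or {}
    all_ids: List[str] = []
    for seqs in marker_seqs.values():
        for sid in seqs:
            if sid not in all_ids:
                all_ids.append(sid)
    specimens = [
        SpecimenRecord(
            specimen_id=sid,
            species=species_of[sid],
            group=groups.get(sid, "true_mangrove"),
            site_id=sites.get(sid, "S01"),
        )
        for sid in all_ids
    ]
    alignments = {mk: MarkerAlignment(mk, seqs) for mk, seqs in marker_seqs.items()}
    return BarcodeDataset(specimens=specimens, alignments=alignments)


@dataclass
class Fixture:
    name: str
    dataset: BarcodeDataset
    expected: Dict


def _perfect_gap() -> Fixture:
    base = "ACGT" * 15
    seqs_by_species = {
        "SpA": base,
        "SpB": _mut(base, range(0, 12)),
        "SpC": _mut(base, range(12, 24)),
    }
    seqs = {}
    species_of = {}
    for sp, s in seqs_by_species.items():
        for i in range(1, 4):
            sid = f"{sp.lower()}{i}"
            seqs[sid] = s
            species_of[sid] = sp
    return Fixture(
        name="perfect_gap",
        dataset=_dataset({"mk": seqs}, species_of),
        expected={"gap_pct": 100.0, "bm_success_pct": 100.0, "monophyly_pct": 100.0},
    )


def _gap_failure() -> Fixture:
    # Species SpA spans a larger intraspecific distance (6 substitutions)
    # than its distance to SpB (2), so SpA has no gap; SpB and SpC do.
    base = "ACGT" * 15
    seqs = {
        "a1": base,
        "a2": _mut(base, range(0, 6)),
        "b1": _mut(base, [0, 1]),
        "b2": _mut(base, [0, 1]),
        "c1": _mut(base, range(24, 36)),
        "c2": _mut(base, range(24, 36)),
    }
    species_of = {s: f"Sp{s[0].upper()}" for s in seqs}
    return Fixture(
        name="gap_failure",
        dataset=_dataset({"mk": seqs}, species_of),
        expected={
            "gap_pct": 66.7,
            "no_gap_species": "SpA",
            "gap_species": ["SpB", "SpC"],
        },
    )


def _bm_ties() -> Fixture:
    # Exact distance ties are equal transition counts over a gap-free
    # alignment.  Hand-enumerated nearest neighbours give the verdicts
    # below; with a fixed BCM threshold of 0.2, queries whose best match
    # exceeds it become unidentified.
    base = "ACGT" * 10
    seqs = {
        "a1": base,
        "a2": _mut(base, [0, 1]),
        "b1": _mut(base, [2, 3]),
        "b2": _mut(base, range(10, 18)),
        "c1": _mut(base, [4, 5]),
        "c2": _mut(base, [4, 5, 6]),
        "d1": _mut(_mut(base, range(16, 22)), range(22, 28), "tv"),
        "d2": _mut(_mut(base, range(28, 34)), range(34, 40), "tv"),
    }
    species_of = {s: f"Sp{s[0].upper()}" for s in seqs}
    return Fixture(
        name="bm_ties",
        dataset=_dataset({"mk": seqs}, species_of),
        expected={
            "bm_verdicts": {
                "a1": "ambiguous",
                "a2": "success",
                "b1": "incorrect",
                "b2": "incorrect",
                "c1": "success",
                "c2": "success",
                "d1": "incorrect",
                "d2": "incorrect",
            },
            "bcm_threshold": 0.2,
            "bcm_verdicts": {
                "a1": "ambiguous",
                "a2": "success",
                "b1": "incorrect",
                "b2": "unidentified",
                "c1": "success",
                "c2": "success",
                "d1": "unidentified",
                "d2": "unidentified",
            },
        },
    )


def _paraphyly() -> Fixture:
    # a1/b1 share ten substitutions and a2/b2 share ten others, so the NJ
    # tree pairs heterospecific individuals: SpA and SpB are paraphyletic.
    base = "ACGT" * 15
    seqs = {
        "a1": _mut(base, list(range(0, 10)) + [20]),
        "b1": _mut(base, list(range(0, 10)) + [21]),
        "a2": _mut(base, list(range(10, 20)) + [22]),
        "b2": _mut(base, list(range(10, 20)) + [23]),
        "c1": _mut(base, range(30, 45)),
        "c2": _mut(base, list(range(30, 45)) + [45]),
    }
    species_of = {s: f"Sp{s[0].upper()}" for s in seqs}
    return Fixture(
        name="paraphyly",
        dataset=_dataset({"mk": seqs}, species_of),
        expected={
            "monophyly_pct": 33.3,
            "monophyletic": ["SpC"],
            "non_monophyletic": ["SpA", "SpB"],
        },
    )


def _hybrid_trio() -> Fixture:
    nuc_base = "ACGT" * 15
    cp_base = "GTCA" * 15
    nuc = {"SpX": nuc_base, "SpY": _mut(nuc_base, range(0, 10)), "SpZ": _mut(nuc_base, range(20, 36))}
    cp = {"SpX": cp_base, "SpY": _mut(cp_base, range(0, 8)), "SpZ": _mut(cp_base, range(20, 32))}
    # F1 of SpX (mother) x SpY: IUPAC ambiguity at the ten diagnostic
    # columns, maternal chloroplast.
    from .seq_io import PAIR_TO_CODE

    hyb_nuc = list(nuc["SpX"])
    for col in range(0, 10):
        hyb_nuc[col] = PAIR_TO_CODE[frozenset((nuc["SpX"][col], nuc["SpY"][col]))]
    nuc_seqs, cp_seqs, species_of, groups = {}, {}, {}, {}
    for sp in ("SpX", "SpY", "SpZ"):
        for i in (1, 2):
            sid = f"{sp[2].lower()}{i}"
            nuc_seqs[sid] = nuc[sp]
            cp_seqs[sid] = cp[sp]
            species_of[sid] = sp
    nuc_seqs["h1"] = "".join(hyb_nuc)
    cp_seqs["h1"] = cp["SpX"]
    species_of["h1"] = "SpX_x_SpY"
    groups["h1"] = "hybrid"
    return Fixture(
        name="hybrid_trio",
        dataset=_dataset({"nuc": nuc_seqs, "cp": cp_seqs}, species_of, groups=groups),
        expected={
            "hybrid_id": "h1",
            "parent_pair": ("SpX", "SpY"),
            "n_diagnostic": 10,
            "n_heterozygous": 10,
            "mother": "SpX",
            "non_hybrid_example": "z1",
        },
    )


def _subspecies() -> Fixture:
    base = "ACGTC" * 10
    g1 = base
    g2 = _mut(_mut(base, [5]), [9], "tv")
    g3 = _gap(_mut(base, [14]), 30, 33)
    seqs = {"g1a": g1, "g1b": g1, "g2a": g2, "g2b": g2, "g3a": g3, "g3b": g3}
    species_of = {s: "SpM" for s in seqs}
    sites = {s: f"P{s[1]}" for s in seqs}  # one population per subspecies
    return Fixture(
        name="subspecies",
        dataset=_dataset({"mk": seqs}, species_of, sites=sites),
        expected={
            "n_haplotypes": 3,
            "n_snv": 3,
            "n_indel": 1,
            "haplotype_groups": [["g1a", "g1b"], ["g2a", "g2b"], ["g3a", "g3b"]],
        },
    )


def _missing_markers() -> Fixture:
    b1 = "ACGT" * 5
    b2 = "TGCA" * 7 + "AC"
    m1 = {"s1": b1, "s2": _mut(b1, [0]), "s3": _mut(b1, range(8, 14))}
    m2 = {"s2": b2, "s3": _mut(b2, range(0, 6)), "s4": _mut(b2, list(range(0, 6)) + [10])}
    species_of = {"s1": "SpA", "s2": "SpA", "s3": "SpB", "s4": "SpB"}
    return Fixture(
        name="missing_markers",
        dataset=_dataset({"m1": m1, "m2": m2}, species_of),
        expected={
            "concat_ids": ["s2", "s3"],
            "concat_length": 20 + 30,
            "pad_ids": ["s1", "s2", "s3", "s4"],
        },
    )


def fixture_suite() -> Dict[str, Fixture]:
    """Deterministic named fixtures covering every pipeline failure mode."""
    fixtures = [
        _perfect_gap(),
        _gap_failure(),
        _bm_ties(),
        _paraphyly(),
        _hybrid_trio(),
        _subspecies(),
        _missing_markers(),
    ]
    return {f.name: f for f in fixtures}
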