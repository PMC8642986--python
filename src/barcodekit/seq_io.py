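"""Data model and I/O for aligned barcode datasets.

A barcode dataset couples a specimen metadata table (one row per collected
individual: species, group, collection site) with one aligned FASTA per
marker.  A specimen may be missing from any alignment (failed PCR or
sequencing), but every sequence must belong to a known specimen.

FASTA headers are written as ``specimen_id|species|site_id``; the ``|``
character is reserved.  The metadata TSV is authoritative — header fields
are convenience annotations only and are ignored on read beyond the
specimen id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Valid specimen group labels.
GROUPS = ("true_mangrove", "associate", "coastal", "hybrid", "introduced")

#: IUPAC nucleotide codes, the alignment gap and the unknown-base symbol.
IUPAC_CODES = set("ACGTRYSWKMBDHVN-")

#: Two-base ambiguity codes mapped to the base pair they encode.
AMBIGUITY_PAIRS: Dict[str, frozenset] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

#: Reverse lookup: unordered base pair -> IUPAC code.
PAIR_TO_CODE = {pair: code for code, pair in AMBIGUITY_PAIRS.items()}


class ValidationError(ValueError):
    """Raised when an input file violates a dataset invariant."""


@dataclass
class SpecimenRecord:
    """One collected individual."""

    specimen_id: str
    species: str
    group: str = "true_mangrove"
    site_id: str = ""
    population_id: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if not self.species:
            raise ValidationError(f"specimen {self.specimen_id!r}: species must be non-empty")
        if self.group not in GROUPS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if self.population_id is None:
            # Sampling sites are the default population unit.
            self.population_id = self.site_id


@dataclass
class MarkerAlignment:
    """Equal-length IUPAC nucleotide sequences for one marker.

    Sequences are stored uppercase; ``N`` is treated downstream as a
    missing observation at that site, not as ambiguity evidence.
    """

    marker: str
    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        upper = {}
        length = None
        for sid, seq in self.sequences.items():
            s = str(seq).upper()
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise ValidationError(
                    f"marker {self.marker!r}: unaligned input — sequence {sid!r} "
                    f"has length {len(s)}, expected {length}"
                )
            bad = set(s) - IUPAC_CODES
            if bad:
                raise ValidationError(
                    f"marker {self.marker!r}: sequence {sid!r} contains "
                    f"non-IUPAC character(s) {sorted(bad)}"
                )
            upper[sid] = s
        self.sequences = upper

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def ids(self) -> List[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, ids: Iterable[str]) -> "MarkerAlignment":
        """Restrict the alignment to the given specimen ids (order preserved)."""
        keep = [i for i in ids if i in self.sequences]
        return MarkerAlignment(self.marker, {i: self.sequences[i] for i in keep})


@dataclass
class BarcodeDataset:
    """Specimen table plus one alignment per sequenced marker."""

    specimens: List[SpecimenRecord]
    alignments: Dict[str, MarkerAlignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.specimens:
            if rec.specimen_id in seen:
                raise ValidationError(f"duplicate specimen_id {rec.specimen_id!r}")
            seen.add(rec.specimen_id)
        for marker, aln in self.alignments.items():
            unknown = set(aln.sequences) - seen
            if unknown:
                raise ValidationError(
                    f"marker {marker!r}: sequences for unknown specimen(s) "
                    f"{sorted(unknown)[:5]} (not in metadata)"
                )

    @property
    def specimen_index(self) -> Dict[str, SpecimenRecord]:
        return {r.specimen_id: r for r in self.specimens}

    def species_of(self, specimen_id: str) -> str:
        return self.specimen_index[specimen_id].species

    @property
    def markers(self) -> List[str]:
        return list(self.alignments)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "specimen_id": r.specimen_id,
                    "species": r.species,
                    "group": r.group,
                    "site_id": r.site_id,
                    "population_id": r.population_id,
                    "latitude": r.latitude,
                    "longitude": r.longitude,
                }
                for r in self.specimens
            ]
        )


def _parse_metadata(metadata_path: Path) -> List[SpecimenRecord]:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"specimen_id", "species", "site_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata {metadata_path}: missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _get(key, default=None):
            v = d.get(key)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return default
            return v

        records.append(
            SpecimenRecord(
                specimen_id=_get("specimen_id", ""),
                species=_get("species", ""),
                group=_get("group", "true_mangrove"),
                site_id=_get("site_id", ""),
                population_id=_get("population_id"),
                latitude=float(_get("latitude")) if _get("latitude") is not None else None,
                longitude=float(_get("longitude")) if _get("longitude") is not None else None,
            )
        )
    return records


def read_fasta_alignment(path: Path, marker: str) -> MarkerAlignment:
    """Read one aligned FASTA file; header text before the first ``|`` is the id."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id.split("|")[0]
        if sid in seqs:
            raise ValidationError(f"{path}: duplicate specimen_id {sid!r}")
        seqs[sid] = str(rec.seq)
    if not seqs:
        raise ValidationError(f"{path}: no FASTA records")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValidationError(
            f"{path}: unaligned input — record lengths {sorted(lengths)} differ"
        )
    return MarkerAlignment(marker, seqs)


def read_dataset(fasta_paths: Mapping[str, Path], metadata_path: Path) -> BarcodeDataset:
    """Load and validate a dataset from per-marker FASTA files plus metadata TSV.

    Specimens present in the metadata but absent from an alignment are
    retained as sequence-missing; sequences without a metadata row raise.
    """
    specimens = _parse_metadata(Path(metadata_path))
    alignments = {
        marker: read_fasta_alignment(Path(p), marker) for marker, p in fasta_paths.items()
    }
    return BarcodeDataset(specimens=specimens, alignments=alignments)


def write_dataset(dataset: BarcodeDataset, out_dir: Path) -> Dict[str, Path]:
    """Write one FASTA per marker plus the metadata TSV; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    meta_path = out_dir / "specimens.tsv"
    dataset.metadata_frame().to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path

    if not dataset.alignments:
        logger.warning("dataset has no alignments; writing metadata only")
    index = dataset.specimen_index
    for marker, aln in dataset.alignments.items():
        records = []
        for sid, seq in aln.sequences.items():
            rec = index[sid]
            header = f"{sid}|{rec.species}|{rec.site_id}"
            records.append(SeqRecord(Seq(seq), id=header, description=""))
        fasta_path = out_dir / f"{marker}.fasta"
        SeqIO.write(records, str(fasta_path), "fasta")
        paths[marker] = fasta_path
    return paths
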