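"""Sequence and metadata input plus barcode quality control.

Reads COI barcode sequences (FASTA) and specimen metadata tables, and
applies the quality filters used for barcode libraries: minimum length,
maximum fraction of ambiguous bases, and absence of internal stop codons
under the invertebrate mitochondrial genetic code. Also provides the
length-eligibility gates that OTU-delimitation algorithms apply before
clustering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")
_IUPAC_RE = re.compile(r"^[ACGTRYSWKMBDHVN-]+$")

#: reason codes used in QC reports, in the order they are checked
TOO_SHORT = "TOO_SHORT"
AMBIGUITY_EXCESS = "AMBIGUITY_EXCESS"
STOP_CODON = "STOP_CODON"


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains non-IUPAC characters."""


class SchemaError(ValueError):
    """Raised when a metadata table violates its schema."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single barcode sequence.

    ``nucleotides`` is the upper-case IUPAC string as read (it may contain
    ambiguity codes and alignment gaps ``-``); ``length_bp`` counts non-gap
    characters only.
    """

    seq_id: str
    nucleotides: str
    length_bp: int = field(init=False)

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if not _IUPAC_RE.match(nt):
            bad = sorted(set(nt) - IUPAC_DNA)
            raise SequenceValidationError(
                f"sequence {self.seq_id!r} contains non-IUPAC characters: {bad}"
            )
        object.__setattr__(self, "length_bp", len(nt) - nt.count("-"))
        if self.length_bp < 1:
            raise SequenceValidationError(f"sequence {self.seq_id!r} is all gaps")

    @property
    def ungapped(self) -> str:
        return self.nucleotides.replace("-", "")


@dataclass(frozen=True)
class SpecimenMetadata:
    """Collection metadata for one sequenced specimen.

    ``species_label`` may be a binomial or an interim label (e.g.
    ``"Odostomia sp. KL01"``); ``genus`` may be empty for specimens lacking
    a generic identification.
    """

    seq_id: str
    taxon_class: str
    taxon_order: str
    family: str
    genus: str
    species_label: str
    locality: str = ""
    lat: Optional[float] = None
    lon: Optional[float] = None
    known_species_in_genus: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.species_label:
            raise SchemaError(f"specimen {self.seq_id!r} has empty species_label")


@dataclass
class QCReport:
    """Partition of the input into passed and failed sequences."""

    passed: list[str]
    failed: list[tuple[str, str]]  # (seq_id, reason code)

    @property
    def failed_ids(self) -> set[str]:
        return {sid for sid, _ in self.failed}

    def to_frame(self) -> pd.DataFrame:
        rows = [(sid, "PASS", "") for sid in self.passed]
        rows += [(sid, "FAIL", reason) for sid, reason in self.failed]
        return pd.DataFrame(rows, columns=["seq_id", "status", "reason"])


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated sequence records.

    Raises :class:`FastaParseError` for structural problems (e.g. sequence
    data before the first header) and :class:`SequenceValidationError` for
    non-IUPAC characters, naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected FASTA header '>' before sequence data"
                    )
                break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(seq_id=entry.id, nucleotides=str(entry.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.nucleotides), width):
                fh.write(rec.nucleotides[i : i + width] + "\n")


_MANDATORY_COLS = ["seq_id", "class", "order", "family", "genus", "species", "locality"]


def read_specimen_table(path: str | Path, sep: str | None = None) -> list[SpecimenMetadata]:
    """Read a delimited specimen table (TSV or CSV, sniffed by extension).

    Expected header: ``seq_id class order family genus species locality
    [lat lon known_species_in_genus]``. Duplicate seq_ids and empty species
    labels are rejected.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    dupes = df["seq_id"][df["seq_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicate seq_id(s) {sorted(set(dupes))}")
    out = []
    for _, row in df.iterrows():
        ksg = row.get("known_species_in_genus", "")
        out.append(
            SpecimenMetadata(
                seq_id=row["seq_id"],
                taxon_class=row["class"],
                taxon_order=row["order"],
                family=row["family"],
                genus=row["genus"],
                species_label=row["species"],
                locality=row.get("locality", ""),
                lat=float(row["lat"]) if row.get("lat", "") else None,
                lon=float(row["lon"]) if row.get("lon", "") else None,
                known_species_in_genus=int(ksg) if ksg else None,
            )
        )
    return out


def write_specimen_table(meta: Iterable[SpecimenMetadata], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "seq_id": m.seq_id,
                "class": m.taxon_class,
                "order": m.taxon_order,
                "family": m.family,
                "genus": m.genus,
                "species": m.species_label,
                "locality": m.locality,
                "lat": "" if m.lat is None else m.lat,
                "lon": "" if m.lon is None else m.lon,
                "known_species_in_genus": ""
                if m.known_species_in_genus is None
                else m.known_species_in_genus,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _stop_codons(genetic_code: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)


def _internal_stop_count(seq: str, frame: int, stops: frozenset[str]) -> int:
    """Count internal stop codons of ``seq`` read in ``frame``.

    A trailing partial codon is ignored; a stop that is the final complete
    codon counts as internal only when at least one codon follows it, i.e.
    never — so the last complete codon is exempt.
    """
    n_codons = (len(seq) - frame) // 3
    count = 0
    for i in range(n_codons - 1):  # last complete codon exempt
        codon = seq[frame + 3 * i : frame + 3 * i + 3]
        if codon in stops:
            count += 1
    return count


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def detect_reading_frame(
    record: SequenceRecord,
    genetic_code: int = 5,
    both_strands: bool = False,
) -> int | tuple[int, str]:
    """Find the reading frame minimising internal stop codons.

    Returns the frame index (0, 1 or 2); ties break to the lowest frame.
    With ``both_strands`` the reverse complement is also scanned and a
    ``(frame, strand)`` tuple is returned, forward strand winning ties.
    """
    seq = record.ungapped
    if len(seq) < 6:
        raise ValueError(f"{record.seq_id!r}: too short to detect a reading frame")
    stops = _stop_codons(genetic_code)
    candidates: list[tuple[int, int, int, str]] = []  # (n_stops, strand_rank, frame, strand)
    strands = [("+", seq)] + ([("-", reverse_complement(seq))] if both_strands else [])
    for strand_rank, (strand, s) in enumerate(strands):
        for frame in range(3):
            candidates.append((_internal_stop_count(s, frame, stops), strand_rank, frame, strand))
    n_stops, _, frame, strand = min(candidates)
    return (frame, strand) if both_strands else frame


def has_internal_stop(seq: str, frame: int, genetic_code: int = 5) -> bool:
    return _internal_stop_count(seq, frame, _stop_codons(genetic_code)) > 0


def qc_filter(
    records: Sequence[SequenceRecord],
    min_len: int = 220,
    max_ambig_frac: float = 0.01,
    genetic_code: int = 5,
    frame: Optional[int] = None,
) -> QCReport:
    """Apply barcode quality filters to unaligned sequences.

    A record fails (first matching reason wins) when it is shorter than
    ``min_len`` non-gap bases, when its fraction of non-ACGT symbols
    strictly exceeds ``max_ambig_frac``, or when its best reading frame
    still contains an internal stop codon under ``genetic_code``. Gap
    characters are stripped before any check. Ambiguity counting considers
    IUPAC ambiguity codes only, not gaps.
    """
    if not records:
        raise ValueError("qc_filter: empty input")
    passed, failed = [], []
    for rec in records:
        seq = rec.ungapped
        if rec.length_bp < min_len:
            failed.append((rec.seq_id, TOO_SHORT))
            continue
        n_ambig = sum(1 for c in seq if c not in "ACGT")
        if n_ambig / rec.length_bp > max_ambig_frac:
            failed.append((rec.seq_id, AMBIGUITY_EXCESS))
            continue
        f = frame if frame is not None else detect_reading_frame(rec, genetic_code)
        if has_internal_stop(seq, f, genetic_code):
            failed.append((rec.seq_id, STOP_CODON))
            continue
        passed.append(rec.seq_id)
    return QCReport(passed=passed, failed=failed)


def eligibility(length_bp: int, algorithm: str) -> bool:
    """Length gate applied before OTU delimitation.

    ``BIN_LIKE`` algorithms consider only sequences strictly longer than
    500 bp; all others (``OTHER``) require strictly more than 400 bp.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if algorithm == "BIN_LIKE":
        return length_bp > 500
    if algorithm == "OTHER":
        return length_bp > 400
    raise ValueError(f"unknown algorithm class {algorithm!r}")
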