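"""Codon-anchored alignment, indel detection and COI structure mapping.

Sequences are aligned against a stop-free reference by translation-guided
alignment: both sequences are translated under the invertebrate
mitochondrial code, the amino-acid sequences are aligned globally, and
gaps are threaded back onto nucleotides in whole codons. Sequences whose
best reading frame still contains internal stops (putative pseudogenes /
NUMTs) fall back to nucleotide-level alignment, so their gaps may be
frame-shifting.

Indel events are anchored to 1-based codon sites in the reference frame;
an insertion between reference codons k-1 and k is reported at site k,
the site it precedes. Events identical in (kind, site, length) are merged
across sequences with their taxa accumulated, mirroring how shared indels
recur across families at hotspot sites. Events can be mapped onto a
membrane-topology region table of COI (transmembrane helices alternating
with external/internal loops) shipped as an editable packaged resource.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Data import CodonTable

from .io_qc import SequenceRecord, SpecimenMetadata, detect_reading_frame

PUTATIVE_PSEUDOGENE = "PUTATIVE_PSEUDOGENE"


def _codon_table(genetic_code: int = 5) -> dict[str, str]:
    tab = CodonTable.unambiguous_dna_by_id[genetic_code]
    d = dict(tab.forward_table)
    for stop in tab.stop_codons:
        d[stop] = "*"
    return d


def translate(seq: str, genetic_code: int = 5) -> str:
    """Translate complete codons; ambiguous codons become 'X'."""
    table = _codon_table(genetic_code)
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


@dataclass
class _SeqAlignment:
    """Pairwise alignment of one query against the reference.

    ``ref_row[p]`` is the query base aligned to reference nt position p
    ('-' for deletions); ``insertions[p]`` holds query bases inserted
    immediately before reference nt position p (p == len(ref) for
    trailing insertions, which are ignored downstream).
    """

    seq_id: str
    ref_row: list[str]
    insertions: dict[int, str]
    frame_shifted: bool


@dataclass
class CodonAlignment:
    """Reference-anchored multiple alignment with codon coordinates.

    ``columns`` maps every alignment column to ``(codon_site, codon_pos)``
    in the reference frame (1-based codon site, codon position 1-3);
    insertion columns carry the anchor site with codon position 0.
    """

    reference_id: str
    reference_seq: str  # ungapped
    rows: dict[str, str]  # seq_id -> aligned string (incl. reference)
    columns: list[tuple[int, int]]
    pairwise: dict[str, _SeqAlignment] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_codons(self) -> int:
        return len(self.reference_seq) // 3

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in self.rows.items():
                fh.write(f">{sid}\n{row}\n")


@dataclass
class IndelEvent:
    """A codon-anchored insertion or deletion shared by one or more taxa."""

    kind: str  # "insertion" | "deletion"
    codon_site: int  # 1-based codon index of the first affected site
    length_codons: int
    length_nt: int
    taxa: set[tuple[str, str]] = field(default_factory=set)  # (species, family)
    seq_ids: set[str] = field(default_factory=set)
    frame_shifting: bool = False
    region: Optional[str] = None
    near: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.kind, self.codon_site, self.length_codons)


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # shorter barcodes are genuinely truncated: free end gaps
    aligner.end_gap_score = 0.0
    return aligner


def _make_nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1
    aligner.end_gap_score = 0.0
    return aligner


def _protein_guided(
    seq_id: str, ref: str, query: str, frame: int, genetic_code: int,
    aligner: Align.PairwiseAligner,
) -> Optional[_SeqAlignment]:
    """Codon-level alignment threaded through an amino-acid alignment."""
    q = query[frame:]
    q = q[: len(q) - len(q) % 3]
    ref_aa = translate(ref, genetic_code)
    q_aa = translate(q, genetic_code)
    if "*" in q_aa[:-1]:
        return None  # internal stop: not alignable in codon space
    aln = aligner.align(ref_aa, q_aa)[0]
    blocks = aln.aligned  # ((ref blocks), (query blocks)) in AA coordinates
    ref_blocks, q_blocks = blocks
    identity = sum(
        1
        for (rs, re_), (qs, _) in zip(ref_blocks, q_blocks)
        for k in range(re_ - rs)
        if ref_aa[rs + k] == q_aa[qs + k]
    )
    aligned_cols = sum(re_ - rs for rs, re_ in ref_blocks)
    coverage = aligned_cols / min(len(ref_aa), len(q_aa))
    if aligned_cols == 0 or coverage < 0.5 or identity / aligned_cols < 0.5:
        return None
    ref_row = ["-"] * len(ref)
    insertions: dict[int, str] = {}
    prev_r = prev_q = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        rs, re_, qs, qe = int(rs), int(re_), int(qs), int(qe)
        if prev_r is not None and qs > prev_q:
            # query residues unmatched in reference -> insertion before codon rs+1
            ins_nt = q[3 * prev_q : 3 * qs]
            if prev_r == rs:  # anchored between ref codons
                insertions[3 * rs] = insertions.get(3 * rs, "") + ins_nt
            else:  # simultaneous gap (rare); anchor at the later ref codon
                insertions[3 * rs] = insertions.get(3 * rs, "") + ins_nt
        for k in range(re_ - rs):
            ref_row[3 * (rs + k) : 3 * (rs + k) + 3] = list(q[3 * (qs + k) : 3 * (qs + k) + 3])
        prev_r, prev_q = re_, qe
    return _SeqAlignment(seq_id=seq_id, ref_row=ref_row, insertions=insertions, frame_shifted=False)


def _nt_fallback(
    seq_id: str, ref: str, query: str, aligner: Align.PairwiseAligner
) -> _SeqAlignment:
    aln = aligner.align(ref, query)[0]
    ref_blocks, q_blocks = aln.aligned
    ref_row = ["-"] * len(ref)
    insertions: dict[int, str] = {}
    prev_r = prev_q = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        rs, re_, qs, qe = int(rs), int(re_), int(qs), int(qe)
        if prev_r is not None and qs > prev_q:
            insertions[rs] = insertions.get(rs, "") + query[prev_q:qs]
        ref_row[rs:re_] = list(query[qs:qe])
        prev_r, prev_q = re_, qe
    return _SeqAlignment(seq_id=seq_id, ref_row=ref_row, insertions=insertions, frame_shifted=True)


def codon_align(
    records: Sequence[SequenceRecord],
    reference: SequenceRecord,
    genetic_code: int = 5,
) -> CodonAlignment:
    """Align records against a stop-free reference in codon space.

    The reference must be in frame 0 with no internal stop codon. Queries
    with a clean reading frame are aligned through their translations, so
    gaps open in whole codons; queries with internal stops in every frame
    are aligned at the nucleotide level and marked frame-shifted.
    Unalignable queries (below 40% amino-acid identity) are excluded and
    listed on the result.
    """
    ref = reference.ungapped
    ref = ref[: len(ref) - len(ref) % 3]
    ref_aa = translate(ref, genetic_code)
    if "*" in ref_aa[:-1]:
        raise ValueError(f"reference {reference.seq_id!r} has internal stop codons")
    prot_aligner = _make_protein_aligner()
    nt_aligner = _make_nt_aligner()
    pairwise: dict[str, _SeqAlignment] = {}
    excluded: list[tuple[str, str]] = []
    for rec in records:
        if rec.seq_id == reference.seq_id:
            continue
        query = rec.ungapped
        frame = detect_reading_frame(rec, genetic_code)
        sa = _protein_guided(rec.seq_id, ref, query, frame, genetic_code, prot_aligner)
        if sa is None:
            sa = _nt_fallback(rec.seq_id, ref, query, nt_aligner)
            n_aligned = sum(1 for c in sa.ref_row if c != "-")
            ident = sum(1 for p, c in enumerate(sa.ref_row) if c != "-" and c == ref[p])
            coverage = n_aligned / min(len(ref), len(query))
            if n_aligned == 0 or coverage < 0.5 or ident / n_aligned < 0.6:
                excluded.append((rec.seq_id, "unalignable"))
                continue
        pairwise[rec.seq_id] = sa

    # column layout: insertion columns (anchored before ref nt position p),
    # then the reference position itself
    ins_width = {
        p: max(len(sa.insertions.get(p, "")) for sa in pairwise.values())
        for p in range(len(ref) + 1)
    } if pairwise else {}
    columns: list[tuple[int, int]] = []
    rows: dict[str, list[str]] = {reference.seq_id: []}
    for sid in pairwise:
        rows[sid] = []

    def emit_insertion_cols(p: int) -> None:
        width = ins_width.get(p, 0)
        if not width:
            return
        site = p // 3 + 1
        for k in range(width):
            columns.append((site, 0))
            rows[reference.seq_id].append("-")
            for sid, sa in pairwise.items():
                ins = sa.insertions.get(p, "")
                rows[sid].append(ins[k] if k < len(ins) else "-")

    for p, base in enumerate(ref):
        emit_insertion_cols(p)
        columns.append((p // 3 + 1, p % 3 + 1))
        rows[reference.seq_id].append(base)
        for sid, sa in pairwise.items():
            rows[sid].append(sa.ref_row[p])
    emit_insertion_cols(len(ref))

    return CodonAlignment(
        reference_id=reference.seq_id,
        reference_seq=ref,
        rows={sid: "".join(chars) for sid, chars in rows.items()},
        columns=columns,
        pairwise=pairwise,
        excluded=excluded,
    )


def _events_for_sequence(sa: _SeqAlignment, ref_len: int) -> list[IndelEvent]:
    events = []
    # deletions: maximal '-' runs over reference positions, excluding runs
    # touching either end of the aligned region (truncation, not deletion)
    first = next((p for p, c in enumerate(sa.ref_row) if c != "-"), None)
    if first is None:
        return []
    last = max(p for p, c in enumerate(sa.ref_row) if c != "-")
    p = first
    while p <= last:
        if sa.ref_row[p] == "-":
            q = p
            while q <= last and sa.ref_row[q] == "-":
                q += 1
            length_nt = q - p
            events.append(
                IndelEvent(
                    kind="deletion",
                    codon_site=p // 3 + 1,
                    length_codons=max(1, math.ceil(length_nt / 3)),
                    length_nt=length_nt,
                    seq_ids={sa.seq_id},
                    frame_shifting=length_nt % 3 != 0,
                )
            )
            p = q
        else:
            p += 1
    for pos, ins in sorted(sa.insertions.items()):
        if pos <= first or pos > last:  # beyond the aligned span
            continue
        events.append(
            IndelEvent(
                kind="insertion",
                codon_site=pos // 3 + 1,
                length_codons=max(1, math.ceil(len(ins) / 3)),
                length_nt=len(ins),
                seq_ids={sa.seq_id},
                frame_shifting=len(ins) % 3 != 0,
            )
        )
    return events


def detect_indels(
    aln: CodonAlignment,
    meta: Optional[Sequence[SpecimenMetadata]] = None,
    edge_margin_codons: int = 4,
) -> list[IndelEvent]:
    """Convert per-sequence gap runs into merged, codon-anchored events.

    Events sharing (kind, codon site, length) are merged; their ``taxa``
    accumulate the (species, family) pairs of the carrying sequences when
    metadata is supplied. Gap placement in the outermost codons of the
    reference is unreliable (terminal mismatches can be traded against a
    gap), so events overlapping the first or last ``edge_margin_codons``
    codons are suppressed.
    """
    n_codons = len(aln.reference_seq) // 3
    by_id = {m.seq_id: m for m in meta} if meta else {}
    merged: dict[tuple[str, int, int], IndelEvent] = {}
    for sa in aln.pairwise.values():
        for ev in _events_for_sequence(sa, len(aln.reference_seq)):
            last_site = ev.codon_site + (ev.length_codons - 1 if ev.kind == "deletion" else 0)
            if ev.codon_site <= edge_margin_codons or last_site > n_codons - edge_margin_codons:
                continue
            tgt = merged.setdefault(ev.key, ev)
            if tgt is not ev:
                tgt.seq_ids |= ev.seq_ids
            m = by_id.get(sa.seq_id)
            if m is not None:
                tgt.taxa.add((m.species_label, m.family))
    return sorted(merged.values(), key=lambda e: (e.codon_site, e.kind, e.length_codons))


def pseudogene_screen(
    events: Sequence[IndelEvent], aln: CodonAlignment, genetic_code: int = 5
) -> dict[str, list[str]]:
    """Flag sequences with pseudogene signatures.

    A sequence is PUTATIVE_PSEUDOGENE when it carries a frame-shifting
    indel, or when its translation has an internal stop at or downstream
    of its first indel site. In-frame indels alone are not flagged —
    codon-multiple indels are consistent with a functional gene.
    """
    first_indel_site: dict[str, int] = {}
    shifted: set[str] = set()
    for ev in events:
        for sid in ev.seq_ids:
            first_indel_site[sid] = min(first_indel_site.get(sid, ev.codon_site), ev.codon_site)
            if ev.frame_shifting:
                shifted.add(sid)
    flags: dict[str, list[str]] = {}
    for sid, sa in aln.pairwise.items():
        reasons = []
        if sid in shifted:
            reasons.append("frame_shifting_indel")
        query = "".join(c for c in sa.ref_row if c != "-")
        aa = translate(query, genetic_code)
        stop_sites = [i + 1 for i, a in enumerate(aa[:-1]) if a == "*"]
        threshold = first_indel_site.get(sid)
        if threshold is not None and any(s >= threshold for s in stop_sites):
            reasons.append("internal_stop_after_indel")
        if reasons:
            flags[sid] = [PUTATIVE_PSEUDOGENE] + reasons
    return flags


@dataclass
class RegionMap:
    """Ordered codon intervals labelling COI membrane-topology regions."""

    intervals: list[tuple[int, int, str]]  # (start_codon, end_codon, label)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, _ in self.intervals:
            if start != prev_end + 1 or end < start:
                raise ValueError("region intervals must be ascending and contiguous")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def region_of(self, codon_site: int) -> str:
        for start, end, label in self.intervals:
            if start <= codon_site <= end:
                return label
        lo, hi = self.span
        raise ValueError(f"codon site {codon_site} outside region map ({lo}-{hi})")

    def neighbours(self, codon_site: int, margin: int) -> list[str]:
        own = self.region_of(codon_site)
        out = []
        for start, end, label in self.intervals:
            if label == own:
                continue
            if start - margin <= codon_site <= end + margin:
                out.append(label)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            intervals=[
                (int(r.start_codon), int(r.end_codon), str(r.label))
                for r in df.itertuples()
            ]
        )

    @classmethod
    def default(cls) -> "RegionMap":
        """Packaged approximation of COI membrane topology over the
        216-codon barcode: helices alternating with external/internal
        loops, the first external loop spanning codons 31-42."""
        with resources.as_file(
            resources.files("barcodekit.data").joinpath("coi_region_map.tsv")
        ) as p:
            return cls.from_tsv(p)


def map_to_structure(
    events: Sequence[IndelEvent],
    rmap: Optional[RegionMap] = None,
    margin: int = 2,
) -> list[IndelEvent]:
    """Label each event with its structural region (in place and returned).

    Events within ``margin`` codons of a neighbouring region boundary also
    receive ``near:<region>`` tags.
    """
    if rmap is None:
        rmap = RegionMap.default()
    for ev in events:
        ev.region = rmap.region_of(ev.codon_site)
        ev.near = [f"near:{r}" for r in rmap.neighbours(ev.codon_site, margin)]
    return list(events)


def hotspot_summary(events: Sequence[IndelEvent]) -> pd.DataFrame:
    """Per-site event table; a site is a hotspot when events there span
    two or more families. Sorted by family count, descending."""
    rows = []
    for site in sorted({e.codon_site for e in events}):
        at = [e for e in events if e.codon_site == site]
        families = {fam for e in at for _, fam in e.taxa}
        rows.append(
            {
                "codon_site": site,
                "n_events": len(at),
                "n_families": len(families),
                "kinds": ",".join(sorted({e.kind for e in at})),
                "hotspot": len(families) >= 2,
            }
        )
    df = pd.DataFrame(rows, columns=["codon_site", "n_events", "n_families", "kinds", "hotspot"])
    if len(df):
        df = df.sort_values(
            ["n_families", "codon_site"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def events_to_frame(events: Sequence[IndelEvent]) -> pd.DataFrame:
    rows = [
        {
            "kind": e.kind,
            "codon_site": e.codon_site,
            "length_codons": e.length_codons,
            "length_nt": e.length_nt,
            "n_taxa": len(e.taxa),
            "families": ";".join(sorted({f for _, f in e.taxa})),
            "species": ";".join(sorted({s for s, _ in e.taxa})),
            "region": e.region or "",
            "near": ";".join(e.near),
            "frame_shifting": e.frame_shifting,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "codon_site", "length_codons", "length_nt", "n_taxa",
            "families", "species", "region", "near", "frame_shifting",
        ],
    )
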