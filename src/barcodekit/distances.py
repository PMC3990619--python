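"""Kimura two-parameter distances and barcode-gap summaries.

The K2P distance corrects observed transition (P) and transversion (Q)
fractions for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Comparisons use pairwise deletion: any site where either sequence carries
a gap or an ambiguity code is excluded from the overlap. Pairs whose
overlap falls below a configurable fraction of the shorter sequence, or
whose log arguments are non-positive (saturation), are masked undefined
rather than clamped.

Per-species summaries report maximum/mean intraspecific divergence and
the nearest-neighbour (NN) distance — the minimum distance to any
heterospecific individual. A species shows a barcode gap when its NN
distance strictly exceeds its maximum intraspecific divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_qc import SequenceRecord, SpecimenMetadata

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

# base encoding for vectorised comparisons: A0 C1 G2 T3, anything else -1
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseComparison:
    """Observed substitution fractions between two aligned sequences."""

    seq_a: str
    seq_b: str
    overlap_bp: int
    P: float  # transition fraction of overlap
    Q: float  # transversion fraction of overlap


class UndefinedComparisonError(ValueError):
    """Raised when two sequences share no unambiguous overlap."""


class SaturationError(ValueError):
    """Raised when the K2P logarithm arguments are non-positive."""


def count_substitutions(
    a: SequenceRecord, b: SequenceRecord, aligned: bool = True
) -> PairwiseComparison:
    """Count transitions and transversions over the unambiguous overlap.

    Both sequences must be aligned to a common coordinate system (equal
    string lengths, gaps as ``-``). Sites with a gap or ambiguity code in
    either sequence are excluded (pairwise deletion).
    """
    if not aligned:
        raise ValueError("unaligned input: align sequences first (see indels.codon_align)")
    if len(a.nucleotides) != len(b.nucleotides):
        raise ValueError(
            f"aligned lengths differ: {a.seq_id} ({len(a.nucleotides)}) vs "
            f"{b.seq_id} ({len(b.nucleotides)})"
        )
    ea, eb = encode(a.nucleotides), encode(b.nucleotides)
    ok = (ea >= 0) & (eb >= 0)
    overlap = int(ok.sum())
    if overlap == 0:
        raise UndefinedComparisonError(f"{a.seq_id} vs {b.seq_id}: no unambiguous overlap")
    xa, xb = ea[ok], eb[ok]
    diff = xa != xb
    # transitions: A<->G (0,2) and C<->T (1,3) -> same parity
    transitions = int((diff & ((xa % 2) == (xb % 2))).sum())
    transversions = int(diff.sum()) - transitions
    return PairwiseComparison(
        seq_a=a.seq_id,
        seq_b=b.seq_id,
        overlap_bp=overlap,
        P=transitions / overlap,
        Q=transversions / overlap,
    )


def k2p(pc: PairwiseComparison) -> float:
    """Kimura two-parameter distance (as a proportion) from P and Q."""
    w1 = 1.0 - 2.0 * pc.P - pc.Q
    w2 = 1.0 - 2.0 * pc.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"{pc.seq_a} vs {pc.seq_b}: saturated (P={pc.P:.4f}, Q={pc.Q:.4f})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P matrix with a mask for undefined cells.

    Distances are stored as proportions; report layers convert to percent.
    ``defined[i, j]`` is False where the pair had insufficient overlap or
    was saturated.
    """

    ids: list[str]
    d: np.ndarray  # (n, n) float, NaN where undefined
    defined: np.ndarray  # (n, n) bool
    overlap: np.ndarray  # (n, n) int

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def get(self, a: str, b: str) -> Optional[float]:
        i, j = self.index(a), self.index(b)
        return float(self.d[i, j]) if self.defined[i, j] else None

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep_ids]
        ix = np.ix_(idx, idx)
        return DistanceMatrix(
            ids=list(keep_ids),
            d=self.d[ix].copy(),
            defined=self.defined[ix].copy(),
            overlap=self.overlap[ix].copy(),
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "d": self.d[i, j] if self.defined[i, j] else float("nan"),
                        "overlap": int(self.overlap[i, j]),
                        "defined": bool(self.defined[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "d", "overlap", "defined"])


def distance_matrix(
    records: Sequence[SequenceRecord],
    min_overlap_frac: float = 0.60,
) -> DistanceMatrix:
    """All-pairs K2P distances with a minimum-overlap comparability floor.

    A pair is masked when its unambiguous overlap is below
    ``min_overlap_frac`` times the shorter sequence's non-gap length, or
    when the K2P correction saturates.
    """
    if len(records) < 2:
        raise ValueError("distance_matrix requires at least 2 records")
    n = len(records)
    ids = [r.seq_id for r in records]
    aln_len = len(records[0].nucleotides)
    for r in records:
        if len(r.nucleotides) != aln_len:
            raise ValueError("records must share one aligned coordinate system")
    enc = np.stack([encode(r.nucleotides) for r in records])
    lengths = np.array([r.length_bp for r in records])
    d = np.full((n, n), np.nan)
    defined = np.zeros((n, n), dtype=bool)
    overlap = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(defined, True)
    for i in range(n):
        ei = enc[i]
        oki = ei >= 0
        for j in range(i + 1, n):
            ej = enc[j]
            ok = oki & (ej >= 0)
            ov = int(ok.sum())
            overlap[i, j] = overlap[j, i] = ov
            if ov < min_overlap_frac * min(lengths[i], lengths[j]) or ov == 0:
                continue
            xa, xb = ei[ok], ej[ok]
            diff = xa != xb
            ts = int((diff & ((xa % 2) == (xb % 2))).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / ov, tv / ov
            w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if w1 <= 0 or w2 <= 0:
                continue  # saturated -> masked
            dist = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            d[i, j] = d[j, i] = dist
            defined[i, j] = defined[j, i] = True
    return DistanceMatrix(ids=ids, d=d, defined=defined, overlap=overlap)


@dataclass
class SpeciesSummary:
    """Per-species divergence summary (all distances in % K2P)."""

    species_label: str
    n: int
    max_intra: Optional[float]  # None for singletons / all-masked
    mean_intra: Optional[float]
    nn_distance: Optional[float]
    nn_species: Optional[str]
    barcode_gap: str  # "present" | "absent" | "not_assessable"


@dataclass
class GenusSummary:
    genus: str
    n_species_sampled: int
    known_species: Optional[int]
    completeness_pct: Optional[float]
    mean_nn_distance: Optional[float]  # % K2P
    mean_gc_pct: Optional[float] = None


def species_summaries(
    m: DistanceMatrix, meta: Sequence[SpecimenMetadata]
) -> list[SpeciesSummary]:
    """Summarise intraspecific divergence and nearest-neighbour distance.

    ``max_intra``/``mean_intra`` are taken over defined conspecific cells
    and are undefined for singletons. ``nn_distance`` is the minimum
    defined distance from any member to any heterospecific individual.
    The barcode gap is "present" iff nn strictly exceeds max_intra.
    """
    by_id = {mm.seq_id: mm for mm in meta}
    missing = [s for s in m.ids if s not in by_id]
    if missing:
        raise ValueError(f"no metadata for ids: {missing[:5]}")
    species_of = np.array([by_id[s].species_label for s in m.ids])
    out = []
    for sp in sorted(set(species_of)):
        members = np.where(species_of == sp)[0]
        others = np.where(species_of != sp)[0]
        n = len(members)
        max_intra = mean_intra = None
        if n >= 2:
            sub = m.d[np.ix_(members, members)]
            okm = m.defined[np.ix_(members, members)]
            iu = np.triu_indices(n, k=1)
            vals = sub[iu][okm[iu]]
            if vals.size:
                max_intra = float(vals.max()) * 100.0
                mean_intra = float(vals.mean()) * 100.0
        nn_distance = nn_species = None
        if len(others):
            cross = m.d[np.ix_(members, others)]
            okc = m.defined[np.ix_(members, others)]
            if okc.any():
                masked = np.where(okc, cross, np.inf)
                flat = int(np.argmin(masked))
                j = flat % len(others)
                nn_distance = float(masked.flat[flat]) * 100.0
                nn_species = str(species_of[others[j]])
        if n == 1 or max_intra is None:
            gap = "not_assessable"
        elif nn_distance is None:
            gap = "not_assessable"
        else:
            gap = "present" if nn_distance > max_intra else "absent"
        out.append(
            SpeciesSummary(
                species_label=sp,
                n=n,
                max_intra=max_intra,
                mean_intra=mean_intra,
                nn_distance=nn_distance,
                nn_species=nn_species,
                barcode_gap=gap,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    """Tabular layout with hyphens in intraspecific columns for singletons."""

    def fmt(x: Optional[float]) -> str:
        return "-" if x is None else f"{x:.2f}"

    rows = [
        {
            "species": s.species_label,
            "n": s.n,
            "max_intra_pct": fmt(s.max_intra),
            "mean_intra_pct": fmt(s.mean_intra),
            "nn_distance_pct": fmt(s.nn_distance),
            "nn_species": s.nn_species or "-",
            "barcode_gap": s.barcode_gap,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def mean_intraspecific_divergence(
    summaries: Sequence[SpeciesSummary], exclude_above_pct: Optional[float] = None
) -> float:
    """Unweighted mean of per-species mean intraspecific divergence (%).

    Species with fewer than two records are excluded. ``exclude_above_pct``
    drops species whose *maximum* intraspecific divergence exceeds the
    given percentage (used to strip putative cryptic complexes).
    """
    vals = [
        s.mean_intra
        for s in summaries
        if s.mean_intra is not None
        and (exclude_above_pct is None or (s.max_intra or 0.0) <= exclude_above_pct)
    ]
    if not vals:
        raise ValueError("no species with >=2 records")
    return float(np.mean(vals))


def genus_summaries(
    summaries: Sequence[SpeciesSummary],
    meta: Sequence[SpecimenMetadata],
    gc_by_species: Optional[dict[str, float]] = None,
) -> list[GenusSummary]:
    """Aggregate species summaries to genus level.

    Mean NN distance is the unweighted mean over member species; sampling
    completeness is 100 * sampled / known when a known-species count is
    supplied. Species without a generic identification are skipped.
    """
    genus_of: dict[str, str] = {}
    known: dict[str, Optional[int]] = {}
    for mm in meta:
        if mm.genus:
            genus_of[mm.species_label] = mm.genus
            if mm.known_species_in_genus is not None:
                known[mm.genus] = mm.known_species_in_genus
    out = []
    for genus in sorted({g for g in genus_of.values()}):
        members = [s for s in summaries if genus_of.get(s.species_label) == genus]
        if not members:
            continue
        nn = [s.nn_distance for s in members if s.nn_distance is not None]
        gcs = (
            [gc_by_species[s.species_label] for s in members if s.species_label in gc_by_species]
            if gc_by_species
            else []
        )
        k = known.get(genus)
        out.append(
            GenusSummary(
                genus=genus,
                n_species_sampled=len(members),
                known_species=k,
                completeness_pct=(100.0 * len(members) / k) if k else None,
                mean_nn_distance=float(np.mean(nn)) if nn else None,
                mean_gc_pct=float(np.mean(gcs)) if gcs else None,
            )
        )
    return out


def divergence_time(d_pct: float, rate_pct_per_my: float = 2.0) -> float:
    """Convert a % K2P divergence to million years at a pairwise rate.

    The default 2%/My is interpreted as pairwise sequence divergence per
    million years, so t = d / rate.
    """
    if rate_pct_per_my <= 0:
        raise ValueError("rate must be positive")
    if d_pct < 0:
        raise ValueError("distance must be non-negative")
    return d_pct / rate_pct_per_my
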