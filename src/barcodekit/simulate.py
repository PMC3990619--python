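"""Synthetic COI-like datasets with known ground truth.

The generator emulates the structure of a marine-invertebrate barcode
library: many species with low intraspecific divergence (well under 1%),
much higher divergence between species, a minority of species carrying a
deep (>2%) intraspecific split partitioned by coast, in-frame codon
indels planted at fixed alignment sites, and a fraction of sequences that
fail quality control (too short, too ambiguous, or pseudogene-like).

Sequences evolve under a discrete two-parameter substitution process: at
pairwise distance d with transition/transversion rate ratio kappa, each
site independently experiences a transition with probability P(d) and a
transversion with probability Q(d), the closed-form two-parameter
transition probabilities, so the K2P estimator is unbiased for d. A
single stop-free ancestor with the target GC content roots the dataset;
species roots evolve from it, which keeps interspecific distances inside
a configured range. Codons that would become stop codons revert to their
ancestral state, and codons inside planted-indel neighbourhoods are held
fixed so that every indel is recoverable at its exact planted site.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_qc import SequenceRecord, SpecimenMetadata, qc_filter, write_fasta, write_specimen_table
from .indels import translate

_BASES = "ACGT"
_STOPS = {"TAA", "TAG"}  # invertebrate mitochondrial code
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV1 = np.array([1, 0, 1, 0])
_TV2 = np.array([3, 2, 3, 2])

_LOCALITIES = [
    "Churchill", "Vancouver Island", "Bay of Fundy",
    "Beaufort Sea", "St. Lawrence Estuary",
]
_CLASSES = ["Gastropoda", "Bivalvia", "Polyplacophora", "Scaphopoda", "Cephalopoda"]


@dataclass(frozen=True)
class PlantedIndel:
    codon_site: int  # 1-based, in ancestor coordinates
    length_codons: int
    kind: str  # "insertion" | "deletion"
    species_index: int  # 0-based index into the species list


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_species: int = 20
    specimens_mean: int = 8  # mean for non-singleton species (min 2)
    singleton_fraction: float = 0.35
    intra_scale: float = 0.005  # expected conspecific pairwise K2P
    inter_range: tuple[float, float] = (0.08, 0.16)
    n_deep_split: int = 0
    deep_split_depth: float = 0.06
    kappa: float = 3.0
    gc_target: float = 0.37
    planted_indels: tuple[PlantedIndel, ...] = ()
    qc_short_frac: float = 0.0
    qc_ambig_frac: float = 0.0
    qc_pseudo_frac: float = 0.0
    barcode_len: int = 648
    seed: int = 0

    def validate(self) -> None:
        if self.barcode_len % 3:
            raise ValueError("barcode_len must be divisible by 3")
        if self.inter_range[0] <= 2 * self.intra_scale:
            raise ValueError("inter range overlaps intraspecific scale")
        if self.n_deep_split > self.n_species:
            raise ValueError("more deep-split species than species")
        if not self.deep_split_depth > 2 * self.intra_scale:
            raise ValueError("deep-split depth must exceed twice the intra scale")
        for frac in (self.singleton_fraction, self.qc_short_frac,
                     self.qc_ambig_frac, self.qc_pseudo_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for pi in self.planted_indels:
            if not 2 <= pi.codon_site <= self.barcode_len // 3 - pi.length_codons:
                raise ValueError(f"indel site {pi.codon_site} too close to an end")
            if pi.species_index >= self.n_species:
                raise ValueError("indel species_index out of range")


@dataclass
class TruthManifest:
    """Ground truth emitted alongside a simulated dataset."""

    species_of: dict[str, str]  # seq_id -> species label (QC-clean sequences)
    n_species: int
    n_otus_expected: int  # species + one extra per deep split
    deep_split_species: list[str]
    realized_max_intra: dict[str, float]  # % K2P-scale proportions *100
    planted_indels: list[dict]
    qc_failures: list[dict]  # {seq_id, kind}
    ancestor_seq: str
    config_hash: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    records: list[SequenceRecord]
    meta: list[SpecimenMetadata]
    manifest: TruthManifest


def k2p_event_probs(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition (P) and transversion (Q) fractions at distance d.

    Rates are scaled so the expected number of substitutions per site is
    d; with alpha/beta = kappa, beta = 1/(kappa+2):
        Q = 1/2 (1 - e^{-4 beta d})
        P = 1/4 + 1/4 e^{-4 beta d} - 1/2 e^{-2(alpha+beta) d}
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    Q = 0.5 * (1.0 - e1)
    P = 0.25 + 0.25 * e1 - 0.5 * e2
    return P, Q


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence must be unambiguous ACGT")
    return arr


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def draw_root_sequence(gc_target: float, n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free coding sequence whose GC fraction is exactly the
    target (to the nearest base).

    A base multiset with round(gc * L) G+C is shuffled; stop codons
    (TAA/TAG) are repaired by composition-preserving swaps, so neither
    the stop constraint nor sampling noise biases the composition.
    """
    L = 3 * n_codons
    n_gc = int(round(gc_target * L))
    n_at = L - n_gc
    chars = np.array(
        list("G" * (n_gc - n_gc // 2) + "C" * (n_gc // 2)
             + "A" * (n_at - n_at // 2) + "T" * (n_at // 2))
    )

    def stop_indices(s: list[str]) -> list[int]:
        return [
            ci for ci in range(n_codons) if "".join(s[3 * ci : 3 * ci + 3]) in _STOPS
        ]

    for _ in range(100):
        rng.shuffle(chars)
        s = list(chars)
        for _repair in range(10 * n_codons):
            stops = stop_indices(s)
            if not stops:
                return "".join(s)
            ci = stops[0]
            k = 3 * ci + int(rng.integers(0, 3))
            j = int(rng.integers(0, L))
            if s[j] == s[k]:
                continue
            s[k], s[j] = s[j], s[k]
            if (
                "".join(s[3 * ci : 3 * ci + 3]) in _STOPS
                or "".join(s[3 * (j // 3) : 3 * (j // 3) + 3]) in _STOPS
            ):
                s[k], s[j] = s[j], s[k]  # swap made things no better; undo
        # fell through: reshuffle and try again
    raise RuntimeError("could not draw a stop-free sequence at this composition")


def evolve_sequence(
    seq: str,
    d: float,
    kappa: float,
    rng: np.random.Generator,
    frozen_codons: Optional[set[int]] = None,
    avoid_stops: bool = True,
) -> str:
    """Evolve ``seq`` to expected distance ``d`` under the two-parameter process.

    ``frozen_codons`` (0-based codon indices) are held at their input
    state; derived codons that would be stops revert to the input codon.
    """
    x = _encode(seq)
    P, Q = k2p_event_probs(d, kappa)
    u = rng.random(len(x))
    pick = rng.random(len(x))
    y = x.copy()
    ts = u < P
    tv = (u >= P) & (u < P + Q)
    y[ts] = _TS_PARTNER[x[ts]]
    y[tv] = np.where(pick[tv] < 0.5, _TV1[x[tv]], _TV2[x[tv]])
    if frozen_codons:
        for ci in frozen_codons:
            y[3 * ci : 3 * ci + 3] = x[3 * ci : 3 * ci + 3]
    if avoid_stops:
        for ci in range(len(y) // 3):
            codon = _decode(y[3 * ci : 3 * ci + 3])
            if codon in _STOPS:
                y[3 * ci : 3 * ci + 3] = x[3 * ci : 3 * ci + 3]
    return _decode(y)


def simulate_pair(
    d: float, kappa: float = 3.0, L: int = 648, n_reps: int = 1000, seed: int = 0
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Independent sequence pairs whose expected K2P distance is ``d``.

    Used as the estimator-recovery oracle: the generating process is the
    closed-form two-parameter model, so the K2P estimate is consistent
    for d.
    """
    if d < 0 or L < 100:
        raise ValueError("need d >= 0 and L >= 100")
    P, Q = k2p_event_probs(d, kappa)
    if P + Q >= 0.7:
        raise ValueError(f"d={d} is beyond the saturation bound of the estimator")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_reps):
        anc = _decode(rng.choice(4, size=L))
        der = evolve_sequence(anc, d, kappa, rng, avoid_stops=False)
        pairs.append(
            (SequenceRecord(f"pair{i:04d}_a", anc), SequenceRecord(f"pair{i:04d}_b", der))
        )
    return pairs


def _aa(seq: str, codon_site: int) -> str:
    """Amino acid of the 1-based codon site."""
    return translate(seq[3 * (codon_site - 1) : 3 * codon_site])


def _indel_context_ok(seq: str, site: int, length: int, kind: str, ins_block: str = "") -> bool:
    """Planted indels must be unambiguous under alignment: the affected
    block's amino acids must differ from both flanking amino acids."""
    left = _aa(seq, site - 1)
    if kind == "deletion":
        block = [_aa(seq, site + k) for k in range(length)]
        right = _aa(seq, site + length)
    else:
        block = [translate(ins_block[3 * k : 3 * k + 3]) for k in range(length)]
        right = _aa(seq, site)
    return all(b not in (left, right) and b != "*" for b in block)


def _draw_insertion_block(root: str, site: int, length: int, rng: np.random.Generator) -> str:
    for _ in range(200):
        block = draw_root_sequence(0.4, length, rng)
        if _indel_context_ok(root, site, length, "insertion", block):
            return block
    raise RuntimeError("could not draw an unambiguous insertion block")


def _apply_indel(seq: str, site: int, length: int, kind: str, block: str) -> str:
    p = 3 * (site - 1)
    if kind == "insertion":
        return seq[:p] + block + seq[p:]
    return seq[:p] + seq[p + 3 * length :]


def _taxonomy(n_species: int, rng: np.random.Generator) -> list[dict]:
    """Assign species to genera (1-3 species), families, orders, classes."""
    out = []
    g = f = o = 0
    species_left = n_species
    while species_left > 0:
        genus_size = min(int(rng.integers(1, 4)), species_left)
        genus = f"Genus{g + 1:02d}"
        family = f"Family{g // 2 + 1:02d}"
        order = f"Order{g // 6 + 1:02d}"
        klass = _CLASSES[(g // 6) % len(_CLASSES)]
        known = genus_size + int(rng.integers(0, 4))
        for k in range(genus_size):
            out.append(
                {
                    "genus": genus,
                    "family": family,
                    "order": order,
                    "class": klass,
                    "species": f"{genus} sp{k + 1:02d}",
                    "known_in_genus": known,
                }
            )
        g += 1
        species_left -= genus_size
    return out


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a dataset, its metadata and a ground-truth manifest.

    Fully deterministic for a given config (the manifest records a hash of
    the config).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_codons = cfg.barcode_len // 3
    ancestor = draw_root_sequence(cfg.gc_target, n_codons, rng)
    taxa = _taxonomy(cfg.n_species, rng)

    # deletions must be alignment-unambiguous: redraw the ancestor codons
    # of any deleted block whose amino acids collide with a flank
    deletions = [pi for pi in cfg.planted_indels if pi.kind == "deletion"]
    for _ in range(500):
        bad = [
            pi
            for pi in deletions
            if not _indel_context_ok(ancestor, pi.codon_site, pi.length_codons, "deletion")
        ]
        if not bad:
            break
        pi = bad[0]
        p = 3 * (pi.codon_site - 1)
        ancestor = (
            ancestor[:p]
            + draw_root_sequence(cfg.gc_target, pi.length_codons, rng)
            + ancestor[p + 3 * pi.length_codons :]
        )
    else:
        raise RuntimeError("could not place planted deletions unambiguously")

    # plan indels on ancestor coordinates; freeze block + flanking codons
    indel_plan: dict[int, list[tuple[PlantedIndel, str]]] = {}
    frozen: dict[int, set[int]] = {}
    for pi in cfg.planted_indels:
        block = ""
        if pi.kind == "insertion":
            block = _draw_insertion_block(ancestor, pi.codon_site, pi.length_codons, rng)
        indel_plan.setdefault(pi.species_index, []).append((pi, block))
        # freeze a generous window around the indel so every carrier keeps
        # the ancestral local context and the event anchors unambiguously
        fz = frozen.setdefault(pi.species_index, set())
        lo = max(0, pi.codon_site - 11)
        hi = min(n_codons, pi.codon_site + pi.length_codons + 10)
        fz.update(range(lo, hi))

    records: list[SequenceRecord] = []
    meta: list[SpecimenMetadata] = []
    species_of: dict[str, str] = {}
    realized_max_intra: dict[str, float] = {}
    deep_species: list[str] = []
    indel_registry: list[dict] = []

    n_deep_assigned = 0
    for si, tax in enumerate(taxa):
        label = tax["species"]
        is_deep = n_deep_assigned < cfg.n_deep_split
        if is_deep:
            n_deep_assigned += 1
            deep_species.append(label)
            n_spec = max(4, 2 + int(rng.poisson(max(cfg.specimens_mean - 2, 0))))
        elif rng.random() < cfg.singleton_fraction:
            n_spec = 1
        else:
            n_spec = 2 + int(rng.poisson(max(cfg.specimens_mean - 2, 0)))
        d_root = rng.uniform(cfg.inter_range[0] / 2, cfg.inter_range[1] / 2)
        fz = frozen.get(si, set())
        root = evolve_sequence(ancestor, d_root, cfg.kappa, rng, frozen_codons=fz)
        subroots = [root]
        localities = [rng.choice(_LOCALITIES)]
        if is_deep:
            subroots = [
                evolve_sequence(root, cfg.deep_split_depth / 2, cfg.kappa, rng, frozen_codons=fz)
                for _ in range(2)
            ]
            localities = ["Pacific coast", "Atlantic coast"]
        seqs = []
        for k in range(n_spec):
            lineage = k % len(subroots)
            u = rng.uniform(0.25, 0.75) * cfg.intra_scale
            seq = evolve_sequence(subroots[lineage], u, cfg.kappa, rng, frozen_codons=fz)
            sid = f"SP{si + 1:03d}-{k + 1:02d}"
            seqs.append(seq)
            # apply high-coordinate indels first so earlier sites keep
            # their ancestor coordinates
            for pi, block in sorted(
                indel_plan.get(si, []), key=lambda t: -t[0].codon_site
            ):
                seq = _apply_indel(seq, pi.codon_site, pi.length_codons, pi.kind, block)
            records.append(SequenceRecord(sid, seq))
            species_of[sid] = label
            meta.append(
                SpecimenMetadata(
                    seq_id=sid,
                    taxon_class=tax["class"],
                    taxon_order=tax["order"],
                    family=tax["family"],
                    genus=tax["genus"],
                    species_label=label,
                    locality=str(localities[lineage % len(localities)]),
                    known_species_in_genus=tax["known_in_genus"],
                )
            )
        for pi, block in indel_plan.get(si, []):
            indel_registry.append(
                {
                    "species": label,
                    "codon_site": pi.codon_site,
                    "length_codons": pi.length_codons,
                    "kind": pi.kind,
                    "seq_ids": [f"SP{si + 1:03d}-{k + 1:02d}" for k in range(n_spec)],
                }
            )
        # realized maximum intraspecific p-distance, corrected: report on
        # the K2P scale via the paired counts
        if n_spec >= 2:
            from .distances import PairwiseComparison, k2p  # local to avoid cycle

            dmax = 0.0
            for a in range(n_spec):
                for b in range(a + 1, n_spec):
                    xa, xb = _encode(seqs[a]), _encode(seqs[b])
                    diff = xa != xb
                    ts = int((diff & ((xa % 2) == (xb % 2))).sum())
                    tv = int(diff.sum()) - ts
                    pc = PairwiseComparison("a", "b", len(xa), ts / len(xa), tv / len(xa))
                    dmax = max(dmax, k2p(pc))
            realized_max_intra[label] = 100.0 * dmax

    # QC-failure sequences, appended with registry entries
    qc_failures: list[dict] = []
    n_clean = len(records)
    donor_pool = list(range(n_clean))

    def add_failures(kind: str, frac: float) -> None:
        n_add = int(round(frac * n_clean))
        for j in range(n_add):
            donor_idx = int(rng.choice(donor_pool))
            donor = records[donor_idx]
            sid = f"QF{kind[:2].upper()}{j + 1:03d}"
            seq = donor.nucleotides
            for attempt in range(50):
                if kind == "short":
                    cand = seq[: int(rng.integers(100, 220))]
                elif kind == "ambiguous":
                    n_amb = max(int(math.ceil(0.015 * len(seq))), 2)
                    pos = rng.choice(len(seq), size=n_amb, replace=False)
                    chars = list(seq)
                    for p in pos:
                        chars[p] = "N"
                    cand = "".join(chars)
                else:  # pseudogene: frameshift by a 1-nt deletion
                    p = int(rng.integers(len(seq) // 4, len(seq) // 2))
                    cand = seq[:p] + seq[p + 1 :]
                rec = SequenceRecord(sid, cand)
                if qc_filter([rec]).failed:
                    records.append(rec)
                    dm = next(m for m in meta if m.seq_id == donor.seq_id)
                    meta.append(
                        SpecimenMetadata(
                            seq_id=sid,
                            taxon_class=dm.taxon_class,
                            taxon_order=dm.taxon_order,
                            family=dm.family,
                            genus=dm.genus,
                            species_label=dm.species_label,
                            locality=dm.locality,
                            known_species_in_genus=dm.known_species_in_genus,
                        )
                    )
                    qc_failures.append({"seq_id": sid, "kind": kind})
                    break
            else:
                raise RuntimeError(f"could not construct a {kind} QC failure")

    add_failures("short", cfg.qc_short_frac)
    add_failures("ambiguous", cfg.qc_ambig_frac)
    add_failures("pseudogene", cfg.qc_pseudo_frac)

    cfg_hash = hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]
    manifest = TruthManifest(
        species_of=species_of,
        n_species=cfg.n_species,
        n_otus_expected=cfg.n_species + cfg.n_deep_split,
        deep_split_species=deep_species,
        realized_max_intra=realized_max_intra,
        planted_indels=indel_registry,
        qc_failures=qc_failures,
        ancestor_seq=ancestor,
        config_hash=cfg_hash,
    )
    return SimulatedDataset(records=records, meta=meta, manifest=manifest)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + metadata TSV + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "meta": outdir / "specimens.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.records, paths["fasta"])
    write_specimen_table(ds.meta, paths["meta"])
    ds.manifest.to_json(paths["truth"])
    return paths
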