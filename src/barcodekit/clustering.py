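"""OTU delimitation: fixed-threshold clustering and barcode-gap discovery.

Two delimiters are provided. ``threshold_cluster`` takes the
single-linkage connected components of the graph whose edges are pairs at
distance <= threshold (default 2%), the classic MOTU recipe.
``abgd_partition`` scans a log-spaced grid of prior maximum intraspecific
divergences; for each prior it looks for the first significant gap in the
ranked pairwise distances beyond the prior, splits there, and recurses
within the resulting groups — a barcode-gap discovery scheme in the
spirit of ABGD. Masked (undefined) distance cells are never edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix


@dataclass
class Partition:
    """Assignment of sequences to OTUs."""

    assignment: dict[str, int]
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def n_singletons(self) -> int:
        counts = pd.Series(list(self.assignment.values())).value_counts()
        return int((counts == 1).sum())

    def groups(self) -> list[frozenset[str]]:
        by_otu: dict[int, set[str]] = {}
        for sid, otu in self.assignment.items():
            by_otu.setdefault(otu, set()).add(sid)
        return sorted((frozenset(g) for g in by_otu.values()), key=lambda g: sorted(g)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["seq_id", "otu_id"]
        )


def _components(m: DistanceMatrix, threshold: float) -> dict[str, int]:
    adj = m.defined & (m.d <= threshold)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # renumber components deterministically by first id occurrence
    remap: dict[int, int] = {}
    out = {}
    for sid, lab in zip(m.ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[sid] = remap[lab]
    return out


def threshold_cluster(m: DistanceMatrix, threshold: float = 0.02) -> Partition:
    """Single-linkage OTUs: components of the graph with edges d <= threshold.

    The matrix should already be restricted to length-eligible sequences
    (see :func:`barcodekit.io_qc.eligibility`).
    """
    if m.n == 0:
        raise ValueError("empty eligible set")
    return Partition(
        assignment=_components(m, threshold),
        method="threshold",
        params={"threshold": threshold},
    )


def pairdiff_threshold(threshold_frac: float, barcode_len: int = 648) -> int:
    """Distance threshold expressed as whole base-pair differences.

    A 2% threshold over the 648-bp barcode corresponds to 13 bp.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    return int(round(threshold_frac * barcode_len))


@dataclass
class AbgdResult:
    """One partition per prior, plus the automatically selected scheme."""

    priors: list[float]
    partitions: list[Partition]
    selected_scheme: int  # index into partitions

    @property
    def selected(self) -> Partition:
        return self.partitions[self.selected_scheme]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scheme": range(1, len(self.priors) + 1),
                "prior": self.priors,
                "n_otus": [p.n_otus for p in self.partitions],
                "n_singletons": [p.n_singletons for p in self.partitions],
                "selected": [i == self.selected_scheme for i in range(len(self.priors))],
            }
        )


def _first_gap(dists: np.ndarray, prior: float, rel_gap_x: float) -> Optional[float]:
    """Split threshold at the first significant distance gap beyond the prior.

    Candidate gaps are intervals between consecutive ranked distances whose
    upper end exceeds the prior; a gap is significant when its width
    exceeds ``rel_gap_x`` times the local distance scale max(d_low, prior).
    Returns the gap's lower edge (a valid single-linkage threshold), or
    None when no gap qualifies.
    """
    ds = np.unique(dists)
    for lo, hi in zip(ds[:-1], ds[1:]):
        if hi <= prior:
            continue
        if (hi - lo) > rel_gap_x * max(lo, prior):
            return lo
    return None


def _abgd_split(m: DistanceMatrix, ids: list[str], prior: float, rel_gap_x: float) -> list[list[str]]:
    if len(ids) < 2:
        return [ids]
    sub = m.submatrix(ids)
    iu = np.triu_indices(sub.n, k=1)
    vals = sub.d[iu][sub.defined[iu]]
    if vals.size == 0:
        return [ids]
    thr = _first_gap(vals, prior, rel_gap_x)
    if thr is None:
        return [ids]
    comp = _components(sub, thr)
    groups: dict[int, list[str]] = {}
    for sid in ids:
        groups.setdefault(comp[sid], []).append(sid)
    if len(groups) == 1:
        return [ids]
    out = []
    for g in groups.values():
        out.extend(_abgd_split(m, g, prior, rel_gap_x))
    return out


def abgd_partition(
    m: DistanceMatrix,
    pmin: float = 0.0006,
    pmax: float = 0.17,
    n_steps: int = 10,
    rel_gap_x: float = 1.5,
    scheme: Optional[int] = None,
) -> AbgdResult:
    """Barcode-gap partitions over a log-spaced grid of priors.

    For each prior P the ranked pairwise distances are scanned for the
    first gap beyond P; groups are split at the gap and re-scanned
    recursively. OTU counts are non-increasing in the prior. The selected
    scheme defaults to the most stable plateau (longest run of consecutive
    priors with an equal OTU count), skipping the degenerate all-merged
    tail when an alternative exists and breaking ties toward larger
    priors; pass ``scheme`` (1-based) to override.
    """
    if m.n < 2:
        raise ValueError("abgd_partition requires >=2 sequences")
    if not m.defined[np.triu_indices(m.n, k=1)].any():
        raise ValueError("fully saturated/masked matrix")
    priors = list(np.geomspace(pmin, pmax, n_steps))
    partitions = []
    for p in priors:
        groups = _abgd_split(m, list(m.ids), p, rel_gap_x)
        assignment = {}
        for otu, g in enumerate(sorted(groups, key=lambda g: sorted(g)[0])):
            for sid in g:
                assignment[sid] = otu
        partitions.append(
            Partition(assignment=assignment, method="abgd", params={"prior": p})
        )
    if scheme is not None:
        if not 1 <= scheme <= len(partitions):
            raise ValueError(f"scheme must be in 1..{len(partitions)}")
        selected = scheme - 1
    else:
        counts = [p.n_otus for p in partitions]
        runs = []  # (length, start, count) per constant run
        start = 0
        for i in range(1, len(counts) + 1):
            if i == len(counts) or counts[i] != counts[start]:
                runs.append((i - start, start, counts[start]))
                start = i
        # the all-merged tail is degenerate for multi-species data; skip it
        # when any alternative plateau exists. Ties go to the larger prior
        # (low priors systematically over-split).
        informative = [r for r in runs if r[2] > 1] or runs
        best_len = max(r[0] for r in informative)
        selected = max(r[1] for r in informative if r[0] == best_len)
    return AbgdResult(priors=priors, partitions=partitions, selected_scheme=selected)


@dataclass
class CongruenceReport:
    shared_ids: list[str]
    n_otus_1: int
    n_otus_2: int
    n_singletons_1: int
    n_singletons_2: int
    agreement: float  # pairwise co-membership agreement in [0, 1]


def partition_congruence(p1: Partition, p2: Partition) -> CongruenceReport:
    """Compare two partitions on their shared sequences.

    The agreement index is the fraction of sequence pairs on which the two
    partitions concur (both co-clustered or both separated); it is 1 iff
    the groupings are identical and 0 when they disagree on every pair.
    """
    shared = sorted(set(p1.assignment) & set(p2.assignment))
    if not shared:
        raise ValueError("partitions share no sequence ids")
    a1 = [p1.assignment[s] for s in shared]
    a2 = [p2.assignment[s] for s in shared]
    n = len(shared)
    concordant = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a1[i] == a1[j]) == (a2[i] == a2[j]):
                concordant += 1
    sub1 = Partition({s: p1.assignment[s] for s in shared}, p1.method)
    sub2 = Partition({s: p2.assignment[s] for s in shared}, p2.method)
    return CongruenceReport(
        shared_ids=shared,
        n_otus_1=sub1.n_otus,
        n_otus_2=sub2.n_otus,
        n_singletons_1=sub1.n_singletons,
        n_singletons_2=sub2.n_singletons,
        agreement=concordant / total if total else 1.0,
    )
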