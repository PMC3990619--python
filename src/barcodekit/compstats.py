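"""Nucleotide composition and the statistical battery.

GC content is computed over unambiguous bases only. Species-level
composition pools base counts across conspecific sequences. The tests
cover: a chi-square test of base-frequency homogeneity among species
within a class, the Pearson correlation of mean nearest-neighbour
distance with mean GC content across genera (with a seeded percentile
bootstrap CI), OLS regressions of intraspecific divergence on sample
size, a one-way ANOVA of NN distance across sampling-completeness bins,
and sequencing success rates with an optional chi-square across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import GenusSummary, SpeciesSummary
from .io_qc import SequenceRecord, SpecimenMetadata


@dataclass
class CompositionProfile:
    """Base counts for one unit (sequence, species, genus, ...)."""

    unit_id: str
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def gc_pct(self) -> float:
        if self.total == 0:
            raise ValueError(f"{self.unit_id!r}: no unambiguous bases")
        return 100.0 * (self.g + self.c) / self.total

    @property
    def counts(self) -> list[int]:
        return [self.a, self.c, self.g, self.t]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    effect: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"test": self.name, "statistic": self.statistic, "df": self.df, "p": self.p_value}
        row.update(self.effect)
        return row


def base_counts(record: SequenceRecord) -> CompositionProfile:
    s = record.ungapped
    return CompositionProfile(
        unit_id=record.seq_id, a=s.count("A"), c=s.count("C"), g=s.count("G"), t=s.count("T")
    )


def gc_content(record: SequenceRecord) -> float:
    """GC percentage over unambiguous bases; gaps/ambiguities excluded."""
    return base_counts(record).gc_pct


def species_composition(
    records: Sequence[SequenceRecord], meta: Sequence[SpecimenMetadata]
) -> list[CompositionProfile]:
    """Pooled base counts per species."""
    by_id = {m.seq_id: m for m in meta}
    pooled: dict[str, CompositionProfile] = {}
    for rec in records:
        m = by_id.get(rec.seq_id)
        if m is None:
            continue
        bc = base_counts(rec)
        p = pooled.setdefault(
            m.species_label, CompositionProfile(m.species_label, 0, 0, 0, 0)
        )
        p.a += bc.a
        p.c += bc.c
        p.g += bc.g
        p.t += bc.t
    return [pooled[k] for k in sorted(pooled)]


def composition_homogeneity(profiles: Sequence[CompositionProfile]) -> TestResult:
    """Pearson chi-square of base-frequency homogeneity among species.

    The contingency table is species x {A, C, G, T}; df = (k-1) * 3.
    Expected counts below 5 trigger a warning but the statistic is still
    computed.
    """
    if len(profiles) < 2:
        raise ValueError("need >=2 species")
    table = np.array([p.counts for p in profiles], dtype=float)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("a species has zero base counts")
    if (table == table[0]).all():
        # identical rows: chi2_contingency handles it, but make the
        # degenerate answer explicit
        return TestResult("composition_homogeneity", 0.0, 1.0, df=(len(profiles) - 1) * 3)
    chi2, p, df, expected = stats.chi2_contingency(table)
    if (expected < 5).any():
        warnings.warn("chi-square expected counts < 5; statistic may be unreliable")
    return TestResult("composition_homogeneity", float(chi2), float(p), df=float(df))


def gc_nn_correlation(
    genera: Sequence[GenusSummary],
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> TestResult:
    """Correlation of mean NN distance with mean GC content across genera.

    Pearson r (default) with its t-distribution p-value, plus a seeded
    percentile bootstrap 95% CI over genera.
    """
    pairs = [
        (g.mean_gc_pct, g.mean_nn_distance)
        for g in genera
        if g.mean_gc_pct is not None and g.mean_nn_distance is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >=3 genera with GC and NN values")
    gc = np.array([p[0] for p in pairs])
    nn = np.array([p[1] for p in pairs])
    if np.std(gc) == 0 or np.std(nn) == 0:
        raise ValueError("zero variance in GC or NN values")
    if method == "pearson":
        r, p = stats.pearsonr(gc, nn)
    elif method == "spearman":
        r, p = stats.spearmanr(gc, nn)
    else:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n = len(gc)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.std(gc[idx]) == 0 or np.std(nn[idx]) == 0:
            continue
        if method == "pearson":
            boots.append(stats.pearsonr(gc[idx], nn[idx])[0])
        else:
            boots.append(stats.spearmanr(gc[idx], nn[idx])[0])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return TestResult(
        "gc_nn_correlation",
        float(r),
        float(p),
        df=float(n - 2),
        effect={"r": float(r), "ci_lo": float(lo), "ci_hi": float(hi), "n_genera": n},
    )


def divergence_vs_n_regression(
    summaries: Sequence[SpeciesSummary], response: str = "mean_intra"
) -> TestResult:
    """OLS of intraspecific divergence on specimens sampled per species."""
    if response not in ("max_intra", "mean_intra"):
        raise ValueError("response must be 'max_intra' or 'mean_intra'")
    pts = [
        (s.n, getattr(s, response))
        for s in summaries
        if s.n >= 2 and getattr(s, response) is not None
    ]
    if len(pts) < 3:
        raise ValueError("need >=3 species with >=2 records")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(y, y[0]):
        return TestResult(
            f"{response}_vs_n_regression", 0.0, 1.0, df=float(len(x) - 2),
            effect={"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0},
        )
    res = stats.linregress(x, y)
    return TestResult(
        f"{response}_vs_n_regression",
        float(res.slope / res.stderr) if res.stderr else float("inf"),
        float(res.pvalue),
        df=float(len(x) - 2),
        effect={
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
        },
    )


DEFAULT_COMPLETENESS_BINS = (0, 20, 40, 60, 80, 100)


def nn_vs_completeness_anova(
    genera: Sequence[GenusSummary],
    bins: Sequence[float] = DEFAULT_COMPLETENESS_BINS,
) -> TestResult:
    """One-way ANOVA of mean NN distance across sampling-completeness bins.

    Default bins are 20-percentage-point categories; bins left empty are
    dropped with a warning.
    """
    usable = [
        g for g in genera
        if g.completeness_pct is not None and g.mean_nn_distance is not None
    ]
    edges = list(bins)
    groups: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    for g in usable:
        c = min(max(g.completeness_pct, edges[0]), edges[-1])
        for b in range(len(edges) - 1):
            if edges[b] <= c < edges[b + 1] or (b == len(edges) - 2 and c == edges[-1]):
                groups[b].append(g.mean_nn_distance)
                break
    kept = [g for g in groups if len(g) >= 1]
    if len(kept) < len(groups):
        warnings.warn(f"dropped {len(groups) - len(kept)} empty completeness bin(s)")
    if len(kept) < 2:
        raise ValueError("need >=2 non-empty completeness bins")
    flat = np.concatenate(kept)
    if np.allclose(flat, flat[0]):
        return TestResult("nn_vs_completeness_anova", float("nan"), float("nan"),
                          effect={"degenerate": 1.0})
    f, p = stats.f_oneway(*kept)
    return TestResult(
        "nn_vs_completeness_anova",
        float(f),
        float(p),
        df=float(len(kept) - 1),
        effect={"n_bins": float(len(kept)), "n_genera": float(len(flat))},
    )


def success_rate(
    n_sequences: int,
    n_specimens: int,
    by_class: Optional[dict[str, tuple[int, int]]] = None,
) -> tuple[float, Optional[TestResult]]:
    """Sequencing success as a percentage (1 decimal).

    ``by_class`` maps class name -> (n_sequences, n_specimens); when
    given, a k x 2 chi-square of (success, failure) across classes is
    also returned.
    """
    if n_specimens <= 0:
        raise ValueError("n_specimens must be positive")
    if not 0 <= n_sequences <= n_specimens:
        raise ValueError("need 0 <= n_sequences <= n_specimens")
    rate = round(100.0 * n_sequences / n_specimens, 1)
    test = None
    if by_class:
        table = np.array(
            [[succ, tot - succ] for succ, tot in by_class.values()], dtype=float
        )
        chi2, p, df, _ = stats.chi2_contingency(table)
        test = TestResult("success_rate_by_class", float(chi2), float(p), df=float(df))
    return rate, test


def composition_table(
    records: Sequence[SequenceRecord], meta: Sequence[SpecimenMetadata], rank: str = "species"
) -> pd.DataFrame:
    """Per-rank pooled composition table (counts + GC%)."""
    attr = {
        "species": "species_label",
        "genus": "genus",
        "family": "family",
        "order": "taxon_order",
        "class": "taxon_class",
    }[rank]
    by_id = {m.seq_id: m for m in meta}
    pooled: dict[str, list[int]] = {}
    for rec in records:
        m = by_id.get(rec.seq_id)
        if m is None:
            continue
        key = getattr(m, attr)
        bc = base_counts(rec)
        acc = pooled.setdefault(key, [0, 0, 0, 0])
        for i, v in enumerate(bc.counts):
            acc[i] += v
    rows = []
    for key in sorted(pooled):
        a, c, g, t = pooled[key]
        total = a + c + g + t
        rows.append(
            {rank: key, "A": a, "C": c, "G": g, "T": t,
             "gc_pct": round(100.0 * (g + c) / total, 2) if total else float("nan")}
        )
    return pd.DataFrame(rows)
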