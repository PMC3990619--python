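"""End-to-end barcode analysis: QC -> alignment/indels -> distances ->
trees -> OTU delimitation -> statistics, with a reproducible report
bundle written to an output directory.

Stage outputs mirror the reporting style of barcode surveys: a QC report,
a per-species distance/barcode-gap summary, an NJ tree in Newick, deep-
divergence cases, OTU partitions from the 2% threshold and barcode-gap
discovery, indel events mapped to COI structure, composition tables and a
statistics table. ``run.json`` records the configuration (and its hash)
so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import clustering, compstats, distances, indels, io_qc, nj_tree


@dataclass
class RunConfig:
    fasta: str
    meta: str
    out_dir: str
    min_len: int = 220
    max_ambig_frac: float = 0.01
    genetic_code: int = 5
    min_overlap_frac: float = 0.60
    threshold: float = 0.02
    pmin: float = 0.0006
    pmax: float = 0.17
    abgd_steps: int = 10
    abgd_gap_width: float = 1.5
    abgd_scheme: Optional[int] = None
    deep_threshold_pct: float = 2.0
    rate_pct_per_my: float = 2.0
    reference_id: Optional[str] = None
    exclude_pseudogenes: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    out_dir: Path
    counts: dict[str, int] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run every stage, writing the report bundle under ``cfg.out_dir``.

    On a stage failure, partial outputs are retained and ``MANIFEST``
    names the last completed stage before the exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(config=cfg, out_dir=out)
    stages_done: list[str] = []

    def checkpoint(stage: str) -> None:
        stages_done.append(stage)
        (out / "MANIFEST").write_text(
            "last_completed_stage\t" + stage + "\n" + "\n".join(stages_done) + "\n"
        )

    try:
        # ---- input + QC -------------------------------------------------
        records = io_qc.read_fasta(cfg.fasta)
        meta = io_qc.read_specimen_table(cfg.meta)
        if not records:
            raise ValueError(f"{cfg.fasta}: no sequences")
        report = io_qc.qc_filter(
            records,
            min_len=cfg.min_len,
            max_ambig_frac=cfg.max_ambig_frac,
            genetic_code=cfg.genetic_code,
        )
        _write(report.to_frame(), out / "qc_report.tsv")
        by_id = {r.seq_id: r for r in records}
        passed = [by_id[s] for s in report.passed]
        if len(passed) < 2:
            raise ValueError("fewer than 2 sequences survive QC")
        result.counts.update(
            n_input=len(records), n_passed=len(passed), n_failed=len(report.failed)
        )
        checkpoint("qc")

        # ---- codon alignment + indels -----------------------------------
        if cfg.reference_id is not None:
            reference = by_id[cfg.reference_id]
        else:
            # prefer the modal sequence length: indel carriers are longer or
            # shorter than the bulk, so the mode is typically indel-free
            lengths = pd.Series([r.length_bp for r in passed])
            modal = lengths.mode().max()
            candidates = [r for r in passed if r.length_bp == modal]
            reference = min(candidates, key=lambda r: r.seq_id)
        aln = indels.codon_align(passed, reference, genetic_code=cfg.genetic_code)
        events = indels.detect_indels(aln, meta)
        events = indels.map_to_structure(events)
        _write(indels.events_to_frame(events), out / "indel_events.tsv")
        _write(indels.hotspot_summary(events), out / "hotspots.tsv")
        pseudo_flags = indels.pseudogene_screen(events, aln, cfg.genetic_code)
        aln.to_fasta(out / "alignment.fasta")
        result.counts.update(n_indel_events=len(events), n_pseudogene_flags=len(pseudo_flags))
        checkpoint("indels")

        # ---- distances + species summaries ------------------------------
        keep_ids = [
            sid
            for sid in aln.rows
            if not (cfg.exclude_pseudogenes and sid in pseudo_flags)
        ]
        aligned_records = [io_qc.SequenceRecord(sid, aln.rows[sid]) for sid in keep_ids]
        m = distances.distance_matrix(aligned_records, min_overlap_frac=cfg.min_overlap_frac)
        m.to_long_frame().to_csv(out / "distances_long.tsv", sep="\t", index=False)
        summaries = distances.species_summaries(m, meta)
        _write(distances.summaries_to_frame(summaries), out / "species_summary.tsv")
        gap_df = pd.DataFrame(
            [
                {
                    "species": s.species_label,
                    "max_intra_pct": s.max_intra,
                    "nn_distance_pct": s.nn_distance,
                    "barcode_gap": s.barcode_gap,
                }
                for s in summaries
            ]
        )
        _write(gap_df, out / "barcode_gap.tsv")
        result.counts.update(n_species=len(summaries))
        checkpoint("distances")

        # ---- NJ tree + deep divergence ----------------------------------
        tree = nj_tree.neighbor_joining(m)
        (out / "nj.newick").write_text(tree.to_newick() + "\n")
        deep = nj_tree.flag_deep_divergence(summaries, cfg.deep_threshold_pct)
        max_intra = {s.species_label: s.max_intra for s in summaries}
        deep_rows = []
        for sp in deep:
            case = nj_tree.subtree_report(
                tree, sp, meta, cfg.rate_pct_per_my, max_intra_pct=max_intra[sp]
            )
            for li, (members, locs) in enumerate(case.lineages, 1):
                deep_rows.append(
                    {
                        "species": sp,
                        "max_intra_pct": case.max_intra,
                        "estimated_time_my": case.estimated_time_my,
                        "lineage": li,
                        "n_members": len(members),
                        "members": ";".join(members),
                        "localities": ";".join(locs),
                    }
                )
        _write(
            pd.DataFrame(
                deep_rows,
                columns=[
                    "species", "max_intra_pct", "estimated_time_my",
                    "lineage", "n_members", "members", "localities",
                ],
            ),
            out / "deep_divergence.tsv",
        )
        result.counts.update(n_deep_divergence=len(deep))
        checkpoint("nj_tree")

        # ---- OTU delimitation -------------------------------------------
        eligible = [
            r.seq_id for r in aligned_records if io_qc.eligibility(r.length_bp, "OTHER")
        ]
        me = m.submatrix(eligible)
        part_thr = clustering.threshold_cluster(me, cfg.threshold)
        _write(part_thr.to_frame(), out / "partitions" / "threshold.tsv")
        abgd = clustering.abgd_partition(
            me,
            pmin=cfg.pmin,
            pmax=cfg.pmax,
            n_steps=cfg.abgd_steps,
            rel_gap_x=cfg.abgd_gap_width,
            scheme=cfg.abgd_scheme,
        )
        _write(abgd.to_frame(), out / "abgd_schemes.tsv")
        _write(abgd.selected.to_frame(), out / "partitions" / "abgd_selected.tsv")
        congruence = clustering.partition_congruence(part_thr, abgd.selected)
        result.counts.update(
            n_otus_threshold=part_thr.n_otus,
            n_singletons_threshold=part_thr.n_singletons,
            n_otus_abgd=abgd.selected.n_otus,
            n_singletons_abgd=abgd.selected.n_singletons,
        )
        checkpoint("clustering")

        # ---- composition + statistics -----------------------------------
        passed_records = [by_id[s] for s in report.passed]
        comp_species = compstats.composition_table(passed_records, meta, "species")
        _write(comp_species, out / "composition.tsv")
        stats_rows = []
        profiles_by_class: dict[str, list[compstats.CompositionProfile]] = {}
        meta_by_id = {mm.seq_id: mm for mm in meta}
        sp_profiles = compstats.species_composition(passed_records, meta)
        class_of_species = {
            mm.species_label: mm.taxon_class for mm in meta
        }
        for prof in sp_profiles:
            profiles_by_class.setdefault(class_of_species[prof.unit_id], []).append(prof)
        for klass, profs in sorted(profiles_by_class.items()):
            if len(profs) >= 2:
                tr = compstats.composition_homogeneity(profs)
                tr.name = f"composition_homogeneity[{klass}]"
                stats_rows.append(tr.to_row())
        gc_by_species = {
            row["species"]: row["gc_pct"] for _, row in comp_species.iterrows()
        }
        genera = distances.genus_summaries(summaries, meta, gc_by_species)
        try:
            stats_rows.append(
                compstats.gc_nn_correlation(genera, seed=cfg.seed).to_row()
            )
        except ValueError:
            pass
        for response in ("mean_intra", "max_intra"):
            try:
                stats_rows.append(
                    compstats.divergence_vs_n_regression(summaries, response).to_row()
                )
            except ValueError:
                pass
        try:
            stats_rows.append(compstats.nn_vs_completeness_anova(genera).to_row())
        except ValueError:
            pass
        rate, _ = compstats.success_rate(len(report.passed), len(records))
        stats_rows.append({"test": "qc_pass_rate_pct", "statistic": rate, "df": None, "p": None})
        mean_intra = None
        try:
            mean_intra = distances.mean_intraspecific_divergence(summaries)
            stats_rows.append(
                {"test": "mean_intraspecific_divergence_pct", "statistic": round(mean_intra, 2),
                 "df": None, "p": None}
            )
            stats_rows.append(
                {
                    "test": "mean_intraspecific_divergence_excl_deep_pct",
                    "statistic": round(
                        distances.mean_intraspecific_divergence(
                            summaries, exclude_above_pct=cfg.deep_threshold_pct
                        ),
                        2,
                    ),
                    "df": None,
                    "p": None,
                }
            )
        except ValueError:
            pass
        stats_df = pd.DataFrame(stats_rows)
        _write(stats_df, out / "stats.tsv")
        genus_df = pd.DataFrame(
            [
                {
                    "genus": g.genus,
                    "n_species_sampled": g.n_species_sampled,
                    "known_species": g.known_species,
                    "completeness_pct": g.completeness_pct,
                    "mean_nn_distance_pct": g.mean_nn_distance,
                    "mean_gc_pct": g.mean_gc_pct,
                }
                for g in genera
            ]
        )
        _write(genus_df, out / "genus_summary.tsv")
        result.counts["congruence_agreement_x1000"] = int(round(congruence.agreement * 1000))
        checkpoint("stats")

        # ---- run metadata -----------------------------------------------
        run_info = {
            "config": dataclasses.asdict(cfg),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "counts": result.counts,
        }
        (out / "run.json").write_text(json.dumps(run_info, indent=1, sort_keys=True) + "\n")
        checkpoint("done")
    except Exception:
        (out / "MANIFEST").write_text(
            "last_completed_stage\t"
            + (stages_done[-1] if stages_done else "none")
            + "\nFAILED\n"
        )
        raise
    result.tables["stats"] = stats_df
    return result
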