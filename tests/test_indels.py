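import numpy as np
import pytest

import barcodekit as bk
from barcodekit.indels import (
    PUTATIVE_PSEUDOGENE,
    RegionMap,
    codon_align,
    detect_indels,
    events_to_frame,
    hotspot_summary,
    map_to_structure,
    pseudogene_screen,
    translate,
)
from barcodekit.io_qc import SequenceRecord, SpecimenMetadata
from barcodekit.simulate import (
    PlantedIndel,
    SimConfig,
    _indel_context_ok,
    draw_root_sequence,
    simulate_dataset,
)


def meta_for(ids, species="S", family="F"):
    return [
        SpecimenMetadata(s, "C", "O", family, "G", species, "loc") for s in ids
    ]


@pytest.fixture(scope="module")
def ref(stop_free_seq):
    return SequenceRecord("REF", stop_free_seq)


class TestCodonAlign:
    def test_identical_sequences_gap_free(self, ref):
        recs = [SequenceRecord(f"s{i}", ref.nucleotides) for i in range(3)]
        aln = codon_align(recs, ref)
        assert all("-" not in row for row in aln.rows.values())
        assert len(aln.columns) == len(ref.nucleotides)

    def test_insertion_opens_gap_block_in_other_rows(self, ref):
        # 3-nt insertion after reference codon 36 -> anchored at codon 37
        ins_at = 36 * 3
        carrier = ref.nucleotides[:ins_at] + "GCT" + ref.nucleotides[ins_at:]
        recs = [
            SequenceRecord("plain", ref.nucleotides),
            SequenceRecord("carrier", carrier),
        ]
        aln = codon_align(recs, ref)
        cols = [i for i, (site, pos) in enumerate(aln.columns) if pos == 0]
        assert len(cols) == 3
        assert {aln.columns[i][0] for i in cols} == {37}
        for i in cols:
            assert aln.rows["plain"][i] == "-"
            assert aln.rows["REF"][i] == "-"
            assert aln.rows["carrier"][i] != "-"

    def test_single_nt_deletion_flagged_frame_shifting(self, ref):
        broken = ref.nucleotides[:301] + ref.nucleotides[302:]
        aln = codon_align([SequenceRecord("fs", broken)], ref)
        events = detect_indels(aln)
        assert any(e.frame_shifting and e.length_nt % 3 != 0 for e in events)

    def test_unalignable_sequence_excluded(self, ref, rng):
        noise = draw_root_sequence(0.5, len(ref.nucleotides) // 3, rng)
        aln = codon_align([SequenceRecord("noise", noise)], ref)
        assert ("noise", "unalignable") in aln.excluded

    def test_reference_with_internal_stop_rejected(self, ref):
        bad = SequenceRecord("bad", "TAA" + ref.nucleotides[3:])
        with pytest.raises(ValueError, match="stop"):
            codon_align([ref], bad)


class TestDetectIndels:
    def test_shared_insertion_merged_across_species(self, ref):
        ins_at = 36 * 3
        recs = [SequenceRecord("plain", ref.nucleotides)]
        meta = meta_for(["plain"], species="P")
        for i, (sp, fam) in enumerate(
            [("S1", "F1"), ("S2", "F2"), ("S3", "F2")]
        ):
            sid = f"c{i}"
            recs.append(
                SequenceRecord(sid, ref.nucleotides[:ins_at] + "GCT" + ref.nucleotides[ins_at:])
            )
            meta += meta_for([sid], species=sp, family=fam)
        aln = codon_align(recs, ref)
        events = detect_indels(aln, meta)
        assert len(events) == 1
        e = events[0]
        assert (e.kind, e.codon_site, e.length_codons) == ("insertion", 37, 1)
        assert len(e.taxa) == 3

    def test_three_codon_insertion_spanning_sites(self, ref):
        ins_at = 36 * 3
        block = "GCTTTAGAT"  # 3 codons, no stops (TTA = Leu)
        carrier = ref.nucleotides[:ins_at] + block + ref.nucleotides[ins_at:]
        aln = codon_align(
            [SequenceRecord("p", ref.nucleotides), SequenceRecord("c", carrier)], ref
        )
        events = detect_indels(aln)
        assert [(e.kind, e.codon_site, e.length_codons) for e in events] == [
            ("insertion", 37, 3)
        ]

    def test_deletion_site_anchoring_distinct_from_insertion(self, ref):
        # deleting reference codon 36 and inserting before codon 37 are
        # neighbouring but distinct events
        del_at = 35 * 3
        deleted = ref.nucleotides[:del_at] + ref.nucleotides[del_at + 3 :]
        aln = codon_align([SequenceRecord("d", deleted)], ref)
        events = detect_indels(aln)
        assert [(e.kind, e.codon_site) for e in events] == [("deletion", 36)]

    def test_no_gaps_no_events(self, ref):
        aln = codon_align([SequenceRecord("s", ref.nucleotides)], ref)
        assert detect_indels(aln) == []

    def test_truncated_sequence_yields_no_terminal_events(self, ref):
        short = SequenceRecord("sh", ref.nucleotides[60:480])
        aln = codon_align([short], ref)
        assert detect_indels(aln) == []

    def test_event_order_invariant_to_input_order(self, ref, rng):
        ins_at = 36 * 3
        carrier = ref.nucleotides[:ins_at] + "GCT" + ref.nucleotides[ins_at:]
        recs = [
            SequenceRecord("a", ref.nucleotides),
            SequenceRecord("b", carrier),
            SequenceRecord("c", ref.nucleotides[: 90 * 3] + ref.nucleotides[91 * 3 :]),
        ]
        e1 = detect_indels(codon_align(recs, ref))
        e2 = detect_indels(codon_align(recs[::-1], ref))
        assert [e.key for e in e1] == [e.key for e in e2]


class TestPlantedIndelRecovery:
    def test_exact_recovery_over_randomized_fixtures(self):
        """200 randomized datasets with known planted indels: detection
        recovers exactly the planted (kind, site, length) set."""
        rng = np.random.default_rng(2014)
        n_checked = 0
        failures = []
        while n_checked < 200:
            seed = int(rng.integers(0, 2**31 - 1))
            n_species = 5
            local = np.random.default_rng(seed)
            n_indels = int(local.integers(1, 4))
            planted = []
            used_sites = set()
            for _ in range(n_indels):
                site = int(local.integers(10, 201))
                if any(abs(site - s) < 6 for s in used_sites):
                    continue
                used_sites.add(site)
                planted.append(
                    PlantedIndel(
                        codon_site=site,
                        length_codons=int(local.integers(1, 4)),
                        kind=str(local.choice(["insertion", "deletion"])),
                        species_index=int(local.integers(0, n_species)),
                    )
                )
            if not planted:
                continue
            cfg = SimConfig(
                n_species=n_species,
                specimens_mean=3,
                singleton_fraction=0.2,
                planted_indels=tuple(planted),
                seed=seed,
            )
            try:
                ds = simulate_dataset(cfg)
            except ValueError:
                continue  # ambiguous deletion context on this ancestor: redraw
            ref = SequenceRecord("REF", ds.manifest.ancestor_seq)
            aln = codon_align(ds.records, ref)
            events = detect_indels(aln, ds.meta)
            got = {(e.kind, e.codon_site, e.length_codons) for e in events}
            want = {
                (p["kind"], p["codon_site"], p["length_codons"])
                for p in ds.manifest.planted_indels
            }
            if got != want:
                failures.append((seed, got, want))
            n_checked += 1
        assert not failures, f"{len(failures)} fixtures missed: {failures[:3]}"

    def test_all_in_frame_events_are_codon_multiples(self, clean_dataset):
        _, ds = clean_dataset
        ref = SequenceRecord("REF", ds.manifest.ancestor_seq)
        aln = codon_align(ds.records, ref)
        for e in detect_indels(aln, ds.meta):
            if not e.frame_shifting:
                assert e.length_nt % 3 == 0


class TestPseudogeneScreen:
    def test_in_frame_indel_not_flagged(self, ref):
        ins_at = 36 * 3
        carrier = ref.nucleotides[:ins_at] + "GCT" + ref.nucleotides[ins_at:]
        aln = codon_align([SequenceRecord("c", carrier)], ref)
        events = detect_indels(aln)
        assert pseudogene_screen(events, aln) == {}

    def test_two_nt_deletion_flagged(self, ref):
        broken = ref.nucleotides[:300] + ref.nucleotides[302:]
        aln = codon_align([SequenceRecord("fs", broken)], ref)
        events = detect_indels(aln)
        flags = pseudogene_screen(events, aln)
        assert "fs" in flags and flags["fs"][0] == PUTATIVE_PSEUDOGENE

    def test_downstream_stop_after_in_frame_indel_flagged(self, ref):
        ins_at = 36 * 3
        seq = ref.nucleotides[:ins_at] + "GCT" + ref.nucleotides[ins_at:]
        # plant a stop well downstream of the indel, on a codon boundary
        # of the post-insertion frame
        stop_at = 150 * 3 + 3
        seq = seq[:stop_at] + "TAA" + seq[stop_at + 3 :]
        aln = codon_align([SequenceRecord("ps", seq)], ref)
        events = detect_indels(aln)
        flags = pseudogene_screen(events, aln)
        assert "ps" in flags


class TestRegionMap:
    def test_default_map_covers_barcode(self):
        rmap = RegionMap.default()
        assert rmap.span == (1, 216)
        assert rmap.region_of(37) == "external loop 1"
        assert rmap.region_of(132) == "external loop 2"

    def test_mid_helix_lookup(self):
        rmap = RegionMap.default()
        assert rmap.region_of(55) == "helix 2"

    def test_site_zero_rejected(self):
        with pytest.raises(ValueError, match="0"):
            RegionMap.default().region_of(0)

    def test_non_contiguous_intervals_rejected(self):
        with pytest.raises(ValueError):
            RegionMap(intervals=[(1, 10, "a"), (12, 20, "b")])

    def test_map_to_structure_near_tags(self, ref):
        ins_at = 30 * 3  # insertion anchored at codon 31: first loop edge
        carrier = ref.nucleotides[:ins_at] + "GCT" + ref.nucleotides[ins_at:]
        aln = codon_align([SequenceRecord("c", carrier)], ref)
        events = map_to_structure(detect_indels(aln))
        assert events[0].region == "external loop 1"
        assert "near:helix 1" in events[0].near


class TestHotspots:
    def _events(self, ref, spec):
        recs, meta = [SequenceRecord("p", ref.nucleotides)], meta_for(["p"], "P", "F0")
        for i, (kind, fam) in enumerate(spec):
            sid = f"s{i}"
            at = 36 * 3
            if kind == "insertion":
                seq = ref.nucleotides[:at] + "GCT" + ref.nucleotides[at:]
            else:
                seq = ref.nucleotides[:at] + ref.nucleotides[at + 3 :]
            recs.append(SequenceRecord(sid, seq))
            meta += meta_for([sid], species=f"S{i}", family=fam)
        aln = codon_align(recs, ref)
        return detect_indels(aln, meta)

    def test_multi_family_site_flagged(self, ref):
        events = self._events(
            ref,
            [("insertion", "F1"), ("insertion", "F2"), ("insertion", "F3"),
             ("deletion", "F4")],
        )
        table = hotspot_summary(events)
        assert bool(table.iloc[0].hotspot)
        assert int(table.iloc[0].n_families) == 4

    def test_single_family_sites_not_hotspots(self, ref):
        events = self._events(ref, [("insertion", "F1")])
        table = hotspot_summary(events)
        assert not table.hotspot.any()

    def test_empty_events_empty_table(self):
        assert len(hotspot_summary([])) == 0
        assert len(events_to_frame([])) == 0
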