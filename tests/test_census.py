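"""ASC/TSC/hTSC stratification, annotation merging, ratios and tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovidy import census as cs
from bovidy.simulate import simulate_reads


def toy_model(copy_id, start, end, strand="+", source="denovo", chrom="Y",
              family="FAM", exons=None, cds=None, **meta):
    return cs.GeneModel(copy_id=copy_id, family=family, chrom=chrom, start=start,
                        end=end, strand=strand, exons=exons or [(start, end)],
                        cds=cds or [], source=source, **meta)


def lift_candidate(i, coverage=0.9, structure_preserved=True, n_best_mappings=1):
    return toy_model(f"c{i}", 100 * i + 1, 100 * i + 50, source="liftover",
                     coverage=coverage, structure_preserved=structure_preserved,
                     n_best_mappings=n_best_mappings)


class TestFilterLiftover:
    def test_coverage_threshold(self):
        acc, rej = cs.filter_liftover([lift_candidate(1, coverage=0.49)])
        assert acc == [] and "coverage" in rej[0][1]
        acc, _ = cs.filter_liftover([lift_candidate(1, coverage=0.5)])
        assert len(acc) == 1

    def test_non_unique_mapping_rejected(self):
        acc, rej = cs.filter_liftover([lift_candidate(1, n_best_mappings=2)])
        assert acc == [] and "non-unique" in rej[0][1]

    def test_structure_not_preserved_rejected(self):
        acc, rej = cs.filter_liftover([lift_candidate(1, structure_preserved=False)])
        assert acc == [] and "structure" in rej[0][1]

    def test_missing_metadata(self):
        with pytest.raises(cs.CensusError, match="metadata"):
            cs.filter_liftover([toy_model("x", 1, 50, source="liftover")])

    def test_published_acceptance_rate(self):
        """380 candidates built so that 311 satisfy all three conditions."""
        cands = [lift_candidate(i) for i in range(311)]
        cands += [lift_candidate(400 + i, coverage=0.3) for i in range(30)]
        cands += [lift_candidate(500 + i, n_best_mappings=2) for i in range(20)]
        cands += [lift_candidate(600 + i, structure_preserved=False) for i in range(19)]
        acc, rej = cs.filter_liftover(cands)
        assert (len(acc), len(cands)) == (311, 380)
        from bovidy._util import pct

        assert pct(len(acc), len(cands)) == 81.84


class TestMergeAnnotations:
    def test_empty_denovo(self):
        primary = [lift_candidate(i) for i in range(3)]
        assert cs.merge_annotations(primary, []) == sorted(primary, key=lambda m: m.start)

    def test_contained_denovo_discarded(self):
        p = toy_model("p", 100, 500, source="liftover")
        d = toy_model("d", 200, 300)
        assert cs.merge_annotations([p], [d]) == [p]

    def test_opposite_strand_overlap_kept(self):
        p = toy_model("p", 100, 500, strand="+", source="liftover")
        d = toy_model("d", 200, 300, strand="-")
        assert cs.merge_annotations([p], [d]) == [p, d]

    def test_constructed_counts(self):
        """10 primary + 10 de novo with 4 exonic overlaps -> 16 models."""
        primary = [toy_model(f"p{i}", 1_000 * i + 1, 1_000 * i + 400, source="liftover")
                   for i in range(10)]
        denovo = [toy_model(f"d{i}", 1_000 * i + 200, 1_000 * i + 600)
                  for i in range(4)]  # overlap p0..p3
        denovo += [toy_model(f"d{i}", 1_000 * i + 500, 1_000 * i + 800)
                   for i in range(4, 10)]  # in the gaps
        merged = cs.merge_annotations(primary, denovo)
        assert len(merged) == 16
        assert {m.copy_id for m in merged if m.source == "denovo"} == {
            f"d{i}" for i in range(4, 10)}


class TestAscAndSupport:
    def test_clean_orf_is_asc(self):
        genome = {"Y": "AA" + "ATG" + "GCTGCA" + "TAA" + "CC"}
        m = toy_model("g", 3, 14, cds=[(3, 14)])
        copies = cs.call_asc([m], genome)
        assert copies[0].asc

    def test_internal_stop_not_asc(self):
        genome = {"Y": "AA" + "ATG" + "TAGGCA" + "TAA" + "CC"}
        m = toy_model("g", 3, 14, cds=[(3, 14)])
        assert not cs.call_asc([m], genome)[0].asc

    def test_minus_strand_orf(self):
        from bovidy._util import revcomp

        fwd = "ATGGCTGCATAA"
        genome = {"Y": "CC" + revcomp(fwd) + "GG"}
        m = toy_model("g", 3, 14, strand="-", cds=[(3, 14)])
        assert cs.call_asc([m], genome)[0].asc

    def test_interval_outside_genome(self):
        with pytest.raises(cs.CensusError, match="outside"):
            cs.call_asc([toy_model("g", 5, 500, cds=[(5, 500)])], {"Y": "ACGT" * 10})

    def test_generator_truth_asc_counts(self, small_sim):
        _, _, y, truth = small_sim
        models = cs.models_from_truth(truth)
        copies = cs.call_asc(models, {"Y": str(y.seq)})
        asc = {c.model.copy_id for c in copies if c.asc}
        assert asc == set(truth.copy_coords) - truth.pseudogene_set

    def test_zero_alignments_zero_counts(self, small_sim):
        _, _, y, truth = small_sim
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        cs.count_support(copies, [], "short")
        assert all(c.short_read_count == 0 for c in copies)

    def test_unknown_chrom_rejected(self, small_sim):
        _, _, y, truth = small_sim
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        bad = [{"name": "r1", "chrom": "chrUn", "pos": 1, "mapq": 60,
                "is_primary": True, "length": 100}]
        with pytest.raises(cs.CensusError, match="chrUn"):
            cs.count_support(copies, bad, "long")

    def test_single_long_read_counts_once(self, small_sim):
        _, _, y, truth = small_sim
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        target = copies[3].model
        aln = [{"name": "r1", "chrom": "Y", "pos": target.start, "mapq": 60,
                "is_primary": True, "length": target.end - target.start + 1}]
        cs.count_support(copies, aln, "long")
        assert copies[3].long_read_count == 1
        assert sum(c.long_read_count for c in copies) == 1

    def test_sam_roundtrip_counts_match(self, small_sim, small_sim_reads, tmp_path):
        from bovidy.simulate import write_sam

        cfg, _, y, truth = small_sim
        sreads, salns, _, _ = small_sim_reads
        sam = tmp_path / "short.sam"
        write_sam(salns, sreads, cfg.chrom_len, sam)
        copies_a = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        copies_b = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        cs.count_support(copies_a, salns, "short")
        cs.count_support(copies_b, str(sam), "short")
        counts_a = {c.model.copy_id: c.short_read_count for c in copies_a}
        counts_b = {c.model.copy_id: c.short_read_count for c in copies_b}
        assert counts_a == counts_b


class TestStratify:
    def test_non_asc_never_tsc(self):
        m = toy_model("g", 1, 10)
        c = cs.AmpliconCopy(model=m, asc=False, short_read_count=99, long_read_count=99)
        cs.stratify([c])
        assert not c.tsc and not c.htsc

    def test_published_family_counts(self):
        """29 annotated copies, 5 with short-read and 4 with long-read
        support -> ASC:TSC:hTSC = 29:5:4 (a real TSPY3-like row)."""
        copies = []
        for i in range(29):
            c = cs.AmpliconCopy(model=toy_model(f"g{i}", 100 * i + 1, 100 * i + 50),
                                asc=True)
            c.short_read_count = 1 if i < 5 else 0
            c.long_read_count = 1 if i < 4 else 0
            copies.append(c)
        cs.stratify(copies)
        assert (sum(c.asc for c in copies), sum(c.tsc for c in copies),
                sum(c.htsc for c in copies)) == (29, 5, 4)

    def test_recovery_and_inflation_on_simulation(self, small_sim, small_sim_reads):
        """hTSC set recovers the expressed set exactly; short-read TSC count
        is inflated at or above it."""
        _, _, y, truth = small_sim
        _, salns, _, lalns = small_sim_reads
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        cs.count_support(copies, salns, "short")
        cs.count_support(copies, lalns, "long")
        cs.stratify(copies)
        htsc = {c.model.copy_id for c in copies if c.htsc}
        assert htsc == truth.expressed_set
        assert sum(c.tsc for c in copies) >= sum(c.htsc for c in copies)

    @given(st.lists(st.tuples(st.booleans(), st.integers(0, 3), st.integers(0, 3)),
                    max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_containment_invariant_fuzz(self, rows):
        copies = [cs.AmpliconCopy(model=toy_model(f"g{i}", 10 * i + 1, 10 * i + 5),
                                  asc=asc, short_read_count=s, long_read_count=l)
                  for i, (asc, s, l) in enumerate(rows)]
        cs.stratify(copies)
        for c in copies:
            assert (not c.htsc or c.tsc) and (not c.tsc or c.asc)


class TestDomainCheck:
    def test_planted_domain_found_in_htscs(self, small_sim, small_sim_reads):
        cfg, _, y, truth = small_sim
        _, salns, _, lalns = small_sim_reads
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        cs.count_support(copies, salns, "short")
        cs.count_support(copies, lalns, "long")
        cs.stratify(copies)
        cs.domain_check(copies, {"Y": str(y.seq)}, motif=cfg.families[0].domain_motif)
        assert all(c.domain_present for c in copies if c.htsc)

    def test_scrambled_domain_absent(self, small_sim):
        _, _, y, truth = small_sim
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        cs.domain_check(copies, {"Y": str(y.seq)}, motif="KQWNDPHM"[::-1])
        assert not any(c.domain_present for c in copies)

    def test_needs_motif_or_pssm(self, small_sim):
        _, _, y, truth = small_sim
        copies = cs.call_asc(cs.models_from_truth(truth), {"Y": str(y.seq)})
        with pytest.raises(cs.CensusError):
            cs.domain_check(copies, {"Y": str(y.seq)})


class TestRatiosAndTiers:
    @pytest.mark.parametrize("num,den,expected", [
        (38, 9, 4.22), (74, 22, 3.36), (67, 37, 1.81), (20, 12, 1.67),
        (3, 5, 0.60), (4, 7, 0.57), (2, 2, 1.00), (0, 0, 0.00),
    ])
    def test_published_ratios(self, num, den, expected):
        assert cs.copy_ratio(num, den) == expected

    def test_nonzero_over_zero_undefined(self):
        assert cs.copy_ratio(5, 0) is None

    @pytest.mark.parametrize("count,tier", [
        (197, "100–200"), (101, "100–200"), (73, "50–100"), (28, "10–50"),
        (29, "10–50"), (16, "10–50"), (10, "1–10"), (3, "1–10"), (2, "1–10"),
        (1, "1–10"), (0, "other"), (250, "other"), (50, "50–100"),
        (100, "100–200"), (11, "10–50"),
    ])
    def test_tier_boundaries(self, count, tier):
        assert cs.tier_classify(count) == tier


class TestGff3Roundtrip:
    def test_models_roundtrip(self, small_sim):
        _, _, _, truth = small_sim
        models = cs.models_from_truth(truth)
        back = cs.models_from_gff3(cs.models_to_gff3(models))
        by_id = {m.copy_id: m for m in back}
        assert by_id.keys() == {m.copy_id for m in models}
        for m in models:
            r = by_id[m.copy_id]
            assert (r.start, r.end, r.strand, r.cds, r.family) == (
                m.start, m.end, m.strand, m.cds, m.family)
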