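import pytest

from plasmabm.profiling import (OverlapSummary, gene_frequency,
                                oncoplot_long_frame, timepoint_overlap)

from conftest import make_variant


def patient_variants(pid, genes, timepoint="C0", start_pos=1000):
    sample = f"{pid}-{timepoint}"
    return [make_variant(patient_id=pid, sample_id=sample, timepoint=timepoint,
                         gene=g, pos=start_pos + i)
            for i, g in enumerate(genes)]


class TestGeneFrequency:
    def test_universal_gene_is_100_percent(self):
        variants = []
        for i in range(4):
            variants += patient_variants(f"P{i}", ["TP53"])
        df = gene_frequency(variants, [f"P{i}" for i in range(4)])
        assert df.loc[df["gene"] == "TP53", "frequency"].iloc[0] == 1.0

    def test_absent_gene_omitted(self):
        variants = patient_variants("P0", ["TP53"])
        df = gene_frequency(variants, ["P0", "P1"])
        assert "KRAS" not in set(df["gene"])
        assert df.loc[df["gene"] == "TP53", "frequency"].iloc[0] == 0.5

    def test_per_group_frequencies_and_sorting(self):
        variants = (patient_variants("P0", ["TP53", "KRAS"])
                    + patient_variants("P1", ["TP53"])
                    + patient_variants("P2", ["EGFR"]))
        groups = {"P0": "DCB", "P1": "NDB", "P2": "NDB"}
        df = gene_frequency(variants, ["P0", "P1", "P2"], groups)
        assert df.iloc[0]["gene"] == "TP53"  # descending frequency
        row = df[df["gene"] == "KRAS"].iloc[0]
        assert row["frequency_DCB"] == 1.0 and row["frequency_NDB"] == 0.0

    def test_simulated_tp53_frequency_near_generator_truth(self, small_cohort,
                                                           default_config):
        """Oracle: P(>=1 TP53 variant) from the gene weights and the uniform
        clone-count distribution, vs the observed baseline frequency."""
        from plasmabm.filtering import filter_somatic
        from plasmabm.simulate import SimulationConfig, default_gene_weights

        config = SimulationConfig()
        w = default_gene_weights()["TP53"]
        lo, hi = config.n_clones_range
        ks = range(lo, hi + 1)
        expected = 1 - sum((1 - w) ** k for k in ks) / len(list(ks))

        kept, _ = filter_somatic(small_cohort.variants, default_config)
        pos = sorted(small_cohort.truth.loc[
            small_cohort.truth["ctdna_positive_c0"], "patient_id"])
        df = gene_frequency(kept, pos)
        observed = df.loc[df["gene"] == "TP53", "frequency"].iloc[0]
        # binomial tolerance at n ~ 70
        assert observed == pytest.approx(expected, abs=0.18)


class TestTimepointOverlap:
    def test_identical_sets_fully_shared(self):
        variants = (patient_variants("P0", ["TP53", "KRAS"])
                    + patient_variants("P0", ["TP53", "KRAS"], timepoint="C4"))
        s = timepoint_overlap(variants, {"P0"})
        assert s.pct_shared == 100.0 and s.c0_only == 0 and s.c4_only == 0

    def test_disjoint_sets_nothing_shared(self):
        variants = (patient_variants("P0", ["TP53"], start_pos=100)
                    + patient_variants("P0", ["KRAS"], timepoint="C4",
                                       start_pos=900))
        s = timepoint_overlap(variants, {"P0"})
        assert s.shared == 0 and s.c0_only == 1 and s.c4_only == 1

    def test_hand_case_4_5_1(self):
        """10 distinct keys: 4 baseline-only, 5 shared, 1 on-treatment-only."""
        c0 = patient_variants("P0", ["G"] * 9, start_pos=100)       # keys 100..108
        c4 = (patient_variants("P0", ["G"] * 5, timepoint="C4",
                               start_pos=104)                        # shared 104..108
              + patient_variants("P0", ["G"], timepoint="C4", start_pos=500))
        s = timepoint_overlap(c0 + c4, {"P0"})
        assert (s.c0_only, s.shared, s.c4_only) == (4, 5, 1)
        assert s.pct_c0_only == pytest.approx(40.0)
        assert s.pct_shared == pytest.approx(50.0)
        assert s.pct_c4_only == pytest.approx(10.0)

    def test_partition_and_symmetry(self, small_cohort):
        paired = set(small_cohort.truth.loc[
            small_cohort.truth["has_on_sample"], "patient_id"])
        variants = [v for v in small_cohort.variants if v.patient_id in paired]
        s = timepoint_overlap(variants, paired)
        assert s.c0_only + s.shared + s.c4_only == s.total_variants
        assert s.pct_c0_only + s.pct_shared + s.pct_c4_only == pytest.approx(100.0)
        # swap the timepoint labels: c0_only and c4_only must swap exactly
        swapped = []
        for v in variants:
            tp = {"C0": "C4", "C4": "C0", "EOT": "C0"}[v.timepoint]
            swapped.append(make_variant(
                patient_id=v.patient_id, sample_id=v.sample_id, timepoint=tp,
                gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                variant_type=v.variant_type, consequence=v.consequence,
                vaf=v.vaf))
        s2 = timepoint_overlap(swapped, paired)
        assert (s2.c0_only, s2.c4_only) == (s.c4_only, s.c0_only)
        assert s2.shared == s.shared

    def test_unpaired_patient_excluded(self):
        variants = (patient_variants("P0", ["TP53"])
                    + patient_variants("P1", ["KRAS"]))
        s = timepoint_overlap(variants, {"P0"})
        assert s.total_variants == 1

    def test_partition_invariant_enforced(self):
        with pytest.raises(AssertionError):
            OverlapSummary(group="x", total_variants=5, c0_only=1, shared=1,
                           c4_only=1)


def test_oncoplot_long_frame_unique_rows(small_cohort):
    patients = [a.patient_id for a in small_cohort.assays if a.timepoint == "C0"]
    df = oncoplot_long_frame(small_cohort.variants, patients)
    assert not df.duplicated().any()
    assert set(df.columns) == {"patient_id", "gene", "status"}
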