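import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmabm import PipelineConfig, SimulationConfig, generate_cohort
from plasmabm.biomarkers import (build_profiles, classify_dynamics,
                                 compute_btmb, compute_hvaf, compute_vafsd)
from plasmabm.errors import CohortValidationError
from plasmabm.types import SampleAssay

from conftest import make_variant


def variants_with_vafs(vafs, sample_id="P0001-C0", timepoint="C0",
                       patient_id="P0001"):
    return [make_variant(pos=1000 + i, vaf=v, sample_id=sample_id,
                         timepoint=timepoint, patient_id=patient_id)
            for i, v in enumerate(vafs)]


class TestBtmb:
    @pytest.mark.parametrize("n_variants, footprint, expected", [
        (2, 0.26, 7.7),    # two mutations on the derived footprint
        (3, 0.26, 11.5),   # the cohort's median burden
        (0, 0.26, 0.0),
        (5, 1.0, 5.0),
    ])
    def test_mutations_per_megabase(self, n_variants, footprint, expected):
        variants = variants_with_vafs([0.02] * n_variants)
        assert round(compute_btmb(variants, footprint), 1) == expected

    def test_nonpositive_footprint_rejected(self):
        with pytest.raises(CohortValidationError):
            compute_btmb([], 0.0)

    @settings(derandomize=True, max_examples=25)
    @given(n=st.integers(0, 40), footprint=st.floats(0.05, 5.0))
    def test_linear_in_count_inverse_in_footprint(self, n, footprint):
        variants = variants_with_vafs([0.02] * n)
        value = compute_btmb(variants, footprint)
        assert value == pytest.approx(n / footprint)
        assert compute_btmb(variants, 2 * footprint) == pytest.approx(value / 2)


class TestHvafVafsd:
    def test_hvaf_is_max_in_percent(self):
        assert compute_hvaf(variants_with_vafs([0.010, 0.039, 0.020])) == \
            pytest.approx(3.9)
        assert compute_hvaf(variants_with_vafs([0.05])) == pytest.approx(5.0)

    def test_hvaf_empty_is_undefined(self):
        assert compute_hvaf([]) is None

    def test_vafsd_hand_computed(self):
        # sd of {0.01, 0.03} with n-1 denominator: 0.01 * sqrt(2) = 0.01414
        value = compute_vafsd(variants_with_vafs([0.01, 0.03]))
        assert value == pytest.approx(0.01 * math.sqrt(2))
        assert round(value, 3) == 0.014

    def test_vafsd_zero_dispersion(self):
        assert compute_vafsd(variants_with_vafs([0.02, 0.02, 0.02])) == \
            pytest.approx(0.0)

    def test_vafsd_single_variant_undefined(self):
        assert compute_vafsd(variants_with_vafs([0.05])) is None

    @settings(derandomize=True, max_examples=40)
    @given(vafs=st.lists(st.floats(0.001, 0.4), min_size=2, max_size=10),
           shift=st.floats(0.0, 0.5), seed=st.integers(0, 99))
    def test_permutation_and_shift_invariance(self, vafs, shift, seed):
        variants = variants_with_vafs(vafs)
        rng = np.random.default_rng(seed)
        shuffled = [variants[i] for i in rng.permutation(len(variants))]
        assert compute_hvaf(shuffled) == pytest.approx(compute_hvaf(variants))
        assert compute_vafsd(shuffled) == pytest.approx(compute_vafsd(variants))
        shifted = variants_with_vafs([min(v + shift, 1.0) for v in vafs])
        if max(vafs) + shift <= 1.0:
            assert compute_vafsd(shifted) == pytest.approx(
                compute_vafsd(variants), abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(vafs=st.lists(st.floats(0.001, 0.4), min_size=2, max_size=10))
    def test_vafsd_zero_iff_all_equal(self, vafs):
        value = compute_vafsd(variants_with_vafs(vafs))
        assert (value == pytest.approx(0.0, abs=1e-15)) == \
            (len(set(vafs)) == 1)


class TestDynamics:
    @pytest.mark.parametrize("c0, on, ratio, cls", [
        (10.0, 12.0, 1.2, "increased"),
        (10.0, 10.0, 1.0, "nc_or_decreased"),  # ties are not "increased"
        (10.0, 5.0, 0.5, "nc_or_decreased"),
    ])
    def test_ratio_classification(self, c0, on, ratio, cls):
        got_ratio, got_cls = classify_dynamics(c0, on)
        assert got_ratio == pytest.approx(ratio)
        assert got_cls == cls

    @pytest.mark.parametrize("c0, on", [(0.0, 5.0), (None, 5.0), (10.0, None)])
    def test_undefined_cases(self, c0, on):
        assert classify_dynamics(c0, on) == (None, "undefined")


class TestBuildProfiles:
    def test_bep_bookkeeping(self):
        """100 baseline draws minus 11 QC failures minus 3 non-evaluable = 86."""
        # flag 11 QC failures (patients 0-10) and 3 non-evaluable draws (11-13)
        assays = []
        for i in range(100):
            pid = f"P{i:03d}"
            assays.append(SampleAssay(
                patient_id=pid, sample_id=f"{pid}-C0", timepoint="C0",
                cfdna_conc_ng_ml=10.0, qc_pass=i >= 11,
                evaluable=not (11 <= i < 14),
            ))
        profiles = build_profiles([], assays)
        assert len(profiles) == 86
        assert all(p.cfdna_c0 == 10.0 for p in profiles)

    def test_ctdna_negative_sample_has_no_variant_markers(self):
        assay = SampleAssay(patient_id="P1", sample_id="P1-C0", timepoint="C0",
                            cfdna_conc_ng_ml=5.0, ctdna_positive=False)
        (profile,) = build_profiles([], [assay])
        assert profile.cfdna_c0 == 5.0
        assert profile.btmb_c0 is None
        assert profile.hvaf_c0 is None
        assert profile.vafsd_c0 is None

    def test_eot_fallback_for_on_treatment_slot(self):
        assays = [
            SampleAssay(patient_id="P1", sample_id="P1-C0", timepoint="C0",
                        cfdna_conc_ng_ml=10.0, ctdna_positive=True),
            SampleAssay(patient_id="P1", sample_id="P1-EOT", timepoint="EOT",
                        cfdna_conc_ng_ml=12.0, ctdna_positive=True),
        ]
        variants = (variants_with_vafs([0.02, 0.04], patient_id="P1",
                                       sample_id="P1-C0")
                    + variants_with_vafs([0.03, 0.06], patient_id="P1",
                                         sample_id="P1-EOT", timepoint="EOT"))
        (profile,) = build_profiles(variants, assays)
        assert profile.on_timepoint == "EOT"
        assert profile.cfdna_on == 12.0
        assert profile.ratio_cfdna == pytest.approx(1.2)
        assert profile.dynamics_cfdna == "increased"
        assert profile.ratio_hvaf == pytest.approx(6.0 / 4.0)

    def test_duplicate_sample_rejected(self):
        assays = [
            SampleAssay(patient_id="P1", sample_id="A", timepoint="C0"),
            SampleAssay(patient_id="P1", sample_id="B", timepoint="C0"),
        ]
        with pytest.raises(CohortValidationError, match="duplicate"):
            build_profiles([], assays)

    def test_eligibility_sets_nest(self, small_cohort, default_config):
        """VAFSD-evaluable within bTMB/hVAF-evaluable within cfDNA-evaluable."""
        from plasmabm.filtering import filter_somatic

        kept, _ = filter_somatic(small_cohort.variants, default_config)
        profiles = build_profiles(kept, small_cohort.assays, default_config)
        cfdna_set = {p.patient_id for p in profiles if p.cfdna_c0 is not None}
        btmb_set = {p.patient_id for p in profiles if p.btmb_c0 is not None}
        hvaf_set = {p.patient_id for p in profiles if p.hvaf_c0 is not None}
        vafsd_set = {p.patient_id for p in profiles if p.vafsd_c0 is not None}
        assert vafsd_set <= hvaf_set <= cfdna_set
        assert vafsd_set <= btmb_set <= cfdna_set
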