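"""Unit and property tests for the raw-measurement derived quantities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traffickpk import measures
from traffickpk.measures import (
    BloodSample,
    CapillaryDepletionSample,
    CellNumberInputs,
    InjectionCheck,
    LabelingBatch,
    TissueSample,
    cells_per_injected,
    corrected_cpm,
    derive_measures,
    fraction_over_pellet,
    labeling_qc,
    lymphocytes_per_gram,
    lymphocytes_per_organ,
    organ_sequestration_pct,
    parenchymal_fraction_pct,
    pct_inj_per_gram,
    pct_inj_per_gram_from_ratio,
    pct_inj_per_ml,
    tissue_rbc_ratio,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


def blood(cpm, vol=20.0, mouse="m1", t=30.0):
    return BloodSample(mouse_id=mouse, time_post_injection_min=t, pellet_cpm=cpm, pellet_volume_ul=vol)


def tissue(cpm, weight, mouse="m1", name="brain", t=30.0):
    return TissueSample(mouse_id=mouse, tissue_name=name, time_post_injection_min=t, wet_weight_g=weight, total_cpm=cpm)


class TestDoseFractions:
    @pytest.mark.parametrize(
        "pellet_cpm, vol, inj, expected",
        [
            (625.0, 20.0, 1_000_000.0, 3.125),  # log10 ~ 0.5
            (0.0, 20.0, 1_000_000.0, 0.0),
            (1_000_000.0, 1000.0, 1_000_000.0, 100.0),  # whole dose in 1 ml
        ],
    )
    def test_pct_inj_per_ml(self, pellet_cpm, vol, inj, expected):
        value = pct_inj_per_ml(blood(pellet_cpm, vol), InjectionCheck(inj))
        assert value == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "cpm, inj, weight, expected",
        [
            (13.5, 150_000.0, 0.45, 0.02),
            (0.0, 150_000.0, 0.45, 0.0),
            (150_000.0, 150_000.0, 1.0, 100.0),
        ],
    )
    def test_pct_inj_per_gram(self, cpm, inj, weight, expected):
        value = pct_inj_per_gram(tissue(cpm, weight), InjectionCheck(inj))
        assert value == pytest.approx(expected, rel=1e-12)

    def test_zero_injected_cpm_rejected(self):
        with pytest.raises(ValueError):
            InjectionCheck(0.0)
        with pytest.raises(ValueError):
            blood(100.0, vol=0.0)


class TestUptakeRatio:
    @pytest.mark.parametrize(
        "cpm, weight, pellet_cpm, vol, expected",
        [
            (75_000.0, 0.5, 300_000.0, 20.0, 10.0),  # 150k cpm/g over 15k cpm/ul
            (150.0, 1.0, 3000.0, 20.0, 1.0),  # equal concentrations
            (0.0, 0.5, 300_000.0, 20.0, 0.0),
        ],
    )
    def test_examples(self, cpm, weight, pellet_cpm, vol, expected):
        r = tissue_rbc_ratio(tissue(cpm, weight), blood(pellet_cpm, vol))
        assert r == pytest.approx(expected, rel=1e-12)

    def test_cross_mouse_requires_override(self):
        t = tissue(100.0, 0.5, mouse="m1")
        b = blood(500.0, mouse="m2")
        with pytest.raises(ValueError, match="mouse"):
            tissue_rbc_ratio(t, b)
        assert tissue_rbc_ratio(t, b, allow_cross_mouse=True) > 0

    def test_zero_pellet_concentration_errors(self):
        with pytest.raises(ValueError, match="zero"):
            tissue_rbc_ratio(tissue(10.0, 0.5), blood(0.0))

    @given(
        tissue_cpm=positive,
        weight=st.floats(min_value=0.01, max_value=10.0),
        pellet_cpm=positive,
        vol=st.floats(min_value=1.0, max_value=100.0),
        inj=positive,
    )
    @settings(max_examples=100, derandomize=True)
    def test_ratio_times_blood_level_identity(self, tissue_cpm, weight, pellet_cpm, vol, inj):
        """%Inj/g via the ratio x blood-level identity equals the direct formula."""
        t = tissue(tissue_cpm, weight)
        b = blood(pellet_cpm, vol)
        c = InjectionCheck(inj)
        direct = pct_inj_per_gram(t, c)
        via_ratio = pct_inj_per_gram_from_ratio(tissue_rbc_ratio(t, b), pct_inj_per_ml(b, c))
        assert via_ratio == pytest.approx(direct, rel=1e-12)

    @given(
        tissue_cpm=positive,
        pellet_cpm=positive,
        gain=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_detector_gain_invariance(self, tissue_cpm, pellet_cpm, gain):
        """Rescaling every cpm by a common detector gain leaves ratios unchanged."""
        r1 = tissue_rbc_ratio(tissue(tissue_cpm, 0.4), blood(pellet_cpm))
        r2 = tissue_rbc_ratio(tissue(tissue_cpm * gain, 0.4), blood(pellet_cpm * gain))
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_from_ratio_examples(self):
        assert pct_inj_per_gram_from_ratio(10.0, 2.0) == pytest.approx(0.02)
        assert pct_inj_per_gram_from_ratio(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            pct_inj_per_gram_from_ratio(-1.0, 2.0)


class TestCapillaryDepletion:
    def sample(self, p_cpm=1425.0, c_cpm=335.0, weight=0.1, conc=500.0):
        return CapillaryDepletionSample(
            cortex_weight_g=weight,
            parenchyma_cpm=p_cpm,
            capillary_cpm=c_cpm,
            rbc_pellet_concentration=conc,
        )

    def test_fraction_over_pellet(self):
        assert fraction_over_pellet(self.sample(), "parenchyma") == pytest.approx(28.5)
        assert fraction_over_pellet(self.sample(c_cpm=0.0), "capillary") == 0.0
        with pytest.raises(ValueError):
            fraction_over_pellet(self.sample(), "serum")

    def test_scale_invariance(self):
        base = fraction_over_pellet(self.sample(), "parenchyma")
        doubled = fraction_over_pellet(self.sample(p_cpm=2850.0, conc=1000.0), "parenchyma")
        assert doubled == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize(
        "p, c, expected",
        [
            (28.5, 6.7, 81.0),  # 100*28.5/(28.5+6.7) = 80.97, prints as 81
            (0.57, 0.82, 41.0),
            (3.3, 3.3, 50.0),
        ],
    )
    def test_parenchymal_fraction(self, p, c, expected):
        assert parenchymal_fraction_pct(p, c) == pytest.approx(expected, abs=0.5)

    @given(p=positive, c=positive)
    @settings(max_examples=100, derandomize=True)
    def test_fractions_complementary(self, p, c):
        total = parenchymal_fraction_pct(p, c) + parenchymal_fraction_pct(c, p)
        assert total == pytest.approx(100.0, abs=1e-9)
        assert 0.0 <= parenchymal_fraction_pct(p, c) <= 100.0

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            parenchymal_fraction_pct(0.0, 0.0)


class TestCellNumbers:
    @pytest.mark.parametrize(
        "cells_ul, hct, ratio, per_gram",
        [(6000.0, 0.40, 10.0, 150_000.0), (6000.0, 0.40, 1.0, 15_000.0), (6000.0, 0.40, 0.0, 0.0)],
    )
    def test_per_gram(self, cells_ul, hct, ratio, per_gram):
        inputs = CellNumberInputs(cells_ul, hct, ratio)
        assert lymphocytes_per_gram(inputs) == pytest.approx(per_gram)

    @pytest.mark.parametrize("weight, expected", [(0.45, 67_500.0), (0.0, 0.0), (1.0, 150_000.0)])
    def test_per_organ(self, weight, expected):
        inputs = CellNumberInputs(6000.0, 0.40, 10.0, organ_weight_g=weight)
        assert lymphocytes_per_organ(inputs) == pytest.approx(expected)

    def test_hematocrit_bounds(self):
        for hct in (0.0, 1.0, 1.3, -0.1):
            with pytest.raises(ValueError):
                CellNumberInputs(6000.0, hct, 10.0)

    @pytest.mark.parametrize("pct_g, expected", [(0.02, 5000.0), (100.0, 1.0), (0.01, 10_000.0)])
    def test_cells_per_injected(self, pct_g, expected):
        assert cells_per_injected(pct_g) == pytest.approx(expected)

    def test_cells_per_injected_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cells_per_injected(0.0)

    @pytest.mark.parametrize(
        "pct_g, weight, expected", [(20.0, 0.123, 2.46), (0.0, 0.123, 0.0), (15.0, 0.123, 1.845)]
    )
    def test_organ_sequestration(self, pct_g, weight, expected):
        assert organ_sequestration_pct(pct_g, weight) == pytest.approx(expected)


class TestLabelingQC:
    def test_specific_activity(self):
        qc = labeling_qc(LabelingBatch(4_797_000.0, 90_000.0, 90.0, 10.0))
        assert qc.specific_activity_cpm_per_cell == pytest.approx(53.3)

    def test_incorporation_boundary_passes_default(self):
        qc = labeling_qc(LabelingBatch(1000.0, 100.0, 90.0, 10.0))
        assert qc.incorporation == pytest.approx(0.90)
        assert qc.passed

    def test_full_incorporation(self):
        qc = labeling_qc(LabelingBatch(1000.0, 100.0, 500.0, 0.0))
        assert qc.incorporation == 1.0 and qc.passed

    def test_below_threshold_fails(self):
        qc = labeling_qc(LabelingBatch(1000.0, 100.0, 80.0, 20.0))
        assert not qc.passed

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            labeling_qc(LabelingBatch(1000.0, 100.0, 0.0, 0.0))


def test_corrected_cpm_clamps_at_zero(caplog):
    assert corrected_cpm(100.0, 30.0) == 70.0
    with caplog.at_level("WARNING"):
        assert corrected_cpm(10.0, 30.0) == 0.0
    assert "clamping" in caplog.text


class TestDeriveMeasures:
    def study_frame(self):
        rows = [
            # mouse m1: check + blood + brain
            dict(mouse_id="m1", group_cells="CD1", group_mouse="CD1", time_min=0.0,
                 sample_type="injection_check", tissue_name="", cpm=150_000.0,
                 weight_g=np.nan, volume_ul=200.0, cells_injected=2814),
            dict(mouse_id="m1", group_cells="CD1", group_mouse="CD1", time_min=30.0,
                 sample_type="blood", tissue_name="", cpm=600.0,
                 weight_g=np.nan, volume_ul=20.0, cells_injected=np.nan),
            dict(mouse_id="m1", group_cells="CD1", group_mouse="CD1", time_min=30.0,
                 sample_type="tissue", tissue_name="brain", cpm=135.0,
                 weight_g=0.45, volume_ul=np.nan, cells_injected=np.nan),
            # mouse m2 has no blood sample: must be excluded
            dict(mouse_id="m2", group_cells="CD1", group_mouse="CD1", time_min=0.0,
                 sample_type="injection_check", tissue_name="", cpm=150_000.0,
                 weight_g=np.nan, volume_ul=200.0, cells_injected=2814),
            dict(mouse_id="m2", group_cells="CD1", group_mouse="CD1", time_min=30.0,
                 sample_type="tissue", tissue_name="brain", cpm=140.0,
                 weight_g=0.44, volume_ul=np.nan, cells_injected=np.nan),
        ]
        return pd.DataFrame(rows)

    def test_values_match_scalar_operations(self):
        derived = derive_measures(self.study_frame())
        b = blood(600.0, 20.0)
        c = InjectionCheck(150_000.0)
        t = tissue(135.0, 0.45)
        row = derived[(derived.mouse_id == "m1") & (derived.tissue_name == "brain")].iloc[0]
        assert row.pct_inj_per_ml == pytest.approx(pct_inj_per_ml(b, c))
        assert row.pct_inj_per_g == pytest.approx(pct_inj_per_gram(t, c))
        assert row.tissue_rbc_ratio_ul_per_g == pytest.approx(tissue_rbc_ratio(t, b))

    def test_mouse_without_blood_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            derived = derive_measures(self.study_frame())
        assert "m2" not in set(derived.mouse_id)
        assert "excluding" in caplog.text

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            derive_measures(self.study_frame().drop(columns=["cpm"]))

    def test_unknown_sample_type_rejected(self):
        df = self.study_frame()
        df.loc[0, "sample_type"] = "serum"
        with pytest.raises(ValueError, match="sample_type"):
            derive_measures(df)
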