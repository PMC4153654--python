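"""Ratio computation, median normalization, aggregation and significance."""

import math

import numpy as np
import pytest

from phosphoquant import (
    Modification,
    NormalizationFactors,
    PsmRecord,
    QuantifiedSite,
    RatioSet,
    aggregate,
    apply_filters,
    call_significance,
    compute_normalization,
    compute_ratios,
    normalize,
)
from phosphoquant.quantification import QuantificationError
from phosphoquant.synthetic_data import SimConfig, generate_proteome, generate_psm_table


def quant_psm(psm_id="x", light=None, medium=None, heavy=None,
              phospho_pos=None, probs=None, sequence="SAMPYLER",
              rml=None, rhl=None):
    mods = []
    if phospho_pos is not None:
        mods.append(Modification(position=phospho_pos, kind="phospho"))
    return PsmRecord(
        psm_id=psm_id, sequence=sequence, modifications=mods,
        protein_accession="P1", ion_score=50.0,
        channel_quantity={"light": light, "medium": medium, "heavy": heavy},
        ratio_medium_light=rml, ratio_heavy_light=rhl,
        site_probabilities=probs or {},
    )


FACTORS_1 = NormalizationFactors(1.0, 1.0, 10)


def test_mixing_style_quantities_give_expected_ratios():
    ratios = compute_ratios(quant_psm(light=100, medium=138, heavy=235))
    assert ratios.medium_over_light == pytest.approx(1.38)
    assert ratios.heavy_over_light == pytest.approx(2.35)


def test_missing_light_denominator_voids_both_ratios():
    ratios = compute_ratios(quant_psm(light=None, medium=138, heavy=235))
    assert ratios.medium_over_light is None
    assert ratios.heavy_over_light is None
    assert not ratios.any_present


def test_equal_channels_give_unit_ratios():
    ratios = compute_ratios(quant_psm(light=100, medium=100, heavy=100))
    assert ratios.medium_over_light == pytest.approx(1.0)
    assert ratios.heavy_over_light == pytest.approx(1.0)


def test_precomputed_ratio_columns_take_precedence():
    ratios = compute_ratios(
        quant_psm(light=100, medium=200, heavy=300, rml=0.266, rhl=0.361)
    )
    assert ratios.medium_over_light == pytest.approx(0.266)
    assert ratios.heavy_over_light == pytest.approx(0.361)


def test_normalization_factor_is_sorted_middle_element():
    psms = [
        quant_psm(psm_id=f"n{i}", light=100, medium=100 * m, heavy=100 * h)
        for i, (m, h) in enumerate([(1.0, 2.0), (1.38, 2.35), (2.0, 3.0)])
    ]
    factors = compute_normalization(psms, min_nonphospho=3)
    assert factors.median_medium_over_light == pytest.approx(1.38)
    assert factors.median_heavy_over_light == pytest.approx(2.35)


def test_unit_ratios_make_normalization_a_noop():
    psms = [
        quant_psm(psm_id=f"n{i}", light=100, medium=100, heavy=100)
        for i in range(5)
    ]
    factors = compute_normalization(psms, min_nonphospho=5)
    assert factors.median_medium_over_light == pytest.approx(1.0)


def test_phosphopeptides_excluded_from_normalization():
    psms = [
        quant_psm(psm_id=f"n{i}", light=100, medium=138, heavy=235)
        for i in range(5)
    ] + [
        quant_psm(psm_id="p", light=100, medium=999, heavy=999,
                  phospho_pos=5, probs={5: 99.0})
    ]
    factors = compute_normalization(psms, min_nonphospho=5)
    assert factors.n_nonphospho_used == 5
    assert factors.median_medium_over_light == pytest.approx(1.38)


def test_too_few_nonphospho_psms_is_fatal():
    psms = [quant_psm(psm_id="n0", light=100, medium=138, heavy=235)]
    with pytest.raises(QuantificationError, match="min_nonphospho"):
        compute_normalization(psms, min_nonphospho=10)


def test_generator_recovers_mixing_factors_at_zero_noise():
    cfg = SimConfig(seed=5, n_proteins=12, n_nonphospho_psms=101,
                    n_phospho_sites=5, psms_per_site=1,
                    ratio_noise_sigma_log2=0.0, frac_missing_channel=0.0,
                    frac_decoy=0.0)
    rng = np.random.default_rng(5)
    proteome = generate_proteome(cfg, rng)
    records, _ = generate_psm_table(cfg, proteome, rng)
    factors = compute_normalization(records)
    assert factors.median_medium_over_light == pytest.approx(1.38, abs=1e-9)
    assert factors.median_heavy_over_light == pytest.approx(2.35, abs=1e-9)


def test_normalize_divides_by_channel_factor():
    factors = NormalizationFactors(1.38, 2.35, 20)
    out = normalize(RatioSet(2.76, None), factors)
    assert out.medium_over_light == pytest.approx(2.0)
    assert out.heavy_over_light is None
    # raw ratio equal to the factor lands on Log2 = 0
    out = normalize(RatioSet(1.38, 2.35), factors)
    assert math.log2(out.medium_over_light) == pytest.approx(0.0)
    # unit factors are the identity
    out = normalize(RatioSet(0.7, 1.4), FACTORS_1)
    assert (out.medium_over_light, out.heavy_over_light) == (0.7, 1.4)


def test_single_psm_aggregation_matches_log2_of_ratio():
    psm = quant_psm(light=1000, medium=266, phospho_pos=5, probs={5: 99.0})
    (site,) = aggregate([psm], FACTORS_1)
    assert site.log2_ns_wt == pytest.approx(math.log2(0.266), abs=1e-9)
    assert site.log2_ns_wt == pytest.approx(-1.91, abs=0.005)
    assert site.log2_ls_wt is None
    assert site.n_psms == 1


def test_aggregation_uses_arithmetic_mean_of_ratios():
    r = 4.0
    psms = [
        quant_psm(psm_id="a", light=100, medium=100 * r,
                  phospho_pos=5, probs={5: 99.0}),
        quant_psm(psm_id="b", light=100, medium=100 / r,
                  phospho_pos=5, probs={5: 99.0}),
    ]
    (site,) = aggregate(psms, FACTORS_1)
    assert site.log2_ns_wt == pytest.approx(math.log2((r + 1 / r) / 2))
    assert site.n_psms == 2


def test_median_aggregation_is_config_selectable():
    psms = [
        quant_psm(psm_id=str(i), light=100, medium=100 * m,
                  phospho_pos=5, probs={5: 99.0})
        for i, m in enumerate([1.0, 2.0, 16.0])
    ]
    (site,) = aggregate(psms, FACTORS_1, method="median")
    assert site.log2_ns_wt == pytest.approx(1.0)


def test_localized_evidence_supersedes_ambiguous_psms():
    psms = [
        quant_psm(psm_id="loc", light=100, medium=400,
                  phospho_pos=5, probs={5: 98.0, 1: 2.0}),
        quant_psm(psm_id="amb", light=100, medium=6400,
                  phospho_pos=5, probs={5: 60.0, 1: 40.0}),
    ]
    (site,) = aggregate(psms, FACTORS_1)
    assert site.n_psms == 1
    assert site.log2_ns_wt == pytest.approx(2.0)
    assert not site.is_ambiguous


def test_all_ambiguous_evidence_pools_into_one_ambiguous_site():
    psms = [
        quant_psm(psm_id="a", light=100, medium=200,
                  phospho_pos=5, probs={5: 60.0, 1: 40.0}),
        quant_psm(psm_id="b", light=100, medium=800,
                  phospho_pos=5, probs={5: 55.0, 1: 45.0}),
    ]
    (site,) = aggregate(psms, FACTORS_1)
    assert site.is_ambiguous
    assert site.n_psms == 2
    assert site.log2_ns_wt == pytest.approx(math.log2(5.0))  # mean(2, 8)
    assert site.site_source_label == "ambiguous"


def test_significance_is_strict_at_the_log2_boundary():
    def call(ns, ls):
        s = QuantifiedSite(
            protein_name="p", accession_field="P1", peptide_sequence="PEP",
            log2_ns_wt=ns, log2_ls_wt=ls,
        )
        s = call_significance(s)
        return s.significant_ns, s.significant_ls

    assert call(-1.91, -1.47) == (True, True)
    assert call(1.0, -1.0) == (False, False)  # strict ">"
    assert call(0.0, 0.0) == (False, False)
    assert call(None, 1.01) == (False, True)  # missing is never significant


def _pipeline_log2s(records, min_nonphospho=10):
    accepted, _ = apply_filters(records)
    factors = compute_normalization(accepted, min_nonphospho)
    sites = aggregate(accepted, factors)
    return {
        (s.accession_field, s.peptide_sequence,
         tuple(sorted(x.peptide_position for x in s.sites))): (
            s.log2_ns_wt, s.log2_ls_wt)
        for s in sites
    }


def test_normalized_nonphospho_median_log2_is_zero():
    cfg = SimConfig(seed=9, n_proteins=15, n_nonphospho_psms=200,
                    n_phospho_sites=10, psms_per_site=2)
    rng = np.random.default_rng(9)
    proteome = generate_proteome(cfg, rng)
    records, _ = generate_psm_table(cfg, proteome, rng)
    accepted, _ = apply_filters(records)
    factors = compute_normalization(accepted)
    from statistics import median

    for channel in ("medium_over_light", "heavy_over_light"):
        values = []
        for psm in accepted:
            if psm.is_phosphopeptide:
                continue
            r = normalize(compute_ratios(psm), factors)
            v = getattr(r, channel)
            if v is not None:
                values.append(v)
        assert abs(math.log2(median(values))) < 1e-9


def test_scale_invariance_under_per_channel_rescaling():
    cfg = SimConfig(seed=13, n_proteins=15, n_nonphospho_psms=150,
                    n_phospho_sites=12, psms_per_site=3)
    rng = np.random.default_rng(13)
    proteome = generate_proteome(cfg, rng)
    records, _ = generate_psm_table(cfg, proteome, rng)
    baseline = _pipeline_log2s(records)

    c = 7.3
    scaled = []
    for psm in records:
        q = dict(psm.channel_quantity)
        if q["medium"] is not None:
            q["medium"] = q["medium"] * c
        scaled.append(
            PsmRecord(
                psm_id=psm.psm_id, sequence=psm.sequence,
                modifications=psm.modifications,
                protein_accession=psm.protein_accession,
                is_decoy=psm.is_decoy, rank=psm.rank,
                ion_score=psm.ion_score, mass_error_ppm=psm.mass_error_ppm,
                channel_quantity=q,
                site_probabilities=psm.site_probabilities,
            )
        )
    rescaled = _pipeline_log2s(scaled)
    assert set(baseline) == set(rescaled)
    for key, (ns, ls) in baseline.items():
        ns2, ls2 = rescaled[key]
        if ns is not None:
            assert ns2 == pytest.approx(ns, abs=1e-9)
        if ls is not None:
            assert ls2 == pytest.approx(ls, abs=1e-9)
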