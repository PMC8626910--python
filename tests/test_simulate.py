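"""Generator tests: cohort composition, assay structure, planted truth."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csfpanel as cp
from csfpanel.simulate import (_sample_ages, default_panel, read_matrix,
                               read_samples, write_matrix, write_samples)


def test_default_cohort_matches_design():
    cohort = cp.generate_cohort(cp.CohortSpec(seed=3))
    assert len(cohort) == 221
    counts = cohort["group"].value_counts().to_dict()
    assert counts == {"PMC": 98, "NC": 76, "AMC": 47}
    amc = cohort[cohort["group"] == "AMC"]
    assert amc["phenotype"].value_counts().to_dict() == {
        "bvFTD": 32, "PPA": 7, "ALS": 4, "PSP": 2, "FTD-ALS": 1, "D-NOS": 1}
    assert amc["gene"].value_counts().to_dict() == {
        "C9orf72": 27, "GRN": 12, "MAPT": 7, "TBK1": 1}
    pmc = cohort[cohort["group"] == "PMC"]
    assert pmc["gene"].value_counts().to_dict() == {
        "C9orf72": 41, "GRN": 38, "MAPT": 16, "TBK1": 3}
    assert cohort["sample_id"].is_unique
    # ages stay inside the configured ranges
    for g, (_, _, lo, hi) in cp.CohortSpec().age_params.items():
        ages = cohort.loc[cohort["group"] == g, "age"]
        assert ages.between(lo, hi).all()


def test_cohort_deterministic_given_seed():
    a = cp.generate_cohort(cp.CohortSpec(seed=5))
    b = cp.generate_cohort(cp.CohortSpec(seed=5))
    pd.testing.assert_frame_equal(a, b)
    c = cp.generate_cohort(cp.CohortSpec(seed=6))
    assert not a["age"].equals(c["age"])


def test_empty_cohort_is_allowed():
    spec = cp.CohortSpec(group_sizes={"AMC": 0, "PMC": 0, "NC": 0},
                         gene_split={"AMC": {}, "PMC": {}},
                         phenotype_split={})
    assert len(cp.generate_cohort(spec)) == 0


def test_inconsistent_split_names_offending_field():
    spec = cp.CohortSpec()
    spec.gene_split["PMC"]["C9orf72"] = 40  # no longer sums to 98
    with pytest.raises(ValueError, match="gene_split\\[PMC\\]"):
        cp.generate_cohort(spec)
    spec2 = cp.CohortSpec()
    spec2.phenotype_split["bvFTD"] = 31
    with pytest.raises(ValueError, match="phenotype_split"):
        cp.generate_cohort(spec2)


def test_truncated_age_sampler_hits_configured_mean():
    # the parent location is calibrated so the truncated mean equals the
    # configured group mean despite the asymmetric range
    rng = np.random.default_rng(0)
    ages = _sample_ages(rng, 10_000, 62.0, 9.0, 38.0, 76.0)
    assert abs(ages.mean() - 62.0) < 0.5
    assert ages.min() >= 38.0 and ages.max() <= 76.0


def test_assay_positive_and_deterministic():
    cohort = cp.generate_cohort(cp.CohortSpec(seed=1))
    m1, s1, t1 = cp.generate_assay(cohort, cp.EffectSpec(), cp.AssaySpec(),
                                   seed=9)
    m2, s2, _ = cp.generate_assay(cohort, cp.EffectSpec(), cp.AssaySpec(),
                                  seed=9)
    assert (m1.to_numpy() > 0).all()
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(s1, s2)
    assert t1.seed == 9
    assert sorted(s1["readout_order"]) == list(range(1, 222))


def test_null_configuration_signal_is_exp_latent():
    # no effects, artefacts or baseline: signal = exp(latent), so the log
    # matrix is standard-normal-ish and group means coincide
    spec = cp.CohortSpec(seed=2)
    cohort = cp.generate_cohort(spec)
    eff = cp.EffectSpec(planted_effects={}, correlation_blocks=[],
                        baseline_log_mean=0.0, baseline_log_sd=1.0)
    assay = cp.AssaySpec(plate_offset_sd=0.0, drift_slope=0.0, noise_sd=0.0)
    m, s, _ = cp.generate_assay(cohort, eff, assay, seed=2)
    logm = np.log(m.to_numpy())
    assert (m.to_numpy() > 0).all()
    assert abs(logm.mean()) < 0.02
    assert abs(logm.std() - 1.0) < 0.02
    grp = s["group"].to_numpy()
    gap = logm[grp == "AMC"].mean() - logm[grp != "AMC"].mean()
    assert abs(gap) < 0.05


def test_block_spearman_matches_gaussian_rank_formula():
    # latent common-rho block: large-n Spearman converges to
    # 6/pi * asin(rho/2)
    rho = 0.85
    n = 5000
    spec = cp.CohortSpec(
        group_sizes={"AMC": 0, "PMC": 0, "NC": n},
        gene_split={"AMC": {}, "PMC": {}}, phenotype_split={},
        seed=4)
    eff = cp.EffectSpec(planted_effects={},
                        correlation_blocks=[(["NPTX2", "VGF", "PTPRN2"], rho)])
    assay = cp.AssaySpec(plate_offset_sd=0.0, drift_slope=0.0, noise_sd=0.0)
    m, _, _ = cp.generate_assay(spec and cp.generate_cohort(spec), eff, assay,
                                seed=4)
    expected = 6 / np.pi * np.arcsin(rho / 2)
    got = stats.spearmanr(m["NPTX2"], m["VGF"]).statistic
    assert abs(got - expected) < 0.03


def test_drift_injection_correlates_with_readout_order():
    spec = cp.CohortSpec(group_sizes={"AMC": 0, "PMC": 0, "NC": 800},
                         gene_split={"AMC": {}, "PMC": {}}, phenotype_split={},
                         seed=5)
    cohort = cp.generate_cohort(spec)
    eff = cp.EffectSpec(planted_effects={}, correlation_blocks=[],
                        baseline_log_sd=0.05)
    assay = cp.AssaySpec(plate_offset_sd=0.0, drift_slope=0.5, noise_sd=0.0)
    m, s, _ = cp.generate_assay(cohort, eff, assay, seed=5)
    order = s["readout_order"].to_numpy()
    for pr in m.columns[:20]:
        rho = stats.spearmanr(order, m[pr]).statistic
        assert rho > 0.5


def test_planted_truth_matches_brute_scan():
    eff = cp.EffectSpec()
    # randomize some shifts, including explicit zeros
    eff.planted_effects = {
        "affected": {"NEFM": 1.0, "CTSS": 0.0, "SPP1": -0.7},
        "grn_carrier": {"GRN": -2.0},
    }
    cohort = cp.generate_cohort(cp.CohortSpec(seed=6))
    _, _, truth = cp.generate_assay(cohort, eff, cp.AssaySpec(), seed=6)
    expected = sorted(pr for pr, sh in eff.planted_effects["affected"].items()
                      if sh != 0.0)
    assert cp.planted_truth(truth, "affected") == expected
    assert cp.planted_truth(truth, "grn_carrier") == ["GRN"]
    with pytest.raises(ValueError, match="unknown contrast"):
        cp.planted_truth(truth, "no_such_contrast")


def test_default_truth_is_the_quartet():
    cohort = cp.generate_cohort(cp.CohortSpec(seed=7))
    _, _, truth = cp.generate_assay(cohort, cp.EffectSpec(), cp.AssaySpec(),
                                    seed=7)
    assert cp.planted_truth(truth) == ["AQP4", "NEFM", "NPTX2", "VGF"]
    shifts = {r["protein"]: r["shift"] for r in truth.planted
              if r["contrast"] == "affected"}
    assert shifts["NEFM"] > 0 and shifts["AQP4"] > 0
    assert shifts["NPTX2"] < 0 and shifts["VGF"] < 0


def test_zero_effects_truth_empty():
    cohort = cp.generate_cohort(cp.CohortSpec(seed=8))
    _, _, truth = cp.generate_assay(
        cohort, cp.EffectSpec(planted_effects={}), cp.AssaySpec(), seed=8)
    assert cp.planted_truth(truth) == []


def test_non_psd_block_rejected():
    eff = cp.EffectSpec(correlation_blocks=[(["NEFM", "NPTX2", "VGF"], -0.9)])
    with pytest.raises(ValueError, match="non-positive-semi-definite"):
        eff.validate()


def test_writers_round_trip(tmp_path, default_dataset):
    matrix, samples, truth = default_dataset
    write_matrix(matrix, tmp_path / "m.tsv")
    write_samples(samples, tmp_path / "s.tsv")
    truth.to_json(tmp_path / "t.json")
    m2 = read_matrix(tmp_path / "m.tsv")
    s2 = read_samples(tmp_path / "s.tsv")
    t2 = cp.TruthTable.from_json(tmp_path / "t.json")
    np.testing.assert_allclose(matrix.to_numpy(), m2.to_numpy(), rtol=1e-12)
    assert list(m2.columns) == list(matrix.columns)
    assert s2["sample_id"].tolist() == samples["sample_id"].tolist()
    np.testing.assert_allclose(s2["age"], samples["age"], rtol=1e-12)
    assert t2.planted == truth.planted
    assert t2.seed == truth.seed
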