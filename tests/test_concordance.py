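"""Agreement statistics, zeta differences, bootstrap and the NI decision."""

import numpy as np
import pytest

from cdxval.calls import filter_invalid
from cdxval.concordance import (
    PrevalenceSpec,
    ZetaInterval,
    ZetaSet,
    all_agreements,
    bootstrap_zeta_ci,
    newcombe10_paired_diff_ci,
    noninferiority_decision,
    pairwise_agreement,
    prevalence_adjust,
    zeta_differences,
)
from cdxval.intervals import newcombe10_ci
from cdxval.simulate import ConcordanceSimSpec, simulate_concordance_cohort

from conftest import make_table, table_from_counts


# ---------------------------------------------------------------------------
# brute-force row-loop oracle, independent of the count-space implementation


def brute_agreement(table, ref, tst, polarity):
    target = {"PPA": "positive", "NPA": "negative"}[polarity]
    num = den = 0
    for _, row in table.frame.iterrows():
        if row[ref] == target:
            den += 1
            if row[tst] == target:
                num += 1
    return num, den


def test_pairwise_agreement_matches_brute_force(seven_row_table):
    num, den = brute_agreement(seven_row_table, "ccd1", "fcd", "PPA")
    assert (num, den) == (3, 5)
    est = pairwise_agreement(seven_row_table, "ccd1", "fcd", "PPA")
    assert (est.numerator, est.denominator) == (3, 5)
    assert est.estimate == pytest.approx(0.6)


def test_all_agreements_match_brute_force_on_random_table():
    table, _ = simulate_concordance_cohort(
        ConcordanceSimSpec(n_samples=60, ccd_sensitivity=0.8, ccd_specificity=0.8, seed=9)
    )
    ags = all_agreements(table)
    for pol in ("PPA", "NPA"):
        for ref, tst, key in [
            ("ccd1", "ccd2", "C1C2"),
            ("ccd1", "fcd", "C1F"),
            ("ccd2", "ccd1", "C2C1"),
            ("ccd2", "fcd", "C2F"),
        ]:
            num, den = brute_agreement(table, ref, tst, pol)
            est = ags[f"{pol}_{key}"]
            assert (est.numerator, est.denominator) == (num, den)


def test_table4_style_rendering():
    # the large-cohort validation rows print exact (Clopper-Pearson) intervals
    est = pairwise_agreement(
        table_from_counts(409, 444), "ccd1", "fcd", "PPA", ci_method="clopper_pearson"
    )
    assert est.render() == "92.1% (89.2, 94.4) 409/444"
    wilson = pairwise_agreement(table_from_counts(409, 444), "ccd1", "fcd", "PPA")
    assert wilson.render() == "92.1% (89.2, 94.3) 409/444"


def test_identical_arms_give_perfect_agreement():
    rows = [("positive",) * 3] * 25 + [("negative",) * 3] * 25
    table = make_table(rows)
    for pol in ("PPA", "NPA", "OPA"):
        est = pairwise_agreement(table, "ccd1", "fcd", pol)
        assert est.estimate == 1.0


def test_zero_denominator_raises():
    table = make_table([("negative", "negative", "negative")] * 3)
    with pytest.raises(ValueError, match="no reference-positive"):
        pairwise_agreement(table, "ccd1", "fcd", "PPA")


def test_opa_counts_both_sides(seven_row_table):
    est = pairwise_agreement(seven_row_table, "ccd1", "fcd", "OPA")
    # rows where ccd1 == fcd: hand count 4 of 7
    assert (est.numerator, est.denominator) == (4, 7)


# ---------------------------------------------------------------------------
# zetas


def test_zetas_vanish_when_fcd_copies_a_comparator_replicate():
    """With FCD an exact copy of CCD1, agreement of FCD with CCD2 equals the
    replicate-to-replicate agreement, so the CCD2-referenced zetas are 0
    exactly (by the defining subtraction) even with imperfect replicate
    concordance."""
    rows = [
        ("positive", "positive", "positive"),
        ("positive", "negative", "positive"),
        ("negative", "negative", "negative"),
        ("negative", "positive", "negative"),
        ("positive", "positive", "positive"),
    ]
    zs = zeta_differences(make_table(rows))
    assert zs["zeta_ppa2"].point == 0.0
    assert zs["zeta_npa2"].point == 0.0
    # with perfect replicate concordance as well, all four are 0
    rows = [("positive",) * 3] * 3 + [("negative",) * 3] * 4
    zs = zeta_differences(make_table(rows))
    assert all(zs[n].point == 0.0 for n in ("zeta_ppa1", "zeta_ppa2", "zeta_npa1", "zeta_npa2"))


def test_zetas_match_brute_force_hand_count():
    # 12-row fixture with a single CCD2/FCD discordance
    rows = [("positive",) * 3] * 6 + [("negative",) * 3] * 5
    rows.append(("positive", "positive", "negative"))
    table = make_table(rows)
    comp = {}
    for pol in ("PPA", "NPA"):
        for ref, tst, key in [
            ("ccd1", "ccd2", "C1C2"),
            ("ccd1", "fcd", "C1F"),
            ("ccd2", "ccd1", "C2C1"),
            ("ccd2", "fcd", "C2F"),
        ]:
            num, den = brute_agreement(table, ref, tst, pol)
            comp[f"{pol}_{key}"] = num / den
    zs = zeta_differences(table)
    assert zs["zeta_ppa1"].point == pytest.approx(comp["PPA_C1C2"] - comp["PPA_C1F"])
    assert zs["zeta_ppa2"].point == pytest.approx(comp["PPA_C2C1"] - comp["PPA_C2F"])
    assert zs["zeta_npa1"].point == pytest.approx(comp["NPA_C1C2"] - comp["NPA_C1F"])
    assert zs["zeta_npa2"].point == pytest.approx(comp["NPA_C2C1"] - comp["NPA_C2F"])
    assert zs["zeta_ppa1"].point == pytest.approx(1.0 - 6 / 7)


def test_zeta_simple_subtraction():
    rows = [("positive",) * 3] * 97
    rows += [("positive", "positive", "negative")] * 3
    rows += [("negative",) * 3] * 10
    zs = zeta_differences(make_table(rows))
    # ccd2 copies ccd1 in the fixture: PPA_C1C2 = 1, PPA_C1F = 0.97
    assert zs["zeta_ppa1"].point == pytest.approx(0.03)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_all_concordant_degenerate_ci():
    rows = [("positive",) * 3] * 10 + [("negative",) * 3] * 10
    zs = bootstrap_zeta_ci(make_table(rows), n_boot=200, seed=5)
    for name in ("zeta_ppa1", "zeta_ppa2", "zeta_npa1", "zeta_npa2"):
        assert zs[name].ci_low == 0.0
        assert zs[name].ci_high == 0.0


def test_bootstrap_reproducible_under_seed():
    table, _ = simulate_concordance_cohort(ConcordanceSimSpec(n_samples=20, seed=3))
    table = filter_invalid(table)
    a = bootstrap_zeta_ci(table, n_boot=200, seed=11)
    b = bootstrap_zeta_ci(table, n_boot=200, seed=11)
    assert a == b
    c = bootstrap_zeta_ci(table, n_boot=200, seed=12)
    assert a != c


def test_bootstrap_requires_min_replicates(seven_row_table):
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_zeta_ci(seven_row_table, n_boot=1)


def test_bootstrap_undefined_replicates_counted_and_guarded():
    # a 2-row table loses its only positive in ~25% of resamples; those
    # replicates are skipped and counted, and a majority of them aborts
    rows = [("positive", "positive", "positive")] + [("negative",) * 3] * 1
    table = make_table(rows)
    zs = bootstrap_zeta_ci(table, n_boot=400, seed=0)
    assert zs.n_undefined_replicates > 0
    with pytest.raises(ValueError, match="unstable"):
        bootstrap_zeta_ci(table, n_boot=4, seed=13)


# ---------------------------------------------------------------------------
# Newcombe paired difference on tables


def test_paired_diff_identical_arms():
    rows = [("positive",) * 3] * 12 + [("negative",) * 3] * 20
    diff, low, high = newcombe10_paired_diff_ci(make_table(rows), "ccd1", "fcd", "PPA")
    assert diff == 0.0
    assert low < 0 < high


def test_paired_diff_matches_count_interface():
    rows = [("positive", "positive", "positive")] * 40
    rows += [("positive", "positive", "negative")] * 3
    rows += [("negative", "negative", "positive")] * 1
    rows += [("negative", "negative", "negative")] * 56
    got = newcombe10_paired_diff_ci(make_table(rows), "ccd1", "fcd", "PPA")
    assert got == pytest.approx(newcombe10_ci(40, 3, 1, 56))


# ---------------------------------------------------------------------------
# prevalence adjustment


def _two_stratum_table():
    pos_rows = (
        [("positive", "positive", "positive", "pretest_positive")] * 6
        + [("positive", "positive", "negative", "pretest_positive")] * 1
        + [("negative", "negative", "positive", "pretest_positive")] * 1
        + [("negative", "negative", "negative", "pretest_positive")] * 2
    )
    neg_rows = (
        [("positive", "positive", "positive", "pretest_negative")] * 1
        + [("negative", "negative", "positive", "pretest_negative")] * 1
        + [("negative", "negative", "negative", "pretest_negative")] * 8
    )
    return make_table(pos_rows + neg_rows)


def test_prevalence_adjust_hand_computed_bayes_table():
    """Stratum joints reweighted to prevalence 0.1, against hand arithmetic."""
    table = _two_stratum_table()
    adj = prevalence_adjust(table, PrevalenceSpec(0.1))
    # hand computation: joint = 0.1*pos_joint + 0.9*neg_joint
    # pos joint (C,F): ++ .6, +- .1, -+ .1, -- .2 ; neg joint: ++ .1, -+ .1, -- .8
    j_pp = 0.1 * 0.6 + 0.9 * 0.1
    j_pn = 0.1 * 0.1 + 0.9 * 0.0
    j_np = 0.1 * 0.1 + 0.9 * 0.1
    j_nn = 0.1 * 0.2 + 0.9 * 0.8
    assert adj.ppa == pytest.approx(j_pp / (j_pp + j_pn), abs=1e-12)
    assert adj.npa == pytest.approx(j_nn / (j_np + j_nn), abs=1e-12)


def test_prevalence_adjust_identity_at_matched_prevalence():
    table = _two_stratum_table()
    adj = prevalence_adjust(table, PrevalenceSpec(0.5))  # strata are 10/10
    pooled_ppa = pairwise_agreement(table, "ccd1", "fcd", "PPA").estimate
    pooled_npa = pairwise_agreement(table, "ccd1", "fcd", "NPA").estimate
    assert adj.ppa == pytest.approx(pooled_ppa, abs=1e-12)
    assert adj.npa == pytest.approx(pooled_npa, abs=1e-12)


@pytest.mark.parametrize("prev", [0.05, 0.3, 0.9])
def test_prevalence_adjust_perfect_agreement_invariant(prev):
    rows = [("positive", "positive", "positive", "pretest_positive")] * 5
    rows += [("negative", "negative", "negative", "pretest_positive")] * 2
    rows += [("positive", "positive", "positive", "pretest_negative")] * 1
    rows += [("negative", "negative", "negative", "pretest_negative")] * 7
    adj = prevalence_adjust(make_table(rows), PrevalenceSpec(prev))
    assert adj.ppa == 1.0
    assert adj.npa == 1.0


def test_prevalence_adjust_errors():
    with pytest.raises(ValueError):
        PrevalenceSpec(0.0)
    rows = [("positive", "positive", "positive", "pretest_positive")] * 3
    with pytest.raises(ValueError, match="stratum unobserved"):
        prevalence_adjust(make_table(rows), PrevalenceSpec(0.5))


# ---------------------------------------------------------------------------
# non-inferiority decision


def _zeta_set(uppers):
    return ZetaSet(
        *(ZetaInterval(point=0.0, ci_low=-0.01, ci_high=u, method="percentile_bootstrap") for u in uppers)
    )


def test_clear_pass():
    res = noninferiority_decision(_zeta_set([0.02] * 4), 0.05, 0.05)
    assert res.pass_overall
    assert res.epsilon1 == pytest.approx(0.02)


def test_clear_fail_on_predictive_side():
    res = noninferiority_decision(_zeta_set([0.02, 0.06, 0.02, 0.02]), 0.05, 0.05)
    assert not res.pass_predictive
    assert res.pass_selective


def test_equality_fails_strict_inequality():
    res = noninferiority_decision(_zeta_set([0.05] * 4), 0.05, 0.05)
    assert not res.pass_predictive and not res.pass_selective


def test_swap_mapping_exchanges_sides():
    zs = _zeta_set([0.06, 0.06, 0.01, 0.01])  # PPA-side uppers high
    res = noninferiority_decision(zs, 0.05, 0.05, swap_mapping=True)
    assert res.epsilon1 == pytest.approx(0.01)
    assert res.epsilon0 == pytest.approx(0.06)


def test_missing_ci_rejected():
    zs = ZetaSet(*(ZetaInterval(point=0.0) for _ in range(4)))
    with pytest.raises(ValueError, match="no CI"):
        noninferiority_decision(zs, 0.05, 0.05)
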