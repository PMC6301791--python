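"""Manifold fitting: recovery, joint fits, bootstrap, outliers, titration."""

import numpy as np
import pandas as pd
import pytest

import allelic_manifolds as am
from conftest import state_sum_rate


def make_series(mechanism="repression", n=20, noise_cv=0.0, seed=0, **kw):
    truth = am.SyntheticTruth(mechanism=mechanism, noise_cv=noise_cv, seed=seed, **kw)
    return am.simulate_allelic_series(truth, n)


# ---------------------------------------------------------------------------
# recovery


def test_noiseless_recovery_repression():
    table, truth = make_series(p_range=(1e-4, 10.0))
    res = am.fit_manifold(table, "repression", n_starts=3, seed=1)
    assert res.params["tsat"] == pytest.approx(truth.tsat, rel=1e-6)
    assert res.params["tbg"] == pytest.approx(truth.tbg, rel=1e-6)
    assert res.params["F"] == pytest.approx(truth.F, rel=1e-6)
    for pid, P in res.P_by_promoter.items():
        assert P == pytest.approx(truth.P_by_promoter[pid], rel=1e-6)
    assert res.loss < 1e-12


def test_noiseless_recovery_stabilization_energy_scale():
    table, truth = make_series("stabilization", alpha=712.0)
    res = am.fit_manifold(table, "stabilization", fixed={"F": 23.9}, n_starts=3, seed=1)
    assert res.params["alpha"] == pytest.approx(712.0, rel=1e-6)
    assert round(res.dg_alpha, 2) == -4.05


def test_fitted_predictions_match_state_sum_oracle():
    table, _ = make_series(p_range=(1e-4, 10.0))
    res = am.fit_manifold(table, "repression", n_starts=3, seed=1)
    s = res.all_params
    for pid, P in res.P_by_promoter.items():
        tm, tp = res.predict(P)
        assert tm == pytest.approx(state_sum_rate(P, 0.0, s["tsat"], s["tbg"]), rel=1e-12)
        assert tp == pytest.approx(state_sum_rate(P, s["F"], s["tsat"], s["tbg"]), rel=1e-12)


def test_no_regulation_limit():
    # t+ == t- exactly: repression collapses to F ~ 0, stabilization to alpha ~ 1
    truth = am.SyntheticTruth(mechanism="stabilization", alpha=1.0, noise_cv=0.0, seed=3)
    table, _ = am.simulate_allelic_series(truth, 15)
    np.testing.assert_allclose(table.df["t_minus"], table.df["t_plus"], rtol=1e-12)
    rep = am.fit_manifold(table, "repression", n_starts=3, seed=1)
    assert rep.params["F"] < 1e-3
    stab = am.fit_manifold(table, "stabilization", n_starts=3, seed=1)
    assert stab.params["alpha"] == pytest.approx(1.0, abs=1e-3)


def test_row_order_does_not_affect_estimates(rng):
    table, _ = make_series(noise_cv=0.1, seed=7, p_range=(1e-3, 3.0), n=30)
    res1 = am.fit_manifold(table, "repression", n_starts=5, seed=2)
    shuffled = am.MeasurementTable(table.df.sample(frac=1.0, random_state=11).reset_index(drop=True))
    res2 = am.fit_manifold(shuffled, "repression", n_starts=5, seed=2)
    for k in res1.params:
        assert res1.params[k] == pytest.approx(res2.params[k], rel=1e-8)
    for pid in res1.P_by_promoter:
        assert res1.P_by_promoter[pid] == pytest.approx(res2.P_by_promoter[pid], rel=1e-7)


def test_loss_at_truth_beats_perturbed_parameters(rng):
    table, truth = make_series(p_range=(1e-4, 10.0), n=15)
    df = table.df
    P_true = np.array([truth.P_by_promoter[p] for p in df["promoter_id"]])

    def loss(tsat, tbg, F, P):
        tm = tsat * P / (1 + P) + tbg
        tp = tsat * P / (1 + F + P) + tbg
        return np.sum((np.log10(tm) - np.log10(df["t_minus"]))**2
                      + (np.log10(tp) - np.log10(df["t_plus"]))**2)

    at_truth = loss(truth.tsat, truth.tbg, truth.F, P_true)
    for _ in range(100):
        factors = rng.lognormal(0.0, 0.3, size=3 + len(P_true))
        perturbed = loss(truth.tsat * factors[0], truth.tbg * factors[1],
                         truth.F * factors[2], P_true * factors[3:])
        assert at_truth <= perturbed


def test_too_few_promoters_is_an_identifiability_error():
    table, _ = make_series(n=3)
    with pytest.raises(am.IdentifiabilityError):
        am.fit_manifold(table, "repression")


# ---------------------------------------------------------------------------
# joint fit


def test_joint_fit_recovers_shared_tsat_and_couplings():
    ta, tra = make_series("stabilization", alpha=30.0, seed=21,
                          architecture="-60.5", p_range=(1e-4, 10.0), n=15)
    tb, trb = make_series("stabilization", alpha=700.0, seed=22,
                          architecture="-61.5", p_range=(1e-4, 10.0), n=15)
    res = am.joint_fit({"-60.5": ta, "-61.5": tb}, "stabilization",
                       fixed={"F": 23.9}, n_starts=3, seed=1)
    assert res["-60.5"].params["alpha"] == pytest.approx(30.0, rel=1e-5)
    assert res["-61.5"].params["alpha"] == pytest.approx(700.0, rel=1e-5)
    assert res["-60.5"].params["tsat"] == res["-61.5"].params["tsat"]
    assert res["-60.5"].params["tsat"] == pytest.approx(15.1, rel=1e-5)


def test_joint_fit_symmetric_on_identical_data():
    ta, _ = make_series("stabilization", alpha=100.0, seed=5, n=12)
    tb = am.MeasurementTable(ta.df.assign(architecture="other"))
    res = am.joint_fit({"a": ta, "other": tb}, "stabilization", fixed={"F": 23.9},
                       n_starts=3, seed=1)
    for k in res["a"].params:
        assert res["a"].params[k] == pytest.approx(res["other"].params[k], rel=1e-9)


def test_joint_fit_matches_independent_fits_on_noiseless_shared_tsat_data():
    ta, _ = make_series("stabilization", alpha=30.0, seed=31, n=15, p_range=(1e-4, 10.0))
    tb, _ = make_series("stabilization", alpha=700.0, seed=32, n=15, p_range=(1e-4, 10.0))
    joint = am.joint_fit({"a": ta, "b": tb}, "stabilization", fixed={"F": 23.9},
                         n_starts=3, seed=1)
    total_joint = sum(r.loss for r in joint.values())
    indep_losses, indep_alpha = [], {}
    for name, t in (("a", ta), ("b", tb)):
        r = am.fit_manifold(t, "stabilization", fixed={"F": 23.9}, n_starts=3, seed=1)
        indep_losses.append(r.loss)
        indep_alpha[name] = r.params["alpha"]
    # sharing tsat cannot lower the loss; at the (noiseless) truth the
    # constraint is inactive so both solutions coincide
    assert total_joint + 1e-9 >= sum(indep_losses)
    assert total_joint < 1e-10
    for name in ("a", "b"):
        assert joint[name].params["alpha"] == pytest.approx(indep_alpha[name], rel=1e-5)


# ---------------------------------------------------------------------------
# acceleration / beta


def test_fit_beta_reduces_to_stabilization_when_beta_fixed_to_one():
    table, _ = make_series("stabilization", alpha=712.0, seed=9, n=15)
    stab = am.fit_manifold(table, "stabilization", fixed={"F": 23.9}, n_starts=3, seed=1)
    accel = am.fit_beta(table, tsat=stab.params["tsat"], F=23.9,
                        fixed={"beta": 1.0}, n_starts=3, seed=1)
    assert accel.params["alpha"] == pytest.approx(stab.params["alpha"], rel=1e-6)
    assert accel.params["tbg"] == pytest.approx(stab.params["tbg"], rel=1e-6)


def test_fully_free_acceleration_fit_is_refused_as_degenerate():
    table, _ = make_series("acceleration", alpha=712.0, beta=3.0, seed=9,
                           p_range=(1e-4, 100.0), n=15)
    with pytest.raises(am.IdentifiabilityError, match="tsat"):
        am.fit_manifold(table, "acceleration", {"F": 23.9}, n_starts=3, seed=1)


def test_fit_beta_warns_when_no_strong_promoters():
    table, _ = make_series("acceleration", alpha=712.0, beta=2.0, seed=13,
                           p_range=(1e-4, 1e-2), n=12)
    with pytest.warns(UserWarning, match="weakly identified"):
        am.fit_beta(table, tsat=15.1, F=23.9, n_starts=3, seed=1)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_seeded_runs_are_identical():
    table, _ = make_series(noise_cv=0.1, seed=17, p_range=(1e-3, 3.0), n=20)
    e1 = am.bootstrap(table, "repression", n_boot=20, seed=5, n_starts=3)
    e2 = am.bootstrap(table, "repression", n_boot=20, seed=5, n_starts=3)
    pd.testing.assert_frame_equal(e1.draws, e2.draws)
    assert e1.ci68 == e2.ci68


def test_bootstrap_ci_collapses_on_noiseless_data():
    table, truth = make_series(p_range=(1e-4, 10.0), n=15)
    ens = am.bootstrap(table, "repression", n_boot=30, seed=5, n_starts=3)
    lo, hi = ens.ci("F", 0.68)
    assert hi - lo < 1e-5 * truth.F
    assert lo <= truth.F <= hi or abs(lo - truth.F) < 1e-5


# ---------------------------------------------------------------------------
# outliers and collapse failure


def test_clean_data_yields_no_flags():
    table, _ = make_series(noise_cv=0.05, seed=19, p_range=(1e-3, 3.0), n=30)
    flagged = am.detect_outliers(table, "repression", seed=1, n_starts=3)
    assert flagged.df["is_outlier"].sum() == 0


def test_injected_outlier_is_flagged():
    table, truth = make_series(noise_cv=0.05, seed=23, p_range=(1e-3, 3.0), n=30)
    df = table.df
    # corrupt one mid-manifold promoter's regulated channel ten-fold
    mid = df.index[len(df) // 2]
    df.loc[mid, "t_plus"] *= 10.0
    corrupted_id = df.loc[mid, "promoter_id"]
    flagged = am.detect_outliers(am.MeasurementTable(df), "repression", seed=1, n_starts=3)
    out = flagged.df.loc[flagged.df["is_outlier"], "promoter_id"].tolist()
    assert out == [corrupted_id]


def test_non_collapsing_scatter_raises(rng):
    # regulated channel scattered over a decade either way, independent of
    # t-: a 2D cloud, not a 1D manifold, and the detector must refuse
    tm = np.logspace(-2.5, 1, 40)
    tp = 0.3 * 10.0 ** rng.uniform(-1, 1, size=40)
    table = am.MeasurementTable.from_arrays(
        [f"p{i}" for i in range(40)], tm, tp, architecture="-40.5")
    with pytest.raises(am.CollapseError):
        am.detect_outliers(table, "repression", seed=1, n_starts=3)


# ---------------------------------------------------------------------------
# titration


def test_flat_titration_has_zero_exponent():
    truth = am.SyntheticTruth(noise_cv=0.0, seed=29)
    tables, _ = am.simulate_titration(truth, [2.5, 5, 10, 25, 50, 100, 250],
                                      exponent=0.0, n_promoters=12)
    res = am.titration_fit(tables, 15.1, 0.0023, n_starts=3)
    assert res.exponent == pytest.approx(0.0, abs=1e-8)


def test_titration_slope_invariant_under_concentration_rescaling():
    truth = am.SyntheticTruth(noise_cv=0.0, seed=29)
    concs = [2.5, 5, 10, 25, 50, 100, 250]
    tables, _ = am.simulate_titration(truth, concs, exponent=1.41, n_promoters=12)
    res = am.titration_fit(tables, 15.1, 0.0023, n_starts=3)
    rescaled = {c / 1000.0: t for c, t in tables.items()}  # uM -> mM
    res_mM = am.titration_fit(rescaled, 15.1, 0.0023, n_starts=3)
    assert res.exponent == pytest.approx(res_mM.exponent, rel=1e-9)


def test_titration_refuses_undefined_slope_ci():
    truth = am.SyntheticTruth(noise_cv=0.0, seed=29)
    tables, _ = am.simulate_titration(truth, [10, 100], exponent=1.0, n_promoters=8)
    with pytest.raises((am.IdentifiabilityError, ValueError)):
        am.titration_fit(tables, 15.1, 0.0023, select=2)
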