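"""B-dot activities, weak-acid/carbonate speciation, and Gibbs energy
landscapes for the three hydrogenotrophic/acetoclastic reactions."""
import math

import numpy as np
import pytest

from quake_biogeo import (
    BdotParams,
    ReactionSpec,
    SolutionCondition,
    bdot_log_gamma,
    delta_g,
    energy_landscape,
    ionic_strength,
    shipped_reactions,
    speciate_carbonate,
    speciate_weak_acid,
    threshold_activity,
)
from quake_biogeo.energetics import R_GAS, baseline_activities, gamma

RT = R_GAS * 298.15


def test_ionic_strength():
    assert ionic_strength({"Na+": 0.5, "Cl-": 0.5}) == pytest.approx(0.5)
    assert ionic_strength({"Mg+2": 0.01, "Cl-": 0.02}) == pytest.approx(0.03)
    assert ionic_strength({}) == 0.0
    with pytest.raises(KeyError):
        ionic_strength({"Xe+": 0.1})
    with pytest.raises(ValueError):
        ionic_strength({"Na+": -0.1})


def test_bdot_log_gamma_limits_and_hand_value():
    params = BdotParams.default()
    assert bdot_log_gamma(-1, 4.5, 0.0, params) == 0.0
    assert bdot_log_gamma(0, 0.0, 0.7, params) == 0.0  # neutral rule
    # hand evaluation: -0.5092*0.83666/(1+0.3283*4.5*0.83666) + 0.041*0.7
    assert bdot_log_gamma(-1, 4.5, 0.7, params) == pytest.approx(-0.16183, abs=1e-5)
    # Setchenow option salts neutral species out
    assert bdot_log_gamma(0, 0.0, 0.7, params, neutral_setchenow_b=0.1) == (
        pytest.approx(0.07)
    )


def test_gamma_charge_dependence():
    g1 = gamma("CH3COO-", 0.66)
    g2 = gamma("CO3-2", 0.66)
    assert 0.0 < g2 < g1 < 1.0


def test_weak_acid_equal_activities_at_pka():
    a_ha, a_a = speciate_weak_acid(1e-3, 4.66, 4.66, (1.0, 1.0))
    assert a_ha == pytest.approx(a_a, rel=1e-12)
    assert a_ha + a_a == pytest.approx(1e-3, rel=1e-12)


def test_neutral_acetic_acid_activity_at_study_conditions():
    """a[CH3COOH] for 1 mM total acetate at pH 7.9 matches the reported
    2.8e-7 within a factor of 2, and scales exactly with the total."""
    g_a = gamma("CH3COO-", 0.66)
    a_mm, _ = speciate_weak_acid(1e-3, 4.66, 7.9, (1.0, g_a))
    assert 1.4e-7 <= a_mm <= 5.6e-7
    a_um, _ = speciate_weak_acid(1e-6, 4.66, 7.9, (1.0, g_a))
    assert a_mm == pytest.approx(1000.0 * a_um, rel=1e-12)


def test_carbonate_speciation_limits_and_hand_value():
    assert speciate_carbonate(0.05, 6.13, 10.11, 1.0) == pytest.approx(
        0.05, rel=1e-3
    )  # fully protonated limit
    assert speciate_carbonate(0.05, 6.13, 10.11, 13.5) < 1e-9
    # hand-evaluated mass balance at pH 7.9 with gamma(HCO3-) = gamma(CO3--) = 1:
    # m_CO2 = 0.05 / (1 + 10^-6.13/10^-7.9 + 10^-6.13*10^-10.11/10^-15.8)
    expected = 0.05 / (1.0 + 10**1.77 + 10**(1.77 - 2.21))
    assert speciate_carbonate(0.05, 6.13, 10.11, 7.9) == pytest.approx(
        expected, rel=1e-9
    )


def test_reaction_table_element_and_charge_balance():
    for rx in shipped_reactions().values():
        rx.validate()
    with pytest.raises(ValueError):
        ReactionSpec("bad", {"H2(aq)": -1.0, "CH4(aq)": 1.0}, 0.0).validate()


def test_delta_g_reduces_to_standard_energy_at_unit_activities():
    rx = shipped_reactions()["hydrogenotrophic_methanogenesis"]
    acts = {sp: 1.0 for sp in rx.stoichiometry}
    assert delta_g(rx, acts) == pytest.approx(rx.delta_g0, abs=1e-12)
    with pytest.raises(KeyError):
        delta_g(rx, {"H2(aq)": 1.0})


def test_hess_identity_exact_for_any_activities():
    rxs = shipped_reactions()
    rng = np.random.default_rng(5)
    species = ["H2(aq)", "CO2(aq)", "CH4(aq)", "CH3COOH(aq)", "H2O(l)"]
    for _ in range(20):
        acts = {sp: 10.0 ** rng.uniform(-10, 0) for sp in species}
        g1 = delta_g(rxs["hydrogenotrophic_methanogenesis"], acts)
        g2 = delta_g(rxs["homoacetogenesis"], acts)
        g3 = delta_g(rxs["methane_carboxylation"], acts)
        assert g3 == pytest.approx(g2 - g1, abs=1e-9)


def test_tenfold_h2_lowers_energy_by_four_decades_of_rt():
    rx = shipped_reactions()["homoacetogenesis"]
    acts = {"H2(aq)": 1e-7, "CO2(aq)": 5e-4, "CH3COOH(aq)": 3e-7, "H2O(l)": 1.0}
    g_lo = delta_g(rx, acts)
    acts["H2(aq)"] = 1e-6
    g_hi = delta_g(rx, acts)
    assert g_lo - g_hi == pytest.approx(4.0 * RT * math.log(10.0), abs=1e-9)


def test_h2_thresholds_order_of_magnitude():
    """Zero-energy H2 activities: ~1e-7 for homoacetogenesis at 1 mM total
    acetate, ~1e-8 for hydrogenotrophic methanogenesis (order of magnitude,
    the stated precision of the shipped thermodynamic constants)."""
    cond = SolutionCondition()
    rxs = shipped_reactions()
    a_ac, log_ac = threshold_activity(rxs["homoacetogenesis"], cond)
    a_me, log_me = threshold_activity(rxs["hydrogenotrophic_methanogenesis"], cond)
    assert abs(log_ac - (-7.0)) < 1.0
    assert abs(log_me - (-8.0)) < 1.0
    # homoacetogenesis needs roughly an order of magnitude more H2
    assert 0.5 < log_ac - log_me < 1.5
    # root-finder contract
    base = baseline_activities(cond)
    for rx, a in ((rxs["homoacetogenesis"], a_ac),
                  (rxs["hydrogenotrophic_methanogenesis"], a_me)):
        acts = dict(base, **{"H2(aq)": a})
        assert abs(delta_g(rx, acts, cond)) < 0.01


def test_threshold_requires_sign_change():
    # acetoclastic methanogenesis has no H2 dependence: no bracket
    with pytest.raises(ValueError):
        threshold_activity(
            shipped_reactions()["acetoclastic_methanogenesis"], SolutionCondition()
        )


def test_energy_landscape_structure():
    cond = SolutionCondition()  # 1 mM total acetate
    rxs = shipped_reactions()
    grid = np.arange(-12.0, 0.0 + 1e-9, 0.25)

    flat = energy_landscape(rxs["acetoclastic_methanogenesis"], cond,
                            log10_grid=grid)
    assert flat["delta_g_kj"].nunique() == 1  # H2 absent from the reaction
    assert (flat["delta_g_kj"] < 0.0).all()  # progresses at any a[H2] at 1 mM

    for name in ("hydrogenotrophic_methanogenesis", "homoacetogenesis"):
        frame = energy_landscape(rxs[name], cond, log10_grid=grid)
        assert np.all(np.isfinite(frame["delta_g_kj"]))
        assert np.all(np.diff(frame["delta_g_kj"]) < 0.0)  # monotone in a[H2]
        at = frame.set_index("log10_activity")["delta_g_kj"]
        assert at[-6.0] < 0.0   # exergonic at the detection limit
    # homoacetogenesis shuts off at the deep-subseafloor H2 background,
    # methanogenesis sits within a few kJ/mol of its threshold there
    acet = energy_landscape(rxs["homoacetogenesis"], cond, log10_grid=grid)
    meth = energy_landscape(rxs["hydrogenotrophic_methanogenesis"], cond,
                            log10_grid=grid)
    assert acet.set_index("log10_activity")["delta_g_kj"][-8.0] > 0.0
    assert abs(meth.set_index("log10_activity")["delta_g_kj"][-8.0]) < 10.0


def test_landscape_rejects_unsorted_grid():
    with pytest.raises(ValueError):
        energy_landscape(
            shipped_reactions()["homoacetogenesis"],
            SolutionCondition(),
            log10_grid=[-2.0, -3.0],
        )


def test_condition_validation():
    with pytest.raises(ValueError):
        SolutionCondition(t_celsius=80.0)
    with pytest.raises(ValueError):
        SolutionCondition(total_acetate=-1.0)
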