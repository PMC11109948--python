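"""Kinetic model tests: oracles, conservation laws, and limit equivalences.

The linear mass-action family is checked against an independent
matrix-exponential solution; the Michaelis-Menten and processive families
are checked against their analytic limits and stoichiometric conservation.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from h4zip.kinetics import (
    IntegrationError,
    MassActionModel,
    MichaelisMentenModel,
    ProcessiveModel,
    disable_site,
    simulate,
    site_rates_to_edge_rates,
)
from h4zip.motifs import build_network

from conftest import random_site_rates

TIMES = np.array([0.0, 5.0, 15.0, 30.0, 60.0])


def expm_trajectory(model: MassActionModel, times, s0):
    """Independent linear-ODE oracle: S(t) = expm(A t) @ S(0)."""
    return np.stack([expm(model.rate_matrix * t) @ s0 for t in times], axis=1)


def test_mass_action_matches_matrix_exponential(wt_network):
    rng = np.random.default_rng(7)
    for _ in range(5):
        model = MassActionModel(wt_network, rng.uniform(0.0, 0.5, wt_network.n_edges))
        traj = simulate(model, TIMES)
        oracle = expm_trajectory(model, TIMES, model.initial_state())
        np.testing.assert_allclose(traj.y, oracle, rtol=1e-6, atol=1e-9)


def test_single_site_first_order_decay():
    net = build_network(("K16",))
    model = MassActionModel.from_site_rates(net, {"K16": 0.1})
    traj = simulate(model, TIMES)
    np.testing.assert_allclose(traj.abundance("unmod"), np.exp(-0.1 * TIMES), rtol=1e-7)


def test_zero_rates_give_constant_trajectory(wt_network):
    zeros = {s: 0.0 for s in wt_network.sites}
    models = [
        MassActionModel.from_site_rates(wt_network, zeros),
        MichaelisMentenModel.from_site_rates(wt_network, zeros, Km=1.0, e_tot=0.25),
        ProcessiveModel.from_site_rates(wt_network, zeros, kon=0.0, koff=0.0, e_tot=0.25),
    ]
    for model in models:
        traj = simulate(model, TIMES)
        assert np.max(np.abs(traj.y - traj.y[:, [0]])) < 1e-12


def test_michaelis_menten_large_km_limit(wt_network):
    """As Km -> infinity, MM fluxes converge to mass action with
    k = kcat * E_tot / Km."""
    rates = random_site_rates(np.random.default_rng(3), wt_network.sites, 10.0, 100.0)
    Km, e_tot = 1e6, 0.25
    mm = MichaelisMentenModel.from_site_rates(wt_network, rates, Km=Km, e_tot=e_tot)
    ma = MassActionModel.from_site_rates(
        wt_network, {s: r * e_tot / Km for s, r in rates.items()}
    )
    y_mm = simulate(mm, TIMES).y
    y_ma = simulate(ma, TIMES).y
    assert np.max(np.abs(y_mm - y_ma)) < 1e-6


def test_michaelis_menten_initial_flux_and_validation(wt_network):
    rates = {"K5": 0.0, "K8": 0.0, "K12": 0.0, "K16": 2.0}
    model = MichaelisMentenModel.from_site_rates(wt_network, rates, Km=0.5, e_tot=0.25)
    dx = model.rhs(0.0, model.initial_state())
    # all substrate unmodified, one active site: flux = kcat*E_tot*1/(Km+1)
    expected = 2.0 * 0.25 / (0.5 + 1.0)
    assert dx[model.network.index("unmod")] == pytest.approx(-expected)
    assert dx[model.network.index("K16ac")] == pytest.approx(expected)
    with pytest.raises(ValueError):
        MichaelisMentenModel.from_site_rates(wt_network, rates, Km=0.0, e_tot=0.25)


def test_michaelis_menten_zero_enzyme(wt_network):
    rates = {s: 1.0 for s in wt_network.sites}
    model = MichaelisMentenModel.from_site_rates(wt_network, rates, Km=1.0, e_tot=0.0)
    assert np.all(model.rhs(0.0, model.initial_state()) == 0.0)


def test_processive_qss_limit(wt_network):
    """Quasi-steady-state limit: the processive model converges to
    Michaelis-Menten with Km = koff/kon when exchange is fast relative to
    catalysis (koff >> kcat) AND the bound substrate fraction is negligible
    (E_tot << Km); both must scale jointly for the trajectories to agree."""
    rates = random_site_rates(np.random.default_rng(4), wt_network.sites, 800.0, 1600.0)
    Km, e_tot, koff = 5000.0, 0.25, 2.4e7
    proc = ProcessiveModel.from_site_rates(
        wt_network, rates, kon=koff / Km, koff=koff, e_tot=e_tot
    )
    mm = MichaelisMentenModel.from_site_rates(wt_network, rates, Km=Km, e_tot=e_tot)
    y_p = simulate(proc, TIMES).y
    y_mm = simulate(mm, TIMES).y
    assert np.max(np.abs(y_p - y_mm)) < 1e-4


def test_processive_binding_equilibrium(wt_network):
    """With catalysis off, binding relaxes to C_tot/(E*S_tot) = kon/koff."""
    zeros = {s: 0.0 for s in wt_network.sites}
    model = ProcessiveModel.from_site_rates(
        wt_network, zeros, kon=2.0, koff=1.0, e_tot=0.25
    )
    traj = simulate(model, np.array([0.0, 500.0]))
    S, C, E = model.split(traj.states[:, -1])
    assert C.sum() / (E * S.sum()) == pytest.approx(2.0, rel=1e-5)


@pytest.mark.parametrize("family", ["mass_action", "michaelis_menten", "processive"])
def test_conservation_and_nonnegativity(family, wt_network):
    """Total H4 (and enzyme, where modeled) is conserved to 1e-8 over 180 min
    and the solver state never goes below round-off-negative."""
    rng = np.random.default_rng(hash(family) % 2**31)
    times = np.linspace(0.0, 180.0, 13)
    for _ in range(3):
        rates = random_site_rates(rng, wt_network.sites)
        if family == "mass_action":
            model = MassActionModel.from_site_rates(wt_network, rates)
        elif family == "michaelis_menten":
            model = MichaelisMentenModel.from_site_rates(
                wt_network, rates, Km=rng.uniform(0.1, 5.0), e_tot=0.25
            )
        else:
            model = ProcessiveModel.from_site_rates(
                wt_network, rates, kon=rng.uniform(0.5, 20.0),
                koff=rng.uniform(0.1, 5.0), e_tot=0.25,
                k_transfer=rng.uniform(0.0, 2.0),
            )
        traj = simulate(model, times)
        assert traj.states.min() > -1e-10
        total_h4 = traj.y.sum(axis=0) if family != "processive" else None
        if family == "processive":
            n = wt_network.n_motifs
            S, C, E = traj.states[:n], traj.states[n:2 * n], traj.states[-1]
            np.testing.assert_allclose((S + C).sum(axis=0), 1.0, atol=1e-8)
            np.testing.assert_allclose(C.sum(axis=0) + E, 0.25, atol=1e-8)
        else:
            np.testing.assert_allclose(total_h4, 1.0, atol=1e-8)


def test_tetra_acetylation_is_monotone(wt_network):
    """The fully acetylated motif is absorbing, so its abundance never falls."""
    rng = np.random.default_rng(9)
    model = ProcessiveModel.from_site_rates(
        wt_network, random_site_rates(rng, wt_network.sites), kon=5.0, koff=1.0, e_tot=0.25
    )
    traj = simulate(model, np.linspace(0, 180, 37))
    tetra = traj.abundance("K5acK8acK12acK16ac")
    assert np.all(np.diff(tetra) >= -1e-10)


def test_transfer_reaction_conserves_and_mixes(wt_network):
    """The within-array hand-off moves enzyme between tails without changing
    totals; with transfer on, bound enzyme spreads faster across motifs."""
    rates = {s: 0.0 for s in wt_network.sites}
    model = ProcessiveModel.from_site_rates(
        wt_network, rates, kon=1.0, koff=0.5, e_tot=0.25, k_transfer=3.0
    )
    x0 = model.initial_state()
    dx = model.rhs(0.0, x0)
    n = wt_network.n_motifs
    assert abs(dx[:n].sum() + dx[n:2 * n].sum()) < 1e-14  # H4 conserved
    assert abs(dx[n:2 * n].sum() + dx[-1]) < 1e-14  # enzyme conserved


def test_disable_site_parameter_counts(wt_network):
    rng = np.random.default_rng(1)
    kcat = rng.uniform(0.01, 1.0, wt_network.n_edges)
    model = ProcessiveModel(wt_network, kcat, kon=2.0, koff=1.0, e_tot=0.25)
    sub = disable_site(model, "K16")
    assert sub.network.n_motifs == 8
    assert sub.edge_kcat.shape == (12,)
    assert (sub.kon, sub.koff, sub.e_tot) == (2.0, 1.0, 0.25)
    # surviving edges keep their original rates
    orig = {(e.source.label, e.site): r for e, r in zip(wt_network.edges, kcat)}
    for e, r in zip(sub.network.edges, sub.edge_kcat):
        assert r == orig[(e.source.label, e.site)]
    with pytest.raises(ValueError):
        disable_site(model, "K99")


def test_disable_site_zero_rate_model_unchanged(wt_network):
    zeros = {s: 0.0 for s in wt_network.sites}
    model = MassActionModel.from_site_rates(wt_network, zeros)
    sub = disable_site(model, "K16")
    traj = simulate(sub, TIMES)
    assert np.max(np.abs(traj.y - traj.y[:, [0]])) < 1e-12


def test_simulate_input_validation(wt_network):
    model = MassActionModel.from_site_rates(wt_network, {s: 0.1 for s in wt_network.sites})
    with pytest.raises(ValueError):
        simulate(model, np.array([1.0, 2.0]))  # must start at 0
    with pytest.raises(ValueError):
        simulate(model, np.array([0.0, 2.0, 1.0]))  # not increasing
    with pytest.raises(ValueError):
        simulate(model, TIMES, init=-np.ones(wt_network.n_motifs))
    with pytest.raises(ValueError):
        MassActionModel(wt_network, np.ones(3))  # wrong edge-rate dimension


def test_integration_error_carries_time(wt_network):
    model = MassActionModel.from_site_rates(wt_network, {s: 0.1 for s in wt_network.sites})
    bad = np.full(wt_network.n_motifs, np.nan)
    with pytest.raises((IntegrationError, ValueError)):
        simulate(model, TIMES, init=np.abs(bad))
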