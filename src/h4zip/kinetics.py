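"""ODE model families for acetylation kinetics on the motif lattice.

Three competing reaction mechanisms for a lysine acetyltransferase working
through the motif lattice:

* ``mass_action`` — the enzyme is in excess and acetylation of each free
  site is first order in the substrate motif; the system is linear.
* ``michaelis_menten`` — one enzyme pool is shared competitively by all
  motifs with the enzyme–substrate complex at equilibrium; every edge flux
  is ``kcat * E_tot * S[m] / (Km + sum_j S[j])``.
* ``processive`` — enzyme, substrate and complex are modeled explicitly:
  the enzyme binds a tail (kon), may dissociate (koff) or acetylate any
  free site while staying bound (per-edge kcat).  An optional within-array
  hand-off reaction (``k_transfer``) lets a bound enzyme jump directly to
  another tail without passing through the free pool — the "spatial"
  variant in which moving within an array is faster than re-binding from
  solution.

Units: time in minutes; substrate abundances as fractions of total H4
(so S_tot = 1 at t = 0); the enzyme is expressed in the same fractional
units (default E_tot = 0.25, i.e. one enzyme per four H4 tails, matching
50 nM complex on 200 nM nucleosomes).

The observation is ``y = S + C``: mass spectrometry sees every H4 tail
whether or not an enzyme is bound.  Tiny negative round-off values are
clipped to zero in the observation only, never in the solver state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .motifs import TransitionNetwork, build_network

__all__ = [
    "IntegrationError",
    "Trajectory",
    "MassActionModel",
    "MichaelisMentenModel",
    "ProcessiveModel",
    "site_rates_to_edge_rates",
    "simulate",
    "disable_site",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


def site_rates_to_edge_rates(net: TransitionNetwork, site_rates: dict[str, float]) -> np.ndarray:
    """Expand per-site rates to per-edge rates (reduced parameterization).

    Every edge acetylating site ``s`` gets rate ``site_rates[s]`` regardless
    of the source motif.
    """
    missing = [s for s in net.sites if s not in site_rates]
    if missing:
        raise ValueError(f"missing site rates for {missing}")
    return np.array([site_rates[e.site] for e in net.edges], dtype=float)


def _check_edge_rates(net: TransitionNetwork, rates) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (net.n_edges,):
        raise ValueError(
            f"expected {net.n_edges} edge rates for this network, got {rates.shape}"
        )
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    return rates


@dataclass
class Trajectory:
    """Simulated time course of observed relative motif abundances."""

    times: np.ndarray
    y: np.ndarray  # (n_motifs, n_times); y = S + C clipped to >= 0
    network: TransitionNetwork
    states: np.ndarray = field(repr=False)  # raw solver states (state_dim, n_times)

    @property
    def labels(self) -> list[str]:
        return self.network.labels

    def abundance(self, motif_label: str) -> np.ndarray:
        return self.y[self.network.index(motif_label)]


class _ModelBase:
    family: str

    def __init__(self, network: TransitionNetwork):
        self.network = network
        self._src = np.array([network.index(e.source) for e in network.edges], dtype=int)
        self._dst = np.array([network.index(e.target) for e in network.edges], dtype=int)

    @property
    def n_motifs(self) -> int:
        return self.network.n_motifs

    def initial_state(self, s0: np.ndarray | None = None) -> np.ndarray:
        raise NotImplementedError

    def observe(self, states: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _default_s0(self) -> np.ndarray:
        s0 = np.zeros(self.n_motifs)
        s0[self.network.index("unmod")] = 1.0
        return s0

    def _scatter(self, flux: np.ndarray) -> np.ndarray:
        ds = np.zeros(self.n_motifs)
        np.subtract.at(ds, self._src, flux)
        np.add.at(ds, self._dst, flux)
        return ds


class MassActionModel(_ModelBase):
    """Linear model: edge flux = k[m, i] * S[m] (enzyme in excess)."""

    family = "mass_action"

    def __init__(self, network: TransitionNetwork, edge_rates):
        super().__init__(network)
        self.edge_rates = _check_edge_rates(network, edge_rates)
        # generator matrix: dS/dt = A @ S; also the exact Jacobian
        n = self.n_motifs
        A = np.zeros((n, n))
        for k, (i, j) in zip(self.edge_rates, zip(self._src, self._dst)):
            A[i, i] -= k
            A[j, i] += k
        self.rate_matrix = A

    @classmethod
    def from_site_rates(cls, network: TransitionNetwork, site_rates: dict[str, float]):
        return cls(network, site_rates_to_edge_rates(network, site_rates))

    def initial_state(self, s0=None) -> np.ndarray:
        return np.array(self._default_s0() if s0 is None else s0, dtype=float)

    def rhs(self, t, x):
        return self.rate_matrix @ x

    def jac(self, t, x):
        return self.rate_matrix

    def observe(self, states):
        return states


class MichaelisMentenModel(_ModelBase):
    """Shared-enzyme-pool model with equilibrium complex (competitive Km)."""

    family = "michaelis_menten"

    def __init__(self, network: TransitionNetwork, edge_kcat, Km: float, e_tot: float):
        super().__init__(network)
        self.edge_kcat = _check_edge_rates(network, edge_kcat)
        if Km <= 0:
            raise ValueError("Km must be positive")
        if e_tot < 0:
            raise ValueError("E_tot must be non-negative")
        self.Km = float(Km)
        self.e_tot = float(e_tot)

    @classmethod
    def from_site_rates(cls, network, site_rates, Km, e_tot):
        return cls(network, site_rates_to_edge_rates(network, site_rates), Km, e_tot)

    def initial_state(self, s0=None) -> np.ndarray:
        return np.array(self._default_s0() if s0 is None else s0, dtype=float)

    def rhs(self, t, x):
        denom = self.Km + x.sum()
        flux = self.edge_kcat * self.e_tot * x[self._src] / denom
        return self._scatter(flux)

    @property
    def _numerator_matrix(self):
        A = getattr(self, "_A", None)
        if A is None:
            n = self.n_motifs
            A = np.zeros((n, n))
            for k, i, j in zip(self.edge_kcat * self.e_tot, self._src, self._dst):
                A[i, i] -= k
                A[j, i] += k
            self._A = A
        return A

    def jac(self, t, x):
        A = self._numerator_matrix
        denom = self.Km + x.sum()
        return A / denom - np.outer(A @ x, np.ones_like(x)) / denom**2

    def observe(self, states):
        return states


class ProcessiveModel(_ModelBase):
    """Explicit enzyme model: binding, release, on-complex catalysis, hand-off.

    State vector: ``[S (n_motifs), C (n_motifs), E]``.  Reactions::

        E + S[m]      -> C[m]              kon * E * S[m]
        C[m]          -> E + S[m]          koff * C[m]
        C[m]          -> C[m + e_i]        kcat[m, i] * C[m]
        C[m] + S[n]   -> S[m] + C[n]       k_transfer * C[m] * S[n]

    The hand-off reaction moves a bound enzyme to another tail in the same
    array without releasing it into solution (k_transfer = 0 disables the
    spatial variant).
    """

    family = "processive"

    def __init__(
        self,
        network: TransitionNetwork,
        edge_kcat,
        kon: float,
        koff: float,
        e_tot: float,
        k_transfer: float = 0.0,
    ):
        super().__init__(network)
        self.edge_kcat = _check_edge_rates(network, edge_kcat)
        for name, v in (("kon", kon), ("koff", koff), ("k_transfer", k_transfer)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if e_tot < 0:
            raise ValueError("E_tot must be non-negative")
        self.kon = float(kon)
        self.koff = float(koff)
        self.e_tot = float(e_tot)
        self.k_transfer = float(k_transfer)

    @classmethod
    def from_site_rates(cls, network, site_rates, kon, koff, e_tot, k_transfer=0.0):
        return cls(
            network, site_rates_to_edge_rates(network, site_rates), kon, koff, e_tot, k_transfer
        )

    def initial_state(self, s0=None) -> np.ndarray:
        s = self._default_s0() if s0 is None else np.asarray(s0, dtype=float)
        if np.any(s < 0):
            raise ValueError("initial substrate abundances must be non-negative")
        n = self.n_motifs
        x = np.zeros(2 * n + 1)
        x[:n] = s
        x[-1] = self.e_tot  # all enzyme initially free
        return x

    def split(self, x):
        n = self.n_motifs
        return x[:n], x[n : 2 * n], x[2 * n]

    def rhs(self, t, x):
        n = self.n_motifs
        S, C, E = self.split(x)
        dS = np.zeros(n)
        dC = np.zeros(n)

        bind = self.kon * E * S
        release = self.koff * C
        dS += release - bind
        dC += bind - release
        dE = release.sum() - bind.sum()

        cat = self.edge_kcat * C[self._src]
        np.subtract.at(dC, self._src, cat)
        np.add.at(dC, self._dst, cat)

        if self.k_transfer > 0.0:
            s_tot = S.sum()
            c_tot = C.sum()
            # C[m] + S[n] -> S[m] + C[n], summed over partners
            dS += self.k_transfer * (C * s_tot - S * c_tot)
            dC += self.k_transfer * (S * c_tot - C * s_tot)

        out = np.empty_like(x)
        out[:n] = dS
        out[n : 2 * n] = dC
        out[-1] = dE
        return out

    @property
    def _cat_matrix(self):
        M = getattr(self, "_M", None)
        if M is None:
            n = self.n_motifs
            M = np.zeros((n, n))
            for k, i, j in zip(self.edge_kcat, self._src, self._dst):
                M[i, i] -= k
                M[j, i] += k
            self._M = M
        return M

    def jac(self, t, x):
        n = self.n_motifs
        S, C, E = self.split(x)
        kon, koff, kt = self.kon, self.koff, self.k_transfer
        s_tot, c_tot = S.sum(), C.sum()
        J = np.zeros((2 * n + 1, 2 * n + 1))
        I = np.eye(n)
        # dS block
        J[:n, :n] = -kon * E * I + kt * (C[:, None] - c_tot * I)
        J[:n, n : 2 * n] = koff * I + kt * (s_tot * I - S[:, None])
        J[:n, -1] = -kon * S
        # dC block
        J[n : 2 * n, :n] = kon * E * I + kt * (c_tot * I - C[:, None])
        J[n : 2 * n, n : 2 * n] = -koff * I + self._cat_matrix + kt * (S[:, None] - s_tot * I)
        J[n : 2 * n, -1] = kon * S
        # dE row
        J[-1, :n] = -kon * E
        J[-1, n : 2 * n] = koff
        J[-1, -1] = -kon * s_tot
        return J

    def observe(self, states):
        n = self.n_motifs
        return states[:n] + states[n : 2 * n]


def simulate(
    model: _ModelBase,
    times,
    init: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a model and return the observed trajectory.

    ``times`` must be increasing and start at 0; ``init`` is a substrate
    abundance vector over motifs (defaults to all mass in the unmodified
    motif), which each family packs into its own state layout.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] != 0:
        raise ValueError("times must start at 0")

    if init is not None and np.any(np.asarray(init) < 0):
        raise ValueError("initial state must be non-negative")
    x0 = model.initial_state(init)

    if len(times) == 1:
        states = x0[:, None]
    else:
        kwargs = {}
        if hasattr(model, "jac"):
            kwargs["jac"] = model.jac
        sol = solve_ivp(
            model.rhs,
            (times[0], times[-1]),
            x0,
            t_eval=times,
            method=method,
            rtol=rtol,
            atol=atol,
            **kwargs,
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if len(sol.t) else float(times[0])
            raise IntegrationError(f"ODE solver failed: {sol.message}", t_fail=t_fail)
        states = sol.y

    y = np.clip(model.observe(states), 0.0, None)
    return Trajectory(times=times, y=y, network=model.network, states=states)


def disable_site(model: _ModelBase, site: str) -> _ModelBase:
    """Model surgery: remove every reaction involving ``site``.

    Returns the same model family on the restricted lattice (the motifs with
    ``site`` unacetylated), keeping the rates of all surviving edges and all
    global parameters unchanged.  This realizes the K16R counterfactual:
    predictions of a wild-type-calibrated model with K16 chemistry disabled.
    """
    if site not in model.network.sites:
        raise ValueError(f"site {site!r} not in model network")
    remaining = tuple(s for s in model.network.sites if s != site)
    sub = build_network(remaining)

    old_rates = (
        model.edge_rates if isinstance(model, MassActionModel) else model.edge_kcat
    )
    by_key = {
        (e.source.label, e.site): r for e, r in zip(model.network.edges, old_rates)
    }
    new_rates = np.array([by_key[(e.source.label, e.site)] for e in sub.edges])

    if isinstance(model, MassActionModel):
        return MassActionModel(sub, new_rates)
    if isinstance(model, MichaelisMentenModel):
        return MichaelisMentenModel(sub, new_rates, model.Km, model.e_tot)
    if isinstance(model, ProcessiveModel):
        return ProcessiveModel(
            sub, new_rates, model.kon, model.koff, model.e_tot, model.k_transfer
        )
    raise TypeError(f"unsupported model type {type(model).__name__}")
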