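"""Dimensionless E-cadherin / beta-catenin / proteasome kinetics per cell.

Species (concentrations scaled to the total E-cadherin reference E0):

* ``Ecad``     -- free cytoplasmic E-cadherin (E)
* ``Bcat``     -- free cytoplasmic beta-catenin (B)
* ``Complex``  -- membrane E-cadherin/beta-catenin complex (C)
* ``BcatPro``  -- beta-catenin--proteasome complex (Q); the free proteasome
  is implied as P0 - Q.

Model (both adhesion branches live in one right-hand side, selected by the
zero/non-zero gate pair; J+/J- are the half-rectified rates of contact-area
change from :func:`contact_forcing`):

    dE/dt = -k1 * phi * E * B + (J- + d_eff) * C
    dB/dt = alpha - k1 * phi * E * B + (J- + d_eff) * C
            - kappa * B * (P0 - Q) + k_minus * Q
    dC/dt =  k1 * phi * E * B - (J- + d_eff) * C
    dQ/dt =  kappa * B * (P0 - Q) - (k_minus + nu) * Q

with phi = [attached] * J+ (complex formation is exclusive to the attached
branch: membrane bond assembly needs cell-cell contact) and d_eff the complex
dissociation rate d, multiplied by a boost factor while detached.  The
contact-loss release term (J- * C) is active in both branches: bonds broken
by a shrinking contact area dump their cadherin and beta-catenin back into
the cytoplasm whether or not the cell has crossed the EMT threshold -- this
is what lets one cell's detachment raise free beta-catenin in its still
attached neighbours and so propagate detachment waves.

E + C (total cadherin) and Q + (P0 - Q) (total proteasome) are conserved;
free beta-catenin is produced at rate alpha and degraded, via the proteasome
complex, at rate nu.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AnalysisError, DomainError, IntegrationError, InvalidParameterError

__all__ = [
    "SPECIES_NAMES",
    "PARAM_NAMES",
    "KineticParams",
    "NetworkState",
    "Moiety",
    "rhs",
    "rhs_vec",
    "contact_forcing",
    "integrate_step",
    "integrate_states",
    "conserved_combinations",
    "detached_steady_state",
]

SPECIES_NAMES = ("Ecad", "Bcat", "Complex", "BcatPro")

# per-instance parameter columns used by the vectorised core and the registry
PARAM_NAMES = (
    "k1", "kappa", "k_minus", "nu", "alpha", "d", "detach_boost",
    "p_plus", "p_minus", "P0", "E0", "beta_thr",
    "phi_gate", "psi_gate", "Jplus", "Jminus",
)
_P = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass
class KineticParams:
    """Dimensionless kinetic parameters (defaults are the package's standard
    conditions, see docs/methods.md for the reasoning behind each value)."""

    binding_ecad_bcat: float = 20.0       # k1
    binding_bcat_proteasome: float = 5.0  # kappa (the trigger parameter)
    dissoc_bcat_proteasome: float = 0.1   # k_minus
    degradation_nu: float = 0.4           # nu
    production_alpha: float = 0.1         # alpha
    dissoc_complex_d: float = 0.2         # d
    threshold_beta: float = 0.18          # EMT/MET threshold on free Bcat
    p_plus: float = 1.0
    p_minus: float = 2.0
    proteasome_total_P0: float = 1.0
    ecad_total_E0: float = 1.0
    detach_dissoc_boost: float = 10.0

    def __post_init__(self):
        for name in ("binding_ecad_bcat", "binding_bcat_proteasome",
                     "dissoc_bcat_proteasome", "degradation_nu",
                     "production_alpha", "dissoc_complex_d", "p_plus",
                     "p_minus", "proteasome_total_P0", "ecad_total_E0",
                     "detach_dissoc_boost"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.threshold_beta <= 0:
            raise InvalidParameterError("threshold_beta must be positive")

    def to_param_row(self, mode: str = "attached",
                     forcing=(0.0, 0.0)) -> np.ndarray:
        row = np.zeros(len(PARAM_NAMES))
        row[_P["k1"]] = self.binding_ecad_bcat
        row[_P["kappa"]] = self.binding_bcat_proteasome
        row[_P["k_minus"]] = self.dissoc_bcat_proteasome
        row[_P["nu"]] = self.degradation_nu
        row[_P["alpha"]] = self.production_alpha
        row[_P["d"]] = self.dissoc_complex_d
        row[_P["detach_boost"]] = self.detach_dissoc_boost
        row[_P["p_plus"]] = self.p_plus
        row[_P["p_minus"]] = self.p_minus
        row[_P["P0"]] = self.proteasome_total_P0
        row[_P["E0"]] = self.ecad_total_E0
        row[_P["beta_thr"]] = self.threshold_beta
        row[_P["phi_gate"]] = 1.0 if mode == "attached" else 0.0
        row[_P["psi_gate"]] = 0.0 if mode == "attached" else 1.0
        row[_P["Jplus"]] = forcing[0]
        row[_P["Jminus"]] = forcing[1]
        return row


@dataclass
class NetworkState:
    ecad_cytoplasm: float = 1.0
    bcat_free: float = 0.0
    complex_membrane: float = 0.0
    bcat_proteasome: float = 0.0
    mode: str = "attached"
    contact_fraction_prev: float = 0.0
    contact_fraction_now: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.ecad_cytoplasm, self.bcat_free,
                         self.complex_membrane, self.bcat_proteasome])

    def with_array(self, y) -> "NetworkState":
        return replace(self, ecad_cytoplasm=float(y[0]), bcat_free=float(y[1]),
                       complex_membrane=float(y[2]), bcat_proteasome=float(y[3]))


def rhs_vec(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Vectorised right-hand side; Y is (n, 4), P is (n, len(PARAM_NAMES))."""
    E, B, C, Q = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3]
    phi = P[:, _P["phi_gate"]] * P[:, _P["Jplus"]]
    d_eff = P[:, _P["d"]] * (1.0 + (P[:, _P["detach_boost"]] - 1.0) * P[:, _P["psi_gate"]])
    form = P[:, _P["k1"]] * phi * E * B
    rel = (P[:, _P["Jminus"]] + d_eff) * C
    bind = P[:, _P["kappa"]] * B * (P[:, _P["P0"]] - Q)
    unbind = P[:, _P["k_minus"]] * Q
    out = np.empty_like(Y)
    out[:, 0] = -form + rel
    out[:, 1] = P[:, _P["alpha"]] - form + rel - bind + unbind
    out[:, 2] = form - rel
    out[:, 3] = bind - unbind - P[:, _P["nu"]] * Q
    return out


def rhs(state: NetworkState, params: KineticParams, forcing=(0.0, 0.0)):
    """Time derivatives of the four species for one cell.

    ``forcing`` is the (J+, J-) pair from :func:`contact_forcing`; the branch
    is selected by ``state.mode``.
    """
    y = state.to_array()
    if np.any(y < 0):
        raise DomainError("negative concentration passed to rhs")
    if forcing[0] < 0 or forcing[1] < 0:
        raise DomainError("forcing must be non-negative")
    row = params.to_param_row(state.mode, forcing)
    dy = rhs_vec(y[None, :], row[None, :])[0]
    return tuple(float(v) for v in dy)


def contact_forcing(g_prev: float, g_now: float, p_plus: float,
                    p_minus: float, dt: float):
    """(J+, J-) translocation forcing from the contact-fraction change.

    J+ = p_plus * max(r, 0), J- = p_minus * max(-r, 0) with
    r = (g_now - g_prev) / dt; at most one of the pair is non-zero.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    r = (g_now - g_prev) / dt
    return (p_plus * max(r, 0.0), p_minus * max(-r, 0.0))


# ---------------------------------------------------------------------------
# Cash-Karp embedded Runge-Kutta 4(5), vectorised across instances.
_CK_A = (
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (3 / 10, -9 / 10, 6 / 5),
    (-11 / 54, 5 / 2, -70 / 27, 35 / 27),
    (1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096),
)
_CK_B5 = (37 / 378, 0, 250 / 621, 125 / 594, 0, 512 / 1771)
_CK_B4 = (2825 / 27648, 0, 18575 / 48384, 13525 / 55296, 277 / 14336, 1 / 4)


def integrate_states(Y, P, dt, rhs_fn=rhs_vec, rtol=1e-8, atol=1e-10,
                     cell_ids=None):
    """Advance all rows of Y by ``dt`` with adaptive Cash-Karp RK45.

    Returns ``(Y_new, n_clipped)`` where ``n_clipped`` counts entries clipped
    at zero after the solve (contact forcing can push explicit steps slightly
    negative).  Deterministic for fixed inputs.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    y = np.array(Y, dtype=float)
    if y.size == 0:
        return y, 0
    t, h = 0.0, float(dt)
    h_min = dt * 1e-12
    while t < dt - 1e-15 * dt:
        h = min(h, dt - t)
        ks = []
        for i in range(6):
            yi = y.copy()
            for j, a in enumerate(_CK_A[i]):
                yi += h * a * ks[j]
            ks.append(rhs_fn(yi, P))
        y5 = y.copy()
        y4 = y.copy()
        for i in range(6):
            y5 += h * _CK_B5[i] * ks[i]
            y4 += h * _CK_B4[i] * ks[i]
        err = np.abs(y5 - y4) / (atol + rtol * np.maximum(np.abs(y), np.abs(y5)))
        emax = float(err.max()) if err.size else 0.0
        if emax <= 1.0:
            t += h
            y = y5
            h *= min(5.0, 0.9 * (emax + 1e-16) ** -0.2)
        else:
            h *= max(0.1, 0.9 * emax ** -0.25)
        if h < h_min:
            bad = None
            if cell_ids is not None and err.size:
                bad = int(cell_ids[int(np.argmax(err.max(axis=1)))])
            raise IntegrationError("integrator step collapsed", cell_id=bad)
    neg = y < 0
    n_clip = int(neg.sum())
    if n_clip:
        y[neg] = 0.0
    return y, n_clip


def integrate_step(state: NetworkState, params: KineticParams,
                   forcing=(0.0, 0.0), dt: float = 0.03) -> NetworkState:
    """Advance one cell's network by ``dt`` (default one MCS worth, 0.03)."""
    y = state.to_array()[None, :]
    row = params.to_param_row(state.mode, forcing)[None, :]
    y_new, _ = integrate_states(y, row, dt)
    return state.with_array(y_new[0])


@dataclass
class Moiety:
    """A linear combination of species with identically zero derivative."""

    label: str
    coefficients: dict  # name -> coefficient, over SPECIES_NAMES + ProteasomeFree

    def value(self, state: NetworkState, params: KineticParams) -> float:
        vals = dict(zip(SPECIES_NAMES, state.to_array()))
        vals["ProteasomeFree"] = params.proteasome_total_P0 - state.bcat_proteasome
        return float(sum(c * vals[n] for n, c in self.coefficients.items()))


def conserved_combinations(params: KineticParams) -> list[Moiety]:
    """Symbolically determined conserved linear combinations of species.

    The system is extended with the implied free proteasome (P = P0 - Q) and
    every combination c . f(x) that vanishes identically -- for all species
    values, forcings and both adhesion branches -- is returned.
    """
    import sympy as sp

    E, B, C, Q, Pf = sp.symbols("E B C Q Pf", nonnegative=True)
    jp, jm, fg, sg = sp.symbols("jp jm fg sg", nonnegative=True)
    k1 = sp.Float(params.binding_ecad_bcat)
    kap = sp.Float(params.binding_bcat_proteasome)
    km = sp.Float(params.dissoc_bcat_proteasome)
    nu = sp.Float(params.degradation_nu)
    al = sp.Float(params.production_alpha)
    d = sp.Float(params.dissoc_complex_d)
    boost = sp.Float(params.detach_dissoc_boost)

    phi = fg * jp
    d_eff = d * (1 + (boost - 1) * sg)
    form = k1 * phi * E * B
    rel = (jm + d_eff) * C
    bind = kap * B * Pf
    unbind = km * Q
    f = [
        -form + rel,                                   # dE
        al - form + rel - bind + unbind,               # dB
        form - rel,                                    # dC
        bind - unbind - nu * Q,                        # dQ
        -bind + unbind + nu * Q,                       # dPf
    ]
    names = list(SPECIES_NAMES) + ["ProteasomeFree"]
    c = sp.symbols("c0:5")
    expr = sp.expand(sum(ci * fi for ci, fi in zip(c, f)))
    poly = sp.Poly(expr, E, B, C, Q, Pf, jp, jm, fg, sg)
    eqs = [sp.Eq(coeff, 0) for coeff in poly.coeffs()]
    sol = sp.linsolve(eqs, c)
    if not sol:
        return []
    (vec,) = sol
    free = sorted(vec.free_symbols, key=lambda s: s.name)
    basis = []
    for fs in free:
        subs = {s: (1 if s == fs else 0) for s in free}
        coeffs = [sp.nsimplify(v.subs(subs)) for v in vec]
        entry = {n: float(co) for n, co in zip(names, coeffs) if co != 0}
        if entry:
            label = " + ".join(f"{n}" if co == 1 else f"{co:g}*{n}"
                               for n, co in entry.items())
            basis.append(Moiety(label=label, coefficients=entry))
    basis.sort(key=lambda m: m.label)
    return basis


def detached_steady_state(params: KineticParams) -> NetworkState:
    """Closed-form steady state of a detached, contact-free cell.

    With no forcing the complex fully dissociates (C = 0, E = E0) and the
    proteasome branch balances production against degradation:
    Q* = alpha / nu,  B* = (k_minus + nu) Q* / (kappa (P0 - Q*)).
    """
    al = params.production_alpha
    nu = params.degradation_nu
    if al == 0.0:
        state = NetworkState(ecad_cytoplasm=params.ecad_total_E0, bcat_free=0.0,
                             complex_membrane=0.0, bcat_proteasome=0.0,
                             mode="detached")
        return state
    if nu == 0.0 or al >= nu * params.proteasome_total_P0:
        raise AnalysisError(
            "no non-negative steady state: beta-catenin production exceeds the "
            "proteasome degradation capacity (alpha >= nu * P0)")
    if params.binding_bcat_proteasome == 0.0:
        raise AnalysisError("no steady state with zero proteasome binding rate")
    q = al / nu
    b = ((params.dissoc_bcat_proteasome + nu) * q
         / (params.binding_bcat_proteasome * (params.proteasome_total_P0 - q)))
    state = NetworkState(ecad_cytoplasm=params.ecad_total_E0, bcat_free=b,
                         complex_membrane=0.0, bcat_proteasome=q,
                         mode="detached")
    resid = np.array(rhs(state, params, (0.0, 0.0)))
    if np.max(np.abs(resid)) > 1e-8:
        raise AnalysisError("steady-state residual exceeds tolerance")
    return state
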