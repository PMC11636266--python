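"""Deterministic ODE model of the three-device receiver genetic circuit.

The receiver cell converts extracellular inducer arrivals into an intracellular
readout via three transcriptional devices:

1. a sensing device constitutively expressing the LacI and TetR repressors;
   the arriving inducers sequester their matching repressor (IPTG binds LacI,
   aTc binds TetR);
2. a data-carrier device: the P_Ai promoter, repressed by free LacI, drives
   ``mRNA_Ai`` -> ``Ai`` — so IPTG arrival de-represses Ai production;
3. an antagonist device: the P_Bi promoter, repressed by free TetR, drives
   ``mRNA_Bi`` -> ``Bi`` — so aTc arrival de-represses Bi production.

Ai and Bi bind irreversibly (rate ``k_seq``) into an inert complex: the
antagonist titrates away stray data-carrier molecules, implementing a
biological subtraction whose result is the free-Ai level, the quantity the
detector thresholds.

State variables are molecule copy numbers per cell; the model is deterministic
(large copy numbers, well-stirred cytoplasm).  Inducer–repressor binding is
treated at rapid equilibrium: the free repressor concentration is the exact
solution of the 1:1 binding quadratic and enters a Hill repression term.

The reaction network is held symbolically (sympy), giving a single source of
truth for the compiled ODE right-hand side, its Jacobian, and the SBML export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "CircuitParams",
    "Reaction",
    "CircuitModel",
    "Trajectory",
    "build_model",
    "inject_arrivals",
    "simulate",
]

#: state variables, in integration order (molecules per cell)
SPECIES = ("IPTG", "aTc", "LacI", "TetR", "mRNA_Ai", "mRNA_Bi", "Ai", "Bi", "AiBi")


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of the receiver circuit (default fixture).

    The defaults are nominal bacterial rates for low-copy-plasmid devices;
    both arms of the circuit are symmetric so the native Bi/Ai ratio is 1.
    All quantities are molecules per cell and seconds.

    The default repressor pool (~100 copies) together with tight inducer
    binding (Kd = 10 molecules) puts the sensing devices in a stoichiometric
    titration regime: an inducer burst overwhelms its repressor and fully
    de-represses the output gene, and expression stays on until the inducer
    pool decays back below the repressor level.  This ultrasensitive switch
    is what makes accumulated channel tails genuinely disruptive — and what
    the antagonist arm is there to cancel.

    Attributes
    ----------
    transcription_rate_ai, transcription_rate_bi
        Maximal (fully de-repressed) transcription rate of each output gene,
        mRNA/s per plasmid copy.
    plasmid_copies
        Gene dose of every device (low-copy plasmid).
    translation_rate
        Proteins synthesised per mRNA per second.
    mrna_degradation_rate, protein_degradation_rate
        First-order decay; the protein rate lumps dilution by growth with
        active (degradation-tagged) turnover — fast proteins (half-life
        ~2.3 min at the default) so the receiver can keep up with the
        channel rather than integrate it.
    repressor_synthesis_laci, repressor_synthesis_tetr
        Lumped constitutive synthesis of each repressor protein
        (transcription x translation at steady-state mRNA), protein/s.
    repression_K_ai, repression_K_bi
        Free-repressor level giving half-maximal repression of P_Ai / P_Bi.
    hill_ai, hill_bi
        Repression cooperativity (LacI and TetR are multimeric).
    binding_K_iptg_laci, binding_K_atc_tetr
        Dissociation constant of the 1:1 inducer-repressor pair, molecules.
    inducer_degradation_rate
        First-order loss of intracellular inducer (dilution + export).
    sequestration_rate
        Mass-action rate of Ai + Bi -> complex, 1/(molecule s).
    complex_unbinding_rate
        Reverse of sequestration; 0 by default (pure subtraction semantics).
    complex_degradation_rate
        First-order decay of the Ai:Bi complex.
    promoter_model
        "hill" (default): repression factor 1 / (1 + (R_free/K)^n) with the
        free repressor from the binding quadratic; "occupancy": non-cooperative
        mass-action promoter occupancy 1 / (1 + R_free/K).
    """

    transcription_rate_ai: float = 0.05
    transcription_rate_bi: float = 0.05
    plasmid_copies: int = 10
    translation_rate: float = 0.05
    mrna_degradation_rate: float = 0.01
    protein_degradation_rate: float = 0.005
    repressor_synthesis_laci: float = 0.5
    repressor_synthesis_tetr: float = 0.5
    repression_K_ai: float = 10.0
    repression_K_bi: float = 10.0
    hill_ai: float = 2.0
    hill_bi: float = 2.0
    binding_K_iptg_laci: float = 10.0
    binding_K_atc_tetr: float = 10.0
    inducer_degradation_rate: float = 0.005
    sequestration_rate: float = 1e-3
    complex_unbinding_rate: float = 0.0
    complex_degradation_rate: float = 0.005
    promoter_model: str = "hill"

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if name == "promoter_model":
                continue
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.plasmid_copies < 1:
            raise ValueError("plasmid_copies must be >= 1")
        if self.promoter_model not in ("hill", "occupancy"):
            raise ValueError(f"unknown promoter_model {self.promoter_model!r}")

    def with_(self, **changes) -> "CircuitParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class Reaction:
    """One reaction: net stoichiometry (species -> change) and a sympy rate law."""

    name: str
    stoichiometry: dict
    rate: sp.Expr


def _free_repressor(total: sp.Expr, inducer: sp.Expr, kd: float) -> sp.Expr:
    """Free repressor after rapid-equilibrium 1:1 binding with the inducer.

    Exact root of  C^2 - (R + I + Kd) C + R I = 0  (bound complex C), with
    R_free = R - C.  Always in [0, R] for nonnegative R, I.
    """
    s = total + inducer + kd
    complex_ = (s - sp.sqrt(s**2 - 4 * total * inducer)) / 2
    return total - complex_


@dataclass
class CircuitModel:
    """Symbolic reaction network plus timed injection events.

    ``assignments`` are derived quantities (free repressor levels) substituted
    into the rate laws before compilation and exported as SBML assignment
    rules.  ``events`` is a list of ``(time_s, {species: added_amount})``.
    """

    params: CircuitParams
    reactions: list
    assignments: dict
    initial_state: np.ndarray
    events: list = field(default_factory=list)

    _compiled: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def species(self) -> tuple:
        return SPECIES

    def total_injected(self, species: str) -> float:
        return float(sum(amounts.get(species, 0.0) for _, amounts in self.events))

    # -- compilation -------------------------------------------------------

    def _symbols(self):
        return sp.symbols(" ".join(SPECIES))

    def rhs_exprs(self) -> list:
        """Net production rate of each species, assignment rules substituted."""
        subs = {sp.Symbol(k): v for k, v in self.assignments.items()}
        exprs = []
        for name in SPECIES:
            total = sp.Integer(0)
            for rxn in self.reactions:
                coeff = rxn.stoichiometry.get(name, 0)
                if coeff:
                    total += coeff * rxn.rate
            exprs.append(total.subs(subs))
        return exprs

    def compiled(self):
        """Lambdified (rhs, jac) callables f(t, y) for the integrator."""
        if self._compiled is None:
            syms = self._symbols()
            exprs = self.rhs_exprs()
            mat = sp.Matrix(exprs)
            jac_rows = mat.jacobian(sp.Matrix(syms)).tolist()
            f = sp.lambdify(syms, exprs, modules="math", cse=True)
            jf = sp.lambdify(syms, jac_rows, modules="math", cse=True)

            def rhs(t, y):
                return f(*y)

            def jac(t, y):
                return np.asarray(jf(*y))

            self._compiled = (rhs, jac)
        return self._compiled


@dataclass(frozen=True)
class Trajectory:
    """Simulated copy-number time courses on a regular output grid."""

    times_s: np.ndarray
    values: pd.DataFrame  # one column per species

    def __getitem__(self, species: str) -> np.ndarray:
        return self.values[species].to_numpy()

    @property
    def free_ai(self) -> np.ndarray:
        """The detector readout: unbound data-carrier molecules."""
        return self["Ai"]

    def ratio(self, floor: float = 1e-12) -> np.ndarray:
        """Bi/Ai ratio, the equilibrium indicator of the period finder."""
        return self["Bi"] / np.maximum(self["Ai"], floor)


def build_model(params: CircuitParams, initial_state: np.ndarray | None = None) -> CircuitModel:
    """Assemble the receiver circuit reaction network for the given constants.

    The network has 9 species and 17 reactions: constitutive repressor
    synthesis and decay (4), inducer decay (2), repressible transcription (2),
    mRNA decay (2), translation (2), output-protein decay (2), sequestration,
    complex unbinding and complex decay (3).
    """
    p = params
    IPTG, aTc, LacI, TetR, mAi, mBi, Ai, Bi, AiBi = sp.symbols(" ".join(SPECIES))
    laci_free = sp.Symbol("LacI_free")
    tetr_free = sp.Symbol("TetR_free")

    assignments = {
        "LacI_free": _free_repressor(LacI, IPTG, p.binding_K_iptg_laci),
        "TetR_free": _free_repressor(TetR, aTc, p.binding_K_atc_tetr),
    }

    if p.promoter_model == "hill":
        rep_ai = 1 / (1 + (laci_free / p.repression_K_ai) ** p.hill_ai)
        rep_bi = 1 / (1 + (tetr_free / p.repression_K_bi) ** p.hill_bi)
    else:  # non-cooperative promoter occupancy
        rep_ai = 1 / (1 + laci_free / p.repression_K_ai)
        rep_bi = 1 / (1 + tetr_free / p.repression_K_bi)

    d_p, d_m = p.protein_degradation_rate, p.mrna_degradation_rate
    reactions = [
        Reaction("laci_synthesis", {"LacI": 1}, sp.Float(p.repressor_synthesis_laci)),
        Reaction("tetr_synthesis", {"TetR": 1}, sp.Float(p.repressor_synthesis_tetr)),
        Reaction("laci_degradation", {"LacI": -1}, d_p * LacI),
        Reaction("tetr_degradation", {"TetR": -1}, d_p * TetR),
        Reaction("iptg_degradation", {"IPTG": -1}, p.inducer_degradation_rate * IPTG),
        Reaction("atc_degradation", {"aTc": -1}, p.inducer_degradation_rate * aTc),
        Reaction(
            "mrna_ai_transcription",
            {"mRNA_Ai": 1},
            p.transcription_rate_ai * p.plasmid_copies * rep_ai,
        ),
        Reaction(
            "mrna_bi_transcription",
            {"mRNA_Bi": 1},
            p.transcription_rate_bi * p.plasmid_copies * rep_bi,
        ),
        Reaction("mrna_ai_degradation", {"mRNA_Ai": -1}, d_m * mAi),
        Reaction("mrna_bi_degradation", {"mRNA_Bi": -1}, d_m * mBi),
        Reaction("ai_translation", {"Ai": 1}, p.translation_rate * mAi),
        Reaction("bi_translation", {"Bi": 1}, p.translation_rate * mBi),
        Reaction("ai_degradation", {"Ai": -1}, d_p * Ai),
        Reaction("bi_degradation", {"Bi": -1}, d_p * Bi),
        Reaction("sequestration", {"Ai": -1, "Bi": -1, "AiBi": 1}, p.sequestration_rate * Ai * Bi),
        Reaction("complex_unbinding", {"Ai": 1, "Bi": 1, "AiBi": -1}, p.complex_unbinding_rate * AiBi),
        Reaction("complex_degradation", {"AiBi": -1}, p.complex_degradation_rate * AiBi),
    ]

    init = np.zeros(len(SPECIES)) if initial_state is None else np.asarray(initial_state, float)
    if init.shape != (len(SPECIES),):
        raise ValueError(f"initial_state must have shape ({len(SPECIES)},)")
    return CircuitModel(params=params, reactions=reactions, assignments=assignments, initial_state=init)


def inject_arrivals(model: CircuitModel, series) -> CircuitModel:
    """Attach the arrival series as discrete additive injection events.

    At every sample time of the series, the expected A_e arrivals of that slot
    are added to the intracellular IPTG pool and the expected B_e arrivals to
    the aTc pool — mirroring one timed event per CSV value.  The input model
    is not mutated.
    """
    if np.any(series.a_counts < 0) or np.any(series.b_counts < 0):
        raise ValueError("arrival counts must be nonnegative")
    events = list(model.events)
    for t, a, b in zip(series.times_s, series.a_counts, series.b_counts):
        amounts = {}
        if a > 0:
            amounts["IPTG"] = float(a)
        if b > 0:
            amounts["aTc"] = float(b)
        if amounts:
            events.append((float(t), amounts))
    events.sort(key=lambda e: e[0])
    new = replace(model, events=events)
    new._compiled = model._compiled  # compilation is event-independent
    return new


def simulate(
    model: CircuitModel,
    horizon_s: float,
    output_step_s: float = 40.0,
    rtol: float = 1e-6,
    atol: float = 1e-6,
) -> Trajectory:
    """Integrate the circuit ODEs with event handling.

    LSODA (stiff-capable, with the symbolic Jacobian) integrates between
    injection events; at each event the injected amounts are added to the
    state.  An output sample that coincides with an event time reports the
    post-injection state, matching the convention that a slot's arrivals are
    credited at the slot's end.

    Raises
    ------
    RuntimeError
        On integrator failure, reporting the time reached and last step.
    """
    if not horizon_s > 0:
        raise ValueError("horizon_s must be > 0")
    rhs, jac = model.compiled()
    out_times = np.arange(0.0, horizon_s + 0.5 * output_step_s, output_step_s)
    out_times = out_times[out_times <= horizon_s + 1e-9]

    event_map: dict[float, dict] = {}
    for t, amounts in model.events:
        if t <= horizon_s + 1e-9:
            merged = event_map.setdefault(round(t, 9), {})
            for k, v in amounts.items():
                merged[k] = merged.get(k, 0.0) + v

    breakpoints = np.unique(np.concatenate([out_times, np.array(sorted(event_map))]))
    breakpoints = breakpoints[(breakpoints >= 0) & (breakpoints <= horizon_s + 1e-9)]

    y = model.initial_state.copy()
    out_values = np.empty((len(out_times), len(SPECIES)))
    out_idx = 0
    sidx = {s: i for i, s in enumerate(SPECIES)}

    t_cur = 0.0
    if breakpoints[0] <= 1e-12:
        ev = event_map.get(round(breakpoints[0], 9))
        if ev:
            for k, v in ev.items():
                y[sidx[k]] += v
        if out_idx < len(out_times) and abs(out_times[out_idx] - breakpoints[0]) < 1e-9:
            out_values[out_idx] = y
            out_idx += 1
        breakpoints = breakpoints[1:]

    for t_next in breakpoints:
        if t_next > t_cur + 1e-12:
            sol = solve_ivp(
                rhs,
                (t_cur, t_next),
                y,
                method="LSODA",
                jac=jac,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed at t={sol.t[-1]:.3f} s "
                    f"(target {t_next:.3f} s): {sol.message}"
                )
            y = np.maximum(sol.y[:, -1], 0.0)  # clip integrator round-off undershoot
        t_cur = t_next
        ev = event_map.get(round(t_next, 9))
        if ev:
            for k, v in ev.items():
                y[sidx[k]] += v
        if out_idx < len(out_times) and abs(out_times[out_idx] - t_next) < 1e-9:
            out_values[out_idx] = y
            out_idx += 1

    if out_idx != len(out_times):  # horizon beyond last breakpoint (no events there)
        raise AssertionError("internal error: output grid not fully covered")

    return Trajectory(times_s=out_times, values=pd.DataFrame(out_values, columns=list(SPECIES)))
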