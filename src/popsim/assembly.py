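"""Dynamic assembly of multi-compound PBPK/PD ODE systems.

A :class:`~popsim.workspace.ModelSelection` names, per compound, an
absorption model (iv, first-order depot, or a compartmental transit
chain), a distribution model (one-compartment, minimal PBPK with
central/portal/liver, or perfusion-limited full PBPK), a set of
elimination mechanisms, up to three chained metabolites and optionally
full target-mediated drug disposition.  :func:`assemble` composes the
chosen mechanism contributions into a single right-hand side over a
contiguous state vector, appends states required by pharmacodynamic
link units, and reserves a re-indexed trailing block for user-scripted
ODEs.

Amount states are in mg (metabolites in parent-equivalent mg so that
mass balance closes exactly; molecular weights convert only inside
concentration observables).  TMDD target/complex states are in µM.

Competitive enzyme inhibition scales each enzyme's intrinsic clearance
by ``1/(1 + Σ_i Cu_i/Ki_i)`` with the unbound inhibitor concentration
taken at the enzyme site (liver compartment when the inhibitor has one,
otherwise central).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import AssemblyError, ContractError, DivergenceError
from .pdmodels import (
    evaluate_basic,
    link_gradient,
    link_initial,
    link_output,
    link_state_count,
    validate_graph,
)
from .population import Individual
from .workspace import (
    CompoundModel,
    CompoundRecord,
    ModelSelection,
    PDGraph,
    PDUnit,
)

__all__ = [
    "StateEntry",
    "StateIndexMap",
    "AssembledODESystem",
    "assemble",
    "count_states",
    "evaluate_rhs",
    "register_custom_block",
]

BLOOD_VOLUME_70KG = 5.6  # L, central volume of the full-PBPK layout


@dataclass(frozen=True)
class StateEntry:
    moiety: str  # compound or metabolite name, "pd", or "custom"
    compartment: str
    index: int


@dataclass(frozen=True)
class StateIndexMap:
    entries: tuple[StateEntry, ...]
    custom_block_offset: int

    def __post_init__(self):
        names = [(e.moiety, e.compartment) for e in self.entries]
        if len(set(names)) != len(names):
            raise AssemblyError("state names must be unique")
        for i, e in enumerate(self.entries):
            if e.index != i:
                raise AssemblyError("state indices must be contiguous from 0")
        object.__setattr__(self, "_lookup", {key: i for i, key in enumerate(names)})

    def index(self, moiety: str, compartment: str) -> int:
        try:
            return self._lookup[(moiety, compartment)]
        except KeyError:
            raise KeyError(f"no state for ({moiety!r}, {compartment!r})") from None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CustomBlock:
    n_states: int
    step_fn: Callable  # (t, full_state, user_slice, ctx) -> gradients
    init_fn: Optional[Callable] = None  # (ctx) -> initial values
    label: str = "custom"


def _dist_compartments(cm: CompoundModel) -> list[str]:
    if cm.distribution == "one_compartment":
        return ["central"]
    if cm.distribution == "minimal_pbpk":
        return ["central", "portal", "liver"]
    return ["central", *cm.organs]


def _compound_layout(name: str, cm: CompoundModel, track_balance: bool) -> list[tuple[str, str]]:
    states: list[tuple[str, str]] = []
    if cm.absorption == "first_order":
        states.append((name, "gut"))
    elif cm.absorption == "cat":
        states += [(name, f"transit{i + 1}") for i in range(cm.n_transit)]
    states += [(name, comp) for comp in _dist_compartments(cm)]
    if cm.tmdd:
        states += [(name, "target"), (name, "complex")]
    if track_balance:
        states.append((name, "eliminated"))
        if cm.absorption != "iv":
            states.append((name, "unabsorbed"))
    for met in cm.metabolites:
        if met.disposition == "one_compartment":
            states.append((met.name, "central"))
        else:
            states += [(met.name, c) for c in ("central", "portal", "liver")]
        if track_balance:
            states.append((met.name, "eliminated"))
    return states


def _profile_pd_units(pd_graph: Optional[PDGraph]) -> list[PDUnit]:
    """Units evaluated inside the ODE, in topological order (long-timescale
    units run post hoc on summarised inputs and carry no states here)."""
    if pd_graph is None:
        return []
    order = validate_graph(pd_graph)
    by_id = {u.unit_id: u for u in pd_graph.units}
    return [by_id[uid] for uid in order if by_id[uid].timescale != "long"]


def _layout(
    selection: ModelSelection, pd_graph: Optional[PDGraph]
) -> tuple[list[tuple[str, str]], list[PDUnit]]:
    selection.validate()
    states: list[tuple[str, str]] = []
    for name, cm in selection.compound_models.items():
        states += _compound_layout(name, cm, selection.track_balance)
    pd_units = _profile_pd_units(pd_graph)
    for u in pd_units:
        if u.kind != "link":
            continue
        n = link_state_count(u)
        if n == 1:
            states.append(("pd", u.unit_id))
        else:
            states += [("pd", f"{u.unit_id}:{k}") for k in range(n)]
    return states, pd_units


def count_states(selection: ModelSelection, pd_graph: Optional[PDGraph] = None) -> int:
    """State count of the system :func:`assemble` would build, without
    constructing the right-hand side."""
    states, _ = _layout(selection, pd_graph)
    return len(states)


@dataclass(frozen=True)
class AssembledODESystem:
    """State-index map plus right-hand-side contract for one model selection."""

    selection: ModelSelection
    compounds: dict[str, CompoundRecord]
    index_map: StateIndexMap
    pd_units: tuple[PDUnit, ...]
    custom_blocks: tuple[CustomBlock, ...] = ()

    @property
    def n_states(self) -> int:
        return len(self.index_map)

    # -- context -----------------------------------------------------------

    def build_context(self, individual: Individual) -> dict:
        """Resolve compound × individual parameters into the numeric
        context the right-hand side consumes."""
        ctx: dict = {"individual": individual, "compounds": {}}
        bw = individual.body_weight
        vols = individual.organ_volumes
        flows = individual.organ_flows
        q_ha = flows.get("hepatic_artery", 21.6)
        q_pv = flows.get("portal_vein", 68.4)
        for name, cm in self.selection.compound_models.items():
            c = self.compounds[name]
            fu_b = c.fu_plasma / c.blood_plasma_ratio
            clint: dict[str, float] = {}
            if "well_stirred_hepatic" in cm.elimination:
                if not c.clint_per_enzyme:
                    raise AssemblyError(
                        f"compound {name!r}, mechanism well_stirred_hepatic: "
                        "parameter clint_per_enzyme missing"
                    )
                liver_g = vols.get("liver", 1.69) * individual.liver_density * 1000.0
                for enz, v in c.clint_per_enzyme.items():
                    if enz not in individual.enzyme_abundances:
                        raise AssemblyError(
                            f"compound {name!r}, mechanism well_stirred_hepatic: "
                            f"enzyme abundance {enz!r} missing from the individual"
                        )
                    # µL/min/pmol × pmol/mg × mg/g × g → µL/min → L/h
                    clint[enz] = (
                        v
                        * individual.enzyme_abundances[enz]
                        * individual.mppgl
                        * liver_g
                        * 60.0
                        / 1.0e6
                    )
            if cm.tmdd and c.tmdd is None:
                raise AssemblyError(
                    f"compound {name!r}, mechanism tmdd: parameter set tmdd missing"
                )
            v_li = vols.get("liver", 1.69)
            v_pv = vols.get("portal_vein", 0.07)
            kp_li = c.kp.get("liver", 1.0)
            if cm.distribution == "one_compartment":
                v_c = c.vss * bw
            elif cm.distribution == "minimal_pbpk":
                v_c = max(c.vss * bw - kp_li * v_li - v_pv, 0.1 * c.vss * bw)
            else:
                v_c = BLOOD_VOLUME_70KG * bw / 70.0
            organs = {}
            if cm.distribution == "full_pbpk":
                for organ in cm.organs:
                    q = flows.get(organ, flows.get("gut", 65.0))
                    if organ == "liver":
                        q = q_ha + q_pv
                    organs[organ] = (vols.get(organ, 1.0), q, c.kp.get(organ, 1.0))
            cc = {
                "record": c,
                "model": cm,
                "V_c": v_c,
                "V_pv": v_pv,
                "V_li": v_li,
                "Kp_li": kp_li,
                "Q_ha": q_ha,
                "Q_pv": q_pv,
                "Q_H": q_ha + q_pv,
                "ka": c.ka,
                "ktr": (cm.n_transit + 1) / c.mtt if cm.absorption == "cat" else 0.0,
                "fa": c.fa,
                "fu": c.fu_plasma,
                "fuB": fu_b,
                "MW": c.molecular_weight,
                "clint": clint,
                "CL_R": c.renal_cl if "renal" in cm.elimination else 0.0,
                "CL_lin": c.linear_cl if "linear_cl" in cm.elimination else 0.0,
                "organs": organs,
                "tmdd": c.tmdd if cm.tmdd else None,
                "mets": [
                    {
                        "name": m.name,
                        "V": m.vss * bw,
                        "cl": m.cl,
                        "fm": m.fraction_formed,
                        "MW": m.molecular_weight,
                        "disposition": m.disposition,
                    }
                    for m in cm.metabolites
                ],
            }
            ctx["compounds"][name] = cc
        ctx["receptor_abundance"] = individual.parameters.get("receptor_abundance", 1.0)
        return ctx

    def initial_state(self, ctx: dict) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        idx = self.index_map.index
        for name, cc in ctx["compounds"].items():
            t = cc["tmdd"]
            if t is not None:
                y0[idx(name, "target")] = t.ksyn / t.kdeg if t.kdeg > 0 else 0.0
        for u in self.pd_units:
            if u.kind == "link" and u.model != "custom":
                init = link_initial(u)
                base = idx("pd", u.unit_id if len(init) == 1 else f"{u.unit_id}:0")
                y0[base : base + len(init)] = init
        offset = self.index_map.custom_block_offset
        for block in self.custom_blocks:
            if block.init_fn is not None:
                vals = np.asarray(block.init_fn(ctx), dtype=float)
                if vals.size != block.n_states:
                    raise ContractError(
                        f"custom block {block.label!r}: init_fn returned {vals.size} "
                        f"values for {block.n_states} states"
                    )
                y0[offset : offset + block.n_states] = vals
            offset += block.n_states
        return y0

    # -- dosing ------------------------------------------------------------

    def dose_targets(self, compound: str, route: str) -> list[tuple[int, float]]:
        """(state index, fraction of dose) pairs receiving a dose.

        Oral first-order dosing deposits fa·dose in the gut depot (the
        balance goes to the unabsorbed bookkeeping state when tracked);
        transit-chain dosing fills the first segment; iv routes target
        the central compartment.
        """
        cm = self.selection.for_compound(compound)
        idx = self.index_map.index
        if route in ("iv_bolus", "iv_infusion"):
            return [(idx(compound, "central"), 1.0)]
        if cm.absorption == "iv":
            raise AssemblyError(
                f"compound {compound!r}: oral dose but absorption model is iv"
            )
        if cm.absorption == "cat":
            return [(idx(compound, "transit1"), 1.0)]
        fa = self.compounds[compound].fa
        targets = [(idx(compound, "gut"), fa)]
        if self.selection.track_balance and fa < 1.0:
            targets.append((idx(compound, "unabsorbed"), 1.0 - fa))
        return targets

    # -- right-hand side ---------------------------------------------------

    def _site_concentrations_uM(self, y: np.ndarray, ctx: dict) -> dict[str, float]:
        """Unbound concentration (µM) of every compound at the enzyme site."""
        idx = self.index_map.index
        site = {}
        for name, cc in ctx["compounds"].items():
            cm = cc["model"]
            if cm.distribution == "minimal_pbpk" or (
                cm.distribution == "full_pbpk" and "liver" in cm.organs
            ):
                a_li = y[idx(name, "liver")]
                conc = a_li / (cc["V_li"] * cc["Kp_li"])
            else:
                conc = y[idx(name, "central")] / cc["V_c"]
            site[name] = cc["fu"] * conc / cc["MW"] * 1000.0
        return site

    def _inhibition_factors(self, site_uM: dict[str, float]) -> dict[str, float]:
        factors: dict[str, float] = {}
        for inhibitor, table in self.selection.inhibition.items():
            cu = site_uM.get(inhibitor, 0.0)
            for enz, ki in table.items():
                factors[enz] = factors.get(enz, 1.0) + cu / ki
        return factors

    def rhs(self, t: float, y: np.ndarray, ctx: dict) -> np.ndarray:
        if not np.isfinite(y).all():
            raise DivergenceError(f"non-finite state at t={t:g} h")
        idx = self.index_map.index
        dy = np.zeros_like(y)
        track = self.selection.track_balance
        site_uM = self._site_concentrations_uM(y, ctx)
        inh = self._inhibition_factors(site_uM)

        for name, cc in ctx["compounds"].items():
            cm = cc["model"]
            c_central = y[idx(name, "central")] / cc["V_c"]

            # absorption ---------------------------------------------------
            abs_input = 0.0
            unabsorbed_flux = 0.0
            if cm.absorption == "first_order":
                i_gut = idx(name, "gut")
                rate = cc["ka"] * y[i_gut]
                dy[i_gut] -= rate
                abs_input = rate
            elif cm.absorption == "cat":
                ktr, ka = cc["ktr"], cc["ka"]
                prev = 0.0
                for seg in range(cm.n_transit):
                    i_seg = idx(name, f"transit{seg + 1}")
                    a = y[i_seg]
                    dy[i_seg] += prev - (ktr + ka) * a
                    abs_input += ka * a
                    prev = ktr * a
                unabsorbed_flux = prev  # outflow of the last segment

            # distribution + elimination ----------------------------------
            hepatic_flux = 0.0
            i_c = idx(name, "central")
            cl_sys = cc["CL_R"] + cc["CL_lin"]
            clint_scaled = {e: v / inh.get(e, 1.0) for e, v in cc["clint"].items()}
            clint_total = sum(clint_scaled.values())

            if cm.distribution == "one_compartment":
                dy[i_c] += abs_input - cl_sys * c_central
                if clint_total > 0.0:
                    clh = (
                        cc["Q_H"] * cc["fuB"] * clint_total
                        / (cc["Q_H"] + cc["fuB"] * clint_total)
                    )
                    hepatic_flux = clh * c_central
                    dy[i_c] -= hepatic_flux
            elif cm.distribution == "minimal_pbpk":
                i_pv, i_li = idx(name, "portal"), idx(name, "liver")
                c_pv = y[i_pv] / cc["V_pv"]
                c_li = y[i_li] / (cc["V_li"] * cc["Kp_li"])
                hepatic_flux = clint_total * cc["fuB"] * c_li
                dy[i_pv] += abs_input + cc["Q_pv"] * (c_central - c_pv)
                dy[i_li] += (
                    cc["Q_ha"] * c_central
                    + cc["Q_pv"] * c_pv
                    - cc["Q_H"] * c_li
                    - hepatic_flux
                )
                dy[i_c] += (
                    cc["Q_H"] * c_li
                    - cc["Q_H"] * c_central
                    - cl_sys * c_central
                )
            else:  # full_pbpk
                dy[i_c] -= cl_sys * c_central
                liver_present = "liver" in cc["organs"]
                for organ, (v_t, q_t, kp_t) in cc["organs"].items():
                    i_t = idx(name, organ)
                    c_out = y[i_t] / (v_t * kp_t)
                    dy[i_t] += q_t * (c_central - c_out)
                    dy[i_c] += q_t * (c_out - c_central)
                    if organ == "liver":
                        flux = clint_total * cc["fuB"] * c_out
                        dy[i_t] += abs_input - flux
                        hepatic_flux = flux
                if not liver_present:
                    dy[i_c] += abs_input
                    if clint_total > 0.0:
                        clh = (
                            cc["Q_H"] * cc["fuB"] * clint_total
                            / (cc["Q_H"] + cc["fuB"] * clint_total)
                        )
                        hepatic_flux = clh * c_central
                        dy[i_c] -= hepatic_flux

            # target-mediated disposition ---------------------------------
            eliminated_flux = cl_sys * c_central
            if cc["tmdd"] is not None:
                tm = cc["tmdd"]
                i_r, i_p = idx(name, "target"), idx(name, "complex")
                r_free, complex_ = y[i_r], y[i_p]
                cu_uM = cc["fu"] * c_central / cc["MW"] * 1000.0
                binding = tm.kon * cu_uM * r_free - tm.koff * complex_
                dy[i_r] += tm.ksyn - tm.kdeg * r_free - binding
                dy[i_p] += binding - (tm.koff + tm.kint) * complex_
                mg_per_uM = cc["V_c"] * cc["MW"] / 1000.0
                dy[i_c] -= binding * mg_per_uM
                eliminated_flux += tm.kint * complex_ * mg_per_uM

            # metabolite chain --------------------------------------------
            feed = hepatic_flux  # flux available to form the first metabolite
            for met in cc["mets"]:
                formed = met["fm"] * feed
                feed_remainder = (1.0 - met["fm"]) * feed
                i_m = idx(met["name"], "central")
                c_m = y[i_m] / met["V"]
                elim_m = met["cl"] * c_m
                if met["disposition"] == "one_compartment":
                    dy[i_m] += formed - elim_m
                else:
                    i_mpv, i_mli = idx(met["name"], "portal"), idx(met["name"], "liver")
                    c_mpv = y[i_mpv] / cc["V_pv"]
                    c_mli = y[i_mli] / cc["V_li"]
                    dy[i_mpv] += cc["Q_pv"] * (c_m - c_mpv)
                    dy[i_mli] += (
                        formed
                        + cc["Q_ha"] * c_m
                        + cc["Q_pv"] * c_mpv
                        - cc["Q_H"] * c_mli
                    )
                    dy[i_m] += cc["Q_H"] * c_mli - cc["Q_H"] * c_m - elim_m
                # the next link in the chain is fed by this metabolite's
                # elimination flux; remainders are booked below
                met["_elim_flux"] = elim_m
                met["_remainder"] = feed_remainder
                feed = elim_m

            if track:
                i_e = idx(name, "eliminated")
                rem = eliminated_flux
                if cc["mets"]:
                    rem += cc["mets"][0]["_remainder"]
                    # downstream remainders belong to the producing metabolite
                    for k, met in enumerate(cc["mets"]):
                        nxt = cc["mets"][k + 1] if k + 1 < len(cc["mets"]) else None
                        kept = nxt["_remainder"] if nxt is not None else met["_elim_flux"]
                        dy[idx(met["name"], "eliminated")] += kept
                else:
                    rem += hepatic_flux
                dy[i_e] += rem
                if cm.absorption == "cat":
                    dy[idx(name, "unabsorbed")] += unabsorbed_flux

        # pharmacodynamic units -------------------------------------------
        if self.pd_units:
            self._pd_gradients(t, y, dy, ctx)

        # user-scripted block ---------------------------------------------
        offset = self.index_map.custom_block_offset
        for block in self.custom_blocks:
            user = y[offset : offset + block.n_states]
            grads = np.asarray(block.step_fn(t, y, user, ctx), dtype=float)
            if grads.size != block.n_states:
                raise ContractError(
                    f"custom block {block.label!r}: step_fn returned {grads.size} "
                    f"gradients for {block.n_states} states"
                )
            dy[offset : offset + block.n_states] += grads
            offset += block.n_states
        return dy

    def _pd_drive(self, name_spec: str, y, ctx, outputs) -> float:
        if name_spec.startswith("unit:"):
            return outputs[name_spec.split(":", 1)[1]]
        parts = name_spec.split(":")
        compound = parts[1]
        cc = ctx["compounds"][compound]
        idx = self.index_map.index
        if len(parts) < 3 or parts[2] == "central":
            return y[idx(compound, "central")] / cc["V_c"]
        comp = parts[2]
        if comp == "liver":
            return y[idx(compound, "liver")] / (cc["V_li"] * cc["Kp_li"])
        if comp == "portal":
            return y[idx(compound, "portal")] / cc["V_pv"]
        v_t, _, kp_t = cc["organs"][comp]
        return y[idx(compound, comp)] / (v_t * kp_t)

    def _pd_gradients(self, t, y, dy, ctx) -> None:
        idx = self.index_map.index
        outputs: dict[str, float] = {}
        for u in self.pd_units:
            drive = self._pd_drive(u.input, y, ctx, outputs)
            if u.kind == "basic":
                outputs[u.unit_id] = float(
                    evaluate_basic(u, drive, ctx["receptor_abundance"])
                )
                continue
            if u.model == "custom":
                # custom link dynamics live in the registered custom block
                outputs[u.unit_id] = y[idx("pd", u.unit_id)]
                continue
            n = link_state_count(u)
            base = idx("pd", u.unit_id if n == 1 else f"{u.unit_id}:0")
            states = y[base : base + n]
            grads = link_gradient(u, drive, states)
            dy[base : base + n] += grads
            outputs[u.unit_id] = float(link_output(u, states))

    # -- observables -------------------------------------------------------

    def observables(self, times: np.ndarray, Y: np.ndarray, ctx: dict) -> dict[str, np.ndarray]:
        """Named trajectories derived from the state matrix (n_times × n_states):
        plasma and organ concentrations (mg/L), TMDD target/complex (µM)
        and every PD unit output."""
        idx = self.index_map.index
        out: dict[str, np.ndarray] = {}
        for name, cc in ctx["compounds"].items():
            cm = cc["model"]
            out[f"C_{name}"] = Y[:, idx(name, "central")] / cc["V_c"]
            if cm.distribution == "minimal_pbpk":
                out[f"C_{name}_portal"] = Y[:, idx(name, "portal")] / cc["V_pv"]
                out[f"C_{name}_liver"] = Y[:, idx(name, "liver")] / (cc["V_li"] * cc["Kp_li"])
            elif cm.distribution == "full_pbpk":
                for organ, (v_t, _, kp_t) in cc["organs"].items():
                    out[f"C_{name}_{organ}"] = Y[:, idx(name, organ)] / (v_t * kp_t)
            if cc["tmdd"] is not None:
                out[f"R_{name}"] = Y[:, idx(name, "target")]
                out[f"P_{name}"] = Y[:, idx(name, "complex")]
            for met in cc["mets"]:
                # stored in parent-equivalent mg; convert to metabolite mg/L
                scale = met["MW"] / cc["MW"]
                out[f"C_{met['name']}"] = Y[:, idx(met["name"], "central")] * scale / met["V"]
        if self.pd_units:
            unit_out: dict[str, np.ndarray] = {}
            for u in self.pd_units:
                drive = self._pd_drive_vector(u.input, Y, ctx, unit_out)
                if u.kind == "basic":
                    unit_out[u.unit_id] = np.asarray(
                        evaluate_basic(u, drive, ctx["receptor_abundance"]), dtype=float
                    )
                elif u.model == "custom":
                    unit_out[u.unit_id] = Y[:, idx("pd", u.unit_id)]
                else:
                    n = link_state_count(u)
                    base = idx("pd", u.unit_id if n == 1 else f"{u.unit_id}:0")
                    unit_out[u.unit_id] = np.asarray(
                        link_output(u, [Y[:, base + k] for k in range(n)]), dtype=float
                    )
            for uid, series in unit_out.items():
                out[f"PD_{uid}"] = series
        return out

    def _pd_drive_vector(self, name_spec, Y, ctx, outputs):
        if name_spec.startswith("unit:"):
            return outputs[name_spec.split(":", 1)[1]]
        parts = name_spec.split(":")
        compound = parts[1]
        cc = ctx["compounds"][compound]
        idx = self.index_map.index
        if len(parts) < 3 or parts[2] == "central":
            return Y[:, idx(compound, "central")] / cc["V_c"]
        comp = parts[2]
        if comp == "liver":
            return Y[:, idx(compound, "liver")] / (cc["V_li"] * cc["Kp_li"])
        if comp == "portal":
            return Y[:, idx(compound, "portal")] / cc["V_pv"]
        v_t, _, kp_t = cc["organs"][comp]
        return Y[:, idx(compound, comp)] / (v_t * kp_t)


def assemble(
    selection: ModelSelection,
    compounds: dict[str, CompoundRecord] | list[CompoundRecord] | tuple[CompoundRecord, ...],
    pd_graph: Optional[PDGraph] = None,
) -> AssembledODESystem:
    """Compose the selected mechanisms into an ODE system.

    Raises :class:`~popsim.errors.AssemblyError` naming the compound,
    mechanism and parameter when a selected mechanism lacks its
    parameters.
    """
    if not isinstance(compounds, dict):
        compounds = {c.name: c for c in compounds}
    for name, cm in selection.compound_models.items():
        if name not in compounds:
            raise AssemblyError(f"no compound record for selected compound {name!r}")
        if "well_stirred_hepatic" in cm.elimination and not compounds[name].clint_per_enzyme:
            raise AssemblyError(
                f"compound {name!r}, mechanism well_stirred_hepatic: "
                "parameter clint_per_enzyme missing"
            )
        if cm.tmdd and compounds[name].tmdd is None:
            raise AssemblyError(
                f"compound {name!r}, mechanism tmdd: parameter set tmdd missing"
            )
    states, pd_units = _layout(selection, pd_graph)
    for u in pd_units:
        if u.kind == "link" and u.model == "custom" and "n_states" not in u.params:
            raise AssemblyError(
                f"PD unit {u.unit_id!r}: custom link model requires an n_states "
                "parameter and a registered custom block"
            )
    entries = tuple(
        StateEntry(moiety, compartment, i) for i, (moiety, compartment) in enumerate(states)
    )
    index_map = StateIndexMap(entries=entries, custom_block_offset=len(entries))
    return AssembledODESystem(
        selection=selection,
        compounds=dict(compounds),
        index_map=index_map,
        pd_units=tuple(pd_units),
    )


def register_custom_block(
    system: AssembledODESystem,
    n_user_states: int,
    step_fn: Callable,
    init_fn: Optional[Callable] = None,
    label: str = "custom",
) -> AssembledODESystem:
    """Append a user-scripted ODE block; returns a new system.

    ``step_fn(t, full_state, user_slice, ctx)`` must return exactly
    ``n_user_states`` gradients (checked at first call); it has read
    access to the whole state vector and the individual's covariates
    via ``ctx``.  ``n_user_states == 0`` returns the system unchanged.
    """
    if n_user_states < 0:
        raise ContractError("n_user_states must be >= 0")
    if n_user_states == 0:
        return system
    entries = list(system.index_map.entries)
    start = len(entries)
    for k in range(n_user_states):
        entries.append(StateEntry("custom", f"{label}:{start + k}", start + k))
    index_map = StateIndexMap(
        entries=tuple(entries),
        custom_block_offset=system.index_map.custom_block_offset,
    )
    blocks = system.custom_blocks + (
        CustomBlock(n_states=n_user_states, step_fn=step_fn, init_fn=init_fn, label=label),
    )
    return replace(system, index_map=index_map, custom_blocks=blocks)


def evaluate_rhs(
    system: AssembledODESystem,
    t: float,
    state: np.ndarray,
    individual: Individual,
    infusions: Optional[list[tuple[int, float]]] = None,
    ctx: Optional[dict] = None,
) -> np.ndarray:
    """Evaluate the assembled right-hand side at one point.

    ``infusions`` lists (state index, rate mg/h) of active constant-rate
    inputs.  Passing a prebuilt ``ctx`` skips re-resolving the
    individual's parameters.
    """
    if ctx is None:
        ctx = system.build_context(individual)
    state = np.asarray(state, dtype=float)
    if state.size != system.n_states:
        raise ContractError(
            f"state length {state.size} does not match n_states {system.n_states}"
        )
    dy = system.rhs(t, state, ctx)
    if infusions:
        for index, rate in infusions:
            dy[index] += rate
    return dy
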