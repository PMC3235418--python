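"""Composite-network assembly, relaxation dynamics, and knockout screening.

Per-node fitted models are consolidated into a single network (one node per
gene plus an optional phenotype sink).  The network is relaxed to equilibrium
by damped synchronous iteration

    I[n+1] = alpha * F(I[n]) + (1 - alpha) * I[n]

where ``F`` is one fuzzy-prediction pass over all nodes from the current
state, run on the bounded normalized scale (genes in [-1, 1], phenotype
carried internally as its defuzzified [0, 1] value).  Iteration stops when
the infinity norm of the update falls below a tolerance (default 1e-7, with
the conservative mixing weight alpha = 0.01).

Gene knockouts clamp a node to the low extreme (-1); a clamped node ignores
its model at every step.  Viability of a knockout is read off the converged
budding fractions across many initial conditions (each observed time point
serving as one): collapse to a single arrested regime is called inviable,
persistence of distinct high/low outcomes (bistability) viable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .errors import NetworkAssemblyError, SimulationError
from .fuzzy_core import _fuzzify_gene_f, _fuzzify_phenotype_f
from .model_search import PHENOTYPE, NodeModel
from .preprocess import (
    ExpressionDataset,
    phenotype_backtransform,
    phenotype_backtransform_inverse,
)

__all__ = [
    "CompositeNetwork",
    "SimulationTrajectory",
    "KnockoutPrediction",
    "assemble",
    "simulate",
    "knockout",
    "viability_screen",
    "initial_conditions_from_dataset",
    "to_networkx",
]

KNOCKOUT_VALUE = -1.0  # normalized low extreme


@dataclass(frozen=True)
class CompositeNetwork:
    """All node models consolidated over shared nodes.

    ``nodes`` covers every model output and every resolved input; nodes
    without a model are pure inputs and hold their value during simulation.
    ``clamped`` maps knocked-out nodes to their fixed values.
    """

    nodes: tuple[str, ...]
    models: dict[str, NodeModel]
    homolog_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    clamped: dict[str, float] = field(default_factory=dict)

    @property
    def phenotype_node(self) -> str | None:
        for out, m in self.models.items():
            if m.is_phenotype:
                return out
        return None


@dataclass
class SimulationTrajectory:
    """Relaxation trajectory: per-node states by iteration (normalized
    scale), convergence flag/count, and the converged budding fraction
    (logistic back-transform of the phenotype node's internal value)."""

    node_order: tuple[str, ...]
    states: np.ndarray  # (n_recorded, n_nodes); first row = initial state
    converged: bool
    iterations: int
    final_phenotype: float | None

    @property
    def final_state(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.states[-1]))


@dataclass
class KnockoutPrediction:
    """Viability call for one (single or double) knockout."""

    knocked_out: tuple[str, ...]
    phenotype_fractions: np.ndarray  # one converged fraction per initial condition
    call: str  # "viable" | "inviable"
    n_converged: int
    n_initial_conditions: int


def assemble(models, homolog_map: dict[str, tuple[str, str]] | None = None
             ) -> CompositeNetwork:
    """Consolidate node models into one composite network.

    Every model input must resolve to a model output, another input, or a
    merged homolog pair whose members then become (pure-input) nodes.
    """
    models = list(models)
    if not models:
        raise NetworkAssemblyError("no models to assemble")
    homolog_map = {k: tuple(v) for k, v in (homolog_map or {}).items()}
    by_output: dict[str, NodeModel] = {}
    for m in models:
        if m.output in by_output:
            raise NetworkAssemblyError(f"duplicate model for output {m.output!r}")
        by_output[m.output] = m
    phen = [m.output for m in models if m.is_phenotype]
    if len(phen) > 1:
        raise NetworkAssemblyError(f"multiple phenotype models: {phen}")
    nodes = dict.fromkeys(by_output)  # insertion-ordered set
    for m in models:
        for inp in m.inputs:
            members = homolog_map.get(inp, (inp,))
            for g in members:
                nodes.setdefault(g)
    return CompositeNetwork(nodes=tuple(nodes), models=by_output,
                            homolog_map=homolog_map)


def to_networkx(net: CompositeNetwork) -> nx.DiGraph:
    """Directed graph of resolved edges (homolog members edge individually)."""
    from .model_search import rule_sign

    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for m in net.models.values():
        for inp, rule in zip(m.inputs, m.rules):
            for member in net.homolog_map.get(inp, (inp,)):
                g.add_edge(member, m.output, sign=rule_sign(rule))
    return g


# ---------------------------------------------------------------------------
# Simulation

def _compile_step(net: CompositeNetwork):
    """Build a fast synchronous inference pass over an indexed state vector.

    Returns ``(order, step)`` where ``order`` fixes the node indexing and
    ``step(state) -> inferred`` applies every unclamped node model (scalar
    fuzzy algebra; clamped and model-less nodes hold their value).
    """
    order = net.nodes
    index = {n: i for i, n in enumerate(order)}
    phen = net.phenotype_node
    plans = []
    for out, m in net.models.items():
        if out in net.clamped:
            continue
        gathers = []
        for inp, rule in zip(m.inputs, m.rules):
            if inp in net.homolog_map:
                a, b = net.homolog_map[inp]
                gathers.append(("merge", index[a], index[b], rule))
            elif inp == phen and phen is not None:
                gathers.append(("phen", index[inp], None, rule))
            else:
                if inp not in index:
                    raise NetworkAssemblyError(
                        f"model for {out!r} references unknown node {inp!r}"
                    )
                gathers.append(("gene", index[inp], None, rule))
        plans.append((index[out], m.is_phenotype, gathers, out))

    def step(state: np.ndarray) -> np.ndarray:
        inferred = state.copy()
        for oi, is_phen, gathers, out in plans:
            z1 = z2 = z3 = 0.0
            for kind, i, j, (r1, r2, r3) in gathers:
                if kind == "merge":
                    v = state[i] if state[i] >= state[j] else state[j]
                    y = _fuzzify_gene_f(v)
                elif kind == "phen":
                    y = _fuzzify_phenotype_f(state[i])
                else:
                    y = _fuzzify_gene_f(state[i])
                z1 += y[r1 - 1]
                z2 += y[r2 - 1]
                z3 += y[r3 - 1]
            den = z1 + z2 + z3
            if den <= 0.0:
                raise SimulationError(
                    f"degenerate all-zero fuzzy state for node {out!r}"
                )
            inferred[oi] = (0.5 * z2 + z3) / den if is_phen else (z3 - z1) / den
        return inferred

    return order, step


def simulate(net: CompositeNetwork, init: dict[str, float], *,
             alpha: float = 0.01, tol: float = 1e-7, max_iter: int = 100_000,
             record_states: bool = True) -> SimulationTrajectory:
    """Relax the network from an initial state.

    ``init`` must cover every unclamped node (genes on [-1, 1]; the phenotype
    node on its internal [0, 1] defuzzified scale).  Clamped nodes keep their
    fixed value at every step.  Non-convergence at ``max_iter`` returns a
    trajectory with ``converged=False`` and a warning, not an exception.
    """
    if not 0.0 < alpha <= 1.0:
        raise SimulationError("alpha must be in (0, 1]")
    order, step = _compile_step(net)
    state = np.empty(len(order))
    for i, n in enumerate(order):
        if n in net.clamped:
            state[i] = net.clamped[n]
        elif n in init:
            state[i] = float(init[n])
        else:
            raise SimulationError(f"initial value missing for unclamped node {n!r}")
    clamp_idx = [i for i, n in enumerate(order) if n in net.clamped]
    clamp_val = np.array([net.clamped[order[i]] for i in clamp_idx])

    recorded = [state.copy()] if record_states else None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        inferred = step(state)
        nxt = alpha * inferred + (1.0 - alpha) * state
        if clamp_idx:
            nxt[clamp_idx] = clamp_val
        delta = float(np.max(np.abs(nxt - state)))
        state = nxt
        if recorded is not None:
            recorded.append(state.copy())
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"simulation did not converge within {max_iter} iterations "
            f"(last update {delta:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    phen = net.phenotype_node
    final_phenotype = None
    if phen is not None:
        final_phenotype = float(phenotype_backtransform(state[order.index(phen)]))
    states = (np.array(recorded) if recorded is not None
              else np.array([state]))
    return SimulationTrajectory(node_order=order, states=states,
                                converged=converged, iterations=iterations,
                                final_phenotype=final_phenotype)


def knockout(net: CompositeNetwork, targets) -> CompositeNetwork:
    """Clamp one or two gene nodes to the low-expression extreme (-1).

    For merged homolog inputs the max-merge still applies, so knocking out a
    single member leaves the pair's input at the surviving member's value.
    """
    targets = (targets,) if isinstance(targets, str) else tuple(targets)
    phen = net.phenotype_node
    for t in targets:
        if t not in net.nodes:
            raise SimulationError(f"unknown node {t!r}")
        if t == phen:
            raise SimulationError("cannot knock out the phenotype node")
    clamped = dict(net.clamped)
    clamped.update({t: KNOCKOUT_VALUE for t in targets})
    return replace(net, clamped=clamped)


def viability_screen(net: CompositeNetwork, initial_conditions, targets=(), *,
                     arrest_spread: float = 0.1, regime_boundary: float = 0.5,
                     alpha: float = 0.01, tol: float = 1e-7,
                     max_iter: int = 100_000) -> KnockoutPrediction:
    """Simulate a (possibly knocked-out) network from every initial condition
    and classify viability from the converged budding fractions.

    Inviable: the spread (max - min) of converged fractions is below
    ``arrest_spread`` (a single arrested state) OR every fraction falls on
    one side of ``regime_boundary`` (one regime only).  Viable otherwise --
    the bistable high/low pattern of a cycling population.
    """
    initial_conditions = list(initial_conditions)
    if len(initial_conditions) < 2:
        raise SimulationError("viability screen needs >= 2 initial conditions")
    knet = knockout(net, targets) if targets else net
    if knet.phenotype_node is None:
        raise SimulationError("network has no phenotype node")
    fractions = []
    for init in initial_conditions:
        traj = simulate(knet, init, alpha=alpha, tol=tol, max_iter=max_iter,
                        record_states=False)
        if traj.converged:
            fractions.append(traj.final_phenotype)
    if not fractions:
        raise SimulationError("no trajectory converged; cannot call viability")
    if len(fractions) < len(initial_conditions):
        warnings.warn(
            f"{len(initial_conditions) - len(fractions)} trajectories did not "
            "converge; viability called on the converged subset",
            RuntimeWarning,
            stacklevel=2,
        )
    fr = np.array(fractions)
    arrested = (fr.max() - fr.min()) < arrest_spread
    one_regime = bool(np.all(fr < regime_boundary) or np.all(fr > regime_boundary))
    call = "inviable" if (arrested or one_regime) else "viable"
    targets = (targets,) if isinstance(targets, str) else tuple(targets)
    return KnockoutPrediction(
        knocked_out=targets, phenotype_fractions=fr, call=call,
        n_converged=len(fractions), n_initial_conditions=len(initial_conditions),
    )


def initial_conditions_from_dataset(dataset: ExpressionDataset,
                                    net: CompositeNetwork) -> list[dict[str, float]]:
    """One initial condition per observed time point: normalized expression
    for gene nodes, the inverse-logistic of the observed budding fraction for
    the phenotype node (0.5 when no phenotype track is present).  Time points
    with missing values for any required node are skipped."""
    phen = net.phenotype_node
    conditions = []
    for t in range(dataset.n_times):
        init: dict[str, float] = {}
        ok = True
        for n in net.nodes:
            if n in net.clamped:
                continue
            if n == phen:
                if dataset.phenotype is None or math.isnan(dataset.phenotype[t]):
                    init[n] = 0.5
                else:
                    p = min(max(float(dataset.phenotype[t]), 1e-9), 1 - 1e-9)
                    init[n] = float(phenotype_backtransform_inverse(p))
                continue
            v = dataset.normalized_row(n)[t]
            if math.isnan(v):
                ok = False
                break
            init[n] = float(v)
        if ok:
            conditions.append(init)
    if not conditions:
        raise SimulationError("no usable time point for initial conditions")
    return conditions
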