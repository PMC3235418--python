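"""Ground-truth fuzzy networks and synthetic time-series expression data.

The generator emulates the structure of a cell-cycle microarray time course
(a handful of co-oscillating genes, ~24 time points, a budding-fraction
phenotype track) while keeping the generating law identical to the law the
inference assumes, so that model recovery is a strict self-consistency test:

* The network contains two planted negative-feedback rings (three and four
  genes, each with one inhibitory edge) whose synchronous update orbits are
  sustained oscillations of period 6 and 8; over the default 24 recorded
  columns every column is therefore a distinct phase of the joint orbit,
  which is what keeps decoy inputs distinguishable from planted ones.
  Remaining genes are driven off the rings through randomly sampled rule
  vectors biased toward monotone activation/inhibition (two-input genes
  straddle the rings, again for identifiability).
* The recorded columns are an exact orbit of the full synchronous update map
  ``col[t+1] = F(col[t])`` from a randomized start, so every gene's true
  model reproduces its series exactly at lag 1; the phenotype track is
  computed instantaneously from the true (noise-free) gene state, so the
  phenotype model is exact at lag 0.
* Measurement noise is additive Gaussian on the log2 scale (where microarray
  error is approximately additive) and is applied after the true states are
  laid down, mirroring the real pipeline order.

``generate_dataset`` additionally rejects degenerate draws (near-constant
genes, distinct genes whose series coincide up to sign -- which would make
the planted inputs unidentifiable) and re-samples deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fuzzy_core
from .errors import DataValidationError, DomainError
from .model_search import PHENOTYPE, NodeModel
from .network_dynamics import CompositeNetwork, _compile_step, assemble
from .preprocess import ExpressionDataset, denormalize_expression, phenotype_backtransform

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "generate_timeseries",
    "generate_dataset",
    "budding_switch_network",
    "budding_switch_initial_conditions",
]

_MONOTONE = ((1, 2, 3), (3, 2, 1))
# near-monotone alternatives (saturating variants); sampled with probability
# 1 - monotone_bias on multi-input edges only, so every node keeps at least
# one medium-preserving rule and its combined triple can never be all-zero
_SATURATING = ((1, 1, 3), (3, 3, 1), (1, 2, 2), (2, 2, 3))

_N_RING = 7  # genes consumed by the two planted oscillator rings (3 + 4)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic study.

    Defaults mirror the modeled cell-cycle series: 17 genes plus a phenotype
    track over 24 time points, in-degree at most 2, and additive log2-scale
    noise with standard deviation 0.1.  ``seed`` fully determines every
    sampled quantity.  ``topology``/``rules``/``phenotype_model`` may pin the
    network explicitly; otherwise it is sampled.
    """

    n_genes: int = 17
    n_timepoints: int = 24
    max_in_degree: int = 2
    noise_sd: float = 0.1
    phenotype_inputs: int = 2
    monotone_bias: float = 0.75
    n_homolog_pairs: int = 0
    seed: int = 0
    topology: dict | None = None
    rules: dict | None = None
    phenotype_model: NodeModel | None = None

    def __post_init__(self) -> None:
        if self.topology is None and self.n_genes < _N_RING:
            raise DomainError(
                f"need at least {_N_RING} genes for the planted oscillator rings "
                "(or pass an explicit topology)"
            )
        if self.n_genes < 2:
            raise DomainError("need at least 2 genes")
        if self.max_in_degree > self.n_genes - 1:
            raise DomainError("max_in_degree exceeds n_genes - 1")
        if self.n_timepoints < 2:
            raise DomainError("need at least 2 time points")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


def _gene_names(spec: SyntheticSpec) -> list[str]:
    return [f"G{i + 1:02d}" for i in range(spec.n_genes)]


def generate_network(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Sample (or materialize) a ground-truth network.

    Returns ``(net, truth)`` where ``truth`` maps each output (genes and the
    phenotype sink) to its true :class:`NodeModel`.  Gene models hold at
    lag 1 of the generated series, the phenotype model at lag 0.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    names = _gene_names(spec)
    truth: dict[str, NodeModel] = {}

    if spec.topology is not None:
        rules = spec.rules or {}
        for out, inputs in spec.topology.items():
            truth[out] = NodeModel(output=out, inputs=tuple(inputs),
                                   rules=tuple(rules.get(out) or
                                               (fuzzy_core.ACTIVATION,) * len(inputs)))
    else:
        # two planted negative-feedback rings, each a directed cycle with a
        # single inhibitory edge: 3 genes (orbit period 6) and 4 genes
        # (orbit period 8) under the synchronous update
        ring1, ring2 = names[:3], names[3:_N_RING]
        for ring in (ring1, ring2):
            for j, out in enumerate(ring):
                inp = ring[j - 1]  # predecessor in the cycle
                rule = fuzzy_core.INHIBITION if j == 0 else fuzzy_core.ACTIVATION
                truth[out] = NodeModel(output=out, inputs=(inp,), rules=(rule,))
        signatures = {(m.inputs, m.rules) for m in truth.values()}
        for i in range(_N_RING, spec.n_genes):
            for _ in range(200):
                d = min(int(rng.integers(1, spec.max_in_degree + 1)), 2)
                if d == 1:
                    inputs = (str(rng.choice(names[:_N_RING])),)
                else:
                    # straddle the rings: two inputs from one ring would sum
                    # two lagged copies of the same orbit, which a decoy
                    # single input could reproduce
                    inputs = tuple(sorted(
                        (str(rng.choice(ring1)), str(rng.choice(ring2)))
                    ))
                rules = [_MONOTONE[rng.integers(2)]]
                for _ in range(d - 1):
                    if rng.random() < spec.monotone_bias:
                        rules.append(_MONOTONE[rng.integers(2)])
                    else:
                        rules.append(_SATURATING[rng.integers(len(_SATURATING))])
                sig = (inputs, tuple(rules))
                if sig not in signatures:
                    signatures.add(sig)
                    truth[names[i]] = NodeModel(output=names[i], inputs=inputs,
                                                rules=tuple(rules))
                    break
            else:  # pragma: no cover - tiny spec corner
                raise DomainError("could not sample a fresh model signature")

    homolog_map: dict[str, tuple[str, str]] = {}
    if spec.n_homolog_pairs:
        drivable = [n for n in names[_N_RING:] if n in truth]
        if spec.n_homolog_pairs > len(drivable):
            raise DomainError("more homolog pairs than driven (non-ring) genes")
        picked = rng.choice(drivable, size=spec.n_homolog_pairs, replace=False)
        for g in map(str, picked):
            twin = f"{g}B"
            truth[twin] = NodeModel(output=twin, inputs=truth[g].inputs,
                                    rules=truth[g].rules)
            homolog_map[f"{g}/{twin}"] = (g, twin)

    if spec.phenotype_model is not None:
        truth[PHENOTYPE] = spec.phenotype_model
    elif PHENOTYPE not in truth:
        if spec.topology is None and spec.phenotype_inputs == 2:
            inputs = tuple(sorted(
                (str(rng.choice(names[:3])), str(rng.choice(names[3:_N_RING])))
            ))
        else:
            k = min(spec.phenotype_inputs, spec.n_genes)
            inputs = tuple(sorted(
                str(g) for g in rng.choice(names, size=k, replace=False)
            ))
        rules = tuple(_MONOTONE[rng.integers(2)] for _ in range(len(inputs)))
        truth[PHENOTYPE] = NodeModel(output=PHENOTYPE, inputs=inputs, rules=rules,
                                     is_phenotype=True)

    net = assemble(truth.values(), homolog_map=homolog_map)
    return net, truth


def _phenotype_fraction(model: NodeModel, state: dict[str, float],
                        homolog_map: dict[str, tuple[str, str]]) -> float:
    """Instantaneous budding fraction implied by a gene state (full chain:
    fuzzify -> rules -> combine -> phenotype centroid -> logistic)."""
    zs = []
    for inp, rule in zip(model.inputs, model.rules):
        members = homolog_map.get(inp, (inp,))
        v = max(state[m] for m in members)
        zs.append(fuzzy_core.apply_rule(fuzzy_core.fuzzify_gene(v), rule))
    x = float(fuzzy_core.defuzzify_phenotype(fuzzy_core.combine(zs)))
    return float(phenotype_backtransform(x))


def _simulate_columns(net: CompositeNetwork, spec: SyntheticSpec,
                      rng: np.random.Generator):
    """True normalized trajectories: an exact orbit of the synchronous update
    map from a randomized start.  Returns (gene_names, true_norm, phenotype)."""
    order, step = _compile_step(net)
    phen = net.phenotype_node
    gene_nodes = [n for n in order if n != phen]
    index = {n: i for i, n in enumerate(order)}

    state = np.empty(len(order))
    n_ring = min(_N_RING, len(gene_nodes))
    # well-separated ring amplitudes: the ring orbits permute/negate their
    # initial values, so near-equal magnitudes would make ring series almost
    # coincide up to sign and leave the planted inputs unidentifiable
    mags = np.linspace(0.33, 0.87, n_ring) + rng.uniform(-0.025, 0.025, size=n_ring)
    rng.shuffle(mags)
    mags *= rng.choice([-1.0, 1.0], size=n_ring)
    for n, v in zip(gene_nodes[:n_ring], mags):
        state[index[n]] = v
    for n in gene_nodes[n_ring:]:
        state[index[n]] = rng.uniform(-0.8, 0.8)
    # homolog twins share their partner's start: identical models plus
    # identical initial values keep the true trajectories identical, so the
    # recorded pair differs only by measurement noise
    for g, twin in net.homolog_map.values():
        state[index[twin]] = state[index[g]]
    if phen is not None:
        state[index[phen]] = 0.5

    T = spec.n_timepoints
    true_norm = np.empty((len(gene_nodes), T))
    phen_track = np.empty(T) if phen is not None else None
    phen_model = net.models[phen] if phen is not None else None
    for t in range(T):
        if t > 0:
            state = step(state)
        for gi, n in enumerate(gene_nodes):
            true_norm[gi, t] = state[index[n]]
        if phen_track is not None:
            by_name = {n: state[index[n]] for n in gene_nodes}
            phen_track[t] = _phenotype_fraction(phen_model, by_name, net.homolog_map)
    return gene_nodes, true_norm, phen_track


def generate_timeseries(net: CompositeNetwork, spec: SyntheticSpec,
                        rng: np.random.Generator | None = None) -> ExpressionDataset:
    """Noisy expression dataset from a ground-truth network.

    True normalized states are laid down as an exact synchronous-update
    orbit, converted to log2 ratios, and perturbed with Gaussian noise of
    standard deviation ``spec.noise_sd``; the phenotype track is computed
    from the noise-free state.  Fully deterministic under ``spec.seed``.
    """
    if net.phenotype_node is None:
        raise DataValidationError("network has no phenotype model")
    rng = np.random.default_rng([spec.seed, 1]) if rng is None else rng
    gene_nodes, true_norm, phen = _simulate_columns(net, spec, rng)
    log2 = denormalize_expression(np.clip(true_norm, -0.999999, 0.999999))
    noisy = log2 + rng.normal(0.0, spec.noise_sd, size=log2.shape)
    return ExpressionDataset(
        gene_ids=gene_nodes,
        times=10.0 * np.arange(spec.n_timepoints),
        log2_matrix=noisy,
        phenotype=phen,
    )


def _columns_identifiable(true_norm: np.ndarray, gene_nodes: list[str],
                          homolog_map: dict[str, tuple[str, str]],
                          phen: np.ndarray | None) -> bool:
    twins = {frozenset(pair) for pair in homolog_map.values()}
    sd = true_norm.std(axis=1)
    if np.any(sd < 0.1):
        return False
    n = len(gene_nodes)
    T = true_norm.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            if frozenset((gene_nodes[i], gene_nodes[j])) in twins:
                continue
            # series must stay separated up to sign by a margin well above
            # measurement noise, or the pair is observationally equivalent
            # as candidate inputs and recovery is ill-posed
            same = np.sqrt(np.sum((true_norm[i] - true_norm[j]) ** 2) / T)
            anti = np.sqrt(np.sum((true_norm[i] + true_norm[j]) ** 2) / T)
            if min(same, anti) < 0.2:
                return False
    if phen is not None and not (phen.min() < 0.45 and phen.max() > 0.55):
        return False
    return True


def generate_dataset(spec: SyntheticSpec, max_attempts: int = 30):
    """Sample a network + dataset pair, rejecting unidentifiable draws.

    Returns ``(net, truth, dataset)``.  Re-draws (deterministically, salted
    from ``spec.seed``) until every gene series has spread, no two distinct
    genes coincide up to sign, and the phenotype visits both regimes.
    """
    for attempt in range(max_attempts):
        net, truth = generate_network(
            spec, rng=np.random.default_rng([spec.seed, 101, attempt])
        )
        rng = np.random.default_rng([spec.seed, 202, attempt])
        gene_nodes, true_norm, phen = _simulate_columns(net, spec, rng)
        if _columns_identifiable(true_norm, gene_nodes, net.homolog_map, phen):
            log2 = denormalize_expression(np.clip(true_norm, -0.999999, 0.999999))
            noisy = log2 + rng.normal(0.0, spec.noise_sd, size=log2.shape)
            dataset = ExpressionDataset(
                gene_ids=gene_nodes,
                times=10.0 * np.arange(spec.n_timepoints),
                log2_matrix=noisy,
                phenotype=phen,
            )
            return net, truth, dataset
    raise DataValidationError(
        f"no identifiable synthetic draw in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Hand-built screening fixture: a bistable budding switch with a planted
# essential gene and a planted redundant (synthetic-lethal) homolog pair.

def budding_switch_network() -> CompositeNetwork:
    """A six-gene network with designed knockout phenotypes.

    * ``SWITCH_A``/``SWITCH_B`` mutually inhibit (the bistable memory);
      ``SWITCH_A`` additionally integrates the essential activator ``ESS``.
    * ``ESS``, ``HOM1`` and ``HOM2`` hold their initial values through
      self-activation; ``REPORTER`` is a sink with no path to the phenotype.
    * Budding is driven by ``SWITCH_A`` and the merged pair ``HOM1/HOM2``.

    Designed calls: wild type viable (bistable across initial conditions),
    ``ESS`` knockout inviable, either single ``HOM`` knockout viable, the
    double ``HOM1``+``HOM2`` knockout inviable (synthetic lethality through
    loss of the redundant input).
    """
    act, inh = fuzzy_core.ACTIVATION, fuzzy_core.INHIBITION
    models = [
        NodeModel(output="SWITCH_A", inputs=("SWITCH_B", "ESS"), rules=(inh, act)),
        NodeModel(output="SWITCH_B", inputs=("SWITCH_A",), rules=(inh,)),
        NodeModel(output="ESS", inputs=("ESS",), rules=(act,)),
        NodeModel(output="HOM1", inputs=("HOM1",), rules=(act,)),
        NodeModel(output="HOM2", inputs=("HOM2",), rules=(act,)),
        NodeModel(output="REPORTER", inputs=("SWITCH_A",), rules=(act,)),
        NodeModel(output=PHENOTYPE, inputs=("SWITCH_A", "HOM1/HOM2"),
                  rules=(act, act), is_phenotype=True),
    ]
    return assemble(models, homolog_map={"HOM1/HOM2": ("HOM1", "HOM2")})


def budding_switch_initial_conditions() -> list[dict[str, float]]:
    """Eight initial conditions standing in for observed time points; the
    essential activator alternates between high and low starts so the wild
    type visits both phenotype regimes."""
    ess = [0.7, -0.7, 0.5, -0.5, 0.8, -0.8, 0.6, -0.6]
    a = [0.2, -0.3, 0.5, 0.1, -0.4, 0.3, -0.2, 0.4]
    hom1 = [0.55, 0.62, 0.58, 0.66, 0.52, 0.6, 0.64, 0.56]
    hom2 = [0.6, 0.54, 0.65, 0.53, 0.61, 0.57, 0.55, 0.63]
    conditions = []
    for i in range(8):
        conditions.append({
            "SWITCH_A": a[i],
            "SWITCH_B": -a[i],
            "ESS": ess[i],
            "HOM1": hom1[i],
            "HOM2": hom2[i],
            "REPORTER": a[i],
            PHENOTYPE: 0.5,
        })
    return conditions
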