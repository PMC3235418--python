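"""Bounded exhaustive model search scored by the coefficient of determination.

For one output node, every input subset of size ``1..max_inputs`` and every
assignment of one of the 27 rule vectors per input is enumerated; each model's
prediction chain is

    (homolog-merge) -> fuzzify inputs -> apply per-input rule ->
    algebraic-sum combine -> centroid defuzzify -> back-transform

and scored against the observed series with the coefficient of determination
R^2 = 1 - SSE/SST.  The search space grows as O(27^N) per subset, so a hard
cap on the evaluated-model count refuses infeasible requests up front.

Temporal alignment is controlled by ``lag``: inputs at time ``t`` predict the
output at time ``t + lag``.  At lag 0 the output is excluded from its own
candidate set (the identity rule would be a trivially perfect fit); at
lag >= 1 self-input is permitted, which admits the self-stimulation loops
seen in real regulatory networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from . import fuzzy_core
from .errors import DataValidationError, DomainError, SearchSpaceError
from .fuzzy_core import RULE_VECTORS, validate_rule
from .preprocess import (
    ExpressionDataset,
    denormalize_expression,
    phenotype_backtransform,
    phenotype_backtransform_inverse,
)

__all__ = [
    "PHENOTYPE",
    "NodeModel",
    "SearchResult",
    "cod",
    "predict_node",
    "predict_series",
    "exhaustive_search",
    "alternative_frequency",
    "count_models",
    "rule_sign",
    "model_edges",
    "save_search_results",
    "load_models",
]

#: Reserved label for the phenotype (fraction of budding cells) node.
PHENOTYPE = "phenotype"

_N_RULES = len(RULE_VECTORS)  # 27


@dataclass(frozen=True)
class NodeModel:
    """One output node's fitted model.

    ``inputs`` are node labels, each possibly a merged homolog pair written
    ``"A/B"`` and resolved through a homolog map; ``rules`` holds one rule
    vector per input (same order).  ``fitness`` is the COD of the fit (<= 1,
    possibly negative; None for hand-built models that were never scored).
    """

    output: str
    inputs: tuple[str, ...]
    rules: tuple[tuple[int, int, int], ...]
    fitness: float | None = None
    is_phenotype: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(
            self, "rules", tuple(validate_rule(r) for r in self.rules)
        )
        if len(self.inputs) != len(self.rules):
            raise DomainError("NodeModel: one rule vector per input required")
        if len(set(self.inputs)) != len(self.inputs):
            raise DomainError("NodeModel: duplicate inputs")
        if not self.inputs:
            raise DomainError("NodeModel: at least one input required")

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)


@dataclass
class SearchResult:
    """Ranked models for one output plus the alternative-input frequency table.

    ``ranked_models`` is sorted by descending fitness with deterministic
    tie-breaking (fewer inputs, then lexicographic input labels, then
    lexicographic rule encoding).  ``input_frequency`` counts, for each
    candidate, its appearances among the stored top models.
    """

    output: str
    ranked_models: list[NodeModel]
    input_frequency: dict[str, int]
    n_evaluated: int
    candidates: tuple[str, ...]
    top_m: int
    lag: int
    scale: str
    dropped_times: tuple[int, ...] = field(default_factory=tuple)

    @property
    def best(self) -> NodeModel:
        return self.ranked_models[0]


def cod(predicted, observed) -> float:
    """Coefficient of determination: ``1 - SSE/SST``.

    Equals 1 iff predictions match observations exactly; 0 for the constant
    mean predictor; may be arbitrarily negative.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 2:
        raise DataValidationError("cod: series must be 1-D, equal length, size >= 2")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise DataValidationError("cod: observed series has zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


# ---------------------------------------------------------------------------
# Input assembly

def _input_series(dataset: ExpressionDataset, label: str,
                  homolog_map: dict[str, tuple[str, str]]) -> np.ndarray:
    """Normalized series for a candidate input; merged homolog pairs take the
    elementwise maximum of their members (NaN propagates)."""
    if label in homolog_map:
        a, b = homolog_map[label]
        return fuzzy_core.homolog_merge(
            dataset.normalized_row(a), dataset.normalized_row(b)
        )
    if label == PHENOTYPE:
        if dataset.phenotype is None:
            raise DataValidationError("dataset has no phenotype track")
        return np.asarray(dataset.phenotype, dtype=float)
    return dataset.normalized_row(label)


def _observed_series(dataset: ExpressionDataset, output: str, scale: str) -> np.ndarray:
    if output == PHENOTYPE:
        if dataset.phenotype is None:
            raise DataValidationError("dataset has no phenotype track")
        obs = np.asarray(dataset.phenotype, dtype=float)
        if scale == "normalized":
            obs = phenotype_backtransform_inverse(np.clip(obs, 1e-12, 1 - 1e-12))
        return obs
    return dataset.log2_row(output) if scale == "native" else dataset.normalized_row(output)


def _fuzzify_input(label: str, values: np.ndarray) -> np.ndarray:
    if label == PHENOTYPE:
        return fuzzy_core.fuzzify_phenotype(values)
    return fuzzy_core.fuzzify_gene(values)


# ---------------------------------------------------------------------------
# Prediction (reference chain, used by tests/CLI; the search uses a
# vectorized equivalent)

def predict_series(model: NodeModel, dataset: ExpressionDataset, *,
                   homolog_map: dict[str, tuple[str, str]] | None = None,
                   lag: int = 0, scale: str = "native") -> np.ndarray:
    """Predicted output series over input times ``0 .. T-1-lag``.

    On the native scale, gene predictions are back-transformed to log2 ratios
    and phenotype predictions to budding fractions; ``scale="normalized"``
    returns the raw defuzzified values.
    """
    homolog_map = dict(homolog_map or {})
    t_in = slice(0, dataset.n_times - lag)
    intermediates = []
    for label, rule in zip(model.inputs, model.rules):
        series = _input_series(dataset, label, homolog_map)[t_in]
        intermediates.append(fuzzy_core.apply_rule(_fuzzify_input(label, series), rule))
    z = fuzzy_core.combine(intermediates)
    if model.is_phenotype:
        x = fuzzy_core.defuzzify_phenotype(z)
        return phenotype_backtransform(x) if scale == "native" else x
    x = fuzzy_core.defuzzify_gene(z)
    return denormalize_expression(x) if scale == "native" else x


def predict_node(model: NodeModel, dataset: ExpressionDataset, time_index: int, *,
                 homolog_map: dict[str, tuple[str, str]] | None = None,
                 lag: int = 0, scale: str = "native") -> float:
    """Single-time prediction: the value the output takes at
    ``time_index + lag``, computed from inputs at ``time_index``."""
    series = predict_series(model, dataset, homolog_map=homolog_map, lag=lag,
                            scale=scale)
    if not 0 <= time_index < series.size:
        raise DataValidationError(f"time_index {time_index} out of range")
    return float(series[time_index])


# ---------------------------------------------------------------------------
# Exhaustive search

def count_models(n_candidates: int, max_inputs: int) -> int:
    """Number of (subset, rule-assignment) models for a candidate pool."""
    from math import comb

    return sum(
        comb(n_candidates, n) * _N_RULES**n
        for n in range(1, min(max_inputs, n_candidates) + 1)
    )


def _rule_transforms(y: np.ndarray) -> np.ndarray:
    """(T, 3) fuzzified series -> (27, T, 3): one transformed series per rule,
    in lexicographic rule order."""
    sel = np.array(RULE_VECTORS) - 1  # (27, 3)
    return y[:, sel].transpose(1, 0, 2)


def _finish_fitness(z: np.ndarray, obs: np.ndarray, sst: float,
                    is_phenotype: bool, scale: str) -> np.ndarray:
    """(M, T, 3) combined triples -> (M,) COD values.

    Models that produce an undefined centroid (all-zero triple) or, on the
    native gene scale, a centroid of exactly +/-1 (the tangent pole has no
    finite log2 ratio) at any time point are degenerate and score -inf.
    """
    den = z.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if is_phenotype:
            pred = (0.5 * z[..., 1] + z[..., 2]) / den
            bad = den <= 0.0
            if scale == "native":
                pred = 1.0 / (1.0 + np.exp(-6.0 * (2.0 * pred - 1.0)))
        else:
            pred = (z[..., 2] - z[..., 0]) / den
            bad = den <= 0.0
            if scale == "native":
                bad = bad | (np.abs(pred) >= 1.0)
                pred = np.tan(pred * (np.pi / 2.0))
        sse = np.sum((pred - obs) ** 2, axis=-1)
        fit = 1.0 - sse / sst
    fit = np.where(bad.any(axis=-1), -np.inf, fit)
    return np.where(np.isfinite(fit), fit, -np.inf)


def _subset_fitness(transforms: list[np.ndarray], obs: np.ndarray, sst: float,
                    is_phenotype: bool, scale: str) -> np.ndarray:
    """Fitness of all 27^N rule assignments for one input subset, flattened in
    lexicographic order (first input's rule is the most significant digit).

    The last two inputs are broadcast fully (27 x 27 at a time); earlier
    inputs are looped, bounding peak memory for large subsets.
    """
    n = len(transforms)
    if n == 1:
        return _finish_fitness(transforms[0], obs, sst, is_phenotype, scale)
    tail = transforms[-2][:, None] + transforms[-1][None, :]  # (27, 27, T, 3)
    tail = tail.reshape(_N_RULES * _N_RULES, *tail.shape[2:])
    if n == 2:
        return _finish_fitness(tail, obs, sst, is_phenotype, scale)
    out = np.empty(_N_RULES**n)
    block = _N_RULES * _N_RULES
    for k, prefix in enumerate(product(range(_N_RULES), repeat=n - 2)):
        base = transforms[0][prefix[0]]
        for j in range(1, n - 2):
            base = base + transforms[j][prefix[j]]
        out[k * block:(k + 1) * block] = _finish_fitness(
            tail + base, obs, sst, is_phenotype, scale
        )
    return out


def exhaustive_search(dataset: ExpressionDataset, output: str,
                      candidates: list[str] | None = None, *,
                      max_inputs: int = 5, top_m: int = 100, lag: int = 0,
                      homolog_map: dict[str, tuple[str, str]] | None = None,
                      scale: str = "native",
                      model_cap: int = 1_000_000_000) -> SearchResult:
    """Enumerate and rank every bounded fuzzy model for one output node.

    Parameters
    ----------
    candidates : optional explicit candidate-input pool.  By default every
        gene (with homolog-pair members replaced by their merged label) is a
        candidate, minus the output itself when ``lag == 0``.
    scale : "native" scores on log2 ratios (genes) / budding fractions
        (phenotype); "normalized" scores on the bounded defuzzified scale.
    model_cap : refuse (with an estimate) rather than enumerate more models.
    """
    if lag < 0:
        raise DomainError("lag must be >= 0")
    if max_inputs < 1:
        raise DomainError("max_inputs must be >= 1")
    homolog_map = {k: tuple(v) for k, v in (homolog_map or {}).items()}
    paired = {g for pair in homolog_map.values() for g in pair}

    if candidates is None:
        pool = [g for g in dataset.gene_ids if g not in paired]
        pool += list(homolog_map)
        if lag == 0:
            pool = [c for c in pool if c != output]
        candidates = sorted(pool)
    else:
        candidates = sorted(dict.fromkeys(candidates))
        if lag == 0 and output in candidates:
            raise DomainError(
                f"output {output!r} cannot be its own input at lag 0"
            )
    if not candidates:
        raise DataValidationError("empty candidate set")

    n_models = count_models(len(candidates), max_inputs)
    if n_models > model_cap:
        raise SearchSpaceError(
            f"search would evaluate {n_models:.3e} models "
            f"({len(candidates)} candidates, max_inputs={max_inputs}); "
            f"cap is {model_cap:.0e} -- lower max_inputs or the candidate list"
        )

    # Listwise deletion over {output + all candidates}: a time pair
    # (t, t+lag) is usable iff every candidate is observed at t and the
    # output at t+lag; all models for this output share the same points.
    t_in = np.arange(dataset.n_times - lag)
    series = {c: _input_series(dataset, c, homolog_map) for c in candidates}
    obs_full = _observed_series(dataset, output, scale)
    usable = np.isfinite(obs_full[t_in + lag])
    for s in series.values():
        usable &= np.isfinite(s[t_in])
    dropped = tuple(int(t) for t in t_in[~usable])
    t_use = t_in[usable]
    if t_use.size < 2:
        raise DataValidationError(
            f"only {t_use.size} usable time point(s) after dropping missing data"
        )
    obs = obs_full[t_use + lag]
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise DataValidationError(f"observed series for {output!r} has zero variance")

    is_phen = output == PHENOTYPE
    transforms = {
        c: _rule_transforms(_fuzzify_input(c, series[c][t_use])) for c in candidates
    }

    # Per-subset top-m (stable argsort => lexicographic rule tie-break),
    # then an exact global merge under the deterministic ordering.
    entries: list[tuple[float, int, tuple[str, ...], tuple[int, ...]]] = []
    n_evaluated = 0
    for n in range(1, min(max_inputs, len(candidates)) + 1):
        shape = (_N_RULES,) * n
        for subset in combinations(candidates, n):
            fit = _subset_fitness([transforms[c] for c in subset], obs, sst,
                                  is_phen, scale)
            n_evaluated += fit.size
            order = np.argsort(-fit, kind="stable")[:top_m]
            for i in order:
                entries.append((float(fit[i]), n, subset,
                                np.unravel_index(int(i), shape)))
    entries.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
    ranked = [
        NodeModel(
            output=output,
            inputs=subset,
            rules=tuple(RULE_VECTORS[r] for r in ridx),
            fitness=fit,
            is_phenotype=is_phen,
        )
        for fit, _, subset, ridx in entries[:top_m]
    ]
    freq = {c: sum(c in m.inputs for m in ranked) for c in candidates}
    return SearchResult(
        output=output, ranked_models=ranked, input_frequency=freq,
        n_evaluated=n_evaluated, candidates=tuple(candidates), top_m=top_m,
        lag=lag, scale=scale, dropped_times=dropped,
    )


def alternative_frequency(result: SearchResult, top_m: int) -> dict[str, int]:
    """Per-candidate count of appearances among the top ``top_m`` stored
    models (the heat-map row of the consensus analysis)."""
    if top_m > len(result.ranked_models):
        raise DataValidationError(
            f"requested top {top_m} but only {len(result.ranked_models)} models stored"
        )
    top = result.ranked_models[:top_m]
    return {c: sum(c in m.inputs for m in top) for c in result.candidates}


# ---------------------------------------------------------------------------
# Edge classification and serialization

def rule_sign(rule) -> str:
    """Classify a rule vector's single-input response as ``positive``
    (monotone increasing), ``negative`` (monotone decreasing) or ``biphasic``
    (anything else, including flat responses)."""
    r = validate_rule(rule)
    xs = np.linspace(-0.96, 0.96, 33)
    z = fuzzy_core.apply_rule(fuzzy_core.fuzzify_gene(xs), r)
    den = z.sum(axis=-1)
    ok = den > 0  # rules like (1,1,1) zero out half the response curve
    if ok.sum() < 2:
        return "biphasic"
    resp = (z[ok, 2] - z[ok, 0]) / den[ok]
    d = np.diff(resp)
    eps = 1e-12
    if np.all(d >= -eps) and np.any(d > eps):
        return "positive"
    if np.all(d <= eps) and np.any(d < -eps):
        return "negative"
    return "biphasic"


def model_edges(models) -> list[tuple[str, str, str]]:
    """(input, output, sign) rows for every edge of the given models."""
    return [
        (inp, m.output, rule_sign(rule))
        for m in models
        for inp, rule in zip(m.inputs, m.rules)
    ]


_FORMAT_VERSION = 1


def _model_to_dict(m: NodeModel) -> dict:
    return {
        "output": m.output,
        "inputs": list(m.inputs),
        "rules": [list(r) for r in m.rules],
        "fitness": m.fitness,
        "is_phenotype": m.is_phenotype,
    }


def _model_from_dict(d: dict) -> NodeModel:
    return NodeModel(
        output=d["output"],
        inputs=tuple(d["inputs"]),
        rules=tuple(tuple(r) for r in d["rules"]),
        fitness=d.get("fitness"),
        is_phenotype=bool(d.get("is_phenotype", False)),
    )


def save_search_results(results: list[SearchResult], path, *,
                        homolog_map: dict[str, tuple[str, str]] | None = None) -> None:
    """Write fitted models to the documented JSON schema (one entry per
    output, ranked models plus frequency table, homolog map and lag)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "homolog_map": {k: list(v) for k, v in (homolog_map or {}).items()},
        "results": [
            {
                "output": r.output,
                "lag": r.lag,
                "scale": r.scale,
                "top_m": r.top_m,
                "n_evaluated": r.n_evaluated,
                "candidates": list(r.candidates),
                "input_frequency": r.input_frequency,
                "models": [_model_to_dict(m) for m in r.ranked_models],
            }
            for r in results
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path):
    """Read a fit JSON back; returns ``(best_models, homolog_map, payload)``
    where ``best_models`` holds the top-ranked model per output."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise DataValidationError(f"{path}: unsupported model-file version")
    homolog_map = {k: tuple(v) for k, v in payload.get("homolog_map", {}).items()}
    best = [_model_from_dict(r["models"][0]) for r in payload["results"] if r["models"]]
    return best, homolog_map, payload
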