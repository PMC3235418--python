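"""Independent brute-force model enumerator.

A deliberately simple scalar re-implementation of the scoring chain
(fuzzify -> rule -> sum -> centroid -> back-transform -> R^2), written
without reference to the package's vectorized search path, used to verify
that the production exhaustive search is actually exhaustive and ranks
identically.  Same conventions: models with an undefined centroid or a
non-finite fitness score -inf; ties break on (fewer inputs, input labels,
rule encoding).
"""

import math
from itertools import combinations, product

ALL_RULES = tuple(product((1, 2, 3), repeat=3))


def _fuzzify(x):
    return (max(-x, 0.0), 1.0 - abs(x), max(x, 0.0))


def _predict(input_values, rules):
    z = [0.0, 0.0, 0.0]
    for x, rule in zip(input_values, rules):
        y = _fuzzify(x)
        for k in range(3):
            z[k] += y[rule[k] - 1]
    den = z[0] + z[1] + z[2]
    if den <= 0.0:
        return None
    pred = (z[2] - z[0]) / den
    if abs(pred) >= 1.0:  # tangent pole: no finite log2 ratio
        return None
    return pred


def enumerate_ranked(normalized, observed, candidates, max_inputs, *,
                     scale="native"):
    """Rank every (subset, rule-assignment) model for a gene output.

    Parameters
    ----------
    normalized : dict label -> list of normalized input values (at the input
        time points).
    observed : list of observed output values, already on the scoring scale
        (log2 for "native", normalized for "normalized"), aligned with the
        input time points.
    """
    t_count = len(observed)
    mean = sum(observed) / t_count
    sst = sum((o - mean) ** 2 for o in observed)
    entries = []
    for n in range(1, max_inputs + 1):
        for subset in combinations(sorted(candidates), n):
            series = [normalized[c] for c in subset]
            for rules in product(ALL_RULES, repeat=n):
                sse = 0.0
                fitness = None
                for t in range(t_count):
                    pred = _predict([s[t] for s in series], rules)
                    if pred is None:
                        fitness = -math.inf
                        break
                    if scale == "native":
                        pred = math.tan(pred * math.pi / 2.0)
                    sse += (observed[t] - pred) ** 2
                if fitness is None:
                    fitness = 1.0 - sse / sst
                    if not math.isfinite(fitness):
                        fitness = -math.inf
                entries.append((fitness, n, subset, rules))
    entries.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
    return entries
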