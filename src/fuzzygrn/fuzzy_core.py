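"""Three-set fuzzy algebra for regulatory logic.

Continuous node values are mapped into degrees of membership in three fuzzy
sets -- (low, medium, high) -- transformed through per-edge rule vectors,
combined across inputs by the algebraic sum (fuzzy OR), and mapped back to a
single value by a simplified centroid.  The triangular membership design makes
fuzzify/defuzzify exact inverses, so a single monotone rule reproduces a
linear activation (identity) or inhibition (negation) without discretization
error.

Conventions
-----------
* Gene values live on the normalized scale [-1, 1]; phenotype (fraction of
  budding cells) on [0, 1].
* A fuzzy triple is an ndarray whose last axis has length 3, ordered
  (low, medium, high).  Fuzzification of a single value yields a triple that
  sums to exactly 1; combining N rule-transformed inputs yields component sums
  of at most N.
* A rule vector is a triple ``(r1, r2, r3)`` with each component in {1, 2, 3}:
  output set ``k`` receives the membership degree of input set ``r_k``.
  ``(1, 2, 3)`` encodes activation, ``(3, 2, 1)`` inhibition.  There are
  exactly ``3**3 = 27`` rule vectors.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .errors import DegenerateTripleError, DomainError

__all__ = [
    "RULE_VECTORS",
    "ACTIVATION",
    "INHIBITION",
    "fuzzify_gene",
    "fuzzify_phenotype",
    "apply_rule",
    "combine",
    "defuzzify_gene",
    "defuzzify_phenotype",
    "homolog_merge",
    "validate_rule",
]

#: All 27 rule vectors in lexicographic order.
RULE_VECTORS: tuple[tuple[int, int, int], ...] = tuple(product((1, 2, 3), repeat=3))

ACTIVATION: tuple[int, int, int] = (1, 2, 3)
INHIBITION: tuple[int, int, int] = (3, 2, 1)


def validate_rule(rule) -> tuple[int, int, int]:
    """Coerce *rule* to a canonical 3-tuple of ints in {1, 2, 3}."""
    try:
        r = tuple(int(c) for c in rule)
    except (TypeError, ValueError) as exc:
        raise DomainError(f"invalid rule vector {rule!r}") from exc
    if len(r) != 3 or any(c not in (1, 2, 3) for c in r):
        raise DomainError(f"invalid rule vector {rule!r}: need 3 components in {{1,2,3}}")
    return r  # type: ignore[return-value]


def fuzzify_gene(x) -> np.ndarray:
    """Map normalized expression ``x`` in [-1, 1] to a (low, medium, high) triple.

    low = max(-x, 0), medium = 1 - |x|, high = max(x, 0); the components sum
    to exactly 1.  Accepts scalars or arrays (triple on a new last axis).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("fuzzify_gene: non-finite input value")
    if np.any(np.abs(x) > 1.0):
        bad = float(np.asarray(x).ravel()[np.argmax(np.abs(np.asarray(x).ravel()) > 1.0)])
        raise DomainError(f"fuzzify_gene: value {bad} outside [-1, 1]")
    low = np.maximum(-x, 0.0)
    med = 1.0 - np.abs(x)
    high = np.maximum(x, 0.0)
    return np.stack([low, med, high], axis=-1)


def fuzzify_phenotype(p) -> np.ndarray:
    """Map a budding fraction ``p`` in [0, 1] to a (low, medium, high) triple.

    The membership apexes sit at 0, 0.5 and 1:
    low = max(1 - 2p, 0), medium = 1 - |2p - 1|, high = max(2p - 1, 0).
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise DomainError("fuzzify_phenotype: non-finite input value")
    if np.any((p < 0.0) | (p > 1.0)):
        raise DomainError("fuzzify_phenotype: value outside [0, 1]")
    t = 2.0 * p - 1.0
    low = np.maximum(-t, 0.0)
    med = 1.0 - np.abs(t)
    high = np.maximum(t, 0.0)
    return np.stack([low, med, high], axis=-1)


def apply_rule(y, rule) -> np.ndarray:
    """Transform fuzzy triple(s) ``y`` through a rule vector.

    Output component ``k`` equals input component ``rule[k]`` (1-based), i.e.
    ``z = [y_{r1}, y_{r2}, y_{r3}]`` -- a selection of the input degrees.
    """
    r = validate_rule(rule)
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != 3:
        raise DomainError("apply_rule: fuzzy triple must have last axis of length 3")
    idx = np.array(r) - 1
    return y[..., idx]


def combine(intermediates) -> np.ndarray:
    """Algebraic-sum (fuzzy OR) combination: componentwise sum of triples.

    The per-input intermediate outputs are summed so that each input
    contributes independently; the centroid denominator renormalizes later.
    """
    triples = [np.asarray(t, dtype=float) for t in intermediates]
    if not triples:
        raise DomainError("combine: at least one intermediate triple is required")
    out = triples[0].copy()
    for t in triples[1:]:
        out = out + t
    return out


def _centroid_denominator(z: np.ndarray) -> np.ndarray:
    den = z.sum(axis=-1)
    if np.any(den <= 0.0):
        raise DegenerateTripleError(
            "defuzzify: all-zero fuzzy triple (undefined centroid; empty model?)"
        )
    return den


def defuzzify_gene(z) -> np.ndarray:
    """Simplified centroid on the gene scale: ``(z3 - z1) / (z1 + z2 + z3)``.

    Set centers at -1, 0, +1; the result is bounded in [-1, 1] and inverts
    :func:`fuzzify_gene` exactly.
    """
    z = np.asarray(z, dtype=float)
    den = _centroid_denominator(z)
    return (z[..., 2] - z[..., 0]) / den


def defuzzify_phenotype(z) -> np.ndarray:
    """Simplified centroid on the phenotype scale with set centers 0, 0.5, 1:
    ``(0.5*z2 + z3) / (z1 + z2 + z3)``."""
    z = np.asarray(z, dtype=float)
    den = _centroid_denominator(z)
    return (0.5 * z[..., 1] + z[..., 2]) / den


def homolog_merge(xa, xb) -> np.ndarray:
    """Merge two functionally redundant genes as the maximum of their
    normalized expression values (logical union), applied before
    fuzzification wherever the merged pair appears as an input."""
    return np.maximum(np.asarray(xa, dtype=float), np.asarray(xb, dtype=float))


# ---------------------------------------------------------------------------
# Scalar fast paths.  The relaxation dynamics iterate these per node for
# thousands of steps, where ndarray dispatch overhead dominates; the float
# versions must agree exactly with the array versions above (property-tested).

def _fuzzify_gene_f(x: float) -> tuple[float, float, float]:
    return (-x if x < 0.0 else 0.0, 1.0 - abs(x), x if x > 0.0 else 0.0)


def _fuzzify_phenotype_f(p: float) -> tuple[float, float, float]:
    t = 2.0 * p - 1.0
    return (-t if t < 0.0 else 0.0, 1.0 - abs(t), t if t > 0.0 else 0.0)
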