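"""Wright path tracing over a fitted standardized model.

Associations between any two variables of a recursive path diagram are
decomposed into *traces*: connecting routes whose per-edge products sum
to the association.  A trace may follow directed edges forward (tail to
head) or backward (head to tail) and may cross at most one two-headed
covariance arc, without visiting a variable twice.

Two rule sets are supported:

* ``strict=True`` — classical Wright rules: the directed steps form a
  backward run followed by a forward run, with the optional arc exactly
  at the turn.  Under these rules the summed trace products equal the
  model-implied correlation for any recursive standardized model.
* ``strict=False`` (default) — additionally admits traces whose single
  forward-to-backward turn happens across a covariance arc (forward to
  an indicator, through its residual arc, backward out of the partner
  indicator's construct).  This is the convention under which compound
  coefficients through residual arcs are quoted in applied work; such
  traces are not correlation components in the classical sense.

Coefficients must be standardized; covariance arcs carry residual
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceGraph",
    "Trace",
    "EffectDecomposition",
    "enumerate_traces",
    "total_effect",
    "compound_path",
    "effect_difference",
]


@dataclass(frozen=True)
class TraceGraph:
    """Standardized path diagram: directed edges plus covariance arcs."""

    directed: dict      # (src, dst) -> coefficient
    arcs: dict          # frozenset({a, b}) -> coefficient

    @classmethod
    def from_edges(cls, directed, arcs=()) -> "TraceGraph":
        d = {(a, b): float(v) for (a, b), v in dict(directed).items()}
        a_ = {frozenset(k): float(v) for k, v in dict(arcs).items()}
        for key in a_:
            if len(key) != 2:
                raise ValueError("covariance arc must join two distinct variables")
        return cls(directed=d, arcs=a_)

    @classmethod
    def from_fit(cls, fit) -> "TraceGraph":
        """Build from a :class:`~akisem.sem_engine.SemFit` standardized solution."""
        std = fit.standardized()
        directed, arcs = {}, {}
        for e in fit.spec.paths:
            directed[(e.src, e.dst)] = std[e.name]
        for c in fit.spec.covariances:
            arcs[frozenset((c.a, c.b))] = std[c.name]
        return cls.from_edges(directed, arcs)

    @property
    def nodes(self) -> set:
        out = set()
        for a, b in self.directed:
            out |= {a, b}
        for key in self.arcs:
            out |= set(key)
        return out


@dataclass(frozen=True)
class Trace:
    """One rule-valid route; ``steps`` are (src, dst, kind, coefficient)
    with kind ``"forward"``, ``"backward"`` or ``"arc"``."""

    steps: tuple

    @property
    def product(self) -> float:
        return float(np.prod([s[3] for s in self.steps]))

    @property
    def nodes(self) -> tuple:
        return (self.steps[0][0],) + tuple(s[1] for s in self.steps)

    def describe(self) -> str:
        sym = {"forward": "->", "backward": "<-", "arc": "<->"}
        bits = [self.steps[0][0]]
        for _, dst, kind, coef in self.steps:
            bits.append(f"{sym[kind]}({coef:+.3f}) {dst}")
        return " ".join(bits)


@dataclass
class EffectDecomposition:
    """Total standardized effect of ``source`` on ``target``."""

    source: str
    target: str
    traces: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(sum(t.product for t in self.traces))

    @property
    def shared_variance_pct(self) -> float:
        """Shared variance in percent: 100 x total^2."""
        return 100.0 * self.total ** 2

    def table(self):
        import pandas as pd

        rows = [{"trace": t.describe(), "product": t.product} for t in self.traces]
        rows.append({"trace": "TOTAL", "product": self.total})
        return pd.DataFrame(rows)


def enumerate_traces(graph: TraceGraph, source, target, strict: bool = False):
    """All rule-valid traces from ``source`` to ``target``.

    Traces are returned in deterministic (lexicographic by node
    sequence) order.  ``source == target`` and unknown nodes are
    errors.
    """
    if source == target:
        raise ValueError("source and target must differ")
    nodes = graph.nodes
    for v in (source, target):
        if v not in nodes:
            raise ValueError(f"unknown node {v!r}")

    fwd, bwd, arc_adj = {}, {}, {}
    for (a, b), v in graph.directed.items():
        fwd.setdefault(a, []).append((b, v))
        bwd.setdefault(b, []).append((a, v))
    for key, v in graph.arcs.items():
        a, b = tuple(key)
        arc_adj.setdefault(a, []).append((b, v))
        arc_adj.setdefault(b, []).append((a, v))

    out = []

    # state: last directed-step kind ("backward"/"forward"/None),
    # whether the single allowed turn was spent, whether the arc was
    # crossed, and whether the previous step was the arc (a
    # forward->backward turn is only legal right after the arc, and
    # only in non-strict mode).
    def step(node, visited, path, last_dir, turned, arc_used, after_arc):
        if node == target:
            out.append(Trace(steps=tuple(path)))
            return
        moves = []
        for nxt, coef in bwd.get(node, ()):  # backward: against arrow
            moves.append((nxt, "backward", coef))
        for nxt, coef in fwd.get(node, ()):
            moves.append((nxt, "forward", coef))
        if not arc_used:
            for nxt, coef in arc_adj.get(node, ()):
                moves.append((nxt, "arc", coef))
        for nxt, kind, coef in sorted(moves, key=lambda m: (m[0], m[1])):
            if nxt in visited:
                continue
            if kind == "arc":
                # strict Wright: the arc replaces the turn, so no
                # forward step may precede it
                if strict and last_dir == "forward":
                    continue
                step(nxt, visited | {nxt}, path + [(node, nxt, "arc", coef)],
                     last_dir, turned, True, True)
                continue
            if kind == "forward":
                if last_dir == "forward" or last_dir is None:
                    ok, nturned = True, turned
                elif not turned:        # backward -> forward turn
                    ok, nturned = True, True
                else:
                    ok = False
                if not ok:
                    continue
                step(nxt, visited | {nxt},
                     path + [(node, nxt, "forward", coef)],
                     "forward", nturned, arc_used, False)
            else:  # backward
                if last_dir in (None, "backward"):
                    ok, nturned = True, turned
                elif (not strict) and after_arc and not turned:
                    # forward -> backward turn across the arc
                    ok, nturned = True, True
                else:
                    ok = False
                if not ok:
                    continue
                step(nxt, visited | {nxt},
                     path + [(node, nxt, "backward", coef)],
                     "backward", nturned, arc_used, False)

    step(source, {source}, [], None, False, False, False)
    out.sort(key=lambda t: t.nodes)
    return out


def total_effect(graph: TraceGraph, source, target, strict: bool = False,
                 through=None) -> EffectDecomposition:
    """Sum of trace products between two variables.

    ``through`` restricts the decomposition to traces whose
    intermediate variables all belong to the given set (``through=()``
    keeps only the direct edge) — the convention used when a printed
    compound coefficient follows one named route rather than every
    admissible trace.
    """
    traces = enumerate_traces(graph, source, target, strict=strict)
    if through is not None:
        allowed = set(through)
        traces = [t for t in traces if set(t.nodes[1:-1]) <= allowed]
    return EffectDecomposition(source=source, target=target, traces=traces)


def compound_path(graph: TraceGraph, nodes) -> float:
    """Product of standardized coefficients along an explicit route.

    Each consecutive pair must be joined by a directed edge (either
    orientation) or an arc; directed edges use the same coefficient in
    both orientations, as in Wright tracing.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("a route needs at least two nodes")
    prod = 1.0
    for a, b in zip(nodes[:-1], nodes[1:]):
        if (a, b) in graph.directed:
            prod *= graph.directed[(a, b)]
        elif (b, a) in graph.directed:
            prod *= graph.directed[(b, a)]
        elif frozenset((a, b)) in graph.arcs:
            prod *= graph.arcs[frozenset((a, b))]
        else:
            raise ValueError(f"no edge between {a!r} and {b!r}")
    return prod


def effect_difference(decomp_a: EffectDecomposition,
                      decomp_b: EffectDecomposition) -> float:
    """Difference of two total effects (CI attached by bootstrapping)."""
    return decomp_a.total - decomp_b.total
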