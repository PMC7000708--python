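"""Path-model specification: a directed acyclic graph over observed variables.

A model is a set of directed regression edges (predictor → outcome) plus free
(co)variance parameters. Variances of all variables are always free;
covariances among exogenous variables are free by default (the usual
convention for path analysis); additional residual covariances can be declared
explicitly.

Text format, one relation per line::

    # comment
    attendance ~ total_animals + body_mass
    total_animals ~ species_richness
    body_mass ~~ area        # free covariance

"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
import networkx as nx

from .exceptions import ParseError, SpecificationError

Edge = tuple[str, str]  # (outcome, predictor)

_NAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


@dataclass(frozen=True)
class PathModelSpec:
    """Immutable path-model structure.

    ``edges`` are ``(outcome, predictor)`` pairs — matching the coefficient
    matrix convention ``A[outcome, predictor]``. ``covariances`` are unordered
    extra free covariances beyond the automatic exogenous block.
    """

    variables: tuple[str, ...]
    edges: tuple[Edge, ...]
    covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e in seen:
                raise SpecificationError(f"duplicate edge {e[0]} ~ {e[1]}")
            seen.add(e)
            for v in e:
                if v not in self.variables:
                    raise SpecificationError(f"edge references unknown variable {v!r}")
        for pair in self.covariances:
            a, b = pair
            if a == b:
                raise SpecificationError(f"covariance of {a!r} with itself")
            for v in pair:
                if v not in self.variables:
                    raise SpecificationError(
                        f"covariance references unknown variable {v!r}"
                    )
        if len({tuple(sorted(p)) for p in self.covariances}) != len(self.covariances):
            raise SpecificationError("duplicate covariance declaration")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise SpecificationError(f"model contains a cycle: {cycle}")

    # -- structure ---------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        """Directed graph with arrows predictor → outcome."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((pred, out) for out, pred in self.edges)
        return g

    @cached_property
    def endogenous(self) -> tuple[str, ...]:
        outs = {out for out, _ in self.edges}
        return tuple(v for v in self.variables if v in outs)

    @cached_property
    def exogenous(self) -> tuple[str, ...]:
        outs = {out for out, _ in self.edges}
        return tuple(v for v in self.variables if v not in outs)

    def parents(self, variable: str) -> tuple[str, ...]:
        return tuple(pred for out, pred in self.edges if out == variable)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))

    # -- edits (return new specs) -----------------------------------------

    def with_edge(self, outcome: str, predictor: str) -> "PathModelSpec":
        return PathModelSpec(self.variables, self.edges + ((outcome, predictor),), self.covariances)

    def without_edge(self, outcome: str, predictor: str) -> "PathModelSpec":
        if (outcome, predictor) not in self.edges:
            raise SpecificationError(f"edge {outcome} ~ {predictor} not in model")
        return PathModelSpec(
            self.variables,
            tuple(e for e in self.edges if e != (outcome, predictor)),
            self.covariances,
        )

    def would_cycle(self, outcome: str, predictor: str) -> bool:
        g = self.graph()
        g.add_edge(predictor, outcome)
        return not nx.is_directed_acyclic_graph(g)

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def drop_variable(self, name: str) -> "PathModelSpec":
        """Remove a variable together with every edge and covariance touching
        it (used e.g. for the presence-absence variant, where total animals
        duplicates species richness, and for dropping GDP from the in situ
        model)."""
        if name not in self.variables:
            raise SpecificationError(f"unknown variable {name!r}")
        return PathModelSpec(
            tuple(v for v in self.variables if v != name),
            tuple(e for e in self.edges if name not in e),
            tuple(p for p in self.covariances if name not in p),
        )

    def isolated(self) -> tuple[str, ...]:
        """Variables appearing in no edge or declared covariance. A freshly
        parsed model has none; stepwise pruning can create them — such a
        variable stays in the model as a member of the saturated exogenous
        block (its direct pathways are claimed absent, its correlations with
        the other exogenous variables remain free)."""
        used = {v for e in self.edges for v in e} | {
            v for p in self.covariances for v in p
        }
        return tuple(v for v in self.variables if v not in used)

    # -- text form ---------------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for out in self.variables:
            preds = self.parents(out)
            if preds:
                lines.append(f"{out} ~ {' + '.join(preds)}")
        for a, b in self.covariances:
            lines.append(f"{a} ~~ {b}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PathModelSpec":
        return parse_model_spec(text)

    @classmethod
    def from_file(cls, path) -> "PathModelSpec":
        with open(path, encoding="utf-8") as fh:
            return parse_model_spec(fh.read())


def parse_model_spec(text: str) -> PathModelSpec:
    """Parse the model-specification DSL into a :class:`PathModelSpec`.

    Raises :class:`~zoosem.exceptions.ParseError` with a line number on syntax
    errors, unknown tokens, duplicate relations or cycles.
    """
    variables: list[str] = []
    edges: list[Edge] = []
    covariances: list[tuple[str, str]] = []

    def note(name: str, lineno: int) -> str:
        if not _NAME.match(name):
            raise ParseError(f"invalid variable name {name!r}", lineno)
        if name not in variables:
            variables.append(name)
        return name

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            left, _, right = line.partition("~~")
            a, b = note(left.strip(), lineno), note(right.strip(), lineno)
            pair = tuple(sorted((a, b)))
            if a == b:
                raise ParseError(f"covariance of {a!r} with itself", lineno)
            if pair in covariances:
                raise ParseError(f"duplicate covariance {a} ~~ {b}", lineno)
            covariances.append(pair)
        elif "~" in line:
            left, _, right = line.partition("~")
            outcome = note(left.strip(), lineno)
            preds = [p.strip() for p in right.split("+")]
            if not preds or any(not p for p in preds):
                raise ParseError("empty predictor list", lineno)
            for p in preds:
                pred = note(p, lineno)
                if (outcome, pred) in edges:
                    raise ParseError(f"duplicate edge {outcome} ~ {pred}", lineno)
                edges.append((outcome, pred))
        else:
            raise ParseError(f"cannot parse {line!r}", lineno)

    if not edges and not covariances:
        raise ParseError("specification declares no relations")
    try:
        return PathModelSpec(tuple(variables), tuple(edges), tuple(covariances))
    except SpecificationError as err:  # cycle etc. — no single line to blame
        raise ParseError(str(err)) from err
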