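"""Prediction maps: rooted trees of pairwise shift models.

A :class:`PredictionMap` is a directed spanning tree over spin systems, rooted
at a single anchor signal. Each non-root system has exactly one primary
incoming edge carrying a fitted ``y = a*x + b`` model, so the whole panel can
be predicted by chaining models from the anchor alone. Optional *alternate*
edges provide a fallback predictor when the primary one is missing in a given
sample (acetone via pyruvate when ethanol is undetected).

Two constructions are provided:

* :func:`published_map` — the fixed serum/plasma map for the 16-system panel:
  valine's methyl doublet anchors the amino acids; leucine bridges to the
  carboxylic-acid/sugar sub-map (via lactate) and to the alcohol/ketone
  sub-map (via ethanol).
* :func:`build_map` — an automatic minimum-error arborescence over the stable
  fitted models, optionally restricted class-by-class with designated bridge
  systems to mimic the sub-map-then-join strategy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .arborescence import UnreachableNodeError, minimum_arborescence
from .regression import ModelMatrix, PairModel
from .registry import Registry, default_registry

__all__ = [
    "MapEdge",
    "PredictionMap",
    "MapError",
    "BindingError",
    "UnreachableSystemError",
    "published_map",
    "build_map",
    "bind_map",
    "PUBLISHED_EDGES",
    "PUBLISHED_ALTERNATES",
    "DEFAULT_ROOT",
]

DEFAULT_ROOT = "valine_CH3"

#: (predictor, response) primary edges of the published serum/plasma map.
PUBLISHED_EDGES: tuple[tuple[str, str], ...] = (
    ("valine_CH3", "alanine_CH3"),
    ("valine_CH3", "leucine_CH3"),
    ("valine_CH3", "isoleucine_CH3"),
    ("valine_CH3", "tyrosine_CH"),
    ("valine_CH3", "glycine_CH2"),
    ("tyrosine_CH", "phenylalanine_CH"),
    ("glycine_CH2", "histidine_CH"),
    ("leucine_CH3", "lactate_CH3"),
    ("leucine_CH3", "ethanol_CH3"),
    ("lactate_CH3", "acetate_CH3"),
    ("lactate_CH3", "pyruvate_CH3"),
    ("lactate_CH3", "formate_CH"),
    ("lactate_CH3", "hydroxybutyrate_CH3"),
    ("lactate_CH3", "glucose_anomeric"),
    ("ethanol_CH3", "acetone_CH3"),
)

#: Fallback edges used per sample when the primary predictor is missing.
PUBLISHED_ALTERNATES: tuple[tuple[str, str], ...] = (
    ("pyruvate_CH3", "acetone_CH3"),
)


class MapError(ValueError):
    pass


class BindingError(MapError):
    """A map edge has no fitted model in the supplied matrix."""


class UnreachableSystemError(MapError):
    """A system cannot be connected to the root through stable models."""


@dataclass
class MapEdge:
    predictor: str
    response: str
    model: PairModel | None = None

    @property
    def bound(self) -> bool:
        return self.model is not None


@dataclass
class PredictionMap:
    """Rooted directed tree of pair models (plus optional alternates)."""

    root: str
    parents: dict[str, MapEdge] = field(default_factory=dict)
    alternates: dict[str, MapEdge] = field(default_factory=dict)
    #: per-node chained error estimates, filled by bind_map:
    chain_rmse: dict[str, float] = field(default_factory=dict)
    chain_envelope: dict[str, float] = field(default_factory=dict)

    # ---- structure -----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return [self.root] + list(self.parents)

    @property
    def n_predicted(self) -> int:
        """Number of non-root systems the map predicts."""
        return len(self.parents)

    def children(self, node: str) -> list[str]:
        return [r for r, e in self.parents.items() if e.predictor == node]

    def path(self, node: str) -> list[MapEdge]:
        """Primary edges from the root down to ``node``."""
        edges: list[MapEdge] = []
        v = node
        while v != self.root:
            e = self.parents[v]
            edges.append(e)
            v = e.predictor
        return list(reversed(edges))

    def depth(self, node: str) -> int:
        return len(self.path(node))

    def topological_order(self) -> list[str]:
        """Root first, every node after its predictor."""
        order = [self.root]
        placed = {self.root}
        pending = dict(self.parents)
        while pending:
            progressed = False
            for r in list(pending):
                if pending[r].predictor in placed:
                    order.append(r)
                    placed.add(r)
                    del pending[r]
                    progressed = True
            if not progressed:
                raise MapError(f"not a rooted tree; dangling: {sorted(pending)}")
        return order

    def validate(self) -> None:
        """Check the arborescence invariants; raise MapError on violation."""
        if self.root in self.parents:
            raise MapError("root must not have an incoming primary edge")
        for r, e in self.parents.items():
            if e.response != r:
                raise MapError(f"edge under key {r!r} targets {e.response!r}")
            if e.predictor == r:
                raise MapError(f"self-loop at {r!r}")
        node_set = set(self.nodes)
        for r, e in self.parents.items():
            if e.predictor not in node_set:
                raise MapError(
                    f"predictor {e.predictor!r} of {r!r} is not a map node"
                )
        self.topological_order()  # raises on cycles / unreachable nodes
        for r, e in self.alternates.items():
            if r == self.root or e.predictor == r:
                raise MapError(f"invalid alternate edge into {r!r}")

    @property
    def is_bound(self) -> bool:
        return all(e.bound for e in self.parents.values()) and all(
            e.bound for e in self.alternates.values()
        )

    def subtree(self, node: str) -> list[str]:
        """Nodes of the sub-map hanging below ``node`` (excluding it)."""
        out: list[str] = []
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                out.append(c)
                stack.append(c)
        return out

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def edge_payload(e: MapEdge) -> dict:
            d = {"predictor": e.predictor, "response": e.response}
            if e.model is not None:
                d["model"] = e.model.to_dict()
            return d

        payload = {
            "root": self.root,
            "edges": [edge_payload(e) for e in self.parents.values()],
            "alternates": [edge_payload(e) for e in self.alternates.values()],
            "chain_rmse": self.chain_rmse,
            "chain_envelope": self.chain_envelope,
        }
        text = json.dumps(payload, indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PredictionMap":
        text = Path(source).read_text(encoding="utf-8") if Path(
            str(source)
        ).exists() else str(source)
        payload = json.loads(text)

        def parse(d: dict) -> MapEdge:
            model = PairModel.from_dict(d["model"]) if "model" in d else None
            return MapEdge(d["predictor"], d["response"], model)

        pmap = cls(
            root=payload["root"],
            parents={d["response"]: parse(d) for d in payload["edges"]},
            alternates={d["response"]: parse(d) for d in payload["alternates"]},
            chain_rmse=dict(payload.get("chain_rmse", {})),
            chain_envelope=dict(payload.get("chain_envelope", {})),
        )
        pmap.validate()
        return pmap


def published_map() -> PredictionMap:
    """The fixed 16-system serum/plasma map (unbound).

    Fifteen systems hang off the valine methyl anchor; coefficients are
    placeholders until :func:`bind_map` attaches a fitted model matrix.
    """
    pmap = PredictionMap(
        root=DEFAULT_ROOT,
        parents={r: MapEdge(p, r) for p, r in PUBLISHED_EDGES},
        alternates={r: MapEdge(p, r) for p, r in PUBLISHED_ALTERNATES},
    )
    pmap.validate()
    return pmap


def bind_map(pmap: PredictionMap, m: ModelMatrix) -> PredictionMap:
    """Attach fitted coefficients/metrics to every edge of a map.

    Also computes per-node chained error estimates along the root path:
    ``chain_rmse`` adds edge RMSEs in quadrature (independent-error view),
    ``chain_envelope`` sums the training max-|residual| of each edge (the
    conservative worst case).
    """
    missing = [
        (e.predictor, e.response)
        for e in list(pmap.parents.values()) + list(pmap.alternates.values())
        if (e.response, e.predictor) not in m
    ]
    if missing:
        raise BindingError(f"no fitted model for edge(s): {missing}")
    bound = PredictionMap(
        root=pmap.root,
        parents={
            r: MapEdge(e.predictor, r, m.get(r, e.predictor))
            for r, e in pmap.parents.items()
        },
        alternates={
            r: MapEdge(e.predictor, r, m.get(r, e.predictor))
            for r, e in pmap.alternates.items()
        },
    )
    bound.validate()
    bound.chain_rmse[bound.root] = 0.0
    bound.chain_envelope[bound.root] = 0.0
    for node in bound.topological_order()[1:]:
        e = bound.parents[node]
        parent = e.predictor
        gain = abs(e.model.a)  # parent error propagates through the slope
        bound.chain_rmse[node] = math.hypot(
            gain * bound.chain_rmse[parent], e.model.rmse
        )
        bound.chain_envelope[node] = (
            gain * bound.chain_envelope[parent] + e.model.max_abs_resid
        )
    return bound


def build_map(
    m: ModelMatrix,
    root_id: str = DEFAULT_ROOT,
    weight: str = "rrmse",
    class_guided: bool = False,
    bridges: tuple[str, ...] = (),
    registry: Registry | None = None,
) -> PredictionMap:
    """Minimum-total-error spanning arborescence over the stable models.

    Edge weight is the model's ``rrmse`` (percent) or ``rmse`` (ppm). With
    ``class_guided`` a response may only be predicted by a system of its own
    chemical class group or by one of the designated ``bridges`` — the
    automated analogue of building per-class sub-maps and joining them at
    chemically chosen bridge signals. Ties break by lower weight, then higher
    r2, then lexicographic (predictor, response).

    The returned map is bound to ``m`` (edges carry the fitted models and
    chained error estimates).
    """
    if weight not in {"rrmse", "rmse"}:
        raise MapError(f"unknown weight metric {weight!r}")
    if root_id not in m.systems:
        raise MapError(f"root {root_id!r} not among fitted systems")
    if class_guided and registry is None:
        registry = default_registry()

    def allowed(pred: str, resp: str) -> bool:
        if not class_guided:
            return True
        if pred in bridges:
            return True
        try:
            return registry.group_of(pred) == registry.group_of(resp)
        except KeyError as exc:
            raise MapError(f"class-guided build needs registry entry: {exc}")

    weights: dict[tuple[str, str], float] = {}
    ties: dict[tuple[str, str], tuple] = {}
    for (resp, pred), pm in m.models.items():
        w = getattr(pm, weight)
        if not (pm.stable and pm.usable and math.isfinite(w)):
            continue
        if not allowed(pred, resp):
            continue
        weights[(pred, resp)] = abs(w)
        ties[(pred, resp)] = (-pm.r2, pred, resp)

    try:
        edges = minimum_arborescence(m.systems, weights, root_id, tie_keys=ties)
    except UnreachableNodeError as exc:
        details = []
        for orphan in exc.nodes:
            if isinstance(orphan, tuple):  # contracted supernode: skip detail
                continue
            unstable = sorted(
                p for p, pm in m.incoming(orphan).items()
                if not (pm.stable and pm.usable)
            )
            details.append(f"{orphan} (unstable candidate models from: {unstable})")
        raise UnreachableSystemError(
            "system(s) not connectable to the root through stable models: "
            + "; ".join(details)
        ) from exc

    pmap = PredictionMap(
        root=root_id,
        parents={r: MapEdge(p, r) for p, r in sorted(edges)},
    )
    pmap.validate()
    return bind_map(pmap, m)
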