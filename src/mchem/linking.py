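"""Educt/product feature pairing by delta-m/z and co-elution.

Post-column derivatization leaves the educt (unreacted metabolite) and its
labeled product co-eluting in the same chromatographic peak, separated in
mass by the reagent's net change.  This module links feature pairs whose
m/z difference matches a registered reaction delta within tolerance and
whose retention times agree, computes per-pair conversion yields, applies
the reaction-A low-yield cut, and assembles the reactivity network.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .reactions import Reaction, ReactivityPrediction, registry_by_id

__all__ = [
    "Condition",
    "Feature",
    "LinkingParams",
    "ReactivityEdge",
    "LinkingError",
    "pair_features",
    "compute_yield",
    "attach_yields",
    "filter_edges",
    "elution_correlation",
    "annotate_features",
    "build_network",
]


class LinkingError(ValueError):
    pass


class Condition(str, enum.Enum):
    UNDERIVATIZED = "underivatized"
    DERIVATIZED = "derivatized"


@dataclass
class Feature:
    """One aligned LC-MS ion feature with per-sample quantification.

    ``areas`` maps sample id -> integrated peak area; ``conditions`` maps the
    same sample ids to whether that run included the derivatization reagent.
    """

    id: str
    mz: float
    rt: float
    areas: dict[str, float] = field(default_factory=dict)
    conditions: dict[str, Condition] = field(default_factory=dict)
    ms2_ref: str | None = None
    observed_reactions: set[str] = field(default_factory=set)
    annotation_smarts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise LinkingError(f"feature {self.id}: mz must be positive")
        if self.rt < 0:
            raise LinkingError(f"feature {self.id}: rt must be non-negative")
        if any(a < 0 for a in self.areas.values()):
            raise LinkingError(f"feature {self.id}: negative area")
        self.conditions = {
            s: Condition(c) for s, c in self.conditions.items()
        }

    def area_in(self, condition: Condition) -> float | None:
        """Summed area over samples of one condition; None if never measured."""
        samples = [s for s, c in self.conditions.items() if c is condition]
        if not samples:
            return None
        return float(sum(self.areas.get(s, 0.0) for s in samples))


@dataclass(frozen=True)
class LinkingParams:
    """Tolerances for precursor/product pairing.

    ``mz_tol`` is interpreted per ``mz_tol_mode``: in ppm mode the effective
    tolerance at product m/z is max(mz_tol_floor_da, mz * mz_tol * 1e-6).
    Correlation gating (ion-identity style) is off unless ``min_correlation``
    is set; it only applies to pairs quantified in >= 3 shared samples.
    """

    mz_tol: float = 10.0
    mz_tol_mode: str = "ppm"  # "ppm" or "da"
    mz_tol_floor_da: float = 0.002
    rt_tol: float = 0.05
    min_correlation: float | None = None
    require_coelution: bool = True
    require_product_only_in_reagent_run: bool = False

    def __post_init__(self) -> None:
        if self.mz_tol <= 0 or self.rt_tol <= 0:
            raise LinkingError("tolerances must be positive")
        if self.mz_tol_mode not in ("ppm", "da"):
            raise LinkingError("mz_tol_mode must be 'ppm' or 'da'")
        if self.min_correlation is not None and not -1 <= self.min_correlation <= 1:
            raise LinkingError("min_correlation must lie in [-1, 1]")

    def mz_tolerance_at(self, mz: float) -> float:
        if self.mz_tol_mode == "da":
            return self.mz_tol
        return max(self.mz_tol_floor_da, mz * self.mz_tol * 1e-6)


@dataclass(frozen=True)
class ReactivityEdge:
    """A directed precursor -> derivatized-product link for one reaction."""

    precursor_id: str
    product_id: str
    reaction_id: str
    delta_observed: float
    mass_error: float  # signed, Da
    rt_delta: float  # signed, minutes
    yield_pct: float | None = None
    correlation: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.precursor_id == self.product_id:
            raise LinkingError("self-edges are not allowed")


def elution_correlation(p: Feature, q: Feature) -> float | None:
    """Pearson correlation of per-sample areas over shared samples.

    Acts as a proxy for chromatographic-shape correlation when only feature
    tables (not raw profiles) are available.  Returns None with fewer than 3
    shared samples or when either vector is constant.
    """
    shared = sorted(p.areas.keys() & q.areas.keys())
    if len(shared) < 3:
        return None
    a = np.array([p.areas[s] for s in shared])
    b = np.array([q.areas[s] for s in shared])
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _product_only_in_reagent_run(q: Feature) -> bool:
    underiv = q.area_in(Condition.UNDERIVATIZED)
    return underiv is None or underiv == 0.0


def pair_features(
    features: list[Feature],
    registry: list[Reaction],
    params: LinkingParams | None = None,
) -> list[ReactivityEdge]:
    """Link all precursor/product pairs consistent with a registered reaction.

    A directed edge p -> q for reaction r is emitted iff
    ``|(mz_q - mz_p) - delta(r)| <= mz_tol`` and ``|rt_q - rt_p| <= rt_tol``
    (and, when correlation gating is enabled and >= 3 shared samples exist,
    the area correlation reaches ``min_correlation``).  A feature may act as
    precursor in several reactions; as a product it accepts at most one edge
    per reaction — the candidate with the smallest |mass error| wins, ties
    broken by smallest |rt delta| then precursor id.  Output is sorted by
    (precursor_id, reaction_id, mass_error).
    """
    params = params or LinkingParams()
    if not registry:
        raise LinkingError("empty reaction registry")
    ids = [f.id for f in features]
    if len(set(ids)) != len(ids):
        raise LinkingError("duplicate feature ids")

    order = np.argsort([f.mz for f in features], kind="stable")
    mzs = np.array([features[i].mz for i in order])
    # best candidate per (product, reaction): (|mass_error|, |rt_delta|, pid, edge)
    best: dict[tuple[str, str], tuple] = {}
    for pi, p in enumerate(features):
        for reaction in registry:
            target = p.mz + reaction.delta_mass
            # window padded slightly: the accept test below uses the
            # tolerance at the candidate's own m/z, which can exceed the
            # tolerance at the target by up to tol*ppm in ppm mode
            tol = params.mz_tolerance_at(target) * 1.01 + 1e-9
            lo = int(np.searchsorted(mzs, target - tol, side="left"))
            hi = int(np.searchsorted(mzs, target + tol, side="right"))
            for j in range(lo, hi):
                qi = int(order[j])
                if qi == pi:
                    continue
                q = features[qi]
                mass_error = (q.mz - p.mz) - reaction.delta_mass
                if abs(mass_error) > params.mz_tolerance_at(q.mz):
                    continue
                rt_delta = q.rt - p.rt
                if params.require_coelution and abs(rt_delta) > params.rt_tol:
                    continue
                if params.require_product_only_in_reagent_run and not _product_only_in_reagent_run(q):
                    continue
                corr = elution_correlation(p, q)
                if (
                    params.min_correlation is not None
                    and corr is not None
                    and corr < params.min_correlation
                ):
                    continue
                edge = ReactivityEdge(
                    precursor_id=p.id,
                    product_id=q.id,
                    reaction_id=reaction.id,
                    delta_observed=q.mz - p.mz,
                    mass_error=mass_error,
                    rt_delta=rt_delta,
                    correlation=corr,
                )
                key = (q.id, reaction.id)
                rank = (abs(mass_error), abs(rt_delta), p.id)
                if key not in best or rank < best[key][0]:
                    best[key] = (rank, edge)
    edges = [e for _, e in best.values()]
    edges.sort(key=lambda e: (e.precursor_id, e.reaction_id, e.mass_error))
    return edges


def compute_yield(product_area: float, educt_area: float) -> float:
    """Conversion yield in percent: product/(product + educt) * 100.

    Both areas must be non-negative and not both zero.
    """
    if product_area < 0 or educt_area < 0:
        raise LinkingError("areas must be non-negative")
    total = product_area + educt_area
    if total == 0:
        raise LinkingError("undefined yield: both areas are zero")
    return 100.0 * product_area / total


def attach_yields(
    edges: list[ReactivityEdge],
    features: list[Feature],
    mode: str = "summed-areas",
) -> list[ReactivityEdge]:
    """Compute conversion yields from derivatized-condition areas.

    ``summed-areas`` pools areas over all derivatized samples before applying
    the yield formula; ``per-sample-mean`` computes a yield per shared
    derivatized sample and averages.  Edges whose product (or educt) carries
    no derivatized-condition signal keep ``yield_pct=None`` and are flagged
    ``undefined_yield`` rather than dropped.
    """
    if mode not in ("summed-areas", "per-sample-mean"):
        raise LinkingError(f"unknown yield mode: {mode!r}")
    by_id = {f.id: f for f in features}
    out = []
    for edge in edges:
        try:
            p = by_id[edge.precursor_id]
            q = by_id[edge.product_id]
        except KeyError as exc:
            raise LinkingError(f"edge endpoint not in feature list: {exc}") from None
        y = _edge_yield(p, q, mode)
        if y is None:
            out.append(replace(edge, yield_pct=None, flags=edge.flags + ("undefined_yield",)))
        else:
            out.append(replace(edge, yield_pct=y))
    return out


def _edge_yield(p: Feature, q: Feature, mode: str) -> float | None:
    deriv_samples = lambda f: {
        s for s, c in f.conditions.items() if c is Condition.DERIVATIZED
    }
    sp, sq = deriv_samples(p), deriv_samples(q)
    if not sp or not sq:
        return None
    if mode == "summed-areas":
        educt = sum(p.areas.get(s, 0.0) for s in sp)
        product = sum(q.areas.get(s, 0.0) for s in sq)
        if educt + product == 0:
            return None
        return compute_yield(product, educt)
    # per-sample-mean over shared derivatized samples with any signal
    yields = []
    for s in sorted(sp & sq):
        educt, product = p.areas.get(s, 0.0), q.areas.get(s, 0.0)
        if educt + product > 0:
            yields.append(compute_yield(product, educt))
    return float(np.mean(yields)) if yields else None


def filter_edges(
    edges: list[ReactivityEdge], registry: list[Reaction]
) -> list[ReactivityEdge]:
    """Apply each reaction's minimum-yield cut (strict: yield < min is dropped).

    With the default registry only reaction A (min 5%) is affected; edges at
    exactly the threshold are kept, and flagged undefined-yield edges pass
    through.
    """
    by_id = registry_by_id(registry)
    out = []
    for edge in edges:
        reaction = by_id.get(edge.reaction_id)
        if reaction is None:
            raise LinkingError(f"edge references unknown reaction {edge.reaction_id!r}")
        if edge.yield_pct is not None and edge.yield_pct < reaction.min_yield_pct:
            continue
        out.append(edge)
    return out


def annotate_features(
    features: list[Feature],
    edges: list[ReactivityEdge],
    registry: list[Reaction],
    predictions: list[ReactivityPrediction] | None = None,
) -> list[Feature]:
    """Attach observed reaction ids and SMARTS evidence to precursor features.

    Each precursor gains the ids of the reactions it was observed in plus the
    union of those reactions' SMARTS patterns; when structure-specific
    predictions are supplied, only the actually matching patterns are kept.
    Mutates and returns the feature list.
    """
    by_id = registry_by_id(registry)
    feat_by_id = {f.id: f for f in features}
    pred_hits: dict[tuple[str, str], tuple[str, ...]] = {}
    if predictions is not None:
        pred_hits = {
            (p.structure_id, p.reaction_id): p.smarts_hits for p in predictions
        }
    for edge in edges:
        if edge.precursor_id not in feat_by_id:
            raise LinkingError(f"edge references unknown feature {edge.precursor_id!r}")
        feat = feat_by_id[edge.precursor_id]
        feat.observed_reactions.add(edge.reaction_id)
    for feat in features:
        if not feat.observed_reactions:
            continue
        smarts: list[str] = []
        for rid in sorted(feat.observed_reactions):
            hits = pred_hits.get((feat.id, rid)) if predictions is not None else None
            pool = hits if hits is not None else by_id[rid].smarts()
            smarts.extend(s for s in pool if s not in smarts)
        feat.annotation_smarts = tuple(smarts)
    return features


def build_network(
    edges: list[ReactivityEdge], features: list[Feature]
) -> nx.DiGraph:
    """Reactivity molecular network: feature nodes, reaction-labeled edges."""
    g = nx.DiGraph()
    for f in features:
        g.add_node(
            f.id,
            mz=f.mz,
            rt=f.rt,
            reactions=",".join(sorted(f.observed_reactions)),
        )
    for e in edges:
        g.add_edge(
            e.precursor_id,
            e.product_id,
            reaction=e.reaction_id,
            delta_observed=e.delta_observed,
            mass_error=e.mass_error,
            yield_pct=e.yield_pct if e.yield_pct is not None else float("nan"),
        )
    return g
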