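"""Global, reference-free fitting of Hammett reaction and substituent constants.

The Hammett relation log(K/K0) = rho * sigma separates what a reaction does
(rho: susceptibility to substituent effects) from what a substituent does
(sigma: inductive electron donation/withdrawal).  The model fitted here is

    y_{s,j} = c_j + rho_j * sigma_s

with an explicit per-reaction offset c_j (the predicted response of the
reference substituent set), so tables that lack the unsubstituted compound
remain fittable.

Two fitting procedures are provided:

* :func:`fit_sigma_hammett` — the robust global method.  Every pair of
  reactions with at least two shared substituent sets contributes a
  Theil–Sen slope (the median of all pairwise point slopes, breakdown
  point ~29%), whose value estimates the rho ratio of the two reactions.
  All log-rho are then solved at once by support-weighted least squares on
  the slope graph, anchored at rho(anchor) = 1, and sigma/c are refined by
  coordinate updates (median for c, mean for sigma).  The result does not
  depend on any reference reaction beyond the arbitrary anchor scale.
* :func:`original_hammett_fit` — the classical sequential procedure (pick a
  reference reaction with rho = 1, assign sigma from it, extend reaction by
  reaction with OLS), kept for comparison; its output depends strongly on
  the reference and expansion order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dataset_io import ReactionTable
from .errors import (
    ConfigurationError,
    ConnectivityError,
    ConvergenceError,
    DegenerateInputError,
    EvaluationError,
    SignError,
    UnknownLabelError,
)

__all__ = [
    "FitConfig",
    "HammettParameters",
    "theil_sen_slope",
    "ols_slope",
    "pairwise_reaction_slopes",
    "fit_global_rho",
    "fit_sigma_offsets",
    "fit_sigma_hammett",
    "original_hammett_fit",
    "predict",
    "predict_table",
    "evaluate_mae",
    "enumeration_bound",
]


@dataclass
class FitConfig:
    """Options for the global sigma-Hammett fit.

    anchor : reaction whose rho is pinned to 1 (default: lexicographically
        first reaction id).
    allow_negative_slopes : if True, slope signs are propagated over a
        maximum-support spanning tree and magnitudes fitted in log space;
        if False (default) any non-positive pairwise slope is an error.
    weighted_sigma : if True, sigma averaging across reactions weights each
        reaction by |rho_j|; default is the unweighted mean.
    on_disconnected : "error" raises ConnectivityError; "per_component"
        fits each connected component with its own anchor (used by
        learning curves on small subsamples).
    """

    anchor: str | None = None
    allow_negative_slopes: bool = False
    weighted_sigma: bool = False
    tol: float = 1e-10
    max_iter: int = 200
    on_disconnected: str = "error"


@dataclass
class HammettParameters:
    """Fitted Hammett parameters.

    ``sigma`` is keyed by substituent-set tuples (group per position, in
    ``positions`` order).  ``offsets[j]`` is the predicted response of the
    reference substituent set in reaction j.  ``rho[anchor_reaction] == 1``
    and ``sigma[reference_substituent_set] == 0`` exactly (gauge).
    """

    rho: dict[str, float]
    sigma: dict[tuple[str, ...], float]
    offsets: dict[str, float]
    anchor_reaction: str
    method: str
    positions: list[str] = field(default_factory=list)
    reference_substituent_set: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def covers(self, reaction_id: str, set_key: tuple[str, ...]) -> bool:
        return reaction_id in self.rho and tuple(set_key) in self.sigma


# ---------------------------------------------------------------------------
# slopes
# ---------------------------------------------------------------------------

def theil_sen_slope(points) -> float:
    """Median of the slopes of all lines through each pair of points.

    Pairs with equal x are skipped; an even number of slopes yields the
    midpoint of the two central values.  Raises DegenerateInputError when
    every pair shares the same x.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise DegenerateInputError("theil_sen_slope needs at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    ii, jj = np.triu_indices(len(x), k=1)
    dx = x[jj] - x[ii]
    keep = dx != 0.0
    if not np.any(keep):
        raise DegenerateInputError("all x values identical; slope undefined")
    return float(np.median((y[jj] - y[ii])[keep] / dx[keep]))


def ols_slope(points) -> float:
    """Ordinary least-squares slope; the non-robust control."""
    pts = np.asarray(list(points), dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    vx = x - x.mean()
    denom = float(vx @ vx)
    if denom == 0.0:
        raise DegenerateInputError("all x values identical; slope undefined")
    return float(vx @ (y - y.mean()) / denom)


def pairwise_reaction_slopes(
    table: ReactionTable, estimator: str = "theil_sen"
) -> dict[tuple[str, str], tuple[float, int]]:
    """Slope of reaction j's responses against reaction i's over shared sets.

    Returns ``{(i, j): (m_ij, support)}`` for every ordered reaction pair
    with >= 2 common substituent sets; m_ij estimates rho_j / rho_i.  Pairs
    with fewer than two common sets, or with no x-spread, are omitted.
    """
    slope_fn = {"theil_sen": theil_sen_slope, "ols": ols_slope}[estimator]
    per = table.by_reaction()
    out: dict[tuple[str, str], tuple[float, int]] = {}
    reactions = table.reactions
    for a_idx, i in enumerate(reactions):
        for j in reactions[a_idx + 1 :]:
            common = sorted(set(per[i]) & set(per[j]))
            if len(common) < 2:
                continue
            yi = np.array([per[i][s] for s in common])
            yj = np.array([per[j][s] for s in common])
            try:
                m_ij = slope_fn(np.column_stack([yi, yj]))
                m_ji = slope_fn(np.column_stack([yj, yi]))
            except DegenerateInputError:
                continue
            out[(i, j)] = (m_ij, len(common))
            out[(j, i)] = (m_ji, len(common))
    return out


# ---------------------------------------------------------------------------
# global rho
# ---------------------------------------------------------------------------

def _slope_graph(slopes) -> nx.Graph:
    g = nx.Graph()
    for (i, j), (m, support) in slopes.items():
        if g.has_edge(i, j):
            continue
        # keep the orientation as stored; the reverse slope is ~1/m
        g.add_edge(i, j, slope=m, support=support, src=i)
    return g


def fit_global_rho(
    slopes: dict[tuple[str, str], tuple[float, int]],
    anchor: str,
    allow_negative: bool = False,
    reactions=None,
) -> dict[str, float]:
    """Solve all reaction constants at once from pairwise slopes.

    log rho is obtained from the support-weighted least-squares system
    log rho_j - log rho_i = log m_ij over every supported ordered pair,
    then rescaled so rho(anchor) = 1 exactly.  ``reactions`` (when given)
    lists every reaction that must be reachable; reactions without any
    supported pair make the graph disconnected.
    """
    nodes = sorted({r for pair in slopes for r in pair} | {anchor} | set(reactions or ()))
    if len(nodes) == 1:
        return {anchor: 1.0}
    g = _slope_graph(slopes)
    for n in nodes:
        g.add_node(n)
    components = [sorted(c) for c in nx.connected_components(g)]
    if len(components) > 1:
        raise ConnectivityError(
            f"reaction graph is disconnected; components: {components}",
            components=components,
        )

    signs = {n: 1.0 for n in nodes}
    if allow_negative:
        # propagate slope signs over the maximum-support spanning tree
        tree = nx.maximum_spanning_tree(g, weight="support")
        for parent, child in nx.bfs_edges(tree, anchor):
            m = g.edges[parent, child]["slope"]
            signs[child] = signs[parent] * math.copysign(1.0, m)
    else:
        bad = [(pair, m) for pair, (m, _) in slopes.items() if m <= 0]
        if bad:
            raise SignError(
                "non-positive pairwise slope(s) under strict-positivity config: "
                + ", ".join(f"{p}: {m:.6g}" for p, m in bad[:5])
            )

    index = {n: k for k, n in enumerate(nodes)}
    rows, rhs, weights = [], [], []
    for (i, j), (m, support) in sorted(slopes.items()):
        mag = abs(m)
        if mag == 0.0 or not math.isfinite(mag):
            continue
        row = np.zeros(len(nodes))
        row[index[j]] = 1.0
        row[index[i]] = -1.0
        rows.append(row)
        rhs.append(math.log(mag))
        weights.append(math.sqrt(support))
    a = np.array(rows) * np.array(weights)[:, None]
    b = np.array(rhs) * np.array(weights)
    # gauge: drop the anchor column (log rho_anchor = 0)
    free = [k for k in range(len(nodes)) if k != index[anchor]]
    sol, *_ = np.linalg.lstsq(a[:, free], b, rcond=None)
    log_rho = np.zeros(len(nodes))
    log_rho[free] = sol
    rho = {n: signs[n] * math.exp(log_rho[index[n]]) for n in nodes}
    rho[anchor] = 1.0 * signs[anchor]
    return rho


# ---------------------------------------------------------------------------
# sigma and offsets
# ---------------------------------------------------------------------------

def fit_sigma_offsets(
    table: ReactionTable,
    rho: dict[str, float],
    weighted: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[dict[tuple[str, ...], float], dict[str, float]]:
    """Recover sigma and per-reaction offsets given fitted rho.

    Coordinate refinement: c_j is the median over observed sets of
    (y - rho_j*sigma_s) (robust), sigma_s the mean over reactions of
    (y - c_j)/rho_j, iterated from sigma = 0 until the largest parameter
    change drops below ``tol``.  The gauge is then shifted so the reference
    substituent set has sigma = 0, with the shift absorbed by the offsets.
    """
    per = table.by_reaction()
    reactions = [j for j in table.reactions if j in rho]
    keys = sorted({s for j in reactions for s in per[j]})
    reactions_by_set: dict[tuple[str, ...], list[str]] = {s: [] for s in keys}
    for j in reactions:
        for s in per[j]:
            reactions_by_set[s].append(j)

    ref = tuple(table.reference_substituent_set)
    sigma = {s: 0.0 for s in keys}
    offsets = {j: 0.0 for j in reactions}
    last_delta = math.inf
    for it in range(max_iter):
        prev_sigma, prev_offsets = dict(sigma), dict(offsets)
        # damping after the first sweeps suppresses limit cycles of the
        # (piecewise-constant) median update on noisy data
        damp = 1.0 if it < 2 else 0.5
        for j in reactions:
            vals = [per[j][s] - rho[j] * sigma[s] for s in sorted(per[j])]
            offsets[j] = (1 - damp) * offsets[j] + damp * float(np.median(vals))
        for s in keys:
            js = reactions_by_set[s]
            est = np.array([(per[j][s] - offsets[j]) / rho[j] for j in js])
            if weighted:
                w = np.array([abs(rho[j]) for j in js])
                sigma[s] = float(est @ w / w.sum())
            else:
                sigma[s] = float(est.mean())
        # re-gauge every sweep: the model is invariant under
        # (sigma + d, c - rho*d), a neutral direction of the alternating
        # update along which noise-driven jitter would never decay
        shift = sigma.get(ref)
        if shift is None:
            shift = float(np.mean(list(sigma.values())))
        if shift != 0.0:
            sigma = {s: v - shift for s, v in sigma.items()}
            offsets = {j: c + rho[j] * shift for j, c in offsets.items()}
        delta = max(
            max(abs(sigma[s] - prev_sigma[s]) for s in keys),
            max(abs(offsets[j] - prev_offsets[j]) for j in reactions),
        )
        last_delta = delta
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"sigma/offset refinement did not converge in {max_iter} iterations "
            f"(last max change {last_delta:.3e})",
            last_residual=last_delta,
        )

    # if the reference set was never observed its sigma is 0 by definition
    sigma[ref] = 0.0
    return sigma, offsets


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------

def fit_sigma_hammett(table: ReactionTable, config: FitConfig | None = None) -> HammettParameters:
    """Robust global fit: pairwise Theil–Sen slopes -> global rho -> sigma/c.

    The output is invariant to input row order and, up to the anchor gauge,
    to the choice of anchor reaction.
    """
    cfg = config or FitConfig()
    anchor = cfg.anchor if cfg.anchor is not None else table.reactions[0]
    if anchor not in table.reactions:
        raise ConfigurationError(f"anchor reaction {anchor!r} not in table")
    slopes = pairwise_reaction_slopes(table)
    try:
        rho = fit_global_rho(
            slopes, anchor,
            allow_negative=cfg.allow_negative_slopes,
            reactions=table.reactions,
        )
    except ConnectivityError:
        if cfg.on_disconnected != "per_component":
            raise
        rho = {}
        g = _slope_graph(slopes)
        for j in table.reactions:
            g.add_node(j)
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            comp_slopes = {
                pair: v for pair, v in slopes.items() if pair[0] in comp
            }
            rho.update(
                fit_global_rho(comp_slopes, comp[0], allow_negative=cfg.allow_negative_slopes)
            )
    # reactions with no usable edge at all still get rho = 1 so their
    # offset (and any solo sigma information) is not lost
    for j in table.reactions:
        rho.setdefault(j, 1.0)
    sigma, offsets = fit_sigma_offsets(
        table, rho, weighted=cfg.weighted_sigma, tol=cfg.tol, max_iter=cfg.max_iter
    )
    return HammettParameters(
        rho=rho,
        sigma=sigma,
        offsets=offsets,
        anchor_reaction=anchor,
        method="sigma_hammett_global",
        positions=table.positions,
        reference_substituent_set=tuple(table.reference_substituent_set),
        diagnostics={"n_edges": len(slopes) // 2},
    )


def _default_expansion_order(per, assigned_sets, remaining) -> list[str]:
    """Greedy order: next reaction is the one sharing the most already
    assigned substituent sets (ties broken lexicographically)."""
    order = []
    remaining = set(remaining)
    assigned = set(assigned_sets)
    while remaining:
        best = None
        for j in sorted(remaining):
            n_shared = len(assigned & set(per[j]))
            if n_shared >= 2 and (best is None or n_shared > best[0]):
                best = (n_shared, j)
        if best is None:
            break
        order.append(best[1])
        remaining.discard(best[1])
        assigned |= set(per[best[1]])
    return order


def original_hammett_fit(
    table: ReactionTable,
    reference_reaction: str,
    expansion_order: list[str] | None = None,
) -> HammettParameters:
    """Hammett's sequential procedure.

    (i) rho(reference) = 1; (ii) sigma assigned from the reference reaction
    (which must observe the reference substituent set); (iii) each further
    reaction's rho and offset come from an OLS line through its already
    assigned sigmas; (iv) its new sets extend {sigma}; (v) repeat.
    Reactions or sets unreachable by the expansion are reported in
    ``diagnostics['unassigned_reactions'/'unassigned_sets']``.
    """
    per = table.by_reaction()
    ref_set = tuple(table.reference_substituent_set)
    if reference_reaction not in table.reactions:
        raise ConfigurationError(f"reference reaction {reference_reaction!r} not in table")
    if ref_set not in per[reference_reaction]:
        raise ConfigurationError(
            f"reference reaction {reference_reaction!r} does not observe the "
            f"reference substituent set {ref_set}"
        )
    rho = {reference_reaction: 1.0}
    c_ref = per[reference_reaction][ref_set]
    offsets = {reference_reaction: c_ref}
    sigma = {s: y - c_ref for s, y in per[reference_reaction].items()}

    remaining = [j for j in table.reactions if j != reference_reaction]
    if expansion_order is None:
        order = _default_expansion_order(per, sigma, remaining)
    else:
        unknown = [j for j in expansion_order if j not in table.reactions]
        if unknown:
            raise ConfigurationError(f"expansion order names unknown reactions: {unknown}")
        order = [j for j in expansion_order if j != reference_reaction]

    for j in order:
        shared = sorted(set(sigma) & set(per[j]))
        if len(shared) < 2:
            continue
        x = np.array([sigma[s] for s in shared])
        y = np.array([per[j][s] for s in shared])
        vx = x - x.mean()
        denom = float(vx @ vx)
        if denom == 0.0 or not math.isfinite(denom):
            continue
        slope = float(vx @ (y - y.mean()) / denom)
        if abs(slope) < 1e-12:
            continue
        intercept = float(y.mean() - slope * x.mean())
        rho[j] = slope
        offsets[j] = intercept
        for s, ys in per[j].items():
            if s not in sigma:
                sigma[s] = (ys - intercept) / slope

    unassigned_reactions = sorted(set(table.reactions) - set(rho))
    unassigned_sets = sorted(set(table.set_keys()) - set(sigma))
    return HammettParameters(
        rho=rho,
        sigma=sigma,
        offsets=offsets,
        anchor_reaction=reference_reaction,
        method="original_hammett",
        positions=table.positions,
        reference_substituent_set=ref_set,
        diagnostics={
            "unassigned_reactions": unassigned_reactions,
            "unassigned_sets": [list(s) for s in unassigned_sets],
            "expansion_order": order,
        },
    )


# ---------------------------------------------------------------------------
# prediction and scoring
# ---------------------------------------------------------------------------

def predict(params: HammettParameters, reaction_id: str, substituent_set) -> float:
    """Predicted response c_j + rho_j * sigma_s for a known reaction and set."""
    key = tuple(substituent_set)
    if reaction_id not in params.rho:
        raise UnknownLabelError(f"reaction {reaction_id!r} not covered by the fit")
    if key not in params.sigma:
        raise UnknownLabelError(f"substituent set {key} not covered by the fit")
    return params.offsets[reaction_id] + params.rho[reaction_id] * params.sigma[key]


def predict_table(params: HammettParameters, table: ReactionTable) -> np.ndarray:
    """Vector of predictions aligned with table.records; NaN where uncovered."""
    out = np.full(len(table.records), np.nan)
    for k, r in enumerate(table.records):
        key = r.set_key(table.positions)
        if params.covers(r.reaction_id, key):
            out[k] = predict(params, r.reaction_id, key)
    return out


def evaluate_mae(params: HammettParameters, table: ReactionTable, per: str = "global"):
    """Mean absolute prediction error, pooled or per reaction.

    Records not covered by the parameters are skipped; their count is
    available via ``per='global'`` only through the raised error when no
    record at all is covered.
    """
    if per not in ("global", "reaction"):
        raise ConfigurationError(f"per must be 'global' or 'reaction', got {per!r}")
    pred = predict_table(params, table)
    y = np.array([r.response for r in table.records])
    covered = ~np.isnan(pred)
    if not covered.any():
        raise EvaluationError("no record of the table is covered by the parameters")
    err = np.abs(pred[covered] - y[covered])
    if per == "global":
        return float(err.mean())
    rxn = np.array([r.reaction_id for r in table.records])[covered]
    return {
        j: float(err[rxn == j].mean())
        for j in sorted(set(rxn))
    }


def enumeration_bound(n_reactions: int) -> int:
    """Number of parameter sets reachable by the original sequential method:
    N_R! (each reference/expansion choice can give a different set)."""
    if n_reactions < 1:
        raise ConfigurationError("n_reactions must be >= 1")
    return math.factorial(n_reactions)
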