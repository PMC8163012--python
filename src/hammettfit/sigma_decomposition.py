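"""Decomposition of molecular substituent constants into per-group terms.

A molecular sigma measured for a whole substituent set is modelled as a sum
of single-substituent contributions:

* categorical (dummy encoding): sigma(s) = sum_p alpha[g_p(s), p], one free
  term per (group, position) pair, baseline group pinned to 0 at every
  position.  N_P*N_G parameters; no geometry needed.
* distance decay: sigma(s) = sum_p alpha[g_p] * f(d_p) with f(d) = d^-gamma
  (power) or exp(-d/lambda) (exponential); the position dependence is
  carried entirely by the distance to the reaction center.  N_G + 1
  parameters.
* three-body (ATM): adds pair interactions
  beta[{g_p, g_q}] * (1 + 3 cos t_p cos t_q cos t_C) / (d_pC d_qC d_pq)^3
  over position pairs, the classic triple-dipole angular/radial shape on
  the (position p, position q, reaction center) triangle.
  N_G + (N_G^2 + N_G)/2 + 1 parameters.

All forms are linear in alpha (and beta) once the decay constant is fixed,
so fitting profiles the linear solve over the decay parameter (variable
projection) with a multistart grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .dataset_io import ReactionTable, ScaffoldGeometry
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    GeometryError,
    IdentifiabilityError,
    UnknownLabelError,
)
from .hammett_core import FitConfig, HammettParameters, fit_sigma_hammett

__all__ = [
    "AlphaModel",
    "AlphaHammett",
    "fit_categorical",
    "fit_distance_decay",
    "fit_atm",
    "fit_alpha_hammett",
    "predict_sigma",
    "count_parameters",
    "count_parameter_increment",
    "r_squared",
    "atm_geometry_factor",
    "DECAY_GRID",
]

#: multistart grid for the decay constant (Å scale)
DECAY_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class AlphaModel:
    """Per-substituent contribution model for molecular sigma.

    Exactly the fields required by ``form`` are populated; the baseline
    group has alpha = 0 (for every position in the categorical form).
    ``decay_identifiable`` is False when the geometry cannot pin down the
    decay constant (single position or all distances equal).
    """

    form: str  # categorical | power | exponential | atm
    baseline_group: str
    positions: list[str]
    alpha_by_group_position: dict[tuple[str, str], float] | None = None
    alpha_by_group: dict[str, float] | None = None
    decay_param: float | None = None
    beta_by_pair: dict[tuple[str, str], float] | None = None
    decay_identifiable: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def sse(self) -> float:
        return self.diagnostics.get("sse", math.nan)


def _decay_fn(form: str):
    if form == "power":
        return lambda d, p: d ** (-p)
    if form == "exponential":
        return lambda d, p: np.exp(-d / p)
    raise ConfigurationError(f"unknown decay form {form!r}")


def _sigma_items(sigma_table) -> tuple[list[tuple[str, ...]], np.ndarray]:
    items = sorted(sigma_table.items())
    keys = [tuple(k) for k, _ in items]
    y = np.array([v for _, v in items], dtype=float)
    return keys, y


# ---------------------------------------------------------------------------
# categorical (dummy encoding)
# ---------------------------------------------------------------------------

def fit_categorical(
    sigma_table: dict[tuple[str, ...], float],
    positions: list[str],
    baseline_group: str = "H",
) -> AlphaModel:
    """Least-squares dummy-encoding fit of sigma as a sum of (group, position) terms."""
    keys, y = _sigma_items(sigma_table)
    groups = sorted({g for k in keys for g in k})
    if baseline_group not in groups:
        raise ConfigurationError(f"baseline group {baseline_group!r} absent from the data")
    cols = [(g, p) for p in positions for g in groups if g != baseline_group]
    col_index = {c: k for k, c in enumerate(cols)}
    design = np.zeros((len(keys), len(cols)))
    for r, key in enumerate(keys):
        for p, g in zip(positions, key):
            if g != baseline_group:
                design[r, col_index[(g, p)]] += 1.0
    coef, rank, unresolved = _rank_revealing_lstsq(design, y, cols)
    if unresolved:
        raise IdentifiabilityError(
            f"rank-deficient categorical design (rank {rank} of {len(cols)}); "
            f"unresolvable (group, position) pairs: {unresolved}",
            unresolved=unresolved,
        )
    alpha = {c: float(v) for c, v in zip(cols, coef)}
    for p in positions:
        alpha[(baseline_group, p)] = 0.0
    resid = y - design @ coef
    return AlphaModel(
        form="categorical",
        baseline_group=baseline_group,
        positions=list(positions),
        alpha_by_group_position=alpha,
        diagnostics={"sse": float(resid @ resid), "rank": int(rank), "n_obs": len(keys)},
    )


def _rank_revealing_lstsq(design, y, labels):
    """lstsq with column-pivot QR rank report; returns coef, rank, unresolved labels."""
    from scipy.linalg import qr

    if design.size == 0:
        return np.zeros(0), 0, []
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(design.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    unresolved = [labels[k] for k in sorted(piv[rank:])]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef, rank, unresolved


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def _joint_polish(design_at, coef0, param0, y):
    """Joint Gauss-Newton refinement of (linear coefs, log decay constant).

    The 1-D profile search leaves the decay constant at ~1e-9 relative
    accuracy on noiseless data; a Levenberg-Marquardt pass from its optimum
    reaches machine precision.  Returns (coef, param, sse), never worse in
    SSE than the input point.
    """

    def resid(theta):
        return design_at(math.exp(theta[-1])) @ theta[:-1] - y

    x0 = np.concatenate([coef0, [math.log(param0)]])
    sse0 = float(resid(x0) @ resid(x0))
    try:
        sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    except Exception:
        return coef0, param0, sse0
    sse1 = float(sol.fun @ sol.fun)
    if not (math.isfinite(sse1) and sse1 <= sse0):
        return coef0, param0, sse0
    return sol.x[:-1], math.exp(sol.x[-1]), sse1


def _decay_design(keys, positions, groups, baseline_group, distances, form, param):
    f = _decay_fn(form)
    cols = [g for g in groups if g != baseline_group]
    col_index = {g: k for k, g in enumerate(cols)}
    d = np.array([distances[p] for p in positions])
    fd = f(d, param)
    design = np.zeros((len(keys), len(cols)))
    for r, key in enumerate(keys):
        for k, g in enumerate(key):
            if g != baseline_group:
                design[r, col_index[g]] += fd[k]
    return design, cols


def fit_distance_decay(
    sigma_table: dict[tuple[str, ...], float],
    geometry: ScaffoldGeometry,
    form: str,
    baseline_group: str = "H",
    positions: list[str] | None = None,
    starts=DECAY_GRID,
) -> AlphaModel:
    """Nonlinear least squares of sigma = sum_p alpha[g_p] f(d_p).

    The decay constant is profiled: for each candidate the alphas solve a
    linear least-squares problem; a bounded 1-D minimisation around each
    grid start refines the constant and the best SSE wins.  With a single
    position or all-equal distances the constant is not identifiable: it is
    fixed at 1.0, flagged, and the alphas absorb the common factor.
    """
    keys, y = _sigma_items(sigma_table)
    if positions is None:
        positions = sorted(geometry.distances)
    missing = [p for p in positions if p not in geometry.distances]
    if missing:
        raise GeometryError(f"geometry lacks distances for positions: {missing}")
    groups = sorted({g for k in keys for g in k})
    if baseline_group not in groups:
        raise ConfigurationError(f"baseline group {baseline_group!r} absent from the data")

    distances = geometry.distances
    distinct = {round(distances[p], 12) for p in positions}
    identifiable = len(positions) > 1 and len(distinct) > 1

    def sse_at(log_param: float) -> float:
        design, _ = _decay_design(
            keys, positions, groups, baseline_group, distances, form, math.exp(log_param)
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        return float(r @ r)

    if not identifiable:
        best_param = 1.0
        per_start = []
    else:
        best_param, best_sse, per_start = None, math.inf, []
        for s in starts:
            res = minimize_scalar(
                sse_at,
                bounds=(math.log(s) - 1.6, math.log(s) + 1.6),
                method="bounded",
                options={"xatol": 1e-13},
            )
            per_start.append({"start": s, "param": math.exp(res.x), "sse": float(res.fun)})
            if res.fun < best_sse:
                best_sse, best_param = float(res.fun), math.exp(res.x)
        if best_param is None:
            raise ConfigurationError("decay optimisation failed on every start")

    design, cols = _decay_design(
        keys, positions, groups, baseline_group, distances, form, best_param
    )
    coef, rank, unresolved = _rank_revealing_lstsq(design, y, cols)
    if unresolved:
        raise IdentifiabilityError(
            f"rank-deficient decay design; unresolvable groups: {unresolved}",
            unresolved=unresolved,
        )
    if identifiable:
        coef, best_param, _ = _joint_polish(
            lambda p: _decay_design(
                keys, positions, groups, baseline_group, distances, form, p
            )[0],
            coef, best_param, y,
        )
        design, cols = _decay_design(
            keys, positions, groups, baseline_group, distances, form, best_param
        )
    alpha = {g: float(v) for g, v in zip(cols, coef)}
    alpha[baseline_group] = 0.0
    resid = y - design @ coef
    return AlphaModel(
        form=form,
        baseline_group=baseline_group,
        positions=list(positions),
        alpha_by_group=alpha,
        decay_param=float(best_param),
        decay_identifiable=identifiable,
        diagnostics={
            "sse": float(resid @ resid),
            "n_obs": len(keys),
            "starts": per_start,
        },
    )


# ---------------------------------------------------------------------------
# three-body (ATM)
# ---------------------------------------------------------------------------

def atm_geometry_factor(p_xyz, q_xyz, center_xyz) -> float:
    """Triple-dipole angular/radial factor for the (p, q, center) triangle:
    (1 + 3 cos t_p cos t_q cos t_C) / (d_pC * d_qC * d_pq)^3."""
    p = np.asarray(p_xyz, float)
    q = np.asarray(q_xyz, float)
    c = np.asarray(center_xyz, float)
    d_pc = np.linalg.norm(p - c)
    d_qc = np.linalg.norm(q - c)
    d_pq = np.linalg.norm(p - q)
    if min(d_pc, d_qc, d_pq) <= 0:
        raise GeometryError("coincident points in ATM triangle")
    area = 0.5 * np.linalg.norm(np.cross(q - p, c - p))
    if area < 1e-10 * max(d_pc, d_qc, d_pq) ** 2:
        raise GeometryError("collinear ATM triangle")
    cos_p = float((q - p) @ (c - p) / (d_pq * d_pc))
    cos_q = float((p - q) @ (c - q) / (d_pq * d_qc))
    cos_c = float((p - c) @ (q - c) / (d_pc * d_qc))
    return (1.0 + 3.0 * cos_p * cos_q * cos_c) / (d_pc * d_qc * d_pq) ** 3


def _pair_key(g1: str, g2: str) -> tuple[str, str]:
    return (g1, g2) if g1 <= g2 else (g2, g1)


def _atm_design(keys, positions, groups, baseline_group, geometry, form, param, factors):
    base, alpha_cols = _decay_design(
        keys, positions, groups, baseline_group, geometry.distances, form, param
    )
    pair_cols = [
        _pair_key(a, b) for a, b in combinations(groups, 2)
    ] + [(g, g) for g in groups]
    pair_cols = sorted(set(pair_cols))
    pair_index = {c: k for k, c in enumerate(pair_cols)}
    pair_block = np.zeros((len(keys), len(pair_cols)))
    pos_pairs = list(combinations(range(len(positions)), 2))
    for r, key in enumerate(keys):
        for a, b in pos_pairs:
            pk = _pair_key(key[a], key[b])
            pair_block[r, pair_index[pk]] += factors[(a, b)]
    return np.hstack([base, pair_block]), alpha_cols, pair_cols


def fit_atm(
    sigma_table: dict[tuple[str, ...], float],
    geometry: ScaffoldGeometry,
    decay_form: str = "power",
    baseline_group: str = "H",
    positions: list[str] | None = None,
    starts=DECAY_GRID,
) -> AlphaModel:
    """Decay model plus ATM pair interactions between occupied positions.

    beta is keyed by unordered group pairs (same-group pairs included) and
    is unconstrained; the single-substituent part shares the decay form.

    The decay constant is taken from the nested two-body fit and alpha/beta
    are then solved linearly: refitting the constant jointly with beta is
    numerically ill-posed (a small change in the constant can be almost
    exactly compensated by the pair terms, so on low-noise data the joint
    objective has a flat valley).  Using the two-body optimum also makes
    SSE(atm) <= SSE(decay) hold by construction (same constant, superset
    of columns).
    """
    if not geometry.has_coordinates:
        raise GeometryError("ATM fit requires position coordinates and a reaction center")
    keys, y = _sigma_items(sigma_table)
    if positions is None:
        positions = sorted(geometry.distances)
    groups = sorted({g for k in keys for g in k})
    if baseline_group not in groups:
        raise ConfigurationError(f"baseline group {baseline_group!r} absent from the data")

    factors = {}
    for a, b in combinations(range(len(positions)), 2):
        factors[(a, b)] = atm_geometry_factor(
            geometry.coordinates[positions[a]],
            geometry.coordinates[positions[b]],
            geometry.reaction_center,
        )

    # decay constant from the nested two-body fit (see docstring)
    decay_fit = fit_distance_decay(
        sigma_table, geometry, decay_form, baseline_group, positions, starts
    )
    identifiable = decay_fit.decay_identifiable
    best_param = decay_fit.decay_param

    design, alpha_cols, pair_cols = _atm_design(
        keys, positions, groups, baseline_group, geometry, decay_form, best_param, factors
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    alpha = {g: float(v) for g, v in zip(alpha_cols, coef[: len(alpha_cols)])}
    alpha[baseline_group] = 0.0
    beta = {c: float(v) for c, v in zip(pair_cols, coef[len(alpha_cols):])}
    resid = y - design @ coef
    return AlphaModel(
        form="atm",
        baseline_group=baseline_group,
        positions=list(positions),
        alpha_by_group=alpha,
        decay_param=float(best_param),
        beta_by_pair=beta,
        decay_identifiable=identifiable,
        diagnostics={
            "sse": float(resid @ resid),
            "n_obs": len(keys),
            "decay_form": decay_form,
            "two_body_sse": decay_fit.sse,
        },
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_sigma(model: AlphaModel, substituent_set, geometry: ScaffoldGeometry | None = None) -> float:
    """Evaluate the fitted decomposition for any substituent set (seen or not)."""
    key = tuple(substituent_set)
    if len(key) != len(model.positions):
        raise ConfigurationError(
            f"substituent set has {len(key)} positions, model expects {len(model.positions)}"
        )
    if model.form == "categorical":
        total = 0.0
        for p, g in zip(model.positions, key):
            if (g, p) not in model.alpha_by_group_position:
                raise UnknownLabelError(f"group {g!r} at position {p!r} unknown to the model")
            total += model.alpha_by_group_position[(g, p)]
        return total
    if geometry is None:
        raise ConfigurationError(f"form {model.form!r} needs a geometry to predict")
    for g in key:
        if g not in model.alpha_by_group:
            raise UnknownLabelError(f"group {g!r} unknown to the model")
    if model.form in ("power", "exponential"):
        f = _decay_fn(model.form)
        return float(
            sum(
                model.alpha_by_group[g] * f(geometry.distances[p], model.decay_param)
                for p, g in zip(model.positions, key)
            )
        )
    if model.form == "atm":
        f = _decay_fn(model.diagnostics.get("decay_form", "power"))
        total = sum(
            model.alpha_by_group[g] * f(geometry.distances[p], model.decay_param)
            for p, g in zip(model.positions, key)
        )
        for a, b in combinations(range(len(model.positions)), 2):
            fac = atm_geometry_factor(
                geometry.coordinates[model.positions[a]],
                geometry.coordinates[model.positions[b]],
                geometry.reaction_center,
            )
            total += model.beta_by_pair[_pair_key(key[a], key[b])] * fac
        return float(total)
    raise ConfigurationError(f"unknown model form {model.form!r}")


# ---------------------------------------------------------------------------
# parameter counting and scoring
# ---------------------------------------------------------------------------

def count_parameters(form: str, n_groups: int, n_positions: int | None = None,
                     n_reactions: int | None = None) -> int:
    """Parameter budget of each decomposition form.

    categorical: N_P*N_G; power/exponential: N_G + 1 (decay constant);
    atm: N_G + (N_G^2 + N_G)/2 + 1; alpha_hammett_total: N_R + N_G + 1
    (one rho per reaction, one alpha per group, one decay constant).
    """
    if n_groups < 1:
        raise ConfigurationError("n_groups must be positive")
    if form == "categorical":
        if not n_positions or n_positions < 1:
            raise ConfigurationError("categorical counting needs n_positions")
        return n_positions * n_groups
    if form in ("power", "exponential"):
        return n_groups + 1
    if form == "atm":
        return n_groups + (n_groups**2 + n_groups) // 2 + 1
    if form == "alpha_hammett_total":
        if not n_reactions or n_reactions < 1:
            raise ConfigurationError("alpha_hammett_total counting needs n_reactions")
        return n_reactions + n_groups + 1
    raise ConfigurationError(f"unknown form {form!r}")


def count_parameter_increment(form: str, n_groups: int, n_positions: int | None = None,
                              add: str = "group") -> int:
    """Extra parameters needed when extending the vocabulary by one
    position (categorical: +N_G; decay/atm: 0, only a distance is needed)
    or by one group (categorical: +N_P; decay: +1; atm: +1 + N_G)."""
    if add == "position":
        return {"categorical": n_groups, "power": 0, "exponential": 0, "atm": 0}[form]
    if add == "group":
        if form == "categorical":
            if not n_positions:
                raise ConfigurationError("categorical increment needs n_positions")
            return n_positions
        if form in ("power", "exponential"):
            return 1
        if form == "atm":
            return 1 + n_groups
    raise ConfigurationError(f"unknown form {form!r} or add {add!r}")


def r_squared(sigma_true, sigma_model) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    yt = np.asarray(sigma_true, float)
    ym = np.asarray(sigma_model, float)
    if yt.shape != ym.shape or yt.size < 2:
        raise ConfigurationError("r_squared needs two equal-length vectors of size >= 2")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("zero variance in sigma_true")
    ss_res = float(np.sum((yt - ym) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# alpha-Hammett: the additive baseline used by delta-ML
# ---------------------------------------------------------------------------

@dataclass
class AlphaHammett:
    """Two-stage additive Hammett model: global rho/c plus a decay-form
    alpha decomposition of the fitted sigmas.

    Generalises to substituent sets never observed in training (any
    combination of known groups), which is what makes it usable as a
    delta-ML baseline.  Total parameter count: N_R + N_G + 1.
    """

    hammett: HammettParameters
    alpha: AlphaModel
    geometry: ScaffoldGeometry

    def predict(self, reaction_id: str, substituent_set) -> float:
        if reaction_id not in self.hammett.rho:
            raise UnknownLabelError(f"reaction {reaction_id!r} not covered by the baseline")
        sigma = predict_sigma(self.alpha, substituent_set, self.geometry)
        return self.hammett.offsets[reaction_id] + self.hammett.rho[reaction_id] * sigma

    def predict_record(self, record, positions) -> float:
        return self.predict(record.reaction_id, record.set_key(positions))


def fit_alpha_hammett(
    table: ReactionTable,
    geometry: ScaffoldGeometry,
    decay_form: str = "power",
    config: FitConfig | None = None,
    baseline_group: str | None = None,
    mode: str = "two_stage",
) -> AlphaHammett:
    """Fit the additive alpha-Hammett model.

    mode="two_stage" (default): global sigma-Hammett fit, then a decay-form
    decomposition of the fitted sigmas — the procedure used for analysing a
    full dataset.

    mode="joint": all of {rho_j}, {c_j}, {alpha_g} and the decay constant
    are fitted together by nonlinear least squares on the responses
    (N_R + N_G + 1 free parameters after the gauge rho(anchor) = 1,
    alpha(baseline) = 0).  On small subsamples the two-stage route breaks
    down — the pairwise slope graph falls apart and per-component gauges
    cannot be pooled — while the joint fit stays well-posed as long as the
    record count exceeds the parameter count; it is the baseline used for
    delta-ML learning curves.
    """
    if baseline_group is None:
        ref_groups = set(table.reference_substituent_set)
        baseline_group = ref_groups.pop() if len(ref_groups) == 1 else "H"
    if mode == "two_stage":
        params = fit_sigma_hammett(table, config)
        alpha = fit_distance_decay(
            params.sigma, geometry, decay_form,
            baseline_group=baseline_group, positions=table.positions,
        )
        return AlphaHammett(hammett=params, alpha=alpha, geometry=geometry)
    if mode != "joint":
        raise ConfigurationError(f"unknown alpha-Hammett mode {mode!r}")
    return _fit_alpha_hammett_joint(table, geometry, decay_form, baseline_group)


def _fit_alpha_hammett_joint(table, geometry, decay_form, baseline_group):
    positions = table.positions
    missing = [p for p in positions if p not in geometry.distances]
    if missing:
        raise GeometryError(f"geometry lacks distances for positions: {missing}")
    groups = table.groups
    if baseline_group not in groups:
        raise ConfigurationError(f"baseline group {baseline_group!r} absent from the data")
    free_groups = [g for g in groups if g != baseline_group]
    reactions = table.reactions
    anchor = reactions[0]
    free_rxn = [j for j in reactions if j != anchor]
    d = np.array([geometry.distances[p] for p in positions])
    f = _decay_fn(decay_form)

    records = table.records
    y = np.array([r.response for r in records])
    rxn_idx = np.array([reactions.index(r.reaction_id) for r in records])
    # per-record group-occupancy counts by position (for sigma evaluation)
    occ = np.zeros((len(records), len(free_groups), len(positions)))
    g_index = {g: k for k, g in enumerate(free_groups)}
    for r_k, rec in enumerate(records):
        for p_k, g in enumerate(rec.set_key(positions)):
            if g != baseline_group:
                occ[r_k, g_index[g], p_k] += 1.0

    distinct = {round(x, 12) for x in d}
    identifiable = len(positions) > 1 and len(distinct) > 1
    n_g, n_r = len(free_groups), len(reactions)

    # rho parameterized as exp(u): reaction constants are positive in the
    # families this model targets, and an unconstrained rho lets reactions
    # with only two sampled records run off to arbitrary sign/scale
    free_rxn_idx = [reactions.index(j) for j in free_rxn]

    def unpack(theta):
        alpha = theta[:n_g]
        rho = np.ones(n_r)
        rho[free_rxn_idx] = np.exp(np.clip(theta[n_g : n_g + len(free_rxn)], -20, 20))
        c = theta[n_g + len(free_rxn) : n_g + len(free_rxn) + n_r]
        param = math.exp(theta[-1]) if identifiable else 1.0
        return alpha, rho, c, param

    # sigma per record = sum_g alpha_g * sum_p occ[g,p] f(d_p)
    def resid(theta):
        alpha, rho, c, param = unpack(theta)
        fd = np.asarray(f(d, param))
        sigma = np.einsum("rgp,p,g->r", occ, fd, alpha)
        return c[rxn_idx] + rho[rxn_idx] * sigma - y

    per = table.by_reaction()
    c0 = np.array([float(np.median(list(per[j].values()))) for j in reactions])
    best = None
    for start in (DECAY_GRID if identifiable else (1.0,)):
        fd = np.asarray(f(d, start))
        design = np.einsum("rgp,p->rg", occ, fd)
        a0, *_ = np.linalg.lstsq(design, y - c0[rxn_idx], rcond=None)
        theta0 = np.concatenate(
            [a0, np.zeros(len(free_rxn)), c0, [math.log(start)]]
        )
        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                            gtol=1e-14, max_nfev=4000)
        sse = float(sol.fun @ sol.fun)
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    sse, theta = best
    alpha_v, rho_v, c_v, param = unpack(theta)
    params = HammettParameters(
        rho={j: float(v) for j, v in zip(reactions, rho_v)},
        sigma={},
        offsets={j: float(v) for j, v in zip(reactions, c_v)},
        anchor_reaction=anchor,
        method="alpha_hammett_joint",
        positions=positions,
        reference_substituent_set=tuple(table.reference_substituent_set),
        diagnostics={"sse": sse},
    )
    alpha = {g: float(v) for g, v in zip(free_groups, alpha_v)}
    alpha[baseline_group] = 0.0
    model = AlphaModel(
        form=decay_form,
        baseline_group=baseline_group,
        positions=positions,
        alpha_by_group=alpha,
        decay_param=float(param),
        decay_identifiable=identifiable,
        diagnostics={"sse": sse, "n_obs": len(records)},
    )
    return AlphaHammett(hammett=params, alpha=model, geometry=geometry)
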