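"""Hammett-consistent synthetic datasets with known ground truth.

Every generated response follows the additive construction

    sigma_s = sum_p alpha[g_p] * f(d_p)  (+ ATM pair terms)
    y_{s,j} = c_j + rho_j * sigma_s + noise,

optionally contaminated with gross response-level outliers and uniform
missingness, so every fitting stage in the package has a parameter-recovery
oracle.  Two presets emulate the regimes the method targets:

* :func:`make_sn2_like` — activation energies for 12 reaction channels on a
  four-position scaffold (two positions near the reacting carbon, two on
  the neighbouring carbon), 5 groups, power-law distance decay; barriers
  fall in the few-to-tens of kcal/mol range typical of computed S_N2
  barriers.
* :func:`make_single_substituent_like` — log10 rate constants for
  single-substituent series across several co-reactants/temperatures, with
  an optional "unphysical" series that is linear in the reaction index
  (an Arrhenius-violating contaminant for outlier-detection tests).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .dataset_io import (
    ReactionTable,
    ScaffoldGeometry,
    build_table,
    make_record,
)
from .errors import ConfigurationError, ConnectivityError
from .sigma_decomposition import atm_geometry_factor

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate",
    "make_sn2_like",
    "make_single_substituent_like",
    "sn2_geometry",
]


@dataclass
class SyntheticConfig:
    """Declarative description of a synthetic world.

    groups: ordered {label: true alpha}, baseline (alpha = 0) first.
    positions: ordered {label: distance in Å}.
    coordinates: optional {label: 3-vector}; needed for pair_interactions.
    decay: ("none", None) | ("power", gamma) | ("exponential", lam).
    pair_interactions: optional {(g1, g2) sorted: beta} using the ATM
        geometric factor.
    rho_range: log-uniform draw interval for rho (positive).
    offset_range: uniform draw interval for c_j.
    outlier rows get +/- outlier_shift added to the response.
    outlier_unit: "record" contaminates records independently; "set" marks
        whole substituent-set series (every record of a chosen set, with
        independent shift signs), the structure of real rate-table
        anomalies where one compound misbehaves across all reactions.
        With "set", the contaminated fraction of each pairwise reaction
        scatter equals outlier_fraction; with "record" it is
        1 - (1 - outlier_fraction)^2.
    """

    n_reactions: int = 12
    groups: dict[str, float] = field(default_factory=lambda: {"H": 0.0, "X": -1.0, "Y": 1.0})
    positions: dict[str, float] = field(default_factory=lambda: {"R1": 1.5})
    coordinates: dict[str, tuple] | None = None
    reaction_center: tuple = (0.0, 0.0, 0.0)
    decay: tuple = ("none", None)
    pair_interactions: dict[tuple[str, str], float] | None = None
    rho_range: tuple[float, float] = (0.2, 5.0)
    offset_range: tuple[float, float] = (-1.0, 1.0)
    signed_rho: bool = False
    noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    outlier_unit: str = "record"
    missing_fraction: float = 0.0
    max_sets: int = 2000
    response_type: str = "activation_energy_kcal_mol"
    reaction_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ConfigurationError("n_reactions must be >= 1")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ConfigurationError("outlier_fraction must be in [0, 0.5)")
        if not (0 <= self.missing_fraction < 1):
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        alphas = list(self.groups.values())
        if not alphas or alphas[0] != 0.0:
            raise ConfigurationError("the first (baseline) group must have alpha = 0")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to check parameter recovery after gauge alignment."""

    rho: dict[str, float]
    offsets: dict[str, float]
    sigma: dict[tuple[str, ...], float]
    alpha: dict[str, float]
    beta: dict[tuple[str, str], float] | None
    decay: tuple
    noise_sd: float
    outlier_rows: list[int]
    geometry: ScaffoldGeometry | None = None


def _decay_values(positions: dict[str, float], decay: tuple) -> np.ndarray:
    form, param = decay
    d = np.array(list(positions.values()))
    if form == "none":
        return np.ones_like(d)
    if form == "power":
        return d ** (-param)
    if form == "exponential":
        return np.exp(-d / param)
    raise ConfigurationError(f"unknown decay form {form!r}")


def _true_sigma(cfg: SyntheticConfig, keys, geometry: ScaffoldGeometry | None):
    pos_labels = list(cfg.positions)
    fd = _decay_values(cfg.positions, cfg.decay)
    sigma = {}
    pair_factor = {}
    if cfg.pair_interactions:
        if geometry is None or not geometry.has_coordinates:
            raise ConfigurationError("pair_interactions need position coordinates")
        for a, b in combinations(range(len(pos_labels)), 2):
            pair_factor[(a, b)] = atm_geometry_factor(
                geometry.coordinates[pos_labels[a]],
                geometry.coordinates[pos_labels[b]],
                geometry.reaction_center,
            )
    for key in keys:
        val = sum(cfg.groups[g] * fd[k] for k, g in enumerate(key))
        if cfg.pair_interactions:
            for (a, b), fac in pair_factor.items():
                pk = tuple(sorted((key[a], key[b])))
                val += cfg.pair_interactions.get(pk, 0.0) * fac
        sigma[key] = float(val)
    return sigma


def _reaction_graph_connected(records, positions) -> bool:
    import networkx as nx

    per: dict[str, set] = {}
    for r in records:
        per.setdefault(r.reaction_id, set()).add(r.set_key(positions))
    g = nx.Graph()
    g.add_nodes_from(per)
    rxns = sorted(per)
    for a_idx, i in enumerate(rxns):
        for j in rxns[a_idx + 1 :]:
            if len(per[i] & per[j]) >= 2:
                g.add_edge(i, j)
    return nx.is_connected(g) if len(g) else False


def generate(config: SyntheticConfig) -> tuple[ReactionTable, SyntheticGroundTruth]:
    """Generate a reaction table plus its ground truth; fully seed-determined."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pos_labels = list(cfg.positions)
    group_labels = list(cfg.groups)

    geometry = None
    if cfg.coordinates is not None:
        geometry = ScaffoldGeometry(
            distances=dict(cfg.positions),
            coordinates={p: np.asarray(c, float) for p, c in cfg.coordinates.items()},
            reaction_center=np.asarray(cfg.reaction_center, float),
        )
    elif cfg.positions:
        geometry = ScaffoldGeometry(distances=dict(cfg.positions))

    n_all = len(group_labels) ** len(pos_labels)
    if n_all <= cfg.max_sets:
        keys = sorted(product(group_labels, repeat=len(pos_labels)))
    else:
        chosen = set()
        baseline_key = tuple(group_labels[0] for _ in pos_labels)
        chosen.add(baseline_key)
        while len(chosen) < cfg.max_sets:
            chosen.add(tuple(rng.choice(group_labels, size=len(pos_labels))))
        keys = sorted(chosen)

    sigma = _true_sigma(cfg, keys, geometry)

    if cfg.reaction_labels is not None:
        if len(cfg.reaction_labels) != cfg.n_reactions:
            raise ConfigurationError("reaction_labels length must equal n_reactions")
        reactions = list(cfg.reaction_labels)
    else:
        reactions = [f"rxn{k + 1:02d}" for k in range(cfg.n_reactions)]
    lo, hi = cfg.rho_range
    rho_vals = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_reactions))
    if cfg.signed_rho:
        rho_vals *= rng.choice([-1.0, 1.0], size=cfg.n_reactions)
    rho = dict(zip(reactions, rho_vals.tolist()))
    offsets = dict(
        zip(reactions, rng.uniform(*cfg.offset_range, size=cfg.n_reactions).tolist())
    )

    for attempt in range(10):
        sub_rng = np.random.default_rng([cfg.seed, 7919, attempt])
        records = []
        clean = []
        for j in reactions:
            for key in keys:
                if cfg.missing_fraction > 0 and sub_rng.random() < cfg.missing_fraction:
                    continue
                y = offsets[j] + rho[j] * sigma[key]
                clean.append(y)
                records.append((j, key, y))
        noise = (
            sub_rng.normal(0.0, cfg.noise_sd, size=len(records))
            if cfg.noise_sd > 0
            else np.zeros(len(records))
        )
        if cfg.outlier_unit == "set":
            n_out_sets = int(math.floor(cfg.outlier_fraction * len(keys)))
            out_keys = {
                keys[i]
                for i in sub_rng.choice(len(keys), size=n_out_sets, replace=False)
            }
            outlier_rows = [k for k, (_, key, _) in enumerate(records) if key in out_keys]
            n_out = len(outlier_rows)
        elif cfg.outlier_unit == "record":
            n_out = int(math.floor(cfg.outlier_fraction * len(records)))
            outlier_rows = sorted(
                sub_rng.choice(len(records), size=n_out, replace=False).tolist()
            )
        else:
            raise ConfigurationError(f"unknown outlier_unit {cfg.outlier_unit!r}")
        shift = np.zeros(len(records))
        if n_out:
            shift[outlier_rows] = cfg.outlier_shift * sub_rng.choice(
                [-1.0, 1.0], size=n_out
            )
        final = [
            make_record(j, dict(zip(pos_labels, key)), y + e + s, cfg.response_type)
            for (j, key, y), e, s in zip(records, noise, shift)
        ]
        if cfg.n_reactions == 1 or _reaction_graph_connected(final, sorted(pos_labels)):
            break
        warnings.warn(
            f"synthetic reaction graph disconnected (attempt {attempt + 1}); "
            "re-drawing missingness",
            stacklevel=2,
        )
    else:
        raise ConnectivityError(
            "could not generate a connected reaction graph in 10 attempts; "
            "lower missing_fraction"
        )

    baseline_key = tuple(group_labels[0] for _ in pos_labels)
    table = build_table(final, reference_substituent_set=_sorted_key(
        baseline_key, pos_labels
    ))
    truth = SyntheticGroundTruth(
        rho=rho,
        offsets=offsets,
        sigma={_sorted_key(k, pos_labels): v for k, v in sigma.items()},
        alpha=dict(cfg.groups),
        beta=dict(cfg.pair_interactions) if cfg.pair_interactions else None,
        decay=cfg.decay,
        noise_sd=cfg.noise_sd,
        outlier_rows=outlier_rows,
        geometry=geometry,
    )
    return table, truth


def _sorted_key(key, pos_labels):
    """Re-order a generator-order set key into sorted-position order
    (ReactionTable vocabularies are always lexicographic)."""
    m = dict(zip(pos_labels, key))
    return tuple(m[p] for p in sorted(pos_labels))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: true inductive strengths; negative = electron withdrawing (lowers the
#: barrier under rho > 0), ordering NO2 > CN > H > CH3 > NH2
SN2_ALPHA = {"H": 0.0, "NO2": -2.5, "CN": -1.8, "CH3": 0.8, "NH2": 1.5}

#: near pair on the reacting carbon, far pair on the neighbouring carbon
SN2_DISTANCES = {"R1": 1.5, "R2": 1.5, "R3": 2.5, "R4": 2.5}

SN2_COORDINATES = {
    "R1": (0.9, 1.2, 0.0),
    "R2": (0.9, -1.2, 0.0),
    "R3": (2.0, 0.0, 1.5),
    "R4": (2.0, 0.0, -1.5),
}


def sn2_geometry() -> ScaffoldGeometry:
    """The four-position scaffold geometry used by the SN2 preset."""
    return ScaffoldGeometry(
        distances=dict(SN2_DISTANCES),
        coordinates={p: np.array(c) for p, c in SN2_COORDINATES.items()},
        reaction_center=np.zeros(3),
    )


def make_sn2_like(
    seed: int,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    outlier_shift: float = 0.0,
    missing_fraction: float = 0.0,
    pair_interactions: dict | None = None,
    n_reactions: int = 12,
) -> tuple[ReactionTable, SyntheticGroundTruth]:
    """Activation-energy preset: 12 reaction channels, 4 positions x 5
    groups (625 fully enumerated substituent sets), power-law decay
    (gamma = 2).  Offsets and rho are drawn so barriers span roughly the
    3-40 kcal/mol regime of computed S_N2 barriers."""
    cfg = SyntheticConfig(
        n_reactions=n_reactions,
        groups=dict(SN2_ALPHA),
        positions=dict(SN2_DISTANCES),
        coordinates=dict(SN2_COORDINATES),
        reaction_center=(0.0, 0.0, 0.0),
        decay=("power", 2.0),
        pair_interactions=pair_interactions,
        rho_range=(0.5, 3.0),
        offset_range=(12.0, 30.0),
        noise_sd=noise_sd,
        outlier_fraction=outlier_fraction,
        outlier_shift=outlier_shift,
        missing_fraction=missing_fraction,
        max_sets=1000,
        response_type="activation_energy_kcal_mol",
        seed=seed,
    )
    return generate(cfg)


def make_single_substituent_like(
    n_reactions: int,
    seed: int,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    outlier_shift: float = 0.0,
    inject_anomalous: bool = False,
) -> tuple[ReactionTable, SyntheticGroundTruth]:
    """log10-rate preset: one substituent position, 10 groups, reactions in
    the role of different co-reactants or temperatures.

    With ``inject_anomalous`` one substituent's series is replaced by a
    line in the reaction index — mimicking a rate series that is linear
    where every physical series is Arrhenius-like — and recorded in
    ``truth.outlier_rows``.
    """
    if n_reactions < 2:
        raise ConfigurationError("n_reactions must be >= 2")
    groups = {
        "H": 0.0, "Br": -0.9, "CF3": -1.6, "Cl": -0.8, "F": -0.5,
        "Me": 0.4, "MeO": 0.7, "NMe2": 1.3, "NO2": -2.0, "tBu": 0.5,
    }
    cfg = SyntheticConfig(
        n_reactions=n_reactions,
        groups=groups,
        positions={"R1": 1.5},
        decay=("none", None),
        rho_range=(0.5, 3.0),
        offset_range=(-2.0, 2.0),
        noise_sd=noise_sd,
        outlier_fraction=outlier_fraction,
        outlier_shift=outlier_shift,
        response_type="log10_k",
        reaction_labels=[f"T{k + 1:02d}" for k in range(n_reactions)],
        seed=seed,
    )
    table, truth = generate(cfg)
    if inject_anomalous:
        anomalous_group = "NMe2"
        mean_c = float(np.mean(list(truth.offsets.values())))
        rxn_index = {j: k for k, j in enumerate(sorted(truth.rho))}
        new_records = []
        anomalous_rows = []
        for k, r in enumerate(table.records):
            if r.set_key(table.positions) == (anomalous_group,):
                y = mean_c + 0.2 * rxn_index[r.reaction_id]
                new_records.append(
                    make_record(r.reaction_id, r.substituent_map, y, r.response_type)
                )
                anomalous_rows.append(k)
            else:
                new_records.append(r)
        table = build_table(
            new_records, reference_substituent_set=table.reference_substituent_set
        )
        truth.outlier_rows = anomalous_rows
    return table, truth
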