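"""Reading, validation and writing of reaction tables, geometries and parameters.

The on-disk formats are deliberately plain:

* reaction tables — long-format CSV, one row per (reaction, substituent set),
  with a ``reaction_id`` column, one column per scaffold position, a
  ``response`` column and a ``response_type`` column;
* scaffold geometry — CSV with ``position,distance_A,x,y,z`` (coordinates
  optional; a ``reaction_center`` row carries the center coordinates);
* fitted parameters — JSON, round-trippable to 1e-12.

Vocabularies (positions, groups, reactions) are always sorted
lexicographically so identical input yields identical in-memory tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    IntegrityError,
    SchemaError,
    GeometryError,
)

RESPONSE_TYPES = ("log10_k", "activation_energy_kcal_mol")

#: conventional unsubstituted reference group
DEFAULT_REFERENCE_GROUP = "H"

_RESERVED_COLUMNS = ("reaction_id", "response", "response_type")
_CENTER_LABEL = "reaction_center"


@dataclass(frozen=True)
class ReactionRecord:
    """One observation: a reaction applied to one substituent set.

    ``substituents`` maps position label -> group label.  ``response`` is
    either log10 of a rate constant or an activation energy in kcal/mol,
    declared by ``response_type``.
    """

    reaction_id: str
    substituents: tuple[tuple[str, str], ...]
    response: float
    response_type: str

    @property
    def substituent_map(self) -> dict[str, str]:
        return dict(self.substituents)

    def set_key(self, positions: list[str]) -> tuple[str, ...]:
        """Substituent-set key: group labels in declared position order."""
        m = self.substituent_map
        return tuple(m[p] for p in positions)


def make_record(reaction_id, substituents, response, response_type) -> ReactionRecord:
    """Build a record from a plain dict of substituents."""
    items = tuple(sorted((str(p), str(g)) for p, g in dict(substituents).items()))
    return ReactionRecord(str(reaction_id), items, float(response), str(response_type))


@dataclass
class ReactionTable:
    """A validated long-format table of reaction observations.

    Attributes
    ----------
    records : list of ReactionRecord
    positions, groups, reactions : sorted label vocabularies
    reference_substituent_set : tuple of group labels (position order), the
        designated unsubstituted set whose sigma is pinned to zero.
    """

    records: list[ReactionRecord]
    positions: list[str]
    groups: list[str]
    reactions: list[str]
    reference_substituent_set: tuple[str, ...]
    response_type: str

    def __post_init__(self):
        self.positions = list(self.positions)
        self.groups = list(self.groups)
        self.reactions = list(self.reactions)
        self.reference_substituent_set = tuple(self.reference_substituent_set)

    # -- derived views -------------------------------------------------
    def set_keys(self) -> list[tuple[str, ...]]:
        """Distinct substituent-set keys, sorted."""
        return sorted({r.set_key(self.positions) for r in self.records})

    def observations(self) -> dict[tuple[str, tuple[str, ...]], float]:
        """Map (reaction_id, set key) -> response."""
        return {
            (r.reaction_id, r.set_key(self.positions)): r.response
            for r in self.records
        }

    def by_reaction(self) -> dict[str, dict[tuple[str, ...], float]]:
        out: dict[str, dict[tuple[str, ...], float]] = {j: {} for j in self.reactions}
        for r in self.records:
            out.setdefault(r.reaction_id, {})[r.set_key(self.positions)] = r.response
        return out

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_sets(self) -> int:
        return len(self.set_keys())

    def subset(self, indices) -> "ReactionTable":
        """Unvalidated sub-table over the given record indices (vocabularies kept)."""
        recs = [self.records[i] for i in indices]
        return ReactionTable(
            records=recs,
            positions=self.positions,
            groups=self.groups,
            reactions=sorted({r.reaction_id for r in recs}),
            reference_substituent_set=self.reference_substituent_set,
            response_type=self.response_type,
        )


def build_table(records, reference_substituent_set=None, validate=True) -> ReactionTable:
    """Assemble a ReactionTable from records, inferring sorted vocabularies."""
    records = list(records)
    if not records:
        raise IntegrityError("reaction table has no records")
    positions = sorted({p for r in records for p, _ in r.substituents})
    groups = sorted({g for r in records for _, g in r.substituents})
    reactions = sorted({r.reaction_id for r in records})
    rtypes = {r.response_type for r in records}
    if len(rtypes) != 1:
        raise IntegrityError(f"mixed response types in one table: {sorted(rtypes)}")
    rtype = rtypes.pop()
    if rtype not in RESPONSE_TYPES:
        raise SchemaError(f"unknown response_type {rtype!r}; expected one of {RESPONSE_TYPES}")
    if reference_substituent_set is None:
        ref_group = DEFAULT_REFERENCE_GROUP if DEFAULT_REFERENCE_GROUP in groups else groups[0]
        reference_substituent_set = tuple(ref_group for _ in positions)
    table = ReactionTable(
        records=records,
        positions=positions,
        groups=groups,
        reactions=reactions,
        reference_substituent_set=tuple(reference_substituent_set),
        response_type=rtype,
    )
    if validate:
        validate_table(table)
    return table


def validate_table(table: ReactionTable) -> None:
    """Enforce the table invariants; raise on violation."""
    if table.n_reactions < 1:
        raise IntegrityError("table must contain at least one reaction")
    if len(table.groups) < 2:
        raise IntegrityError("table must contain at least two distinct groups")
    seen = set()
    for r in table.records:
        if not math.isfinite(r.response):
            raise IntegrityError(
                f"non-finite response for reaction {r.reaction_id!r}, set {r.substituents!r}"
            )
        m = r.substituent_map
        if sorted(m) != table.positions:
            raise IntegrityError(
                f"record in {r.reaction_id!r} uses positions {sorted(m)} "
                f"but the table declares {table.positions}"
            )
        for g in m.values():
            if g not in table.groups:
                raise IntegrityError(f"group {g!r} not in declared vocabulary")
        key = (r.reaction_id, r.set_key(table.positions))
        if key in seen:
            raise IntegrityError(
                f"duplicate observation for reaction {key[0]!r}, set {key[1]}"
            )
        seen.add(key)
    per_reaction = table.by_reaction()
    for j in table.reactions:
        if len(per_reaction.get(j, {})) < 2:
            raise IntegrityError(
                f"reaction {j!r} has fewer than two distinct substituent sets"
            )
    if len(table.reference_substituent_set) != len(table.positions):
        raise IntegrityError(
            "reference substituent set length does not match the position vocabulary"
        )


# ---------------------------------------------------------------------------
# reaction-table CSV
# ---------------------------------------------------------------------------

def read_reaction_table(path, schema_config: dict | None = None) -> ReactionTable:
    """Read and validate a long-format reaction CSV.

    ``schema_config`` keys (all optional): ``positions`` — explicit list of
    position columns (otherwise every non-reserved column is a position);
    ``reference_substituent_set`` — tuple of group labels in position order;
    ``reference_group`` — single group label replicated over all positions.
    """
    cfg = dict(schema_config or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"reaction table {path} is missing columns: {missing}")
    if "positions" in cfg:
        positions = [str(p) for p in cfg["positions"]]
        absent = [p for p in positions if p not in df.columns]
        if absent:
            raise SchemaError(f"declared position columns absent from {path}: {absent}")
    else:
        positions = sorted(c for c in df.columns if c not in _RESERVED_COLUMNS)
    if not positions:
        raise SchemaError(f"reaction table {path} declares no position columns")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            response = float(d["response"])
        except ValueError as exc:
            raise IntegrityError(f"non-numeric response {d['response']!r}") from exc
        records.append(
            make_record(
                d["reaction_id"],
                {p: d[p] for p in positions},
                response,
                d["response_type"],
            )
        )
    ref = cfg.get("reference_substituent_set")
    if ref is None and "reference_group" in cfg:
        ref = tuple(cfg["reference_group"] for _ in positions)
    return build_table(records, reference_substituent_set=ref)


def write_reaction_table(table: ReactionTable, path) -> None:
    """Write a table back to the long-format CSV (full float precision)."""
    rows = []
    for r in table.records:
        d = {"reaction_id": r.reaction_id}
        d.update({p: g for p, g in zip(table.positions, r.set_key(table.positions))})
        d["response"] = repr(r.response)
        d["response_type"] = r.response_type
        rows.append(d)
    cols = ["reaction_id", *table.positions, "response", "response_type"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scaffold geometry
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldGeometry:
    """Distances (Å) of each scaffold position from the reaction center,
    plus optional Cartesian coordinates for three-body models."""

    distances: dict[str, float]
    coordinates: dict[str, np.ndarray] | None = None
    reaction_center: np.ndarray | None = None

    def __post_init__(self):
        self.distances = {str(p): float(d) for p, d in self.distances.items()}
        for p, d in self.distances.items():
            if not (d > 0 and math.isfinite(d)):
                raise GeometryError(f"distance for position {p!r} must be positive, got {d}")
        if self.coordinates is not None:
            self.coordinates = {
                str(p): np.asarray(c, dtype=float) for p, c in self.coordinates.items()
            }
            if self.reaction_center is None:
                raise GeometryError("coordinates given without a reaction center")
            self.reaction_center = np.asarray(self.reaction_center, dtype=float)
            for p, c in self.coordinates.items():
                if p not in self.distances:
                    raise GeometryError(f"coordinates for undeclared position {p!r}")
                d = float(np.linalg.norm(c - self.reaction_center))
                if abs(d - self.distances[p]) > 1e-6:
                    raise GeometryError(
                        f"|coordinates - center| = {d:.8f} Å disagrees with declared "
                        f"distance {self.distances[p]:.8f} Å for position {p!r}"
                    )

    @property
    def has_coordinates(self) -> bool:
        return self.coordinates is not None


def read_geometry(path) -> ScaffoldGeometry:
    df = pd.read_csv(path)
    required = {"position", "distance_A"}
    if not required.issubset(df.columns):
        raise SchemaError(f"geometry file {path} must have columns {sorted(required)}")
    has_xyz = {"x", "y", "z"}.issubset(df.columns)
    distances, coords, center = {}, {}, None
    for row in df.itertuples(index=False):
        label = str(row.position)
        if label == _CENTER_LABEL:
            if has_xyz:
                center = np.array([row.x, row.y, row.z], dtype=float)
            continue
        distances[label] = float(row.distance_A)
        if has_xyz and not (pd.isna(row.x) or pd.isna(row.y) or pd.isna(row.z)):
            coords[label] = np.array([row.x, row.y, row.z], dtype=float)
    if coords and set(coords) != set(distances):
        raise SchemaError("geometry coordinates must cover all positions or none")
    return ScaffoldGeometry(
        distances=distances,
        coordinates=coords or None,
        reaction_center=center,
    )


def write_geometry(geom: ScaffoldGeometry, path) -> None:
    rows = []
    for p in sorted(geom.distances):
        row = {"position": p, "distance_A": repr(float(geom.distances[p]))}
        if geom.has_coordinates:
            row.update(dict(zip("xyz", (repr(float(v)) for v in geom.coordinates[p]))))
        rows.append(row)
    if geom.has_coordinates:
        rows.append(
            {
                "position": _CENTER_LABEL,
                "distance_A": repr(0.0),
                **dict(zip("xyz", (repr(float(v)) for v in geom.reaction_center))),
            }
        )
    cols = ["position", "distance_A"] + (["x", "y", "z"] if geom.has_coordinates else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fitted-parameter JSON
# ---------------------------------------------------------------------------

_SET_SEP = "|"


def set_key_to_str(key: tuple[str, ...]) -> str:
    return _SET_SEP.join(key)


def str_to_set_key(s: str) -> tuple[str, ...]:
    return tuple(s.split(_SET_SEP))


def write_parameters(params, path) -> None:
    """Serialize a HammettParameters or AlphaModel to JSON.

    Float values are written with ``repr`` precision and round-trip exactly.
    """
    from .hammett_core import HammettParameters  # local import: avoid cycle
    from .sigma_decomposition import AlphaModel

    if isinstance(params, HammettParameters):
        payload = {
            "kind": "hammett",
            "method": params.method,
            "anchor_reaction": params.anchor_reaction,
            "rho": params.rho,
            "sigma": {set_key_to_str(k): v for k, v in params.sigma.items()},
            "offsets": params.offsets,
            "positions": list(params.positions),
            "reference_substituent_set": list(params.reference_substituent_set),
            "diagnostics": params.diagnostics,
        }
    elif isinstance(params, AlphaModel):
        payload = {
            "kind": "alpha",
            "form": params.form,
            "baseline_group": params.baseline_group,
            "positions": list(params.positions),
            "alpha_by_group_position": (
                None
                if params.alpha_by_group_position is None
                else {f"{g}@{p}": v for (g, p), v in params.alpha_by_group_position.items()}
            ),
            "alpha_by_group": params.alpha_by_group,
            "decay_param": params.decay_param,
            "beta_by_pair": (
                None
                if params.beta_by_pair is None
                else {f"{a}~{b}": v for (a, b), v in params.beta_by_pair.items()}
            ),
            "decay_identifiable": params.decay_identifiable,
            "diagnostics": params.diagnostics,
        }
    else:
        raise TypeError(f"cannot serialize {type(params).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_parameters(path):
    """Inverse of :func:`write_parameters`."""
    from .hammett_core import HammettParameters
    from .sigma_decomposition import AlphaModel

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind == "hammett":
        for field_name in ("anchor_reaction", "rho", "sigma", "offsets"):
            if field_name not in payload:
                raise SchemaError(f"parameter file {path} lacks field {field_name!r}")
        return HammettParameters(
            rho=dict(payload["rho"]),
            sigma={str_to_set_key(k): v for k, v in payload["sigma"].items()},
            offsets=dict(payload["offsets"]),
            anchor_reaction=payload["anchor_reaction"],
            method=payload.get("method", "sigma_hammett_global"),
            positions=list(payload.get("positions", [])),
            reference_substituent_set=tuple(payload.get("reference_substituent_set", ())),
            diagnostics=payload.get("diagnostics", {}),
        )
    if kind == "alpha":
        for field_name in ("form", "baseline_group"):
            if field_name not in payload:
                raise SchemaError(f"parameter file {path} lacks field {field_name!r}")
        abgp = payload.get("alpha_by_group_position")
        if abgp is not None:
            abgp = {tuple(k.split("@", 1)): v for k, v in abgp.items()}
        beta = payload.get("beta_by_pair")
        if beta is not None:
            beta = {tuple(k.split("~", 1)): v for k, v in beta.items()}
        return AlphaModel(
            form=payload["form"],
            baseline_group=payload["baseline_group"],
            positions=list(payload.get("positions", [])),
            alpha_by_group_position=abgp,
            alpha_by_group=payload.get("alpha_by_group"),
            decay_param=payload.get("decay_param"),
            beta_by_pair=beta,
            decay_identifiable=payload.get("decay_identifiable", True),
            diagnostics=payload.get("diagnostics", {}),
        )
    raise SchemaError(f"parameter file {path} has unknown kind {kind!r}")
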