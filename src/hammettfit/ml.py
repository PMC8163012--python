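"""Kernel ridge regression on one-hot composition vectors, and delta-ML.

Molecules are represented purely by composition — which group occupies
which scaffold position, plus reaction descriptors — as fingerprint-like
indicator vectors (no Cartesian information, so the comparison against the
additive Hammett models is information-fair).  KRR solves
(K + lambda*I) a = y in the dual; the default Laplacian kernel
exp(-||x - x'||_1 / w) is a natural match for binary vectors.

Delta-ML trains the same machine on the residuals of the additive
alpha-Hammett baseline, so the kernel only has to learn the (smoother)
non-additive correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .dataset_io import ReactionRecord, ReactionTable
from .errors import (
    ConfigurationError,
    EncodingError,
    SolverError,
)
from .hammett_core import FitConfig, fit_sigma_hammett, predict_table
from .sigma_decomposition import AlphaHammett, fit_alpha_hammett

__all__ = [
    "OneHotEncoding",
    "KRRModel",
    "build_encoding",
    "encode",
    "encode_records",
    "kernel_matrix",
    "krr_train",
    "krr_predict",
    "grid_search_cv",
    "delta_train",
    "learning_curve",
    "DEFAULT_WIDTH_GRID",
    "DEFAULT_REG_GRID",
]

DEFAULT_WIDTH_GRID = tuple(2.0**k for k in range(-2, 7))
DEFAULT_REG_GRID = (1e-10, 1e-8, 1e-6, 1e-4, 1e-2)


@dataclass(frozen=True)
class OneHotEncoding:
    """Ordered indicator blocks: one per scaffold position, then reaction
    descriptor blocks (nucleophile/leaving-group parts of the reaction id,
    or a plain reaction-id block).

    ``reaction_splitter``: if set, reaction ids are split on it and part k
    feeds the k-th non-position block.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    position_names: tuple[str, ...]
    reaction_splitter: str | None = None

    @property
    def vector_length(self) -> int:
        return sum(len(vocab) for _, vocab in self.blocks)


def build_encoding(table: ReactionTable, reaction_splitter: str | None = None) -> OneHotEncoding:
    """Encoding for a table: position blocks over the group vocabulary plus
    reaction blocks (split descriptor blocks when a splitter is given)."""
    blocks = [(p, tuple(table.groups)) for p in table.positions]
    if reaction_splitter is not None:
        parts = [r.split(reaction_splitter) for r in table.reactions]
        n_parts = {len(p) for p in parts}
        if n_parts != {2} and len(n_parts) != 1:
            raise EncodingError("reaction ids do not split consistently")
        k = n_parts.pop()
        for b in range(k):
            vocab = tuple(sorted({p[b] for p in parts}))
            blocks.append((f"reaction_part{b}", vocab))
    else:
        blocks.append(("reaction", tuple(table.reactions)))
    return OneHotEncoding(
        blocks=tuple(blocks),
        position_names=tuple(table.positions),
        reaction_splitter=reaction_splitter,
    )


def encode(record: ReactionRecord, encoding: OneHotEncoding) -> np.ndarray:
    """Indicator vector: exactly one 1 per block."""
    subs = record.substituent_map
    if encoding.reaction_splitter is not None:
        parts = record.reaction_id.split(encoding.reaction_splitter)
    else:
        parts = [record.reaction_id]
    vec = np.zeros(encoding.vector_length)
    offset = 0
    part_idx = 0
    for name, vocab in encoding.blocks:
        if name in encoding.position_names:
            label = subs.get(name)
            if label is None:
                raise EncodingError(f"record lacks position {name!r}")
        else:
            if part_idx >= len(parts):
                raise EncodingError(
                    f"reaction id {record.reaction_id!r} has too few parts for the encoding"
                )
            label = parts[part_idx]
            part_idx += 1
        try:
            vec[offset + vocab.index(label)] = 1.0
        except ValueError:
            raise EncodingError(f"label {label!r} not in block {name!r} vocabulary") from None
        offset += len(vocab)
    return vec


def encode_records(records, encoding: OneHotEncoding) -> np.ndarray:
    return np.array([encode(r, encoding) for r in records])


# ---------------------------------------------------------------------------
# kernels and KRR
# ---------------------------------------------------------------------------

def kernel_matrix(xa: np.ndarray, xb: np.ndarray, kernel: str, width: float) -> np.ndarray:
    if width <= 0:
        raise ConfigurationError("kernel width must be positive")
    if kernel == "laplacian":
        return np.exp(-cdist(xa, xb, metric="cityblock") / width)
    if kernel == "gaussian":
        return np.exp(-cdist(xa, xb, metric="sqeuclidean") / (2.0 * width**2))
    raise ConfigurationError(f"unknown kernel {kernel!r}")


@dataclass
class KRRModel:
    kernel: str
    kernel_width: float
    regularization: float
    training_vectors: np.ndarray
    dual_coefficients: np.ndarray
    target_kind: str = "response"  # response | residual

    def __post_init__(self):
        if len(self.dual_coefficients) != len(self.training_vectors):
            raise ConfigurationError("dual coefficient / training vector length mismatch")


def krr_train(
    x: np.ndarray,
    y: np.ndarray,
    kernel: str = "laplacian",
    width: float = 4.0,
    regularization: float = 1e-8,
    target_kind: str = "response",
) -> KRRModel:
    """Solve (K + lambda*I) a = y by Cholesky; deterministic given inputs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 2 or len(x) != len(y) or len(y) < 1:
        raise ConfigurationError("krr_train needs matching X (2-D) and y with n >= 1")
    if regularization < 0:
        raise ConfigurationError("regularization must be >= 0")
    k = kernel_matrix(x, x, kernel, width)
    k[np.diag_indices_from(k)] += regularization
    try:
        a = cho_solve(cho_factor(k, lower=True), y)
    except np.linalg.LinAlgError as exc:
        raise SolverError(
            "singular kernel system (duplicate rows at zero regularization?); "
            "increase the regularization"
        ) from exc
    return KRRModel(
        kernel=kernel,
        kernel_width=float(width),
        regularization=float(regularization),
        training_vectors=x,
        dual_coefficients=a,
        target_kind=target_kind,
    )


def krr_predict(model: KRRModel, x_new: np.ndarray) -> np.ndarray:
    x_new = np.atleast_2d(np.asarray(x_new, float))
    if x_new.shape[1] != model.training_vectors.shape[1]:
        raise EncodingError(
            f"query dimension {x_new.shape[1]} != training dimension "
            f"{model.training_vectors.shape[1]}"
        )
    k = kernel_matrix(x_new, model.training_vectors, model.kernel, model.kernel_width)
    return k @ model.dual_coefficients


# ---------------------------------------------------------------------------
# cross-validated grid search
# ---------------------------------------------------------------------------

def _fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def grid_search_cv(
    x: np.ndarray,
    y: np.ndarray,
    kernel: str = "laplacian",
    width_grid=DEFAULT_WIDTH_GRID,
    reg_grid=DEFAULT_REG_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (width, regularization) search by mean held-out MAE over
    seeded shuffled folds.  Ties go to the smoother model: larger
    regularization first, then larger width."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(width_grid) == 0 or len(reg_grid) == 0:
        raise ConfigurationError("empty hyperparameter grid")
    if len(x) < n_folds:
        raise ConfigurationError(f"need at least n_folds={n_folds} samples, got {len(x)}")
    folds = _fold_indices(len(x), n_folds, seed)
    best = None
    for width in width_grid:
        for reg in reg_grid:
            maes = []
            for f, test_idx in enumerate(folds):
                train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
                model = krr_train(x[train_idx], y[train_idx], kernel, width, reg)
                pred = krr_predict(model, x[test_idx])
                maes.append(float(np.mean(np.abs(pred - y[test_idx]))))
            score = float(np.mean(maes))
            key = (score, -reg, -width)
            if best is None or key < best[0]:
                best = (key, (float(width), float(reg)))
    return best[1]


# ---------------------------------------------------------------------------
# delta-ML
# ---------------------------------------------------------------------------

def delta_train(
    table: ReactionTable,
    baseline: AlphaHammett,
    encoding: OneHotEncoding,
    kernel: str = "laplacian",
    width: float = 4.0,
    regularization: float = 1e-8,
) -> KRRModel:
    """KRR on the residuals y - baseline(y); predictions must be re-based
    by adding the baseline (see ``predict_records``)."""
    residuals = []
    for r in table.records:
        try:
            base = baseline.predict_record(r, table.positions)
        except Exception as exc:
            raise ConfigurationError(
                f"baseline failed on reaction {r.reaction_id!r}, "
                f"set {r.set_key(table.positions)}: {exc}"
            ) from exc
        residuals.append(r.response - base)
    x = encode_records(table.records, encoding)
    return krr_train(
        x, np.array(residuals), kernel, width, regularization, target_kind="residual"
    )


def predict_records(
    model: KRRModel,
    records,
    encoding: OneHotEncoding,
    baseline: AlphaHammett | None = None,
    positions=None,
) -> np.ndarray:
    """Predict responses for records; adds the baseline when the model was
    trained on residuals."""
    x = encode_records(records, encoding)
    pred = krr_predict(model, x)
    if model.target_kind == "residual":
        if baseline is None:
            raise ConfigurationError("residual model needs the baseline to predict")
        base = np.array([baseline.predict_record(r, positions) for r in records])
        pred = pred + base
    return pred


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

_CURVE_METHODS = ("sigma_hammett", "alpha_hammett", "ml", "delta_ml")


def _fit_and_predict(method, train_table, holdout_records, table, encoding,
                     geometry, hyper, kernel):
    """One curve point: fit `method` on the sub-table, predict the holdout.

    Returns per-record predictions; holdout records a Hammett-family model
    cannot cover fall back to the training-mean response.
    """
    y_train_mean = float(np.mean([r.response for r in train_table.records]))
    n_hold = len(holdout_records)
    # subsampled noisy tables can show spurious negative pairwise slopes,
    # disconnected slope graphs and slow sigma/offset coupling; curves must
    # degrade gracefully, not raise
    cfg = FitConfig(
        allow_negative_slopes=True, on_disconnected="per_component",
        tol=1e-8, max_iter=1000,
    )

    if method in ("sigma_hammett", "alpha_hammett"):
        if method == "sigma_hammett":
            params = fit_sigma_hammett(train_table, cfg)
            hold_table = ReactionTable(
                records=list(holdout_records),
                positions=table.positions,
                groups=table.groups,
                reactions=sorted({r.reaction_id for r in holdout_records}),
                reference_substituent_set=table.reference_substituent_set,
                response_type=table.response_type,
            )
            pred = predict_table(params, hold_table)
        else:
            baseline = fit_alpha_hammett(train_table, geometry, config=cfg)
            pred = np.full(n_hold, np.nan)
            for k, r in enumerate(holdout_records):
                try:
                    pred[k] = baseline.predict_record(r, table.positions)
                except Exception:
                    pass
        pred = np.where(np.isnan(pred), y_train_mean, pred)
        return pred

    x_train = encode_records(train_table.records, encoding)
    y_train = np.array([r.response for r in train_table.records])
    width, reg = hyper
    if method == "ml":
        model = krr_train(x_train, y_train, kernel, width, reg)
        return predict_records(model, holdout_records, encoding)
    if method == "delta_ml":
        # the joint 18-parameter fit stays well-posed on subsamples where
        # the two-stage slope graph has already fallen apart
        baseline = fit_alpha_hammett(train_table, geometry, mode="joint")
        model = delta_train(train_table, baseline, encoding, kernel, width, reg)
        corr = krr_predict(model, encode_records(holdout_records, encoding))
        pred = np.empty(n_hold)
        for k, r in enumerate(holdout_records):
            try:
                pred[k] = baseline.predict_record(r, table.positions) + corr[k]
            except Exception:
                pred[k] = y_train_mean
        return pred
    raise ConfigurationError(f"unknown learning-curve method {method!r}")


def learning_curve(
    table: ReactionTable,
    method: str,
    train_sizes,
    n_repeats: int = 10,
    n_folds_final: int = 15,
    seed: int = 0,
    geometry=None,
    encoding: OneHotEncoding | None = None,
    hyper: tuple[float, float] | None = None,
    kernel: str = "laplacian",
) -> pd.DataFrame:
    """MAE versus training-set size.

    Per repeat, a seeded permutation sets aside 1/``n_folds_final`` of the
    records as the holdout; nested training subsets of each requested size
    are drawn from the remainder, the method is fitted and scored on the
    holdout.  Returns a DataFrame with columns size, mean_mae, sd_mae.
    For the kernel methods, ``hyper`` is (width, regularization); if None
    it is chosen once by 5-fold grid search on the first repeat's pool
    (capped at 400 points).
    """
    if method not in _CURVE_METHODS:
        raise ConfigurationError(f"method must be one of {_CURVE_METHODS}")
    records = table.records
    n = len(records)
    n_hold = max(1, n // n_folds_final)
    train_sizes = sorted(int(s) for s in train_sizes)
    if train_sizes[0] < 2:
        raise ConfigurationError("train sizes must be >= 2")
    if train_sizes[-1] > n - n_hold:
        raise ConfigurationError(
            f"largest train size {train_sizes[-1]} exceeds available pool "
            f"({n - n_hold} = {n} records minus {n_hold} holdout)"
        )
    if encoding is None and method in ("ml", "delta_ml"):
        encoding = build_encoding(table)

    if hyper is None and method in ("ml", "delta_ml"):
        rng = np.random.default_rng([seed, 9173])
        pool = rng.permutation(n)[: min(400, n - n_hold)]
        sub = [records[i] for i in pool]
        x = encode_records(sub, encoding)
        y = np.array([r.response for r in sub])
        hyper = grid_search_cv(x, y, kernel=kernel, seed=seed)

    rows = []
    maes = np.zeros((len(train_sizes), n_repeats))
    for rep in range(n_repeats):
        perm = np.random.default_rng([seed, rep]).permutation(n)
        hold_idx, pool_idx = perm[:n_hold], perm[n_hold:]
        holdout = [records[i] for i in hold_idx]
        for si, size in enumerate(train_sizes):
            train_table = table.subset(pool_idx[:size])
            pred = _fit_and_predict(
                method, train_table, holdout, table, encoding, geometry, hyper, kernel
            )
            y_hold = np.array([r.response for r in holdout])
            maes[si, rep] = float(np.mean(np.abs(pred - y_hold)))
    for si, size in enumerate(train_sizes):
        rows.append(
            {
                "size": size,
                "mean_mae": float(maes[si].mean()),
                "sd_mae": float(maes[si].std(ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["method"] = method
    out.attrs["hyper"] = hyper
    return out
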