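"""Global potency models: Tanimoto-kernel SVR and ridge regression on
folded ECFP4 fingerprints, with three-fold double cross-validation.

The outer CV loop estimates generalization; the inner loop selects
hyper-parameters.  The final model is refit on all training data.  The
kernel is the Tanimoto similarity |a AND b| / |a OR b| on 2048-bit
Morgan fingerprints of radius 2 (bond diameter 4), which is positive
semi-definite on binary vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .records import CompoundRecord, Origin

N_BITS = 2048
FP_RADIUS = 2  # Morgan radius 2 == bond diameter 4

DEFAULT_SVR_GRID = {"C": (0.1, 1.0, 10.0, 100.0), "epsilon": (0.01, 0.1, 0.5)}
DEFAULT_RIDGE_GRID = {"alpha": (0.01, 0.1, 1.0, 10.0, 100.0)}

_fp_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=N_BITS
)


def fingerprint(record: Union[CompoundRecord, str, Chem.Mol]) -> np.ndarray:
    """Folded 2048-bit ECFP4 as a 0/1 vector."""
    if isinstance(record, CompoundRecord):
        mol = record.mol
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("unparseable molecule")
    arr = np.zeros(N_BITS, dtype=np.uint8)
    fp = _fp_gen.GetFingerprint(mol)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(records: Sequence) -> np.ndarray:
    return np.vstack([fingerprint(r) for r in records])


def tanimoto_kernel(a: np.ndarray, b: Optional[np.ndarray] = None) -> np.ndarray:
    """Tanimoto similarity matrix between rows of binary matrices.

    Pairs of all-zero vectors get similarity 0 with a warning.
    Accepts single vectors, returning a scalar.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    single = b is not None and np.asarray(b).ndim == 1 and a.shape[0] == 1
    bb = a if b is None else np.atleast_2d(np.asarray(b, dtype=float))
    inter = a @ bb.T
    na = a.sum(axis=1)[:, None]
    nb = bb.sum(axis=1)[None, :]
    union = na + nb - inter
    zero = union == 0
    if zero.any():
        warnings.warn("all-zero fingerprint pair; similarity set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(zero, 0.0, inter / np.where(zero, 1.0, union))
    return float(k[0, 0]) if single else k


@dataclass
class ModelEvaluation:
    """Coefficient of determination and mean absolute error (pIC50 units)."""

    r_squared: float
    mae: float
    n_test: int
    per_fold: list[dict] = field(default_factory=list)


@dataclass
class GlobalModel:
    """A fitted global potency model with its outer-CV generalization estimate."""

    method: str  # "svr" | "ridge"
    estimator: object
    train_fps: np.ndarray
    best_params: dict
    outer_cv: ModelEvaluation

    def predict(self, records: Sequence) -> np.ndarray:
        if len(records) == 0:
            return np.zeros(0)
        fps = fingerprint_matrix(records)
        if self.method == "svr":
            return self.estimator.predict(tanimoto_kernel(fps, self.train_fps))
        return self.estimator.predict(fps.astype(float))


def _fit_one(method: str, params: dict, k_or_x: np.ndarray, y: np.ndarray):
    if method == "svr":
        est = SVR(kernel="precomputed", **params)
    elif method == "ridge":
        est = Ridge(**params)
    else:
        raise ValueError(f"unknown method {method!r}")
    est.fit(k_or_x, y)
    return est


def _param_combinations(grid: dict) -> list[dict]:
    import itertools

    keys = sorted(grid)
    return [
        dict(zip(keys, vals))
        for vals in itertools.product(*(grid[k] for k in keys))
    ]


def train_global_model(
    records: Sequence[CompoundRecord],
    method: str = "svr",
    n_folds: int = 3,
    grid: Optional[dict] = None,
    seed: int = 0,
) -> GlobalModel:
    """Fit a global model with three-fold double cross-validation.

    Hyper-parameters are selected on the inner folds, generalization is
    estimated on the outer folds, and the returned estimator is refit
    on all data with the parameters winning most outer folds (ties: the
    first in grid order).  Deterministic given ``seed``.
    """
    y = np.asarray([r.potency for r in records], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("all training records need finite potencies")
    if np.ptp(y) == 0:
        raise ValueError("degenerate training set: single potency value")
    if len(records) < 30:
        warnings.warn(
            f"only {len(records)} training compounds; global models are "
            "unreliable below ~30",
            stacklevel=2,
        )
    if grid is None:
        grid = DEFAULT_SVR_GRID if method == "svr" else DEFAULT_RIDGE_GRID
    combos = _param_combinations(grid)

    fps = fingerprint_matrix(records)
    x = tanimoto_kernel(fps) if method == "svr" else fps.astype(float)

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_stats = []
    winners = []
    for train_idx, test_idx in outer.split(x):
        inner = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
        best_params, best_mae = None, np.inf
        for params in combos:
            maes = []
            for in_tr, in_te in inner.split(train_idx):
                tr = train_idx[in_tr]
                te = train_idx[in_te]
                est = _fit_one(method, params, x[np.ix_(tr, tr)] if method == "svr" else x[tr], y[tr])
                pred = est.predict(
                    x[np.ix_(te, tr)] if method == "svr" else x[te]
                )
                maes.append(mean_absolute_error(y[te], pred))
            m = float(np.mean(maes))
            if m < best_mae:
                best_mae, best_params = m, params
        est = _fit_one(
            method,
            best_params,
            x[np.ix_(train_idx, train_idx)] if method == "svr" else x[train_idx],
            y[train_idx],
        )
        pred = est.predict(
            x[np.ix_(test_idx, train_idx)] if method == "svr" else x[test_idx]
        )
        fold_stats.append(
            {
                "r_squared": float(r2_score(y[test_idx], pred)),
                "mae": float(mean_absolute_error(y[test_idx], pred)),
                "n_test": len(test_idx),
                "params": best_params,
            }
        )
        winners.append(tuple(sorted(best_params.items())))

    counts = {w: winners.count(w) for w in winners}
    final_params = dict(max(counts, key=lambda w: (counts[w], -winners.index(w))))
    final = _fit_one(method, final_params, x, y)
    outer_eval = ModelEvaluation(
        r_squared=float(np.mean([f["r_squared"] for f in fold_stats])),
        mae=float(np.mean([f["mae"] for f in fold_stats])),
        n_test=len(records),
        per_fold=fold_stats,
    )
    return GlobalModel(
        method=method,
        estimator=final,
        train_fps=fps,
        best_params=final_params,
        outer_cv=outer_eval,
    )


def evaluate(model: GlobalModel, records: Sequence[CompoundRecord]) -> ModelEvaluation:
    """R2 (coefficient of determination) and MAE on a held-out set."""
    if not records:
        raise ValueError("empty test set")
    y = np.asarray([r.potency for r in records], dtype=float)
    pred = model.predict(records)
    return ModelEvaluation(
        r_squared=float(r2_score(y, pred)),
        mae=float(mean_absolute_error(y, pred)),
        n_test=len(records),
    )


def split_series_for_training(
    ea_records: Sequence[CompoundRecord],
    background: Sequence[CompoundRecord] = (),
    seed: int = 0,
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Training protocol split: background actives + 50% of the series.

    The series half is stratified by potency quartile so both halves
    span the potency range; the other half is the external validation
    set.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    eas = list(ea_records)
    y = np.asarray([r.potency for r in eas], dtype=float)
    quartiles = np.quantile(y, [0.25, 0.5, 0.75])
    strata = np.digitize(y, quartiles)
    train_idx: list[int] = []
    for q in np.unique(strata):
        idx = np.nonzero(strata == q)[0]
        perm = rng.permutation(idx)
        train_idx.extend(perm[: len(idx) // 2 + len(idx) % 2])
    train = list(background) + [eas[i] for i in sorted(train_idx)]
    holdout = [eas[i] for i in range(len(eas)) if i not in set(train_idx)]
    return train, holdout


def predict_population(
    model: GlobalModel, vas: Sequence[CompoundRecord]
) -> tuple[list[tuple[CompoundRecord, float]], dict[str, dict[str, float]]]:
    """Predict and rank a VA population.

    Returns the records with predictions in stable descending order
    (ties broken by canonical SMILES) and per-origin boxplot quantiles
    (min, q1, median, q3, max).
    """
    if not vas:
        return [], {}
    preds = model.predict(vas)
    ranked = sorted(
        zip(vas, preds.tolist()), key=lambda rp: (-rp[1], rp[0].smiles)
    )
    summary: dict[str, dict[str, float]] = {}
    by_origin: dict[str, list[float]] = {}
    for rec, p in zip(vas, preds.tolist()):
        by_origin.setdefault(rec.origin.value, []).append(p)
    for origin, vals in by_origin.items():
        q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
        summary[origin] = {
            "min": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "max": float(q[4]),
            "n": len(vals),
        }
    return ranked, summary
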