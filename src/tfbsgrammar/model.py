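"""Strand-aware vs strand-agnostic motif-count activity models.

L1-penalized linear regression of tile expression on motif-count features:
either one count per motif (strand-agnostic, 18 features for the default
roster) or one count per motif per orientation (strand-aware, 36 features).
Evaluated by 10-fold cross-validation with the penalty chosen by nested CV
on each training split; performance is the Pearson r of held-out
predictions, per fold and pooled over the concatenated folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .design import NT, T, TileDesign
from .motifs import Motif, is_palindromic

__all__ = [
    "featurize",
    "fit_lasso_cv",
    "compare_models",
    "top_coefficients",
    "ModelReport",
]


def featurize(tiles: list[TileDesign], strand_aware: bool,
              motif_names: list[str] | None = None) -> pd.DataFrame:
    """Motif-count feature matrix (tiles x features).

    Strand-agnostic: one column per motif (alphabetical).  Strand-aware:
    two columns per motif, ``<motif>:NT`` before ``<motif>:T``; summing the
    two recovers the agnostic column exactly.
    """
    if motif_names is None:
        motif_names = sorted({p.motif_name for t in tiles for p in t.placements})
    known = set(motif_names)
    for t in tiles:
        for p in t.placements:
            if p.motif_name not in known:
                raise KeyError(f"motif {p.motif_name!r} not in feature roster")
    if strand_aware:
        columns = [f"{m}:{o}" for m in motif_names for o in (NT, T)]
    else:
        columns = list(motif_names)
    X = np.zeros((len(tiles), len(columns)))
    col_idx = {c: j for j, c in enumerate(columns)}
    for i, t in enumerate(tiles):
        for p in t.placements:
            key = f"{p.motif_name}:{p.orientation}" if strand_aware else p.motif_name
            X[i, col_idx[key]] += 1
    return pd.DataFrame(X, columns=columns, index=[t.tile_id for t in tiles])


@dataclass
class ModelReport:
    strand_aware: bool
    folds: int
    seed: int
    fold_assignments: np.ndarray
    per_fold_r: list[float]
    per_fold_rho: list[float]
    pooled_r: float
    pooled_rho: float
    coefficients: pd.Series  # full-data fit
    intercept: float

    def to_dict(self) -> dict:
        return {
            "strand_aware": self.strand_aware,
            "folds": self.folds,
            "seed": self.seed,
            "per_fold_r": self.per_fold_r,
            "per_fold_rho": self.per_fold_rho,
            "pooled_r": self.pooled_r,
            "pooled_rho": self.pooled_rho,
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
        }


def _safe_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Correlation with 0.0 for degenerate (constant) inputs."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    r = (pearsonr(a, b) if method == "pearson" else spearmanr(a, b)).statistic
    return 0.0 if np.isnan(r) else float(r)


def _lasso(seed: int, inner_cv: int):
    return make_pipeline(
        StandardScaler(),
        LassoCV(cv=inner_cv, alphas=30, random_state=seed, max_iter=5000),
    )


def fit_lasso_cv(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    inner_cv: int = 5,
    background_ids=None,
    strand_aware: bool | None = None,
) -> ModelReport:
    """Nested cross-validated lasso on motif-count features.

    Outer ``folds``-fold split (seeded, shuffled); the penalty is chosen by
    ``inner_cv``-fold cross-validation on each training split.  Features
    are standardized inside each fit; the intercept is unpenalized.  When
    ``background_ids`` is given, the response is centered within each
    background (equivalent to an unpenalized background intercept) before
    fitting, since the two backbones have different baselines.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if np.all(y == y[0]):
        raise ValueError("response is constant")
    n = len(y)
    if n < 10 * folds:
        raise ValueError(f"need at least {10 * folds} rows for {folds}-fold CV, got {n}")
    if background_ids is not None:
        y = y.copy()
        for bg in pd.unique(np.asarray(background_ids)):
            mask = np.asarray(background_ids) == bg
            y[mask] = y[mask] - y[mask].mean()
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    preds = np.empty(n)
    per_fold_r, per_fold_rho = [], []
    for k, (train, test) in enumerate(kf.split(Xv)):
        assignments[test] = k
        model = _lasso(seed, inner_cv)
        model.fit(Xv[train], y[train])
        p = model.predict(Xv[test])
        preds[test] = p
        per_fold_r.append(_safe_corr(y[test], p, "pearson"))
        per_fold_rho.append(_safe_corr(y[test], p, "spearman"))
    pooled_r = _safe_corr(y, preds, "pearson")
    pooled_rho = _safe_corr(y, preds, "spearman")

    full = _lasso(seed, inner_cv)
    full.fit(Xv, y)
    lasso = full.named_steps["lassocv"]
    scaler = full.named_steps["standardscaler"]
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    coefs = pd.Series(lasso.coef_ / scale, index=list(X.columns)
                      if isinstance(X, pd.DataFrame) else None)
    if strand_aware is None:
        strand_aware = any(str(c).endswith((":NT", ":T")) for c in coefs.index)
    return ModelReport(
        strand_aware=bool(strand_aware),
        folds=folds,
        seed=seed,
        fold_assignments=assignments,
        per_fold_r=per_fold_r,
        per_fold_rho=per_fold_rho,
        pooled_r=pooled_r,
        pooled_rho=pooled_rho,
        coefficients=coefs,
        intercept=float(lasso.intercept_),
    )


def compare_models(report_aware: ModelReport, report_agnostic: ModelReport) -> float:
    """Percent improvement of the strand-aware model, same folds required."""
    if (report_aware.folds != report_agnostic.folds
            or report_aware.seed != report_agnostic.seed
            or not np.array_equal(report_aware.fold_assignments,
                                  report_agnostic.fold_assignments)):
        raise ValueError("reports come from different fold assignments")
    r_aw, r_ag = report_aware.pooled_r, report_agnostic.pooled_r
    return 100.0 * (r_aw - r_ag) / r_ag


def top_coefficients(
    report: ModelReport, k: int = 30, motifs: dict[str, Motif] | None = None
) -> pd.DataFrame:
    """The k coefficients with largest magnitude, with orientation labels."""
    coefs = report.coefficients
    order = coefs.abs().sort_values(ascending=False).index[: max(k, 0)]
    rows = []
    for feat in order:
        motif, _, orient = str(feat).partition(":")
        palindromic = (is_palindromic(motifs[motif].kmer)
                       if motifs and motif in motifs else None)
        rows.append({
            "feature": feat,
            "motif": motif,
            "orientation": orient or "both",
            "coefficient": coefs[feat],
            "palindromic": palindromic,
        })
    return pd.DataFrame(rows, columns=["feature", "motif", "orientation",
                                       "coefficient", "palindromic"])
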