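"""Estimate per-cohort landmark-gene signatures from clinical/genetic risk data.

The model is a two-stage linear factor regression.  Disease data Y
(risk factors x patients) is summarized by a rank-k decomposition

    Y = H F + e_Y,

with the latent features F extracted by truncated SVD of the standardized
factor matrix.  The landmark expression matrix Z (genes x patients) is then
regressed onto those features,

    Z = B F + e_Z,      B_hat = Z F' (F F')^{-1},

yielding per-gene signature weights B (genes x features).  A supervised mode
accepts user-provided loadings H or signed marker gene sets; a survival mode
appends the Cox log-partial-hazard of each patient as an extra feature.
Signatures fitted independently in several cohorts are screened by their
cross-cohort Pearson correlation before any drug matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    CohortData,
    FeatureDecomposition,
    SignatureSet,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_CONSISTENCY_THRESHOLD = 0.4


def _is_binary(row: np.ndarray) -> bool:
    finite = row[np.isfinite(row)]
    return bool(np.isin(finite, (0.0, 1.0)).all())


def standardize_factors(Y: np.ndarray) -> np.ndarray:
    """Standardize each factor row; NaNs are masked then set to the row mean.

    Continuous rows are z-scored (population sd); binary 0/1 rows are centred
    only, so a rare aberration keeps its small leverage.  Masked (missing)
    entries become 0 after centring, i.e. the factor's mean.
    """
    Y = np.asarray(Y, dtype=float)
    out = np.empty_like(Y)
    for j in range(Y.shape[0]):
        row = Y[j]
        mask = np.isfinite(row)
        if not mask.any():
            raise ValidationError(f"factor row {j} is entirely missing")
        vals = row[mask]
        if np.ptp(vals) == 0:
            raise ValidationError(f"factor row {j} is constant")
        centred = row - vals.mean()
        if not _is_binary(row):
            centred = centred / vals.std()
        centred[~mask] = 0.0
        out[j] = centred
    return out


def extract_features(Y: np.ndarray, k: int,
                     feature_names: list[str] | None = None
                     ) -> FeatureDecomposition:
    """Rank-k SVD summary of the standardized disease matrix.

    Convention: ``H = U_k S_k`` carries all scale, ``F = V_k'`` has unit-norm
    rows; each feature is oriented so that the largest-|loading| entry of its
    H column is positive, making signs reproducible across runs.
    """
    Ys = standardize_factors(Y)
    p, n = Ys.shape
    if not 1 <= k <= min(p, n):
        raise ValidationError(f"k={k} outside [1, {min(p, n)}]")
    U, s, Vt = np.linalg.svd(Ys, full_matrices=False)
    if s[k - 1] <= 1e-12 * max(p, n) * s[0]:
        raise ValidationError(f"k={k} exceeds the numerical rank of Y")
    H = U[:, :k] * s[:k]
    F = Vt[:k]
    # orient: largest-|loading| entry of each H column positive
    flip = np.sign(H[np.abs(H).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    H = H * flip
    F = F * flip[:, None]
    total = float((s ** 2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    fd = FeatureDecomposition(H=H, F=F, k=k, explained_fraction=explained,
                              feature_names=feature_names or [])
    fd.validate(unit_norm=True)
    return fd


def supervised_features(
    Y: np.ndarray | None = None,
    H: np.ndarray | None = None,
    marker_signatures: dict[str, tuple[list[str], list[str]]] | None = None,
    Z: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    allow_missing: bool = False,
    unit_norm: bool | None = None,
) -> FeatureDecomposition:
    """Supervised feature extraction from given loadings or marker gene sets.

    Two entry points:

    * ``H`` (p_disease x k) given: ``F = argmin ||Y - H F||`` by per-patient
      least squares; F is returned on its natural scale (``H = I`` gives
      ``F = Y`` exactly) unless ``unit_norm=True``.
    * ``marker_signatures`` given: per feature a pair
      ``(up_genes, down_genes)``; each F row is the per-patient score
      mean(z-scored expression of up markers) - mean(down markers), then
      unit-normed.
    """
    if (H is None) == (marker_signatures is None):
        raise ValidationError("provide exactly one of H or marker_signatures")
    if H is not None:
        if Y is None:
            raise ValidationError("H mode requires Y")
        H = np.asarray(H, dtype=float)
        k = H.shape[1]
        if np.linalg.matrix_rank(H) < k:
            raise ValidationError("H is rank-deficient")
        F, *_ = np.linalg.lstsq(H, np.asarray(Y, dtype=float), rcond=None)
        names = [f"feature_{j + 1}" for j in range(k)]
        if unit_norm:
            norms = np.linalg.norm(F, axis=1, keepdims=True)
            H = H * norms.T
            F = F / norms
        resid = np.asarray(Y, dtype=float) - H @ F if not unit_norm else None
        total = float(np.sum(np.asarray(Y, dtype=float) ** 2))
        expl = (
            np.full(k, np.nan) if total == 0 or resid is None
            else np.full(k, 1 - float(np.sum(resid ** 2)) / total)
        )
        fd = FeatureDecomposition(H=H, F=F, k=k, explained_fraction=expl,
                                  feature_names=names)
        fd.validate(unit_norm=bool(unit_norm))
        return fd

    if Z is None or gene_ids is None:
        raise ValidationError("marker mode requires Z and gene_ids")
    Z = np.asarray(Z, dtype=float)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Zz = (Z - Z.mean(axis=1, keepdims=True)) / sd
    index = {g: i for i, g in enumerate(gene_ids)}
    rows, names = [], []
    for name, (up, down) in marker_signatures.items():
        missing = [g for g in list(up) + list(down) if g not in index]
        if missing and not allow_missing:
            raise ValidationError(f"marker genes absent from gene_ids: {missing}")
        up_idx = [index[g] for g in up if g in index]
        down_idx = [index[g] for g in down if g in index]
        if not up_idx and not down_idx:
            raise ValidationError(f"signature {name!r} has no usable markers")
        score = np.zeros(Z.shape[1])
        if up_idx:
            score = score + Zz[up_idx].mean(axis=0)
        if down_idx:
            score = score - Zz[down_idx].mean(axis=0)
        rows.append(score)
        names.append(name)
    F = np.vstack(rows)
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValidationError("a marker score row is identically zero")
    F = F / norms
    k = F.shape[0]
    fd = FeatureDecomposition(H=np.eye(k) * norms.ravel(), F=F, k=k,
                              explained_fraction=np.full(k, np.nan),
                              feature_names=names)
    fd.validate(unit_norm=True)
    return fd


def cox_risk_feature(
    survival: SurvivalTable,
    covariates: pd.DataFrame | np.ndarray | None = None,
    penalizer: float = 1e-4,
) -> np.ndarray:
    """Per-patient log-partial-hazard from a ridge-stabilized Cox fit.

    Covariates default to the extra columns of the survival table; they are
    standardized before fitting (Efron ties).  Returns a unit-normed feature
    row aligned with the table's patient order.
    """
    from lifelines import CoxPHFitter

    survival.validate()
    df = survival.table
    if int(df["event"].sum()) < 2:
        raise ValidationError("need at least 2 events for a Cox fit")
    if covariates is None:
        if not survival.covariate_names:
            raise ValidationError("no covariates in survival table")
        X = df[survival.covariate_names].to_numpy(dtype=float)
        names = survival.covariate_names
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(df):
            X = X.T
        names = [f"x{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValidationError("constant covariate in Cox fit")
    Xs = (X - X.mean(axis=0)) / sd

    fit_df = pd.DataFrame(Xs, columns=names, index=df.index)
    fit_df["time"] = df["time"].to_numpy()
    fit_df["event"] = df["event"].to_numpy()
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(fit_df, duration_col="time", event_col="event")
    except Exception as exc:  # pragma: no cover - lifelines raises many types
        raise ValidationError(
            f"Cox fit failed to converge (ridge penalty {penalizer}): {exc}"
        ) from exc
    lp = cph.predict_log_partial_hazard(fit_df[names]).to_numpy(dtype=float)
    norm = np.linalg.norm(lp)
    if norm == 0:
        raise ValidationError("Cox linear predictor is identically zero")
    return lp / norm


def fit_signatures(Z: np.ndarray, features: FeatureDecomposition | np.ndarray,
                   cohort_id: str = "", gene_ids: list[str] | None = None,
                   feature_names: list[str] | None = None) -> SignatureSet:
    """Least-squares signatures ``B_hat = Z F' (F F')^{-1}``.

    Residual rows are orthogonal to every feature row (normal equations,
    checked to 1e-8 relative scale).
    """
    F = features.F if isinstance(features, FeatureDecomposition) else np.asarray(features)
    if feature_names is None and isinstance(features, FeatureDecomposition):
        feature_names = features.feature_names
    Z = np.asarray(Z, dtype=float)
    gram = F @ F.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            f"F F' is singular (cond={cond:.3g}); lower the rank k"
        )
    B = np.linalg.solve(gram, F @ Z.T).T
    resid = Z - B @ F
    ortho = np.abs(resid @ F.T).max(initial=0.0)
    scale = max(np.abs(Z).max(initial=0.0), 1.0)
    if ortho > 1e-8 * scale * max(F.shape[1], 1):
        raise ValidationError(f"normal equations violated (|resid F'| = {ortho:.3g})")
    k = F.shape[0]
    p = Z.shape[0]
    sig = SignatureSet(
        cohort_id=cohort_id,
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(p)],
        feature_names=list(feature_names) if feature_names
        else [f"feature_{j + 1}" for j in range(k)],
        B=B,
    )
    sig.validate()
    return sig


def signatures_from_cohort(cohort: CohortData, k: int,
                           feature_names: list[str] | None = None
                           ) -> tuple[FeatureDecomposition, SignatureSet]:
    """Convenience: extract features from Y and fit signatures on Z."""
    fd = extract_features(cohort.Y, k, feature_names=feature_names)
    sig = fit_signatures(cohort.Z, fd, cohort_id=cohort.cohort_id,
                         gene_ids=cohort.gene_ids)
    return fd, sig


# ---------------------------------------------------------------------------
# cross-cohort consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Per-feature cross-cohort signature agreement."""

    table: pd.DataFrame  # feature, mean_r, pass, n_pairs
    pairwise: pd.DataFrame  # feature, cohort_a, cohort_b, r
    flips: dict[tuple[str, str], bool]  # (cohort, feature) -> sign flipped
    threshold: float

    def passing_features(self) -> list[str]:
        return self.table.loc[self.table["pass"], "feature"].tolist()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def signature_consistency(sets: list[SignatureSet],
                          threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
                          align_signs: bool = True) -> ConsistencyReport:
    """Screen features by mean pairwise Pearson r across cohorts.

    Each cohort's signature vector is sign-aligned to the first cohort before
    correlating (the flip is recorded); a feature passes when its mean
    pairwise r exceeds ``threshold``.  ``align_signs=False`` skips the
    alignment — appropriate for permutation/shuffle controls, where aligning
    by the observed correlation would select |r| and bias the null upward.
    """
    if len(sets) < 2:
        raise ValidationError("consistency requires at least 2 cohorts")
    ref = sets[0]
    for s in sets[1:]:
        if s.gene_ids != ref.gene_ids:
            raise ValidationError("gene_ids differ across signature sets")
        if s.feature_names != ref.feature_names:
            raise ValidationError("feature_names differ across signature sets")

    flips: dict[tuple[str, str], bool] = {}
    aligned: dict[str, dict[str, np.ndarray]] = {}
    for feat in ref.feature_names:
        vecs = {}
        ref_vec = ref.vector(feat)
        for s in sets:
            v = s.vector(feat)
            flip = align_signs and s is not ref and _pearson(ref_vec, v) < 0
            flips[(s.cohort_id, feat)] = bool(flip)
            vecs[s.cohort_id] = -v if flip else v
        aligned[feat] = vecs

    pair_rows, summary_rows = [], []
    for feat, vecs in aligned.items():
        ids = [s.cohort_id for s in sets]
        rs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = _pearson(vecs[ids[i]], vecs[ids[j]])
                rs.append(r)
                pair_rows.append(
                    {"feature": feat, "cohort_a": ids[i], "cohort_b": ids[j],
                     "r": r}
                )
        mean_r = float(np.mean(rs))
        summary_rows.append(
            {"feature": feat, "mean_r": mean_r, "pass": mean_r > threshold,
             "n_pairs": len(rs)}
        )
    return ConsistencyReport(
        table=pd.DataFrame(summary_rows),
        pairwise=pd.DataFrame(pair_rows),
        flips=flips,
        threshold=threshold,
    )


def project_signatures(sets: list[SignatureSet],
                       features: list[str] | None = None,
                       n_components: int = 2) -> dict[str, pd.DataFrame]:
    """PCA of the stacked signature matrix for a 2-D overview plot.

    Columns of the stacked matrix are (cohort, feature) signature vectors;
    features are rendered at unit length on the leading PCs, genes as points
    (their PC scores).
    """
    if features is None:
        features = sets[0].feature_names
    cols, labels = [], []
    for s in sets:
        for feat in features:
            cols.append(s.vector(feat))
            labels.append(f"{s.cohort_id}:{feat}")
    if len(cols) < 2:
        raise ValidationError("projection requires at least 2 feature vectors")
    M = np.column_stack(cols)
    M = M - M.mean(axis=0, keepdims=True)
    U, s_vals, Vt = np.linalg.svd(M, full_matrices=False)
    n_components = min(n_components, len(s_vals))
    gene_coords = U[:, :n_components] * s_vals[:n_components]
    feat_dirs = Vt[:n_components].T  # one unit row per (cohort, feature)
    norms = np.linalg.norm(feat_dirs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    feat_coords = feat_dirs / norms
    pc_cols = [f"PC{i + 1}" for i in range(n_components)]
    return {
        "genes": pd.DataFrame(gene_coords, index=sets[0].gene_ids,
                              columns=pc_cols),
        "features": pd.DataFrame(feat_coords, index=labels, columns=pc_cols),
        "explained": pd.DataFrame(
            {"PC": pc_cols,
             "fraction": (s_vals[:n_components] ** 2) / (s_vals ** 2).sum()}
        ),
    }
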