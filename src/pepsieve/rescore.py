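"""Target-decoy PSM rescoring with predicted-spectrum and RT features.

The scoring model follows the semi-supervised scheme popularized by
Percolator: PSMs are split spectrum-wise into cross-validation folds; within
each training split, confidently identified targets (q <= q_select on the
current score) are used as positives against all decoys to fit an
L2-regularized linear classifier, iterating positive re-selection to
convergence; each held-out fold is then scored with weights it never
influenced. Before merging, each fold's scores are normalized so the decoy
median maps to 0 and the score at the fold's q_select threshold maps to 1,
anchoring the acceptance boundary across folds.

PSM collections are pandas DataFrames in the TSV dialect documented in
:func:`read_psm_table`.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .spectra import FragmentSet, Peptidoform, Spectrum, fragment_mz, match_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "RescoreConfig",
    "spectral_features",
    "rt_features",
    "tryptic_like",
    "compute_qvalues",
    "pep_estimate",
    "impute_features",
    "semi_supervised_rescore",
    "default_feature_matrix",
    "read_psm_table",
    "write_psm_table",
    "read_predicted_intensities",
]

# Intensity transform constant: spectra are TIC-normalized (sum to 1), so
# intensities live near 1e-2..1e-4; the 1e4 rescale keeps the log2 argument
# well above 1 for real peaks while log2(0*1e4+1)=0 for unmatched ions.
_TRANSFORM_SCALE = 1.0e4


@dataclass(frozen=True)
class RescoreConfig:
    folds: int = 3
    q_select: float = 0.01
    max_iter: int = 10
    seed: int = 0
    plus_one: bool = False


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def transform_intensities(x: np.ndarray) -> np.ndarray:
    """TIC-normalize then log2(x*1e4 + 1); zero-sum vectors stay all-zero."""
    x = np.asarray(x, dtype=float)
    tic = x.sum()
    if tic > 0:
        x = x / tic
    return np.log2(x * _TRANSFORM_SCALE + 1.0)


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention PCC := 0."""
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    cos = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return 1.0 - 2.0 * np.arccos(cos) / np.pi


def spectral_features(
    observed: Spectrum,
    predicted: np.ndarray,
    p: Peptidoform,
    tol: float = 0.02,
) -> dict[str, float]:
    """Predicted-vs-observed fragment intensity agreement features.

    ``predicted`` must align with the charge-1 FragmentSet vector (b series
    then y series). Both vectors are TIC-normalized and log-transformed
    before correlation; a zero-variance vector yields PCC 0 by convention.
    """
    frags = fragment_mz(p, max_frag_charge=1)
    theo = frags.vector_mz(charges=(1,))
    predicted = np.asarray(predicted, dtype=float)
    if len(predicted) != len(theo):
        raise ValueError(
            f"predicted vector length {len(predicted)} != fragment count "
            f"{len(theo)} for {p.sequence!r}"
        )
    obs_raw = match_peaks(observed, theo, tol=tol)
    obs = transform_intensities(obs_raw)
    pred = transform_intensities(predicted)
    n = frags.n_fragments
    n_matched = int(np.count_nonzero(obs_raw))
    return {
        "pcc_all": _pcc(pred, obs),
        "pcc_b": _pcc(pred[:n], obs[:n]),
        "pcc_y": _pcc(pred[n:], obs[n:]),
        "spectral_angle": _spectral_angle(pred, obs),
        "fraction_matched": n_matched / len(theo),
        "n_matched": float(n_matched),
    }


def rt_features(
    observed_rt: float | None, predicted_rt: float, run_rt_span: float
) -> dict[str, float]:
    """Retention-time agreement features; missing RT yields NaNs to impute."""
    if run_rt_span <= 0:
        raise ValueError("run_rt_span must be positive")
    if observed_rt is None or (isinstance(observed_rt, float) and np.isnan(observed_rt)):
        return {"abs_rt_error": np.nan, "signed_rt_error": np.nan,
                "relative_rt_error": np.nan}
    signed = float(observed_rt - predicted_rt)
    return {
        "abs_rt_error": abs(signed),
        "signed_rt_error": signed,
        "relative_rt_error": abs(signed) / run_rt_span,
    }


def tryptic_like(p: Peptidoform | str) -> bool:
    """True iff the peptide ends on a basic K/R residue (tryptic-like)."""
    seq = p.sequence if isinstance(p, Peptidoform) else p
    return seq[-1] in ("K", "R")


# ---------------------------------------------------------------------------
# Target-decoy statistics
# ---------------------------------------------------------------------------

def _td_order(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Descending score order; at score ties decoys rank above targets."""
    # lexsort: last key is primary. Conservative: decoy first within a tie.
    return np.lexsort((~is_decoy, -scores))


def compute_qvalues(
    scores: np.ndarray, is_decoy: np.ndarray, plus_one: bool = False
) -> np.ndarray:
    """Target-decoy q-values, monotone non-increasing in score.

    At every threshold, FDR = (decoys above [+1]) / max(targets above, 1);
    q-values are the running minimum FDR from the permissive end, clipped to
    [0, 1]. Score ties rank decoys above targets (conservative).
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if is_decoy.all():
        raise ValueError("q-value estimation requires at least one target")
    if not is_decoy.any():
        raise ValueError("q-value estimation requires at least one decoy")
    order = _td_order(scores, is_decoy)
    d_sorted = is_decoy[order]
    n_decoy = np.cumsum(d_sorted)
    n_target = np.cumsum(~d_sorted)
    fdr = (n_decoy + (1 if plus_one else 0)) / np.maximum(n_target, 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def pep_estimate(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Posterior error probability via isotonic local decoy-fraction.

    The decoy indicator is regressed on score with a monotone non-increasing
    fit (sklearn isotonic regression), giving a smoothed local estimate of
    the probability that a PSM at that score is incorrect. In the
    uninformative limit (all scores equal) every PSM gets D/(D+T).
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if is_decoy.all() or not is_decoy.any():
        raise ValueError("PEP estimation requires both targets and decoys")
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0,
                             out_of_bounds="clip")
    pep = iso.fit_transform(scores, is_decoy.astype(float))
    return np.asarray(pep, dtype=float)


# ---------------------------------------------------------------------------
# Feature matrix handling
# ---------------------------------------------------------------------------

def impute_features(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute missing values; return (imputed matrix, boolean mask).

    The mask records which entries were imputed so downstream models can use
    missingness itself as a feature.
    """
    if features.columns.duplicated().any():
        raise ValueError("duplicate feature column names")
    mask = features.isna()
    imputed = features.copy()
    for col in imputed.columns:
        med = 0.0 if imputed[col].isna().all() else imputed[col].median()
        imputed[col] = imputed[col].fillna(med)
    if not np.isfinite(imputed.to_numpy(dtype=float)).all():
        raise ValueError("non-finite feature values after imputation")
    return imputed, mask


def _fold_of(spectrum_id: str, seed: int, folds: int) -> int:
    digest = hashlib.sha256(f"{seed}|{spectrum_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % folds


def _targets_at_q(scores, is_decoy, q_thresh, plus_one) -> int:
    q = compute_qvalues(scores, is_decoy, plus_one=plus_one)
    return int(np.sum((q <= q_thresh) & ~is_decoy))


def _fit_fold(
    X_train: np.ndarray,
    y_decoy: np.ndarray,
    base_train: np.ndarray,
    cfg: RescoreConfig,
) -> tuple[StandardScaler, LogisticRegression] | None:
    """Iteratively re-selected positives vs decoys; returns fitted scorer.

    Returns None when the training split is degenerate (no decoys or no
    initial positives), in which case the caller falls back to base score.
    """
    is_decoy = y_decoy.astype(bool)
    if not is_decoy.any() or is_decoy.all():
        return None
    try:
        q_base = compute_qvalues(base_train, is_decoy, plus_one=cfg.plus_one)
    except ValueError:
        return None
    positives = (~is_decoy) & (q_base <= cfg.q_select)
    if not positives.any():
        return None

    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    # inner 2-fold choice of regularization strength
    C = _select_C(Xs, is_decoy, positives, cfg)

    clf = None
    for _ in range(cfg.max_iter):
        rows = positives | is_decoy
        clf = LogisticRegression(C=C, max_iter=1000)
        clf.fit(Xs[rows], is_decoy[rows].astype(int))
        # higher score = more target-like
        s = clf.decision_function(Xs) * -1.0
        q_new = compute_qvalues(s, is_decoy, plus_one=cfg.plus_one)
        new_pos = (~is_decoy) & (q_new <= cfg.q_select)
        if not new_pos.any():
            break
        if np.array_equal(new_pos, positives):
            positives = new_pos
            break
        positives = new_pos
    return scaler, clf


def _select_C(Xs, is_decoy, positives, cfg: RescoreConfig) -> float:
    grid = (0.01, 0.1, 1.0)
    n = len(Xs)
    rng = np.random.default_rng(cfg.seed)
    half = rng.permutation(n) % 2
    best_C, best_score = grid[0], -1
    for C in grid:
        accepted = 0
        ok = True
        for h in (0, 1):
            tr, va = half != h, half == h
            rows = tr & (positives | is_decoy)
            if is_decoy[rows].all() or not is_decoy[rows].any():
                ok = False
                break
            clf = LogisticRegression(C=C, max_iter=1000)
            clf.fit(Xs[rows], is_decoy[rows].astype(int))
            s = -clf.decision_function(Xs[va])
            try:
                accepted += _targets_at_q(
                    s, is_decoy[va], cfg.q_select, cfg.plus_one)
            except ValueError:
                ok = False
                break
        if ok and accepted > best_score:
            best_score, best_C = accepted, C
    return best_C


def semi_supervised_rescore(
    psms: pd.DataFrame,
    feature_matrix: pd.DataFrame,
    config: RescoreConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated semi-supervised rescoring of a PSM table.

    Returns a copy of ``psms`` with new ``score`` and ``q_value`` columns;
    target/decoy labels and the PSM set itself are never altered. Folds are
    assigned by a seeded hash of ``spectrum_id``, so all PSMs of one spectrum
    land in the same fold and results are reproducible.
    """
    cfg = config or RescoreConfig()
    if len(psms) != len(feature_matrix):
        raise ValueError("psms and feature_matrix row counts differ")
    features, mask = impute_features(feature_matrix)
    if mask.to_numpy().any():
        features = pd.concat(
            [features, mask.astype(float).add_suffix("_missing")], axis=1)

    X = features.to_numpy(dtype=float)
    base = psms["base_score"].to_numpy(dtype=float)
    is_decoy = psms["is_decoy"].to_numpy(dtype=bool)
    fold = np.array(
        [_fold_of(sid, cfg.seed, cfg.folds) for sid in psms["spectrum_id"]])

    scores = np.empty(len(psms), dtype=float)
    for f in range(cfg.folds):
        hold = fold == f
        train = ~hold
        if not hold.any():
            continue
        fitted = None
        if train.any():
            fitted = _fit_fold(X[train], is_decoy[train], base[train], cfg)
        if fitted is None:
            warnings.warn(
                f"fold {f}: degenerate training split, falling back to "
                "base score", stacklevel=2)
            s_hold = base[hold].astype(float)
            s_decoy = base[is_decoy].astype(float)
        else:
            scaler, clf = fitted
            s_hold = -clf.decision_function(scaler.transform(X[hold]))
            s_decoy = -clf.decision_function(scaler.transform(X[is_decoy]))
        # z-scale each fold on the *full* decoy set scored by its own model:
        # the shared reference cancels fold-to-fold scale noise, so a
        # monotone model reproduces the base-score ranking exactly
        if len(s_decoy) and np.std(s_decoy) > 0:
            s_hold = (s_hold - s_decoy.mean()) / s_decoy.std()
        scores[hold] = s_hold

    out = psms.copy()
    out["score"] = scores
    out["q_value"] = compute_qvalues(scores, is_decoy, plus_one=cfg.plus_one)
    return out


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------

_PSM_COLUMNS = [
    "psm_id", "spectrum_id", "sample_id", "replicate_id", "sequence", "mods",
    "charge", "is_decoy", "protein_ids", "base_score", "observed_rt",
    "predicted_rt",
]


def read_psm_table(path: str) -> pd.DataFrame:
    """Read the tab-separated PSM dialect.

    Fixed columns: psm_id, spectrum_id, sample_id, replicate_id, sequence,
    mods (semicolon 'pos:name'), charge, is_decoy (0/1), protein_ids (comma
    list), base_score, observed_rt, predicted_rt; any further columns
    prefixed ``feat_`` are PSM features.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mods": str, "protein_ids": str})
    missing = [c for c in _PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing PSM columns {missing}")
    df["mods"] = df["mods"].fillna("")
    df["protein_ids"] = df["protein_ids"].fillna("")
    df["is_decoy"] = df["is_decoy"].astype(int).astype(bool)
    return df


def write_psm_table(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["is_decoy"] = out["is_decoy"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("feat_")]


def default_feature_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """All ``feat_`` columns plus the base search-engine score."""
    feats = df[feature_columns(df)].copy()
    feats["feat_base_score"] = df["base_score"]
    return feats


def read_predicted_intensities(path: str) -> dict[str, np.ndarray]:
    """Read a predicted-intensity TSV keyed by spectrum_id.

    The vector columns follow the charge-1 FragmentSet order (b then y) and
    are named ``i0..i{k-1}``; trailing NaNs (shorter peptides) are trimmed.
    """
    df = pd.read_csv(path, sep="\t")
    vec_cols = [c for c in df.columns if c.startswith("i")]
    out: dict[str, np.ndarray] = {}
    for row in df.itertuples(index=False):
        vec = np.array([getattr(row, c) for c in vec_cols], dtype=float)
        vec = vec[~np.isnan(vec)]
        out[str(row.spectrum_id)] = vec
    return out
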