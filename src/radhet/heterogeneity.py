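"""Per-patient heterogeneity quantification.

Two complementary views of intra-patient inter-tumor heterogeneity:

* the *absolute coefficient of variation* (CV, in %) of each feature across
  a patient's lesions, pooled into a per-patient mean CV;
* two pairwise-dissimilarity summaries of the patient's lesion feature
  vectors under the cosine distance — the **maximal tumoral divergence**
  (MTD, the maximum pairwise dissimilarity) and the **average tumoral
  heterogeneity** (ATH, the mean pairwise dissimilarity).

Features are min-max normalized cohort-wide before the cosine step, which
makes every vector nonnegative and bounds both indexes by 1.0 exactly (the
bound is attained by two lesions with orthogonal normalized vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

META_COLUMNS = ["patient_id", "lesion_id", "site_label"]

__all__ = [
    "META_COLUMNS",
    "feature_columns",
    "absolute_cv",
    "CVProfile",
    "cv_profile",
    "normalize_features",
    "dissimilarity_matrix",
    "HeterogeneityIndexes",
    "indexes",
    "patient_indexes",
    "cohort_indexes",
    "aggregate_patient_values",
]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a feature table that hold feature values."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Coefficient of variation
# ---------------------------------------------------------------------------

def absolute_cv(values) -> float:
    """Absolute coefficient of variation in percent: ``100 * |s / mean|``
    with the sample (n-1) standard deviation.

    Returns NaN (flagged undefined) when the mean is numerically zero
    relative to the data scale, to avoid reporting infinities for features
    that straddle zero.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 values")
    mu = x.mean()
    scale = np.abs(x).max()
    if scale == 0:
        return 0.0
    if abs(mu) < 1e-12 * scale:
        return float("nan")
    return float(100.0 * abs(x.std(ddof=1) / mu))


@dataclass
class CVProfile:
    """Per-group, per-feature absolute CVs (%).

    ``per_feature`` is indexed by group with one column per feature;
    ``pooled`` is the arithmetic mean over each group's defined (non-NaN)
    feature CVs; ``skipped_groups`` lists groups with fewer than 2 lesions.
    """

    per_feature: pd.DataFrame
    pooled: pd.Series
    skipped_groups: list = field(default_factory=list)


def cv_profile(table: pd.DataFrame, group_by="patient") -> CVProfile:
    """CV profile grouped by patient or by (patient, organ site).

    Groups with fewer than 2 lesions cannot yield a CV and are skipped
    (recorded in ``skipped_groups``), mirroring the impossibility of
    estimating spread from a single lesion.
    """
    if group_by == "patient":
        keys = ["patient_id"]
    elif group_by in ("patient_organ", ("patient", "organ"), "patient,organ"):
        keys = ["patient_id", "site_label"]
    else:
        raise ValueError(f"unknown grouping {group_by!r}")
    feats = feature_columns(table)
    rows, skipped = {}, []
    for name, grp in table.groupby(keys, sort=True):
        key = name if len(keys) > 1 else name[0] if isinstance(name, tuple) else name
        if len(grp) < 2:
            skipped.append(key)
            continue
        rows[key] = {f: absolute_cv(grp[f].to_numpy()) for f in feats}
    if not rows:
        raise InsufficientDataError("no group with >= 2 lesions")
    per_feature = pd.DataFrame.from_dict(rows, orient="index")[feats]
    pooled = per_feature.mean(axis=1, skipna=True)
    return CVProfile(per_feature=per_feature, pooled=pooled, skipped_groups=skipped)


# ---------------------------------------------------------------------------
# Normalization and cosine dissimilarity
# ---------------------------------------------------------------------------

def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale every feature column over all lesions of the cohort.

    Constant features map to 0 everywhere.  Scaling is cohort-wide so the
    cosine dissimilarity of any two lesions is bounded by 1 and invariant
    to the raw feature scales.
    """
    out = table.copy()
    for f in feature_columns(table):
        col = out[f].to_numpy(dtype=np.float64)
        lo, hi = col.min(), col.max()
        out[f] = (col - lo) / (hi - lo) if hi > lo else 0.0
    return out


def dissimilarity_matrix(vectors) -> np.ndarray:
    """Pairwise cosine dissimilarity ``1 - a.b/(|a||b|)`` between lesion
    feature vectors (rows).

    Entries are clipped to [0, 1]; vectors are expected nonnegative (use
    :func:`normalize_features` first).  An all-zero vector — a lesion at
    the cohort minimum on every feature — is maximally dissimilar (1) to
    any nonzero vector and identical (0) to another all-zero vector.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("need >= 2 lesion vectors")
    norms = np.linalg.norm(X, axis=1)
    n = X.shape[0]
    D = np.zeros((n, n))
    nz = norms > 0
    if nz.any():
        Xn = np.zeros_like(X)
        Xn[nz] = X[nz] / norms[nz, None]
        D = 1.0 - Xn @ Xn.T
    zero = ~nz
    if zero.any():
        D[zero, :] = 1.0
        D[:, zero] = 1.0
        D[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.clip(0.5 * (D + D.T), 0.0, 1.0)


@dataclass
class HeterogeneityIndexes:
    """Maximal tumoral divergence and average tumoral heterogeneity.

    Both are undefined (``defined = False``, values NaN) for patients with
    fewer than two lesions: no pairwise dissimilarity exists.
    """

    mtd: float
    ath: float
    n_lesions: int
    defined: bool = True

    @classmethod
    def undefined(cls, n_lesions: int) -> "HeterogeneityIndexes":
        return cls(float("nan"), float("nan"), n_lesions, defined=False)


def indexes(matrix: np.ndarray) -> HeterogeneityIndexes:
    """MTD = max off-diagonal entry; ATH = mean over the n(n-1)/2 pairs."""
    D = np.asarray(matrix, dtype=np.float64)
    n = D.shape[0]
    if n < 2:
        return HeterogeneityIndexes.undefined(n)
    iu = np.triu_indices(n, k=1)
    pairs = D[iu]
    return HeterogeneityIndexes(
        mtd=float(pairs.max()), ath=float(pairs.mean()), n_lesions=n
    )


def patient_indexes(table: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Per-patient heterogeneity indexes for every patient in the table.

    Returns a DataFrame indexed by patient with columns ``n_lesions``,
    ``mtd``, ``ath``, ``defined``.  Patients with one lesion are flagged
    undefined rather than dropped.
    """
    work = normalize_features(table) if normalize else table
    feats = feature_columns(work)
    rows = {}
    for pid, grp in work.groupby("patient_id", sort=True):
        X = grp[feats].to_numpy(dtype=np.float64)
        if len(grp) < 2:
            idx = HeterogeneityIndexes.undefined(len(grp))
        else:
            idx = indexes(dissimilarity_matrix(X))
        rows[pid] = {
            "n_lesions": idx.n_lesions, "mtd": idx.mtd,
            "ath": idx.ath, "defined": idx.defined,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_patient_values(values) -> float:
    """Cohort-level index: unweighted mean over patients with a defined value."""
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise InsufficientDataError("no patient with a defined index")
    return float(x.mean())


def cohort_indexes(table: pd.DataFrame, normalize: bool = True):
    """Cohort-level MTD/ATH (unweighted patient mean) + the per-patient table.

    Returns ``(HeterogeneityIndexes, per_patient_dataframe)``.
    """
    per_patient = patient_indexes(table, normalize=normalize)
    defined = per_patient[per_patient["defined"]]
    if defined.empty:
        raise InsufficientDataError("no patient with >= 2 lesions")
    cohort = HeterogeneityIndexes(
        mtd=aggregate_patient_values(defined["mtd"]),
        ath=aggregate_patient_values(defined["ath"]),
        n_lesions=int(per_patient["n_lesions"].sum()),
    )
    return cohort, per_patient
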