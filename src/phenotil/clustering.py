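"""Gaussian-mixture phenotyping of TILs and patient niche-count vectors.

TIL contextual feature vectors are z-scored (statistics learned on the
training TILs and reused at assignment time) and clustered with a
K-component Gaussian mixture (K = 8 in the published configuration,
diagonal covariances with a variance floor).  Hard cluster assignments
are pooled per patient into the niche-count vector N_i, the input of
the survival risk model.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

PAPER_K = 8


class InsufficientDataError(ValueError):
    """Too few TILs to fit the requested mixture."""


@dataclasses.dataclass
class PhenotypeModel:
    """Standardization statistics plus a fitted Gaussian mixture."""

    K: int
    feature_names: list[str]
    mean_: np.ndarray        # per-feature standardization mean
    sd_: np.ndarray          # per-feature standardization sd (zero-variance -> 1)
    zero_variance: np.ndarray  # bool mask of features with sd 0 in training
    weights_: np.ndarray     # (K,)
    means_: np.ndarray       # (K, D) in standardized space
    variances_: np.ndarray   # (K, D) diagonal covariances
    converged: bool
    seed: int
    n_tils: int

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(float)
        return (X - self.mean_) / self.sd_

    def _gm(self) -> GaussianMixture:
        gm = GaussianMixture(n_components=self.K, covariance_type="diag")
        gm.weights_ = self.weights_
        gm.means_ = self.means_
        gm.covariances_ = self.variances_
        gm.precisions_cholesky_ = 1.0 / np.sqrt(self.variances_)
        return gm

    def responsibilities(self, features: pd.DataFrame) -> np.ndarray:
        """Posterior component probabilities, rows summing to 1."""
        if len(features) == 0:
            return np.zeros((0, self.K))
        return self._gm().predict_proba(self.standardize(features))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": self.K,
            "feature_names": self.feature_names,
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "zero_variance": self.zero_variance.astype(int).tolist(),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "variances": self.variances_.tolist(),
            "converged": self.converged,
            "seed": self.seed,
            "n_tils": self.n_tils,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            K=d["K"], feature_names=d["feature_names"],
            mean_=np.asarray(d["mean"]), sd_=np.asarray(d["sd"]),
            zero_variance=np.asarray(d["zero_variance"], bool),
            weights_=np.asarray(d["weights"]), means_=np.asarray(d["means"]),
            variances_=np.asarray(d["variances"]), converged=d["converged"],
            seed=d["seed"], n_tils=d["n_tils"],
        )


def fit_phenotype_model(
    features: pd.DataFrame,
    K: int = PAPER_K,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 200,
    variance_floor: float = 1e-6,
) -> PhenotypeModel:
    """Fit the K-component diagonal Gaussian mixture over TIL features.

    Features are z-scored on the input (zero-variance features are kept
    but recorded and given unit scale so they stay inert).  EM uses
    k-means++ initialization with ``n_init`` seeded restarts, keeping
    the best log-likelihood; non-convergence is flagged, not fatal.

    Raises
    ------
    InsufficientDataError
        If fewer than ``10 * K`` TILs are provided.
    """
    X = features.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    n, _ = X.shape
    if n < 10 * K:
        raise InsufficientDataError(f"need >= {10 * K} TILs to fit K={K}; got {n}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero_var = sd == 0
    sd_safe = np.where(zero_var, 1.0, sd)
    Z = (X - mean) / sd_safe
    gm = GaussianMixture(
        n_components=K, covariance_type="diag", n_init=n_init,
        init_params="k-means++", max_iter=max_iter, reg_covar=variance_floor,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(Z)
    if not gm.converged_:
        warnings.warn("EM did not converge; returning best-so-far parameters")
    return PhenotypeModel(
        K=K, feature_names=list(features.columns), mean_=mean, sd_=sd_safe,
        zero_variance=zero_var, weights_=gm.weights_, means_=gm.means_,
        variances_=np.maximum(gm.covariances_, variance_floor),
        converged=bool(gm.converged_), seed=seed, n_tils=n,
    )


def assign_clusters(model: PhenotypeModel, features: pd.DataFrame) -> np.ndarray:
    """Hard cluster labels in 1..K (argmax posterior, ties -> lowest index)."""
    if len(features) == 0:
        return np.zeros(0, int)
    resp = model.responsibilities(features)
    return resp.argmax(axis=1) + 1


def patient_cluster_matrix(
    labels: np.ndarray,
    patient_ids: np.ndarray,
    K: int = PAPER_K,
    all_patients: list | None = None,
) -> pd.DataFrame:
    """Per-patient niche-count matrix (patients x K).

    ``labels[i]`` in 1..K is the cluster of the TIL belonging to
    ``patient_ids[i]``; counts are pooled over all of a patient's
    tiles.  Patients listed in ``all_patients`` but owning no TILs get
    zero rows (with a warning).
    """
    labels = np.asarray(labels, int)
    patient_ids = np.asarray(patient_ids)
    if len(labels) != len(patient_ids):
        raise ValueError("labels and patient_ids must align")
    if len(labels) and (labels.min() < 1 or labels.max() > K):
        raise ValueError(f"labels must lie in 1..{K}")
    index = pd.Index(
        all_patients if all_patients is not None else pd.unique(patient_ids),
        name="patient_id",
    )
    mat = pd.DataFrame(0, index=index, columns=[f"C{j}" for j in range(1, K + 1)])
    for pid, lab in zip(patient_ids, labels):
        mat.loc[pid, f"C{lab}"] += 1
    empty = mat.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} patient(s) have zero assigned TILs")
    return mat


def bic_sweep(features: pd.DataFrame, k_range=range(2, 13), seed: int = 0,
              n_init: int = 2) -> pd.DataFrame:
    """Non-normative model-selection helper: BIC across candidate K."""
    X = features.to_numpy(float)
    Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1.0, X.std(0))
    rows = []
    for k in k_range:
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             n_init=n_init, init_params="k-means++",
                             random_state=seed, reg_covar=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(Z)
        rows.append({"K": k, "bic": gm.bic(Z), "loglik": gm.score(Z) * len(Z)})
    return pd.DataFrame(rows)
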