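"""Population-structure and relatedness inference.

* :class:`GenotypePCA` — principal components of MAF-filtered,
  mean-imputed dosages with Patterson normalisation (centre by 2p, scale
  by sqrt(2p(1-p))).
* :func:`kinship` — VanRaden method-1 genomic relationship matrix G and
  identity-by-state similarity/distance matrices.
* :func:`nj_tree` — Saitou–Nei neighbour joining on a genetic distance
  matrix (delegates to scikit-bio; negative branch lengths are clamped to
  zero with the deficit shifted to the adjacent edge).
* :class:`AdmixtureEM` — binomial admixture model with ancestry fractions
  Q and component frequencies F fitted by EM (FRAPPE-style multiplicative
  updates, monotone in log-likelihood), plus entry-masking cross-validation
  over K in :func:`admixture_cv`.

Missing-data policy: PCA mean-imputes to the locus mean dosage, the EM
marginalises by dropping missing terms from the likelihood, kinship
mean-imputes for G and uses pairwise-complete loci for IBS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from popfinger.io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _as_dosage(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.dosages.astype(float)
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    samples: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


class GenotypePCA(BaseEstimator):
    """PCA of genotype dosages with Patterson normalisation.

    Sites with minor allele frequency below ``maf_min`` are removed,
    missing dosages are filled with the locus mean, and each locus is
    centred by its mean dosage 2p and scaled by sqrt(2p(1-p)).  Component
    signs follow a deterministic convention: the largest-|score| entry of
    each component is positive.

    Attributes (after fit): ``scores_``, ``eigenvalues_``,
    ``explained_variance_ratio_``, ``components_``, ``kept_sites_``.
    """

    def __init__(self, n_components: int = 10, maf_min: float = 0.05):
        self.n_components = n_components
        self.maf_min = maf_min

    def fit(self, X, y=None) -> "GenotypePCA":
        D = _as_dosage(X)
        if D.shape[0] < 2:
            raise ValueError("PCA needs at least 2 samples")
        called = D != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, D, 0.0).sum(axis=0) / (2.0 * n_called)
        maf = np.minimum(p, 1.0 - p)
        keep = (n_called > 0) & (maf >= self.maf_min)
        if not keep.any():
            raise ValueError("no sites pass the MAF filter")
        self.kept_sites_ = np.flatnonzero(keep)
        p = p[keep]
        Dk = D[:, keep]
        mean = 2.0 * p
        scale = np.sqrt(2.0 * p * (1.0 - p))
        Z = np.where(Dk == MISSING, 0.0, Dk - mean) / scale
        self.mean_ = mean
        self.scale_ = scale

        n = Z.shape[0]
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        ncomp = min(self.n_components, S.size)
        scores = U[:, :ncomp] * S[:ncomp]
        # deterministic sign: largest-|score| entry positive per component
        flips = np.ones(ncomp)
        for k in range(ncomp):
            i = int(np.argmax(np.abs(scores[:, k])))
            if scores[i, k] < 0:
                flips[k] = -1.0
        scores = scores * flips
        self.components_ = Vt[:ncomp] * flips[:, None]
        self.scores_ = scores
        self.eigenvalues_ = S[:ncomp] ** 2 / (n - 1)
        total = float(np.sum(S**2))
        self.explained_variance_ratio_ = (S[:ncomp] ** 2) / total if total > 0 else np.zeros(ncomp)
        return self

    def transform(self, X) -> np.ndarray:
        D = _as_dosage(X)[:, self.kept_sites_]
        Z = np.where(D == MISSING, 0.0, D - self.mean_) / self.scale_
        return Z @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_


def pca(matrix: GenotypeMatrix, maf_min: float = 0.05, n_components: int = 10) -> PCAResult:
    """Thin functional wrapper over :class:`GenotypePCA`."""
    est = GenotypePCA(n_components=n_components, maf_min=maf_min).fit(matrix)
    return PCAResult(
        scores=est.scores_,
        eigenvalues=est.eigenvalues_,
        explained_variance_ratio=est.explained_variance_ratio_,
        samples=list(matrix.samples),
    )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrices:
    """VanRaden G plus IBS similarity/distance, all samples x samples."""

    G: np.ndarray
    ibs_similarity: np.ndarray
    ibs_distance: np.ndarray
    samples: list[str]

    def frame(self, which: str = "G") -> pd.DataFrame:
        arr = getattr(self, {"G": "G", "ibs": "ibs_similarity", "ibs_distance": "ibs_distance"}[which])
        return pd.DataFrame(arr, index=self.samples, columns=self.samples)


def kinship(matrix: GenotypeMatrix) -> KinshipMatrices:
    """Genomic relationship matrix (VanRaden method 1) and IBS matrices.

    G = Z Z' / (2 * sum p(1-p)) with Z the 2p-centred dosage matrix
    (missing entries contribute 0 after centring).  IBS similarity of a
    sample pair is the mean over co-called loci of (2 - |g_i - g_j|)/2;
    distance is its complement.  A pair with no co-called loci is an error.
    """
    if matrix.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    D = matrix.dosages.astype(float)
    called = D != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, D, 0.0).sum(axis=0) / (2.0 * n_called)
    C = called.astype(float)
    co_called = C @ C.T
    if np.any(co_called == 0):
        raise ValueError("sample pair with no co-called loci")

    informative = (n_called > 0) & (p > 0) & (p < 1)
    pk = p[informative]
    Z = np.where(called[:, informative], D[:, informative] - 2.0 * pk, 0.0)
    denom = 2.0 * float(np.sum(pk * (1.0 - pk)))
    if denom == 0.0:
        raise ValueError("no polymorphic loci for G matrix")
    G = Z @ Z.T / denom
    # sum over co-called loci of |g_i - g_j| via masked differences
    n = matrix.n_samples
    Dm = np.where(called, D, 0.0)
    abs_sum = np.empty((n, n))
    for i in range(n):
        diff = np.abs(Dm[i] - Dm)  # rows j
        diff[~(called[i] & called)] = 0.0
        abs_sum[i] = diff.sum(axis=1)
    sim = 1.0 - abs_sum / (2.0 * co_called)
    sim = (sim + sim.T) / 2.0
    return KinshipMatrices(G=G, ibs_similarity=sim, ibs_distance=1.0 - sim,
                           samples=list(matrix.samples))


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(distance: np.ndarray | pd.DataFrame, labels: list[str] | None = None) -> str:
    """Neighbour-joining tree (newick string) from a distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
        distance = distance.to_numpy()
    distance = np.asarray(distance, dtype=float)
    if labels is None:
        labels = [f"t{i}" for i in range(distance.shape[0])]
    if distance.shape[0] != distance.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distance, distance.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distance), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    tree = nj(DistanceMatrix(distance, ids=labels))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

class AdmixtureEM(BaseEstimator):
    """Binomial admixture model fitted by EM.

    Each individual i carries ancestry fractions q_i over K components
    with component allele frequencies f_k; the alternate-dosage likelihood
    at locus l is Binomial(2, x_il) with x_il = sum_k q_ik f_kl.  The EM
    updates (FRAPPE-style) are monotone in log-likelihood; missing
    genotypes are dropped from the likelihood.  Parameters are floored
    away from {0, 1} at ``param_floor``.

    Attributes (after fit): ``Q_`` (samples x K, rows sum to 1), ``F_``
    (K x sites), ``loglik_trace_``, ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 500,
        param_floor: float = 1e-6,
    ):
        self.n_components = n_components
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.param_floor = param_floor

    def fit(self, X, y=None) -> "AdmixtureEM":
        G = _as_dosage(X)
        n, L = G.shape
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if K > n:
            raise ValueError(f"n_components={K} exceeds sample count {n}")
        W = (G != MISSING).astype(float)
        Gw = np.where(W > 0, G, 0.0)
        floor = self.param_floor
        rng = np.random.default_rng(self.seed)

        if K == 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                f = Gw.sum(axis=0) / np.maximum(2.0 * W.sum(axis=0), 1e-300)
            F = np.clip(f, floor, 1.0 - floor)[None, :]
            Q = np.ones((n, 1))
            self.Q_, self.F_ = Q, F
            self.loglik_trace_ = [self._loglik(Gw, W, Q, F)]
            self.n_iter_, self.converged_ = 0, True
            return self

        Q = rng.dirichlet(np.ones(K), size=n)
        F = rng.uniform(0.2, 0.8, size=(K, L))
        Q = np.clip(Q, floor, None)
        Q /= Q.sum(axis=1, keepdims=True)

        denom_q = 2.0 * W.sum(axis=1)  # called loci per sample
        if np.any(denom_q == 0):
            raise ValueError("sample with no called genotypes")
        trace = [self._loglik(Gw, W, Q, F)]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            Xhat = Q @ F
            np.clip(Xhat, floor, 1.0 - floor, out=Xhat)
            ra = W * Gw / Xhat          # g / x
            rb = W * (2.0 - Gw) / (1.0 - Xhat)
            F_new = np.empty_like(F)
            Q_new = np.empty_like(Q)
            for k in range(K):
                qf = Q[:, k : k + 1] * F[k]          # n x L
                q1f = Q[:, k : k + 1] * (1.0 - F[k])
                A = ra * qf                           # expected alt-allele counts
                B = rb * q1f
                sa, sb = A.sum(axis=0), B.sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    F_new[k] = np.where(sa + sb > 0, sa / (sa + sb), F[k])
                Q_new[:, k] = (A + B).sum(axis=1) / denom_q
            F = np.clip(F_new, floor, 1.0 - floor)
            Q = np.clip(Q_new, floor, None)
            Q /= Q.sum(axis=1, keepdims=True)
            trace.append(self._loglik(Gw, W, Q, F))
            if abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break
        self.Q_, self.F_ = Q, F
        self.loglik_trace_ = trace
        self.n_iter_ = it
        self.converged_ = converged
        return self

    @staticmethod
    def _loglik(Gw: np.ndarray, W: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
        X = np.clip(Q @ F, 1e-12, 1.0 - 1e-12)
        return float(np.sum(W * (Gw * np.log(X) + (2.0 - Gw) * np.log1p(-X))))

    def expected_dosage(self) -> np.ndarray:
        return 2.0 * (self.Q_ @ self.F_)


@dataclass
class CVResult:
    errors: pd.DataFrame  # columns: K, cv_error
    selected_k: int


def admixture_cv(
    X,
    k_range=range(1, 6),
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 300,
    error: str = "mse",
) -> CVResult:
    """Entry-masking cross-validation error over K.

    Called genotype entries are partitioned into ``folds`` random folds;
    each fold is masked in turn, the model refitted, and the error over
    masked entries measured as (g - 2*x_hat)^2 / 2 (``error='mse'``) or as
    binomial deviance (``error='deviance'``).  The selected K minimises the
    mean error.  If a fold would leave a sample or site with no data the
    fold assignment is re-randomised once, then raises.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2 (masking fraction would be 0)")
    if error not in ("mse", "deviance"):
        raise ValueError("error must be 'mse' or 'deviance'")
    G = _as_dosage(X)
    W = G != MISSING
    rng = np.random.default_rng(seed)

    def make_folds(r: np.random.Generator) -> np.ndarray:
        f = np.full(G.shape, -1, dtype=int)
        f[W] = r.integers(0, folds, size=int(W.sum()))
        return f

    fold_of = make_folds(rng)
    for _attempt in range(2):
        ok = True
        for f in range(folds):
            kept = W & (fold_of != f)
            if np.any(kept.sum(axis=1) == 0) or np.any(kept.sum(axis=0) == 0):
                ok = False
                break
        if ok:
            break
        fold_of = make_folds(rng)
    else:
        raise ValueError("a fold leaves a sample or site with no data")

    records = []
    for K in k_range:
        errs = []
        for f in range(folds):
            masked = W & (fold_of == f)
            Gm = G.copy()
            Gm[masked] = MISSING
            est = AdmixtureEM(
                n_components=K, seed=int(rng.integers(0, 2**31 - 1)),
                tol=tol, max_iter=max_iter,
            ).fit(Gm)
            xhat = np.clip(est.Q_ @ est.F_, 1e-9, 1 - 1e-9)
            g = G[masked]
            x = xhat[masked]
            if error == "mse":
                errs.append(float(np.mean((g - 2.0 * x) ** 2 / 2.0)))
            else:
                dev = -2.0 * (g * np.log(x) + (2.0 - g) * np.log1p(-x))
                errs.append(float(np.mean(dev)))
        records.append({"K": int(K), "cv_error": float(np.mean(errs))})
    errors = pd.DataFrame.from_records(records)
    selected = int(errors.loc[errors["cv_error"].idxmin(), "K"])
    return CVResult(errors=errors, selected_k=selected)
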