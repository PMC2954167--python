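"""Admixture-model inference: likelihood, supervised and unsupervised EM,
cross-run label alignment, and Evanno delta-K model selection.

The model is the classic admixture likelihood: individual i carries ancestry
proportions Q_i on the K-simplex, population k carries allele frequencies
P_k, and each genotype is Binomial(2, q_il) with q_il = sum_k Q_ik P_kl.
Estimation is by EM (expectation over the latent ancestry of each allele
copy) with multiple random restarts; the per-run maximized log-likelihood
plays the role of the model score L(K) consumed by the delta-K criterion.

Estimators follow the scikit-learn protocol: ``fit`` on an (n_samples,
n_snps) call matrix with values {0, 1, 2} and missing encoded as -1 or NaN,
fitted attributes with trailing underscores, ``get_params``/``set_params``
inherited from ``BaseEstimator``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .genotype_io import GenotypeMatrix

_LOG2 = float(np.log(2.0))
FREQ_CLIP = 1e-6


def _as_calls(X) -> tuple[np.ndarray, np.ndarray]:
    """Return (float calls with missing as 0, observation mask)."""
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X) & (X >= 0)
    G = np.where(mask, X, 0.0)
    return G, mask


def admixture_loglik(X, Q, P) -> float:
    """Log-likelihood of genotypes under the admixture model.

    ``X`` is (n, L) calls counting copies of allele A (missing -1/NaN),
    ``Q`` (n, K) ancestry proportions, ``P`` (K, L) allele-A frequencies.
    Includes the binomial coefficient (log 2 per heterozygote); missing
    calls contribute zero. Frequencies are clipped away from {0, 1}.
    """
    G, mask = _as_calls(X)
    Q = np.asarray(Q, dtype=float)
    P = np.clip(np.asarray(P, dtype=float), FREQ_CLIP, 1 - FREQ_CLIP)
    q = np.clip(Q @ P, FREQ_CLIP, 1 - FREQ_CLIP)
    ll = G * np.log(q) + (2 - G) * np.log1p(-q) + (G == 1) * _LOG2
    return float(np.sum(ll * mask))


def _em_q_update(G, mask, Q, P, Pt=None):
    """One EM step for Q with P fixed.

    Uses the identity A@P' + B@(1-P)' = (A-B)@P' + rowsum(B) to touch the
    big (n, L) arrays as few times as possible.
    """
    if Pt is None:
        Pt = np.ascontiguousarray(P.T)
    q = np.clip(Q @ P, FREQ_CLIP, 1 - FREQ_CLIP)
    B = (2 - G) / (1 - q)
    B *= mask
    U = (G - 2 * q) / (q * (1 - q))
    U *= mask                                  # U = A - B
    copies = 2 * mask.sum(axis=1, keepdims=True).astype(float)
    Qn = Q * (U @ Pt + B.sum(axis=1, keepdims=True)) / np.maximum(copies, 1.0)
    Qn /= Qn.sum(axis=1, keepdims=True)
    return Qn


def _em_p_update(G, mask, Q, P):
    q = np.clip(Q @ P, FREQ_CLIP, 1 - FREQ_CLIP)
    A = np.where(mask, G / q, 0.0)
    B = np.where(mask, (2 - G) / (1 - q), 0.0)
    num = (Q.T @ A) * P                     # expected allele-A copies per (k, l)
    den = num + (Q.T @ B) * (1 - P)
    with np.errstate(invalid="ignore", divide="ignore"):
        Pn = np.where(den > 0, num / den, P)
    return np.clip(Pn, FREQ_CLIP, 1 - FREQ_CLIP)


@dataclass
class AdmixtureResult:
    """Fitted admixture parameters and convergence record."""

    Q: np.ndarray
    P_hat: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    seed: int | None = None
    flags: list = field(default_factory=list)


class SupervisedAdmixture(BaseEstimator):
    """Per-individual ancestry estimation with fixed reference frequencies.

    Maximizes the admixture likelihood over Q only, holding the ancestral
    allele frequencies at ``P_ref`` (rows = reference populations). The EM
    iteration is monotone in the log-likelihood and stops when the largest
    elementwise change in Q falls below ``tol``.

    Attributes (after ``fit``): ``Q_``, ``loglik_``, ``n_iter_``,
    ``converged_``, ``flags_``.
    """

    def __init__(self, P_ref=None, tol: float = 1e-6, max_iter: int = 2000,
                 accelerate: bool = True):
        self.P_ref = P_ref
        self.tol = tol
        self.max_iter = max_iter
        self.accelerate = accelerate

    def fit(self, X, y=None):
        if self.P_ref is None:
            raise ValueError("P_ref must be provided")
        P = np.clip(np.asarray(self.P_ref, dtype=float), FREQ_CLIP, 1 - FREQ_CLIP)
        G, mask = _as_calls(X)
        n, L = G.shape
        K = P.shape[0]
        if P.shape[1] != L:
            raise ValueError(f"P_ref covers {P.shape[1]} SNPs, data has {L}")
        self.flags_ = []
        if K > 1 and np.allclose(P, P[0], atol=1e-12):
            # identical rows: Q unidentifiable by convention -> uniform
            self.Q_ = np.full((n, K), 1.0 / K)
            self.loglik_ = admixture_loglik(X, self.Q_, P)
            self.n_iter_ = 0
            self.converged_ = True
            self.flags_.append("unidentifiable: identical reference rows")
            return self
        # warm start: least-squares ancestry projection of mean dosage,
        # clipped onto the simplex; EM stays monotone from any start but
        # needs far fewer iterations from a near-solution
        obs = mask.sum(axis=0)
        fill = np.where(obs > 0, (G * mask).sum(axis=0) / np.maximum(obs, 1), 1.0)
        D = np.where(mask, G, fill[None, :]) / 2.0
        gram = P @ P.T + 1e-8 * np.eye(K)
        Q = np.clip(np.linalg.solve(gram, P @ D.T).T, 1e-3, None)
        Q /= Q.sum(axis=1, keepdims=True)
        Pt = np.ascontiguousarray(P.T)
        converged = False
        it = 0
        if not self.accelerate:
            for it in range(1, self.max_iter + 1):
                Qn = _em_q_update(G, mask, Q, P, Pt)
                delta = np.abs(Qn - Q).max()
                Q = Qn
                if delta < self.tol:
                    converged = True
                    break
        else:
            # SQUAREM-style acceleration with a monotonicity safeguard:
            # the extrapolated step is kept only if the log-likelihood does
            # not decrease, so the monotone-EM guarantee is preserved
            ll = admixture_loglik(X, Q, P)
            while it < self.max_iter:
                Q1 = _em_q_update(G, mask, Q, P, Pt)
                Q2 = _em_q_update(G, mask, Q1, P, Pt)
                it += 2
                if np.abs(Q2 - Q1).max() < self.tol:
                    Q = Q2
                    ll = admixture_loglik(X, Q, P)
                    converged = True
                    break
                R = Q1 - Q
                V = Q2 - Q1 - R
                vnorm = np.sqrt((V * V).sum())
                alpha = -1.0 if vnorm < 1e-30 else min(
                    -1.0, -np.sqrt((R * R).sum()) / vnorm)
                Qa = Q - 2 * alpha * R + alpha ** 2 * V
                Qa = np.clip(Qa, 1e-9, None)
                Qa /= Qa.sum(axis=1, keepdims=True)
                Qn = _em_q_update(G, mask, Qa, P, Pt)
                it += 1
                ll_n = admixture_loglik(X, Qn, P)
                ll_2 = admixture_loglik(X, Q2, P)
                if ll_n >= ll_2:
                    Q, ll = Qn, ll_n
                else:
                    Q, ll = Q2, ll_2
        self.Q_ = Q
        self.loglik_ = admixture_loglik(X, Q, P)
        self.n_iter_ = it
        self.converged_ = converged
        if not converged:
            self.flags_.append("not converged")
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).Q_


class UnsupervisedAdmixture(BaseEstimator):
    """Joint EM estimation of ancestry proportions Q and frequencies P.

    ``n_init`` random restarts are run (Dirichlet-random Q, observed
    frequencies perturbed for P); the restart with the highest final
    log-likelihood is kept. Deterministic given ``random_state``.

    Attributes: ``Q_``, ``P_``, ``loglik_``, ``n_iter_``, ``converged_``,
    ``loglik_path_``, ``flags_``.
    """

    def __init__(self, n_components: int = 3, n_init: int = 1,
                 tol: float = 1e-4, max_iter: int = 500,
                 random_state=None, accelerate: bool = True):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.accelerate = accelerate

    def fit(self, X, y=None):
        G, mask = _as_calls(X)
        n, L = G.shape
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        rng = np.random.default_rng(self.random_state)
        self.flags_ = []
        obs = mask.sum(axis=0)
        freq = np.where(obs > 0, (G * mask).sum(axis=0) / np.maximum(2 * obs, 1), 0.5)
        if K == 1:
            self.P_ = np.clip(freq[None, :], FREQ_CLIP, 1 - FREQ_CLIP)
            self.Q_ = np.ones((n, 1))
            self.loglik_ = admixture_loglik(X, self.Q_, self.P_)
            self.n_iter_ = 0
            self.converged_ = True
            self.loglik_path_ = [self.loglik_]
            return self
        if K > min(n, L):
            self.flags_.append("degenerate: K exceeds data capacity")
        best = None
        for _ in range(self.n_init):
            Q = rng.dirichlet(np.ones(K), size=n)
            P = np.clip(freq[None, :] + rng.normal(0, 0.1, size=(K, L)),
                        0.05, 0.95)
            if self.accelerate:
                Q, P, it, converged, path = self._fit_squarem(X, G, mask, Q, P)
            else:
                Q, P, it, converged, path = self._fit_plain(X, G, mask, Q, P)
            if best is None or path[-1] > best[0]:
                best = (path[-1], Q, P, it, converged, path)
        self.loglik_, self.Q_, self.P_, self.n_iter_, self.converged_, \
            self.loglik_path_ = best
        if not self.converged_:
            self.flags_.append("not converged")
        return self

    def _fit_plain(self, X, G, mask, Q, P):
        ll_prev = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            Qn = _em_q_update(G, mask, Q, P)
            Pn = _em_p_update(G, mask, Q, P)
            Q, P = Qn, Pn
            ll = admixture_loglik(X, Q, P)
            path.append(ll)
            if ll - ll_prev < self.tol and it > 1:
                converged = True
                break
            ll_prev = ll
        return Q, P, it, converged, path

    def _fit_squarem(self, X, G, mask, Q, P):
        """Joint (Q, P) EM with safeguarded SQUAREM extrapolation.

        Each cycle takes two EM base steps, extrapolates along the observed
        parameter trajectory, then applies one stabilizing EM step; the
        extrapolated point is kept only if the log-likelihood does not
        drop below the plain two-step value.
        """
        def em(Q, P):
            return _em_q_update(G, mask, Q, P), _em_p_update(G, mask, Q, P)

        path = []
        ll_prev = -np.inf
        converged = False
        it = 0
        while it < self.max_iter:
            Q1, P1 = em(Q, P)
            Q2, P2 = em(Q1, P1)
            it += 2
            ll2 = admixture_loglik(X, Q2, P2)
            if ll2 - ll_prev < self.tol and path:
                Q, P = Q2, P2
                path.append(ll2)
                converged = True
                break
            RQ, RP = Q1 - Q, P1 - P
            VQ, VP = Q2 - 2 * Q1 + Q, P2 - 2 * P1 + P
            vnorm = np.sqrt((VQ * VQ).sum() + (VP * VP).sum())
            if vnorm < 1e-30:
                Q, P, ll_prev = Q2, P2, ll2
                path.append(ll2)
                continue
            alpha = min(-1.0, -np.sqrt((RQ * RQ).sum() + (RP * RP).sum()) / vnorm)
            Qa = np.clip(Q - 2 * alpha * RQ + alpha ** 2 * VQ, 1e-9, None)
            Qa /= Qa.sum(axis=1, keepdims=True)
            Pa = np.clip(P - 2 * alpha * RP + alpha ** 2 * VP,
                         FREQ_CLIP, 1 - FREQ_CLIP)
            Qn, Pn = em(Qa, Pa)
            it += 1
            ll_n = admixture_loglik(X, Qn, Pn)
            if ll_n >= ll2:
                Q, P, ll_prev = Qn, Pn, ll_n
            else:
                Q, P, ll_prev = Q2, P2, ll2
            path.append(ll_prev)
        return Q, P, it, converged, path

    def fit_transform(self, X, y=None):
        return self.fit(X).Q_


# ---------------------------------------------------------------------------
# functional wrappers over GenotypeMatrix
# ---------------------------------------------------------------------------

def supervised_admixture(gm: GenotypeMatrix, P_ref, tol: float = 1e-6,
                         max_iter: int = 2000) -> AdmixtureResult:
    """Estimate per-individual ancestry with the reference panel fixed."""
    P = P_ref.P if hasattr(P_ref, "P") else np.asarray(P_ref)
    est = SupervisedAdmixture(P_ref=P, tol=tol, max_iter=max_iter).fit(gm.calls)
    return AdmixtureResult(Q=est.Q_, P_hat=np.asarray(P), loglik=est.loglik_,
                           n_iter=est.n_iter_, converged=est.converged_,
                           flags=est.flags_)


def unsupervised_admixture(gm: GenotypeMatrix, K: int, seed=None,
                           n_init: int = 1, max_iter: int = 500,
                           tol: float = 1e-4) -> AdmixtureResult:
    """Jointly estimate Q and P at a fixed number of ancestral populations."""
    est = UnsupervisedAdmixture(n_components=K, n_init=n_init, tol=tol,
                                max_iter=max_iter, random_state=seed).fit(gm.calls)
    return AdmixtureResult(Q=est.Q_, P_hat=est.P_, loglik=est.loglik_,
                           n_iter=est.n_iter_, converged=est.converged_,
                           seed=seed, flags=est.flags_)


# ---------------------------------------------------------------------------
# label alignment across runs
# ---------------------------------------------------------------------------

def _best_permutation(Q_ref: np.ndarray, Q: np.ndarray) -> tuple:
    """Column permutation of Q maximizing agreement with Q_ref."""
    K = Q.shape[1]
    score = Q_ref.T @ Q          # (K_ref, K) column similarity
    if K <= 6:
        best, best_s = None, -np.inf
        for perm in itertools.permutations(range(K)):
            s = sum(score[k, perm[k]] for k in range(K))
            if s > best_s:
                best, best_s = perm, s
        return best
    rows, cols = linear_sum_assignment(-score)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return tuple(perm)


def align_runs(Q_list, return_permutations: bool = False):
    """Resolve label switching across runs and average the Q matrices.

    The first run is the reference; every other run's columns are permuted
    to maximize the column-wise dot product with the reference, then the
    element-wise mean is taken (rows stay on the simplex).
    """
    mats = [np.asarray(Q, dtype=float) for Q in Q_list]
    shape = mats[0].shape
    for Q in mats:
        if Q.shape != shape:
            raise ValueError("all Q matrices must have the same shape")
    perms = [tuple(range(shape[1]))]
    aligned = [mats[0]]
    for Q in mats[1:]:
        perm = _best_permutation(mats[0], Q)
        perms.append(perm)
        aligned.append(Q[:, list(perm)])
    mean = np.mean(aligned, axis=0)
    if return_permutations:
        return mean, perms
    return mean


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class RunSet:
    """Replicate model scores (and aligned Q) across a range of K."""

    K_values: list
    runs_per_K: int
    logliks: dict                       # K -> list of per-run log-likelihoods
    aligned_Q: dict = field(default_factory=dict)

    def validate(self):
        for K in self.K_values:
            if len(self.logliks.get(K, [])) != self.runs_per_K:
                raise ValueError(f"K={K}: expected {self.runs_per_K} runs")


@dataclass
class DeltaKTable:
    """Per-K curvature summary and the selected number of populations."""

    table: pd.DataFrame                 # K, mean_L, sd_L, mean_abs_L2, delta_K
    best_K: int | None
    flags: list = field(default_factory=list)


def evanno_delta_k(runset: RunSet) -> DeltaKTable:
    """Evanno's delta-K: mean |L''(K)| over runs divided by the SD of L(K).

    L''(K) is the per-run second difference L_r(K+1) - 2 L_r(K) + L_r(K-1);
    delta-K is defined only at interior K with both neighbors present, and
    is flagged undefined where the across-run SD of L(K) is zero. ``best_K``
    is the interior K with the largest defined delta-K.
    """
    runset.validate()
    Ks = sorted(runset.K_values)
    if len(Ks) < 3:
        raise ValueError("need at least three consecutive K values")
    rows, flags = [], []
    for K in Ks:
        L = np.asarray(runset.logliks[K], dtype=float)
        rows.append({"K": K, "mean_L": L.mean(),
                     "sd_L": L.std(ddof=1), "mean_abs_L2": np.nan,
                     "delta_K": np.nan})
    df = pd.DataFrame(rows)
    for i, K in enumerate(Ks[1:-1], start=1):
        if Ks[i - 1] != K - 1 or Ks[i + 1] != K + 1:
            flags.append(f"K={K}: neighbors not consecutive, delta-K skipped")
            continue
        L_prev = np.asarray(runset.logliks[K - 1], dtype=float)
        L_here = np.asarray(runset.logliks[K], dtype=float)
        L_next = np.asarray(runset.logliks[K + 1], dtype=float)
        curvature = np.abs(L_next - 2 * L_here + L_prev)
        df.loc[i, "mean_abs_L2"] = curvature.mean()
        sd = df.loc[i, "sd_L"]
        if sd == 0:
            flags.append(f"K={K}: zero run-to-run SD, delta-K undefined")
        else:
            df.loc[i, "delta_K"] = curvature.mean() / sd
    defined = df["delta_K"].notna()
    best_K = int(df.loc[df.loc[defined, "delta_K"].idxmax(), "K"]) if defined.any() else None
    return DeltaKTable(table=df, best_K=best_K, flags=flags)


def scan_K(gm: GenotypeMatrix, K_values, runs_per_K: int = 10, seed=0,
           n_init: int = 1, max_iter: int = 200, tol: float = 0.5) -> RunSet:
    """Run unsupervised estimation across a K range with replicate restarts.

    Run r at every K uses seed ``seed + r`` so the per-run second
    differences in the delta-K formula pair runs consistently across K.
    """
    logliks: dict = {}
    aligned: dict = {}
    for K in K_values:
        Qs, lls = [], []
        for r in range(runs_per_K):
            res = unsupervised_admixture(gm, K, seed=int(seed) + r,
                                         n_init=n_init, max_iter=max_iter,
                                         tol=tol)
            Qs.append(res.Q)
            lls.append(res.loglik)
        logliks[K] = lls
        aligned[K] = align_runs(Qs)
    return RunSet(K_values=list(K_values), runs_per_K=runs_per_K,
                  logliks=logliks, aligned_Q=aligned)


# ---------------------------------------------------------------------------
# subpopulation assignment
# ---------------------------------------------------------------------------

def assign_subpopulations(Q, ancestry_index: int, random_state: int = 0):
    """Split a cohort into high/low subgroups on one ancestry coefficient.

    Fits a two-component 1-D Gaussian mixture to the named coefficient.
    Returns (labels, threshold, flags): labels are "high"/"low" per sample;
    the threshold is the decision boundary between the two component means.
    If the fitted components are not separated (or the coefficient is
    constant) the data are flagged unimodal and the median is used.
    """
    Q = np.asarray(Q, dtype=float)
    x = Q[:, ancestry_index]
    flags: list = []
    med = float(np.median(x))
    if np.ptp(x) < 1e-9 or len(x) < 4:
        flags.append("degenerate coefficient distribution; median threshold")
        labels = np.where(x > med, "high", "low")
        return labels, med, flags
    gmm = GaussianMixture(n_components=2, n_init=5,
                          random_state=random_state).fit(x[:, None])
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    hi, lo = np.argmax(means), np.argmin(means)
    separation = abs(means[hi] - means[lo]) / max(sds.mean(), 1e-12)
    if separation < 1.0:
        flags.append("unimodal coefficient distribution; median threshold")
        labels = np.where(x > med, "high", "low")
        return labels, med, flags
    # decision boundary: equal-posterior point between the component means
    grid = np.linspace(means[lo], means[hi], 2001)
    post = gmm.predict_proba(grid[:, None])
    cross = np.argmin(np.abs(post[:, hi] - post[:, lo]))
    threshold = float(grid[cross])
    comp = gmm.predict(x[:, None])
    labels = np.where(comp == hi, "high", "low")
    return labels, threshold, flags
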