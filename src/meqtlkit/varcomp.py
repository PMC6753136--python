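"""REML variance decomposition of CpG methylation.

Fits ``y ~ N(Xb, sigma2_A*K + sigma2_h*H + sigma2_e*I)`` by restricted
maximum likelihood and reports the additive-genetic (h2) and household
fractions of total variance.  The same engine, fed a genomic relationship
matrix instead of a pedigree kinship, estimates the variance in a CpG jointly
explained by a SNP set (the GREML-style h2 of cis- or trans-meQTLs).

Numerics: expectation-maximization warm start followed by average-information
updates with step halving, so the restricted log-likelihood never decreases
across accepted iterations.  Family-structured covariance matrices are block
diagonal; the solver detects the blocks from the joint sparsity of the
covariance list and performs all linear algebra batched per block size, which
makes genome-scale scans over pedigree cohorts cheap.  Negative variance
proposals are clamped at 1e-10 and flagged as boundary fits.  A rank check on
the Gram matrix of the covariance components detects unidentifiable models
(e.g. kinship = identity with an empty household matrix) up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "VarianceDecomposition",
    "GRM",
    "fit_variance_components",
    "heritability_scan",
    "select_unrelated",
    "grm_from_snps",
    "meqtl_variance_explained",
]

_CLAMP = 1e-10


class RankError(ValueError):
    """Covariate matrix is rank deficient."""


class MatrixError(ValueError):
    """A covariance matrix is malformed (asymmetric or not PSD)."""


@dataclass
class VarianceDecomposition:
    """REML estimates for one trait.

    ``h2 = sigma2_A / (sigma2_A + sigma2_h + sigma2_e)`` and
    ``household_effect = sigma2_h / total``.  ``boundary`` flags components
    clamped at the zero boundary; ``identifiable`` is False when the
    covariance components are linearly dependent and the split is arbitrary.
    """

    sigma2_A: float
    sigma2_h: float
    sigma2_e: float
    h2: float
    household_effect: float
    converged: bool
    n_iter: int
    loglik: float = float("nan")
    boundary: bool = False
    identifiable: bool = True


@dataclass
class GRM:
    """Genomic relationship matrix over a sample set."""

    matrix: np.ndarray
    sample_ids: list = field(default_factory=list)
    n_snps_used: int = 0
    n_snps_skipped: int = 0


# ---------------------------------------------------------------------------
# blocked REML engine
# ---------------------------------------------------------------------------

class _BlockedREML:
    """Precomputed block decomposition for a fixed (X, [V_1..V_c, I]) model.

    Reusable across many traits: build once per (covariates, covariance
    list), call :meth:`fit` per phenotype vector.
    """

    def __init__(self, X: np.ndarray, vcovs: list[np.ndarray]):
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise RankError("covariate matrix is singular")
        for i, V in enumerate(vcovs):
            if not np.allclose(V, V.T, atol=1e-8):
                raise MatrixError(f"covariance component {i} is not symmetric")
        self.n, self.p = n, p
        self.c = len(vcovs) + 1  # + identity
        comps = vcovs + [np.eye(n)]

        # identifiability: Gram matrix of the components must be full rank
        gram = np.array([[float(np.sum(a * b)) for b in comps] for a in comps])
        self.identifiable = (
            np.linalg.matrix_rank(gram, tol=1e-8 * max(1.0, gram.max())) == self.c
        )

        diagonal_only = all(
            not np.any(np.abs(V - np.diag(np.diag(V))) > 1e-12) for V in vcovs
        )
        if diagonal_only:
            # all blocks are singletons: extract diagonals directly
            idx = np.arange(n)[:, None]
            V_stack = np.stack([np.diag(V)[:, None, None] for V in comps])
            self.groups = [{"idx": idx, "V": V_stack, "X": X[:, None, :]}]
        else:
            adj = np.zeros((n, n), dtype=bool)
            for V in vcovs:
                adj |= np.abs(V) > 1e-12
            np.fill_diagonal(adj, True)
            n_blocks, labels = connected_components(csr_matrix(adj), directed=False)

            groups: dict[int, list[np.ndarray]] = {}
            for b in range(n_blocks):
                idx = np.flatnonzero(labels == b)
                groups.setdefault(idx.size, []).append(idx)

            self.groups = []
            for size, blocks in sorted(groups.items()):
                idx = np.stack(blocks)  # (m, s)
                V_stack = np.stack(
                    [np.stack([V[np.ix_(ix, ix)] for ix in blocks]) for V in comps]
                )  # (c, m, s, s)
                X_stack = X[idx]  # (m, s, p)
                self.groups.append({"idx": idx, "V": V_stack, "X": X_stack})

        # PSD check per component on the blocked pieces (cheap)
        for i, V in enumerate(vcovs):
            for g in self.groups:
                w = np.linalg.eigvalsh(g["V"][i])
                if w.min() < -1e-6:
                    raise MatrixError(f"covariance component {i} is not PSD")

    # -- core quantities at a parameter point ------------------------------
    def _evaluate(self, y: np.ndarray, sig: np.ndarray):
        p, c = self.p, self.c
        logdetV = 0.0
        S = np.zeros((p, p))
        Xty = np.zeros(p)
        pieces = []
        for g in self.groups:
            Vb = np.einsum("i,imst->mst", sig, g["V"])
            L = np.linalg.cholesky(Vb)
            logdetV += 2.0 * np.sum(np.log(np.einsum("mss->ms", L)))
            yb = y[g["idx"]]  # (m, s)
            rhs = np.concatenate([yb[:, :, None], g["X"]], axis=2)
            sol = np.linalg.solve(Vb, rhs)
            Viy, ViX = sol[:, :, 0], sol[:, :, 1:]
            S += np.einsum("msp,msq->pq", g["X"], ViX)
            Xty += np.einsum("msp,ms->p", g["X"], Viy)
            pieces.append((g, Vb, Viy, ViX, yb))
        Sinv = np.linalg.inv(S)
        beta = Sinv @ Xty
        sign, logdetS = np.linalg.slogdet(S)
        if sign <= 0:
            raise RankError("X'V^{-1}X not positive definite")

        yPy = 0.0
        trPV = np.zeros(c)
        w_list = [[] for _ in range(c)]  # w_i = V_i P y, per block group
        Py_groups = []
        for g, Vb, Viy, ViX, yb in pieces:
            Pyb = Viy - np.einsum("msp,p->ms", ViX, beta)
            Py_groups.append(Pyb)
            yPy += float(np.einsum("ms,ms->", yb, Pyb))
            Vinv = np.linalg.inv(Vb)
            for i in range(c):
                Vi = g["V"][i]
                # tr(P V_i) = tr(V^-1 V_i) - tr(Sinv * sum_b X'V^-1 V_i V^-1 X)
                trPV[i] += float(np.einsum("mst,mts->", Vinv, Vi))
                Mi = np.einsum("msp,mst,mtq->pq", ViX, Vi, ViX)
                trPV[i] -= float(np.einsum("pq,qp->", Sinv, Mi))
                w_list[i].append(np.einsum("mst,mt->ms", Vi, Pyb))
        ll = -0.5 * (logdetV + logdetS + yPy)

        # y' P V_i P y = (Py)' V_i (Py) = (Py)' w_i
        yPVPy = np.zeros(c)
        for i in range(c):
            yPVPy[i] = sum(
                float(np.einsum("ms,ms->", wb, Pyb))
                for wb, Pyb in zip(w_list[i], Py_groups)
            )

        # AI_ij = 0.5 w_i' P w_j, applying P blockwise to each w_j
        Pw = []
        for j in range(c):
            Xtw = np.zeros(p)
            sols = []
            for (g, Vb, _, ViX, _), wb in zip(pieces, w_list[j]):
                Viw = np.linalg.solve(Vb, wb[:, :, None])[:, :, 0]
                Xtw += np.einsum("msp,ms->p", g["X"], Viw)
                sols.append(Viw)
            bw = Sinv @ Xtw
            Pw.append(
                [
                    Viw - np.einsum("msp,p->ms", ViX, bw)
                    for (g, Vb, _, ViX, _), Viw in zip(pieces, sols)
                ]
            )
        AI = np.zeros((c, c))
        for i in range(c):
            for j in range(i, c):
                val = 0.5 * sum(
                    float(np.einsum("ms,ms->", wi, pwj))
                    for wi, pwj in zip(w_list[i], Pw[j])
                )
                AI[i, j] = AI[j, i] = val
        grad = 0.5 * (yPVPy - trPV)
        return ll, grad, AI, trPV, yPVPy

    def loglik(self, y: np.ndarray, sig: np.ndarray) -> float:
        return self._evaluate(y, sig)[0]

    def fixed_effects(self, y: np.ndarray, sig: np.ndarray):
        """GLS fixed-effect estimates and their covariance at variance point ``sig``."""
        p = self.p
        S = np.zeros((p, p))
        Xty = np.zeros(p)
        for g in self.groups:
            Vb = np.einsum("i,imst->mst", sig, g["V"])
            yb = y[g["idx"]]
            rhs = np.concatenate([yb[:, :, None], g["X"]], axis=2)
            sol = np.linalg.solve(Vb, rhs)
            Viy, ViX = sol[:, :, 0], sol[:, :, 1:]
            S += np.einsum("msp,msq->pq", g["X"], ViX)
            Xty += np.einsum("msp,ms->p", g["X"], Viy)
        cov = np.linalg.inv(S)
        return cov @ Xty, cov

    def conditional_residuals(self, y: np.ndarray, sig: np.ndarray) -> np.ndarray:
        """Residuals after removing fixed effects and the BLUPs of all random
        effects: ``e_hat = sigma2_e * P y``."""
        beta, _ = self.fixed_effects(y, sig)
        resid = np.zeros(self.n)
        for g in self.groups:
            Vb = np.einsum("i,imst->mst", sig, g["V"])
            yb = y[g["idx"]] - np.einsum("msp,p->ms", g["X"], beta)
            Py = np.linalg.solve(Vb, yb[:, :, None])[:, :, 0]
            resid[g["idx"].ravel()] = sig[-1] * Py.ravel()
        return resid

    def fit(self, y: np.ndarray, max_iter: int = 100, tol: float = 1e-6,
            em_iters: int = 20) -> tuple[np.ndarray, bool, int, float, bool]:
        n, p, c = self.n, self.p, self.c
        vy = float(np.var(y))
        if vy == 0:
            sig = np.full(c, _CLAMP)
            sig[-1] = _CLAMP
            return sig, True, 0, float("nan"), True
        sig = np.full(c, vy / c)
        boundary = False
        ll, grad, AI, trPV, yPVPy = self._evaluate(y, sig)
        self.trace = [ll]
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            # active set: components pinned at the zero boundary whose
            # gradient still points outward are frozen, so the remaining
            # components can converge instead of creeping
            at_boundary = (sig <= 2 * _CLAMP) & (grad < 0)
            free = ~at_boundary
            if it <= em_iters:
                new = sig + (sig**2 / n) * (yPVPy - trPV)
                new = np.maximum(new, _CLAMP)
                new[at_boundary] = _CLAMP
            else:
                delta = np.zeros(c)
                AI_f = AI[np.ix_(free, free)]
                try:
                    delta[free] = np.linalg.solve(
                        AI_f + 1e-12 * np.eye(int(free.sum())), grad[free]
                    )
                except np.linalg.LinAlgError:
                    delta[free] = grad[free] / np.maximum(np.diag(AI)[free], 1e-12)
                step = 1.0
                new = np.maximum(sig + step * delta, _CLAMP)
                # step halving: keep restricted likelihood non-decreasing
                for _ in range(12):
                    try:
                        if self.loglik(y, new) >= ll - 1e-12:
                            break
                    except np.linalg.LinAlgError:
                        pass
                    step /= 2.0
                    new = np.maximum(sig + step * delta, _CLAMP)
            # component-change criterion is relative to the trait variance so
            # convergence behaves identically across measurement scales
            change = np.max(np.abs(new - sig)) / vy
            sig = new
            new_ll, grad, AI, trPV, yPVPy = self._evaluate(y, sig)
            rel_ll = abs(new_ll - ll) / max(1.0, abs(ll))
            ll = new_ll
            self.trace.append(ll)
            if change < tol or rel_ll < 1e-10:
                converged = True
                break
        boundary = bool(np.any(sig <= 2 * _CLAMP))
        return sig, converged, it, ll, boundary


def fit_variance_components(
    y: np.ndarray,
    covariates: np.ndarray | None,
    vcov_list: list[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-6,
    model: _BlockedREML | None = None,
) -> VarianceDecomposition:
    """REML decomposition of one trait into the listed covariance components.

    ``vcov_list`` is typically ``[K, H]`` (kinship, household); a residual
    identity component is always appended.  ``covariates`` (without an
    intercept column is fine — one is added if absent) enter as fixed
    effects.  Passing a prebuilt ``model`` (see :func:`heritability_scan`)
    skips the block decomposition.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = _design(covariates, n)
    if n <= X.shape[1] + 2:
        raise RankError("too few samples for the fixed-effect design")
    if model is None:
        model = _BlockedREML(X, [np.asarray(V, dtype=float) for V in vcov_list])
    sig, converged, n_iter, ll, boundary = model.fit(y, max_iter=max_iter, tol=tol)
    return _make_result(sig, converged, n_iter, ll, boundary, model.identifiable)


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    has_const = np.any(np.all(X == X[0], axis=0))
    if not has_const:
        X = np.column_stack([np.ones(n), X])
    return X


def _make_result(sig, converged, n_iter, ll, boundary, identifiable) -> VarianceDecomposition:
    s_a, s_h, s_e = (float(sig[0]), float(sig[1]), float(sig[2])) if sig.size == 3 else (
        float(sig[0]), 0.0, float(sig[-1]))
    total = s_a + s_h + s_e
    return VarianceDecomposition(
        sigma2_A=s_a,
        sigma2_h=s_h,
        sigma2_e=s_e,
        h2=s_a / total if total > 0 else 0.0,
        household_effect=s_h / total if total > 0 else 0.0,
        converged=converged,
        n_iter=n_iter,
        loglik=ll,
        boundary=boundary,
        identifiable=identifiable,
    )


# ---------------------------------------------------------------------------
# scans and helpers
# ---------------------------------------------------------------------------

H2_BINS = (0.1, 0.3, 0.6)


def heritability_scan(
    cpgs,
    covariates: np.ndarray | None,
    K: np.ndarray,
    H: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """Per-CpG variance decomposition plus threshold bin counts.

    Returns one row per CpG (failures are flagged, never abort the scan) and
    summary counts of CpGs with h2 above 0.1 / 0.3 / 0.6 and household
    fraction above 0.1.
    """
    betas = cpgs.betas if hasattr(cpgs, "betas") else cpgs
    n = betas.shape[0]
    X = _design(covariates, n)
    model = _BlockedREML(X, [np.asarray(K, float), np.asarray(H, float)])
    rows = []
    for cpg_id in betas.columns:
        y = betas[cpg_id].to_numpy(dtype=float)
        try:
            sig, converged, n_iter, ll, boundary = model.fit(y, max_iter=max_iter, tol=tol)
            d = _make_result(sig, converged, n_iter, ll, boundary, model.identifiable)
            rows.append(
                {
                    "cpg_id": cpg_id, "sigma2_A": d.sigma2_A, "sigma2_h": d.sigma2_h,
                    "sigma2_e": d.sigma2_e, "h2": d.h2, "household": d.household_effect,
                    "converged": d.converged, "failed": False,
                }
            )
        except (np.linalg.LinAlgError, RankError, MatrixError):
            rows.append(
                {
                    "cpg_id": cpg_id, "sigma2_A": np.nan, "sigma2_h": np.nan,
                    "sigma2_e": np.nan, "h2": np.nan, "household": np.nan,
                    "converged": False, "failed": True,
                }
            )
    table = pd.DataFrame(rows).set_index("cpg_id")
    ok = table[~table["failed"]]
    counts = {f"h2_gt_{t}": int((ok["h2"] > t).sum()) for t in H2_BINS}
    counts["household_gt_0.1"] = int((ok["household"] > 0.1).sum())
    return table, counts


def select_unrelated(pedigree: pd.DataFrame, seed: int = 0) -> list[str]:
    """One individual per family plus all singletons, deterministic in seed."""
    rng = np.random.default_rng(seed)
    chosen = []
    for _, grp in pedigree.groupby("family_id", sort=True):
        ids = sorted(grp["sample_id"])
        chosen.append(ids[int(rng.integers(0, len(ids)))])
    return sorted(chosen)


def grm_from_snps(genotypes, snp_ids) -> GRM:
    """Standard GRM: ``G_ij = (1/m) sum_k (g_ik - 2p_k)(g_jk - 2p_k) / (2 p_k (1-p_k))``.

    Monomorphic SNPs are skipped (counted in ``n_snps_skipped``).
    """
    dos = genotypes.dosages[list(snp_ids)].to_numpy(dtype=float)
    p = dos.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1) & (dos.std(axis=0) > 0)
    skipped = int((~keep).sum())
    dos = dos[:, keep]
    p = p[keep]
    if dos.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left for the GRM")
    Z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
    G = (Z @ Z.T) / dos.shape[1]
    return GRM(
        matrix=G,
        sample_ids=list(genotypes.dosages.index),
        n_snps_used=dos.shape[1],
        n_snps_skipped=skipped,
    )


def meqtl_variance_explained(
    y: np.ndarray, grm: GRM, covariates: np.ndarray | None = None,
    max_iter: int = 100, tol: float = 1e-6,
) -> VarianceDecomposition:
    """GREML-style fraction of trait variance captured by a SNP-set GRM.

    Fits ``y ~ N(Xb, sigma2_g*G + sigma2_e*I)`` on (ideally unrelated)
    samples and reports ``sigma2_g / (sigma2_g + sigma2_e)`` in the ``h2``
    field; ``converged=False`` flags estimates from non-converged fits.
    """
    y = np.asarray(y, dtype=float)
    X = _design(covariates, y.size)
    model = _BlockedREML(X, [grm.matrix])
    sig, converged, n_iter, ll, boundary = model.fit(y, max_iter=max_iter, tol=tol)
    total = float(sig[0] + sig[1])
    return VarianceDecomposition(
        sigma2_A=float(sig[0]), sigma2_h=0.0, sigma2_e=float(sig[1]),
        h2=float(sig[0]) / total if total > 0 else 0.0,
        household_effect=0.0, converged=converged, n_iter=n_iter,
        loglik=ll, boundary=boundary, identifiable=model.identifiable,
    )
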