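"""Bivariate genomic REML and BLUP for two environment-traits.

Model
-----
Records y1, y2 (pseudo-phenotypes at the two THI environments) follow

    [y1; y2] = [1 mu1; 1 mu2] + [Z1 0; 0 Z2][a1; a2] + [e1; e2],

with additive effects [a1; a2] ~ N(0, G0 (x) G) for the genomic
relationship matrix G and 2x2 trait covariance G0, and residuals
~ N(0, R0 (x) I). Variance components are estimated by restricted
maximum likelihood.

Numerics
--------
Because the analysis set carries both records on the same animals, the
model can be rotated by the eigendecomposition G = U diag(d) U': the
transformed records decouple into independent 2x2 problems with
covariance V_i = d_i G0 + R0, making each REML iteration O(n) after a
single eigendecomposition. The optimizer takes average-information
(AI) steps with step halving, falling back to an EM step (which never
decreases the restricted likelihood) when the AI step fails; estimates
are projected to the positive-semidefinite cone each iteration, with
eigenvalues floored at 1e-10 of the trace and within-matrix
correlations bounded away from +-1 so the rotated 2x2 covariances stay
invertible even for degenerate (identical) inputs.

``solve_mme`` assembles the full mixed-model equations with explicit
record-to-animal incidence, so animals missing one environment (or all
records) still receive GEBVs through genomic relationships.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GEBVTable, GRM, PseudoPhenotypeTable, VarianceComponents

__all__ = [
    "fit_greml",
    "solve_mme",
    "reml_loglik",
    "fit_greml_univariate",
    "solve_gblup_univariate",
]

_EIG_FLOOR_REL = 1e-10
_MAX_ABS_CORR = 1.0 - 1e-6


# ---------------------------------------------------------------------------
# parameter handling
# ---------------------------------------------------------------------------

def _project_psd(a: np.ndarray) -> np.ndarray:
    """Symmetrize, floor eigenvalues at 1e-10 of trace, bound |corr| < 1."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    floor = _EIG_FLOOR_REL * max(float(np.trace(a)), 1e-8)
    w = np.maximum(w, floor)
    a = (v * w) @ v.T
    a = 0.5 * (a + a.T)
    cap = _MAX_ABS_CORR * np.sqrt(a[0, 0] * a[1, 1])
    if abs(a[0, 1]) > cap:
        off = np.sign(a[0, 1]) * cap
        a[0, 1] = a[1, 0] = off
    return a


def _pack(G0: np.ndarray, R0: np.ndarray, diagonal: bool) -> np.ndarray:
    if diagonal:
        return np.array([G0[0, 0], G0[1, 1], R0[0, 0], R0[1, 1]])
    return np.array([G0[0, 0], G0[0, 1], G0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])


def _unpack(theta: np.ndarray, diagonal: bool) -> tuple[np.ndarray, np.ndarray]:
    if diagonal:
        G0 = np.diag(theta[:2]).astype(float)
        R0 = np.diag(theta[2:]).astype(float)
    else:
        G0 = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        R0 = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return G0, R0


# basis of symmetric 2x2 derivative matrices per free parameter
_E_FULL = [
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
]
_E_DIAG = [_E_FULL[0], _E_FULL[2]]


# ---------------------------------------------------------------------------
# rotated-likelihood machinery
# ---------------------------------------------------------------------------

def _inv2(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched 2x2 inverse; returns (inverse, determinant)."""
    det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] * v[:, 1, 0]
    inv = np.empty_like(v)
    inv[:, 0, 0] = v[:, 1, 1]
    inv[:, 1, 1] = v[:, 0, 0]
    inv[:, 0, 1] = -v[:, 0, 1]
    inv[:, 1, 0] = -v[:, 1, 0]
    inv /= det[:, None, None]
    return inv, det


class _Rotated:
    """Eigen-rotated data and per-iteration sufficient statistics."""

    def __init__(self, Y: np.ndarray, Gmat: np.ndarray):
        d, U = np.linalg.eigh(0.5 * (Gmat + Gmat.T))
        if d.min() <= 0:
            raise ValueError(
                "GRM is not positive definite; blend it (blend_epsilon > 0) first"
            )
        self.d = d
        self.U = U
        self.yt = U.T @ Y          # (n, 2)
        self.x = U.T @ np.ones(Y.shape[0])  # (n,)
        self.n = Y.shape[0]

    def stats(self, G0: np.ndarray, R0: np.ndarray) -> dict:
        d, x, yt = self.d, self.x, self.yt
        V = d[:, None, None] * G0 + R0
        Vinv, det = _inv2(V)
        if np.any(det <= 0) or not np.all(np.isfinite(det)):
            return {"ok": False}
        S = np.einsum("i,ijk->jk", x**2, Vinv)
        rhs = np.einsum("i,ijk,ik->j", x, Vinv, yt)
        try:
            b = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            return {"ok": False}
        r = yt - x[:, None] * b
        q = np.einsum("ijk,ik->ij", Vinv, r)
        sign, logdet_s = np.linalg.slogdet(S)
        if sign <= 0:
            return {"ok": False}
        ll = -0.5 * (np.log(det).sum() + logdet_s + np.einsum("ij,ij->", r, q))
        if not np.isfinite(ll):
            return {"ok": False}
        # REML projection diagonal blocks P_ii = Vinv - x^2 Vinv S^-1 Vinv
        Sinv = np.linalg.inv(S)
        VS = np.einsum("ijk,kl->ijl", Vinv, Sinv)
        P = Vinv - (x**2)[:, None, None] * np.einsum("ijk,ikl->ijl", VS, Vinv)
        return {
            "ok": True, "V": V, "Vinv": Vinv, "S": S, "Sinv": Sinv,
            "b": b, "r": r, "q": q, "P": P, "ll": float(ll),
        }

    # -- AI-REML pieces ------------------------------------------------------
    def score_and_ai(self, st: dict, diagonal: bool) -> tuple[np.ndarray, np.ndarray]:
        d, x = self.d, self.x
        q, P, Vinv, Sinv = st["q"], st["P"], st["Vinv"], st["Sinv"]
        bases = _E_DIAG if diagonal else _E_FULL
        coefs = [d, np.ones(self.n)]  # G0-block then R0-block derivatives
        ws = []
        score = []
        for c in coefs:
            for E in bases:
                tr = c @ np.einsum("ijk,kj->i", P, E)
                quad = c @ np.einsum("ij,jk,ik->i", q, E, q)
                score.append(-0.5 * (tr - quad))
                ws.append(c[:, None] * (q @ E.T))
        k = len(ws)
        ai = np.empty((k, k))
        pws = []
        for w in ws:
            t1 = np.einsum("ijk,ik->ij", Vinv, w)
            h = x @ t1
            pw = t1 - x[:, None] * np.einsum("ijk,k->ij", Vinv, Sinv @ h)
            pws.append(pw)
        for a in range(k):
            for b_ in range(a, k):
                ai[a, b_] = ai[b_, a] = 0.5 * np.einsum("ij,ij->", ws[a], pws[b_])
        return np.array(score), ai

    def em_step(self, st: dict, G0: np.ndarray, R0: np.ndarray):
        d = self.d
        q, r, P = st["q"], st["r"], st["P"]
        ghat = d[:, None] * (q @ G0.T)              # BLUP of rotated additive effects
        ehat = r - ghat
        # E-step expectations: E[g g'|y]/d_i and E[e e'|y] averaged over components
        gg = np.einsum("ij,ik,i->jk", ghat, ghat, 1.0 / d) / self.n
        tg = G0 - np.einsum("jk,ikl,lm,i->jm", G0, P, G0, d) / self.n
        G0n = gg + tg
        ee = np.einsum("ij,ik->jk", ehat, ehat) / self.n
        te = R0 - np.einsum("jk,ikl,lm->jm", R0, P, R0) / self.n
        R0n = ee + te
        return _project_psd(G0n), _project_psd(R0n)


def reml_loglik(Y: np.ndarray, Gmat: np.ndarray, G0: np.ndarray, R0: np.ndarray) -> float:
    """Restricted log-likelihood (up to a constant) of the bivariate model.

    ``Y`` is the (n, 2) complete-case record matrix aligned with the
    rows of the (blended, positive-definite) relationship matrix.
    """
    st = _Rotated(np.asarray(Y, float), np.asarray(Gmat, float)).stats(
        np.asarray(G0, float), np.asarray(R0, float)
    )
    if not st["ok"]:
        return -np.inf
    return st["ll"]


# ---------------------------------------------------------------------------
# data alignment
# ---------------------------------------------------------------------------

def _complete_case(y: PseudoPhenotypeTable, G: GRM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Y, analysis ids, index into G) for animals with both records in G."""
    wide = y.pivot()
    in_g = pd.Index(G.animal_ids)
    both = wide.notna().all(axis=1)
    ids = [a for a in G.animal_ids if a in wide.index and both.get(a, False)]
    if len(ids) < 3:
        raise ValueError(
            f"only {len(ids)} animals have records in both environments and the GRM"
        )
    idx = in_g.get_indexer(ids)
    Y = wide.loc[ids].to_numpy(float)
    return Y, np.asarray(ids, dtype=object), idx


# ---------------------------------------------------------------------------
# REML driver
# ---------------------------------------------------------------------------

def fit_greml(
    y: PseudoPhenotypeTable,
    G: GRM,
    tol: float = 1e-8,
    max_iter: int = 200,
    covariance: str = "full",
) -> VarianceComponents:
    """Estimate G0 and R0 by AI-accelerated EM-REML.

    Parameters
    ----------
    y
        Pseudo-phenotype records; the analysis set is the animals with
        records in both environments that are present in the GRM.
    G
        Blended (positive-definite) genomic relationship matrix.
    tol
        Convergence threshold on the max absolute change of the free
        parameters between iterations.
    max_iter
        Iteration cap; hitting it returns ``converged=False`` rather
        than raising.
    covariance
        "full" (6 free parameters) or "diagonal" (G0 and R0 constrained
        to zero covariance; the fit then decouples exactly into two
        univariate analyses).

    Notes
    -----
    Start values assign half the phenotypic (co)variance to each of G0
    and R0. Each accepted AI step must not decrease the restricted
    likelihood (checked with step halving); otherwise an EM step is
    taken, which is monotone by construction.
    """
    if covariance not in ("full", "diagonal"):
        raise ValueError("covariance must be 'full' or 'diagonal'")
    diagonal = covariance == "diagonal"

    Y, ids, idx = _complete_case(y, G)
    Gsub = G.matrix[np.ix_(idx, idx)]
    rot = _Rotated(Y, Gsub)

    Sy = np.cov(Y, rowvar=False)
    G0 = _project_psd(np.asarray(Sy) / 2.0)
    R0 = _project_psd(np.asarray(Sy) / 2.0)
    if diagonal:
        G0 = np.diag(np.diag(G0))
        R0 = np.diag(np.diag(R0))

    st = rot.stats(G0, R0)
    if not st["ok"]:
        raise RuntimeError("likelihood undefined at the starting values")
    ll_path = [st["ll"]]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        theta = _pack(G0, R0, diagonal)
        score, ai = rot.score_and_ai(st, diagonal)

        accepted = False
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None and np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(10):  # step halving
                cand = theta + step * delta
                G0c, R0c = _unpack(cand, diagonal)
                G0c, R0c = _project_psd(G0c), _project_psd(R0c)
                if diagonal:
                    G0c = np.diag(np.diag(G0c))
                    R0c = np.diag(np.diag(R0c))
                stc = rot.stats(G0c, R0c)
                if stc["ok"] and stc["ll"] >= st["ll"] - 1e-10:
                    G0n, R0n, stn = G0c, R0c, stc
                    accepted = True
                    break
                step *= 0.5
        if not accepted:  # monotone EM fallback
            G0n, R0n = rot.em_step(st, G0, R0)
            if diagonal:
                G0n = np.diag(np.diag(G0n))
                R0n = np.diag(np.diag(R0n))
            stn = rot.stats(G0n, R0n)
            if not stn["ok"]:
                raise RuntimeError("EM step produced an undefined likelihood")

        change = np.max(np.abs(_pack(G0n, R0n, diagonal) - theta))
        G0, R0, st = G0n, R0n, stn
        ll_path.append(st["ll"])
        if change < tol:
            converged = True
            break

    return VarianceComponents(
        G0=G0,
        R0=R0,
        loglik=st["ll"],
        n_iter=n_iter,
        converged=converged,
        env_labels=y.env_labels,
        loglik_path=ll_path,
    )


# ---------------------------------------------------------------------------
# univariate counterparts (used for the decoupling identity)
# ---------------------------------------------------------------------------

def fit_greml_univariate(
    values: np.ndarray,
    Gmat: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, float, float, bool]:
    """Single-trait genomic REML by the same rotated AI/EM scheme.

    Returns ``(sigma2_a, sigma2_e, loglik, converged)``.
    """
    yv = np.asarray(values, float)
    d, U = np.linalg.eigh(0.5 * (Gmat + Gmat.T))
    if d.min() <= 0:
        raise ValueError("relationship matrix must be positive definite")
    yt = U.T @ yv
    x = U.T @ np.ones(len(yv))
    n = len(yv)
    floor = _EIG_FLOOR_REL * max(float(np.var(yv)), 1e-8)

    def stats(sa, se):
        V = d * sa + se
        if np.any(V <= 0):
            return None
        S = np.sum(x**2 / V)
        b = np.sum(x * yt / V) / S
        r = yt - x * b
        q = r / V
        ll = -0.5 * (np.log(V).sum() + np.log(S) + r @ q)
        P = 1.0 / V - x**2 / (V**2 * S)
        return {"V": V, "b": b, "r": r, "q": q, "P": P, "ll": float(ll)}

    sa = se = max(float(np.var(yv)) / 2.0, floor)
    st = stats(sa, se)
    converged = False
    for _ in range(max_iter):
        q, P, V = st["q"], st["P"], st["V"]
        score = np.array(
            [-0.5 * (d @ P - d @ q**2), -0.5 * (P.sum() - q @ q)]
        )
        ws = [d * q, q]
        ai = np.empty((2, 2))
        S = np.sum(x**2 / V)
        pws = []
        for w in ws:
            h = np.sum(x * w / V) / S
            pws.append(w / V - x / V * h)
        for a in range(2):
            for b_ in range(a, 2):
                ai[a, b_] = ai[b_, a] = 0.5 * (ws[a] @ pws[b_])
        accepted = False
        try:
            delta = np.linalg.solve(ai, score)
            step = 1.0
            for _ in range(10):
                sac = max(sa + step * delta[0], floor)
                sec = max(se + step * delta[1], floor)
                stc = stats(sac, sec)
                if stc is not None and np.isfinite(stc["ll"]) and stc["ll"] >= st["ll"] - 1e-10:
                    san, sen, stn = sac, sec, stc
                    accepted = True
                    break
                step *= 0.5
        except np.linalg.LinAlgError:
            pass
        if not accepted:  # EM
            ghat = d * sa * st["q"]
            ehat = st["r"] - ghat
            san = max(float(np.mean(ghat**2 / d) + sa - sa**2 * np.mean(d * st["P"])), floor)
            sen = max(float(np.mean(ehat**2) + se - se**2 * np.mean(st["P"])), floor)
            stn = stats(san, sen)
        change = max(abs(san - sa), abs(sen - se))
        sa, se, st = san, sen, stn
        if change < tol:
            converged = True
            break
    return sa, se, st["ll"], converged


def solve_gblup_univariate(
    values: np.ndarray, Gmat: np.ndarray, sigma2_a: float, sigma2_e: float
) -> tuple[float, np.ndarray]:
    """Single-trait GBLUP: GLS mean and BLUP a = sigma2_a G V^-1 (y - mu)."""
    yv = np.asarray(values, float)
    n = len(yv)
    V = sigma2_a * Gmat + sigma2_e * np.eye(n)
    Vinv_y = np.linalg.solve(V, yv)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
    a = sigma2_a * (Gmat @ np.linalg.solve(V, yv - mu))
    return mu, a


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(
    y: PseudoPhenotypeTable, G: GRM, vc: VarianceComponents
) -> GEBVTable:
    """Solve the bivariate mixed-model equations at given components.

    Builds the full Henderson system with explicit record-to-animal
    incidence: animals missing one (or both) environments still appear
    in the additive-effect vector and get GEBVs through G. Residual
    covariance is block-diagonal per animal, using the subset of R0
    matching that animal's observed environments.

    Returns a :class:`GEBVTable` covering every animal in the GRM under
    both environments, plus the estimated environment means.
    """
    env1, env2 = y.env_labels
    n_a = G.n_animals
    in_g = pd.Index(G.animal_ids)

    wide = y.pivot().reindex(G.animal_ids)
    obs = wide.notna().to_numpy()  # (n_a, 2)

    G0 = np.asarray(vc.G0, float)
    R0 = np.asarray(vc.R0, float)
    if np.linalg.det(G0) <= 0:
        raise ValueError("additive (co)variance block G0 is singular; cannot invert")

    # record list: (animal index, trait index, value)
    rec_an, rec_tr, rec_y = [], [], []
    for t in range(2):
        rows = np.flatnonzero(obs[:, t])
        rec_an.append(rows)
        rec_tr.append(np.full(len(rows), t))
        rec_y.append(wide.to_numpy()[rows, t])
    rec_an = np.concatenate(rec_an)
    rec_tr = np.concatenate(rec_tr)
    rec_y = np.concatenate(rec_y)
    n_rec = len(rec_y)
    if n_rec == 0:
        raise ValueError("no records for any animal in the GRM")

    # per-animal inverse residual blocks -> dense R^-1 over records
    rinv = np.zeros((n_rec, n_rec))
    rec_index = {}
    for k, (j, t) in enumerate(zip(rec_an, rec_tr)):
        rec_index[(j, t)] = k
    for j in range(n_a):
        ts = np.flatnonzero(obs[j])
        if len(ts) == 0:
            continue
        block = R0[np.ix_(ts, ts)]
        if np.linalg.det(block) <= 0:
            raise ValueError(
                f"residual (co)variance block R0[{list(ts)}][{list(ts)}] is singular"
            )
        binv = np.linalg.inv(block)
        ks = [rec_index[(j, t)] for t in ts]
        rinv[np.ix_(ks, ks)] = binv

    # design matrices: W = [X | Z], effects = (mu1, mu2, a_t1 (n_a), a_t2 (n_a))
    n_eff = 2 + 2 * n_a
    W = np.zeros((n_rec, n_eff))
    for k in range(n_rec):
        W[k, rec_tr[k]] = 1.0
        W[k, 2 + rec_tr[k] * n_a + rec_an[k]] = 1.0

    try:
        ginv = np.linalg.inv(G.matrix)
    except np.linalg.LinAlgError as err:
        raise ValueError("genomic relationship matrix G is singular; blend it") from err
    g0inv = np.linalg.inv(G0)

    lhs = W.T @ rinv @ W
    lhs[2:, 2:] += np.kron(g0inv, ginv)
    rhs = W.T @ rinv @ rec_y
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as err:
        raise ValueError("mixed-model coefficient matrix is singular") from err

    mu = (float(sol[0]), float(sol[1]))
    a = sol[2:].reshape(2, n_a)
    data = pd.DataFrame(
        {
            "animal_id": np.tile(G.animal_ids, 2),
            "env": np.repeat([env1, env2], n_a),
            "gebv": a.ravel(),
        }
    )
    return GEBVTable(data=data, fixed_means=mu, env_labels=y.env_labels)
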