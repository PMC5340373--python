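"""FIML machinery for the three-level normative model.

Model per score row (test i, participant j, study k):

    y_ijk = gamma_i0 + gamma_i' u_jk + nu_ik + eps_ijk

with fixed effects per test (intercept + covariate slopes), study intercept
errors nu_k ~ N(0, diag(sigma_b2)) shared by all participants of a study,
and participant residual vectors eps_jk ~ N(0, Sigma_w[S_j, S_j]) on the
observed test subset S_j. Missing-by-design scores are simply absent rows;
FIML uses whatever each participant observed.

Likelihood evaluation is profiled: for fixed variance parameters the fixed
effects are the GLS solution, so the optimizer only searches the variance
space (log-Cholesky factor of Sigma_w, log sigma_b2). When all participants
of a study observe the same subset S, the study covariance
I_n (x) Sigma_w[S,S] + J_n (x) diag(sigma_b2)[S] decomposes into n-1
Helmert-contrast blocks with covariance V1 = Sigma_w[S,S] and one mean
block with Vn = V1 + n*diag(sigma_b2)[S]; the likelihood then depends on
the data only through small per-study cross-product matrices, which are
additive across studies sharing (S, n). Studies are therefore merged into
grouped blocks, so one likelihood evaluation costs O(#distinct patterns x
p^3) regardless of the number of studies or participants. Studies whose
participants differ in observed tests fall back to dense assembly of the
full study covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import EstimabilityError

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# study blocks


@dataclass
class HomogeneousBlock:
    """All participants in the study observed the same test subset S."""

    n: int                 # participants
    S: np.ndarray          # observed tests, 0-based, sorted
    ybar: np.ndarray       # mean score vector over participants (len s)
    ubar: np.ndarray       # mean design vector [1, covariates] (len c+1)
    Syy_c: np.ndarray      # centered cross-products, s x s
    Syu_c: np.ndarray      # s x (c+1)
    Suu_c: np.ndarray      # (c+1) x (c+1)


@dataclass
class GroupedBlock:
    """Sufficient statistics pooled over studies sharing (S, n).

    Within-block (Helmert contrast) statistics are the sums of the centered
    cross-products; the mean-block statistics are participant-count-weighted
    outer products of the study means.
    """

    n: int                 # participants per study (common to the group)
    k: int                 # number of studies pooled
    S: np.ndarray
    Syy_c: np.ndarray      # sum over studies, s x s
    Syu_c: np.ndarray      # s x (c+1)
    Suu_c: np.ndarray      # (c+1) x (c+1)
    B_yy: np.ndarray       # sum_k n * ybar ybar', s x s
    B_yu: np.ndarray       # sum_k n * ybar ubar', s x (c+1)
    B_uu: np.ndarray       # sum_k n * ubar ubar', (c+1) x (c+1)


@dataclass
class DenseBlock:
    """Ragged missingness: participants observed different subsets."""

    y: np.ndarray          # stacked scores, length m
    tests: np.ndarray      # 0-based test index per row
    pidx: np.ndarray       # participant index per row (0..n-1 within study)
    U: np.ndarray          # per-row design vector, m x (c+1)


def build_blocks(frame: pd.DataFrame, covariates: tuple[str, ...]):
    """Split a long-format frame into per-study likelihood blocks."""
    cols = list(covariates)
    order = np.lexsort(
        (
            frame["test"].to_numpy(),
            pd.factorize(frame["ID"])[0],
            pd.factorize(frame["study"])[0],
        )
    )
    study = pd.factorize(frame["study"])[0][order]
    pid_raw = pd.factorize(frame["ID"])[0][order]
    tests = frame["test"].to_numpy(int)[order] - 1
    y = frame["score"].to_numpy(float)[order]
    U_all = np.ones((len(frame), 1 + len(cols)))
    if cols:
        U_all[:, 1:] = frame[cols].to_numpy(float)[order]

    blocks = []
    bounds = np.flatnonzero(np.diff(study)) + 1
    for lo, hi in zip(np.r_[0, bounds], np.r_[bounds, len(study)]):
        t_s, y_s, u_s, pid_s = tests[lo:hi], y[lo:hi], U_all[lo:hi], pid_raw[lo:hi]
        # participant boundaries within the (sorted) study slice
        pb = np.flatnonzero(np.diff(pid_s)) + 1
        starts = np.r_[0, pb]
        counts = np.diff(np.r_[starts, hi - lo])
        n = starts.size
        s0 = counts[0]
        homogeneous = (counts == s0).all() and (
            t_s.reshape(n, s0) == t_s[:s0]
        ).all() if (counts == s0).all() else False
        if homogeneous:
            S = t_s[:s0]
            Y = y_s.reshape(n, s0)
            U = u_s[starts]
            ybar = Y.mean(axis=0)
            ubar = U.mean(axis=0)
            blocks.append(
                HomogeneousBlock(
                    n, S.copy(), ybar, ubar,
                    Y.T @ Y - n * np.outer(ybar, ybar),
                    Y.T @ U - n * np.outer(ybar, ubar),
                    U.T @ U - n * np.outer(ubar, ubar),
                )
            )
        else:
            pidx = np.repeat(np.arange(n), counts)
            blocks.append(DenseBlock(y_s.copy(), t_s.copy(), pidx, u_s.copy()))
    return blocks


def group_blocks(blocks):
    """Pool homogeneous blocks sharing (S, n); pass dense blocks through."""
    groups: dict = {}
    dense = []
    for blk in blocks:
        if isinstance(blk, DenseBlock):
            dense.append(blk)
            continue
        key = (blk.S.tobytes(), blk.n)
        g = groups.get(key)
        if g is None:
            s, c = blk.Syy_c.shape[0], blk.Suu_c.shape[0]
            g = GroupedBlock(
                n=blk.n, k=0, S=blk.S,
                Syy_c=np.zeros((s, s)), Syu_c=np.zeros((s, c)),
                Suu_c=np.zeros((c, c)), B_yy=np.zeros((s, s)),
                B_yu=np.zeros((s, c)), B_uu=np.zeros((c, c)),
            )
            groups[key] = g
        g.k += 1
        g.Syy_c += blk.Syy_c
        g.Syu_c += blk.Syu_c
        g.Suu_c += blk.Suu_c
        g.B_yy += blk.n * np.outer(blk.ybar, blk.ybar)
        g.B_yu += blk.n * np.outer(blk.ybar, blk.ubar)
        g.B_uu += blk.n * np.outer(blk.ubar, blk.ubar)
    return list(groups.values()), dense


# ---------------------------------------------------------------------------
# parameter transform: theta <-> (Sigma_w, sigma_b2)

SB_LOG_FLOOR = -18.0  # exp(-18) ~ 1.5e-8: effectively a zero boundary


class ParamTransform:
    """Pack (Sigma_w, sigma_b2) into an unconstrained vector.

    Sigma_w = L L' with L lower triangular and log-parameterized diagonal
    (guarantees positive definiteness); sigma_b2 = exp(tau) elementwise
    (guarantees non-negativity; the zero boundary is approached as
    tau -> -inf and floored at ``SB_LOG_FLOOR``).
    """

    def __init__(self, p: int, estimate_between: bool):
        self.p = p
        self.estimate_between = estimate_between
        self.tril = np.tril_indices(p)
        self.n_chol = p * (p + 1) // 2
        self.n_params = self.n_chol + (p if estimate_between else 0)
        self._diag_mask = self.tril[0] == self.tril[1]

    def pack(self, sigma_within: np.ndarray, sigma_between: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(sigma_within)
        v = L[self.tril].copy()
        v[self._diag_mask] = np.log(v[self._diag_mask])
        if not self.estimate_between:
            return v
        tau = np.log(np.maximum(sigma_between, np.exp(SB_LOG_FLOOR)))
        return np.concatenate([v, np.maximum(tau, SB_LOG_FLOOR)])

    def unpack(self, theta: np.ndarray):
        L = np.zeros((self.p, self.p))
        v = theta[: self.n_chol].copy()
        v[self._diag_mask] = np.exp(v[self._diag_mask])
        L[self.tril] = v
        sigma_within = L @ L.T
        if self.estimate_between:
            sigma_between = np.exp(np.maximum(theta[self.n_chol:], SB_LOG_FLOOR))
        else:
            sigma_between = np.zeros(self.p)
        return sigma_within, sigma_between, L

    def chain_grad(self, d_sw: np.ndarray, d_sb2: np.ndarray, L: np.ndarray,
                   sigma_between: np.ndarray) -> np.ndarray:
        """Map gradients w.r.t. (Sigma_w, sigma_b2) to theta space."""
        GL = 2.0 * d_sw @ L
        g = GL[self.tril].copy()
        g[self._diag_mask] *= L[self.tril][self._diag_mask]
        if not self.estimate_between:
            return g
        return np.concatenate([g, d_sb2 * sigma_between])


# ---------------------------------------------------------------------------
# per-block computations


def _dense_cov(block: DenseBlock, sigma_within, sigma_between):
    """Full study covariance for a ragged block (brute-force assembly)."""
    same_p = block.pidx[:, None] == block.pidx[None, :]
    same_t = block.tests[:, None] == block.tests[None, :]
    cov = np.where(same_p, sigma_within[block.tests[:, None], block.tests[None, :]], 0.0)
    # diagonal: Sigma_w[t,t] + sigma_b2[t]; cross-participant same test:
    # sigma_b2[t]; same participant cross-test: Sigma_w[ti,tj]; else 0
    cov += np.where(same_t, sigma_between[block.tests][:, None], 0.0)
    return cov


def _dense_design(block: DenseBlock, p: int, n_design: int) -> np.ndarray:
    m = block.y.size
    X = np.zeros((m, n_design * p))
    rows = np.arange(m)
    for c in range(n_design):
        X[rows, c * p + block.tests] = block.U[:, c]
    return X


def _cross(Syy, Syu, Suu, Gs):
    """(Y - U Gs')'(Y - U Gs') from cross-products."""
    t = Syu @ Gs.T
    return Syy - t - t.T + (Gs @ Suu @ Gs.T)


class _Batch:
    """Grouped blocks of a common subset size, stacked for batched linalg."""

    def __init__(self, groups: list[GroupedBlock], p: int, n_design: int):
        self.S = np.stack([g.S for g in groups])            # (G, s)
        self.n = np.array([g.n for g in groups], float)
        self.k = np.array([g.k for g in groups], float)
        self.N = self.n * self.k
        self.Syy = np.stack([g.Syy_c for g in groups])
        self.Syu = np.stack([g.Syu_c for g in groups])
        self.Suu = np.stack([g.Suu_c for g in groups])
        self.Byy = np.stack([g.B_yy for g in groups])
        self.Byu = np.stack([g.B_yu for g in groups])
        self.Buu = np.stack([g.B_uu for g in groups])
        cols = np.arange(n_design)
        # global fixed-effect index for each group's local vec(Gs)
        self.gidx = (cols[None, :, None] * p + self.S[:, None, :]).reshape(
            len(groups), -1
        )


def prepare_blocks(blocks, p: int, n_design: int):
    """Group and batch homogeneous blocks; returns (batches, dense_blocks)."""
    grouped, dense = group_blocks(blocks)
    by_size: dict[int, list[GroupedBlock]] = {}
    for g in grouped:
        by_size.setdefault(g.S.size, []).append(g)
    batches = [_Batch(gs, p, n_design) for gs in by_size.values()]
    return batches, dense


def profiled_nll_grad(theta, blocks, transform: ParamTransform, n_design: int,
                      want_grad: bool = True, return_gamma: bool = False,
                      return_gls: bool = False):
    """Negative profiled log-likelihood (+ gradient in theta space).

    ``blocks`` is either a raw block list (from :func:`build_blocks`) or a
    pre-batched ``(batches, dense)`` pair from :func:`prepare_blocks`. Fixed
    effects are solved by GLS at the current variance parameters; by the
    envelope theorem the gradient of the profiled likelihood equals the
    partial gradient w.r.t. the variance parameters at that solution.
    """
    p = transform.p
    if isinstance(blocks, tuple):
        batches, dense = blocks
    else:
        batches, dense = prepare_blocks(blocks, p, n_design)
    sigma_within, sigma_between, L = transform.unpack(theta)
    q = n_design * p
    A = np.zeros((q, q))
    b = np.zeros(q)
    bcache, dcache = [], []

    for bt in batches:
        nG, s = bt.S.shape
        ar = np.arange(s)
        V1 = sigma_within[bt.S[:, :, None], bt.S[:, None, :]]
        Vn = V1.copy()
        Vn[:, ar, ar] += bt.n[:, None] * sigma_between[bt.S]
        c1 = np.linalg.cholesky(V1)
        cn = np.linalg.cholesky(Vn)
        V1inv = np.linalg.inv(V1)
        Vninv = np.linalg.inv(Vn)
        ld1 = 2.0 * np.log(c1[:, ar, ar]).sum(axis=1)
        ldn = 2.0 * np.log(cn[:, ar, ar]).sum(axis=1)
        # kron(Suu_c, V1inv) + kron(B_uu, Vninv), batched over groups
        kronA = (
            np.einsum("gab,gcd->gacbd", bt.Suu, V1inv)
            + np.einsum("gab,gcd->gacbd", bt.Buu, Vninv)
        ).reshape(nG, n_design * s, n_design * s)
        bloc = (V1inv @ bt.Syu + Vninv @ bt.Byu).transpose(0, 2, 1).reshape(nG, -1)
        for i in range(nG):
            ix = bt.gidx[i]
            A[np.ix_(ix, ix)] += kronA[i]
            b[ix] += bloc[i]
        bcache.append((V1inv, Vninv, ld1, ldn))

    for blk in dense:
        cov = _dense_cov(blk, sigma_within, sigma_between)
        cf = cho_factor(cov, lower=True)
        Sinv = cho_solve(cf, np.eye(blk.y.size))
        ld = 2.0 * np.log(np.diag(cf[0])).sum()
        X = _dense_design(blk, p, n_design)
        SiX = Sinv @ X
        A += X.T @ SiX
        b += SiX.T @ blk.y
        dcache.append((Sinv, ld, X))

    try:
        g = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        g, *_ = np.linalg.lstsq(A, b, rcond=None)
    G = g.reshape(n_design, p).T  # p x n_design fixed-effect matrix

    ll = 0.0
    d_sw = np.zeros((p, p)) if want_grad else None
    d_sb2 = np.zeros(p) if want_grad else None

    for bt, (V1inv, Vninv, ld1, ldn) in zip(batches, bcache):
        nG, s = bt.S.shape
        ar = np.arange(s)
        Gs = G[bt.S]  # (G, s, n_design)
        tw = np.einsum("gsc,gtc->gst", bt.Syu, Gs)
        W = bt.Syy - tw - tw.transpose(0, 2, 1) + Gs @ bt.Suu @ Gs.transpose(0, 2, 1)
        tm = np.einsum("gsc,gtc->gst", bt.Byu, Gs)
        M = bt.Byy - tm - tm.transpose(0, 2, 1) + Gs @ bt.Buu @ Gs.transpose(0, 2, 1)
        ll += -0.5 * (
            (bt.N * s).sum() * _LOG2PI
            + ((bt.N - bt.k) * ld1).sum()
            + (bt.k * ldn).sum()
            + np.einsum("gij,gij->", V1inv, W)
            + np.einsum("gij,gij->", Vninv, M)
        )
        if want_grad:
            dV1 = -0.5 * (
                (bt.N - bt.k)[:, None, None] * V1inv - V1inv @ W @ V1inv
            )
            dVn = -0.5 * (bt.k[:, None, None] * Vninv - Vninv @ M @ Vninv)
            dsum = dV1 + dVn
            for i in range(nG):
                d_sw[np.ix_(bt.S[i], bt.S[i])] += dsum[i]
            np.add.at(d_sb2, bt.S, bt.n[:, None] * dVn[:, ar, ar])

    for blk, (Sinv, ld, X) in zip(dense, dcache):
        r = blk.y - X @ g
        Sir = Sinv @ r
        ll += -0.5 * (blk.y.size * _LOG2PI + ld + r @ Sir)
        if want_grad:
            Dfull = -0.5 * (Sinv - np.outer(Sir, Sir))
            same_p = blk.pidx[:, None] == blk.pidx[None, :]
            ii, jj = np.where(same_p)
            np.add.at(d_sw, (blk.tests[ii], blk.tests[jj]), Dfull[ii, jj])
            for t in range(p):
                mask = blk.tests == t
                if mask.any():
                    d_sb2[t] += Dfull[np.ix_(mask, mask)].sum()

    out = [-ll]
    if want_grad:
        grad = -transform.chain_grad(d_sw, d_sb2, L, sigma_between)
        out.append(grad)
    if return_gamma:
        out.append(G)
    if return_gls:
        out.append(A)
    return tuple(out) if len(out) > 1 else out[0]


def loglik_at(gamma: np.ndarray, sigma_within: np.ndarray, sigma_between: np.ndarray,
              blocks, n_design: int) -> float:
    """Log-likelihood at *given* parameters (no profiling, no grouping)."""
    p = sigma_within.shape[0]
    G = np.asarray(gamma, float).reshape(p, n_design)
    g = G.T.ravel()
    ll = 0.0
    for blk in blocks:
        if isinstance(blk, HomogeneousBlock):
            S, n = blk.S, blk.n
            V1 = sigma_within[np.ix_(S, S)]
            Vn = V1 + n * np.diag(sigma_between[S])
            c1 = cho_factor(V1, lower=True)
            cn = cho_factor(Vn, lower=True)
            Gs = G[S]
            W = _cross(blk.Syy_c, blk.Syu_c, blk.Suu_c, Gs)
            rbar = blk.ybar - Gs @ blk.ubar
            ll += -0.5 * (
                n * S.size * _LOG2PI
                + (n - 1) * 2.0 * np.log(np.diag(c1[0])).sum()
                + 2.0 * np.log(np.diag(cn[0])).sum()
                + np.trace(cho_solve(c1, W))
                + n * rbar @ cho_solve(cn, rbar)
            )
        else:
            cov = _dense_cov(blk, sigma_within, sigma_between)
            cf = cho_factor(cov, lower=True)
            X = _dense_design(blk, p, n_design)
            r = blk.y - X @ g
            ll += -0.5 * (
                blk.y.size * _LOG2PI
                + 2.0 * np.log(np.diag(cf[0])).sum()
                + r @ cho_solve(cf, r)
            )
    return float(ll)


def study_loglik(gamma, sigma_within, sigma_between, study_frame: pd.DataFrame,
                 covariates: tuple[str, ...] = ("age", "gender", "education")) -> float:
    """Log-density of one study's stacked score vector at given parameters.

    The study covariance couples participants through the shared study
    intercept errors: scores of any two participants on the same test m
    covary by ``sigma_between[m]``. Returns ``-inf`` if the implied
    covariance is not positive definite at these parameters.
    """
    sigma_within = np.asarray(sigma_within, float)
    sigma_between = np.asarray(sigma_between, float)
    blocks = build_blocks(study_frame, tuple(covariates))
    if len(blocks) != 1:
        raise ValueError("study_frame must contain exactly one study")
    try:
        return loglik_at(gamma, sigma_within, sigma_between, blocks, 1 + len(covariates))
    except np.linalg.LinAlgError:
        return -np.inf


# ---------------------------------------------------------------------------
# moment-based starting values


def starting_values(frame: pd.DataFrame, p: int, covariates: tuple[str, ...]):
    """Cheap method-of-moments starts for the FIML optimizer.

    Fixed effects from per-test least squares ignoring nesting; Sigma_w from
    pairwise-complete within-study-centered residual covariances (eigenvalue
    floor keeps it positive definite); sigma_b2 from the between-study
    variance of per-study mean residuals, floored at 1e-4.
    """
    cols = list(covariates)
    nc = 1 + len(cols)
    G0 = np.zeros((p, nc))
    resid = np.empty(len(frame))
    tests = frame["test"].to_numpy(int)
    y = frame["score"].to_numpy(float)
    U = np.ones((len(frame), nc))
    if cols:
        U[:, 1:] = frame[cols].to_numpy(float)
    for m in range(p):
        mask = tests == m + 1
        Um, ym = U[mask], y[mask]
        if mask.sum() > nc:
            coef, *_ = np.linalg.lstsq(Um, ym, rcond=None)
        else:
            coef = np.zeros(nc)
            coef[0] = ym.mean()
        G0[m] = coef
        resid[mask] = ym - Um @ coef

    rf = frame[["study", "ID", "test"]].copy()
    rf["resid"] = resid
    study_test_mean = rf.groupby(["study", "test"])["resid"].transform("mean")
    rf["resid_w"] = rf["resid"] - study_test_mean

    wide = rf.pivot_table(index=["study", "ID"], columns="test", values="resid_w")
    wide = wide.reindex(columns=range(1, p + 1))
    sw0 = wide.cov(min_periods=2).to_numpy()
    diag_fill = np.nanmean(np.diag(sw0)) if np.isfinite(np.diag(sw0)).any() else 1.0
    sw0 = np.where(np.isfinite(sw0), sw0, 0.0)
    for m in range(p):
        if sw0[m, m] <= 0:
            sw0[m, m] = diag_fill
    # eigenvalue floor: pairwise-complete covariances need not be PD
    evals, evecs = np.linalg.eigh((sw0 + sw0.T) / 2.0)
    floor = max(1e-3 * evals.max(), 1e-6)
    sw0 = (evecs * np.maximum(evals, floor)) @ evecs.T

    means = rf.groupby(["study", "test"])["resid"].agg(["mean", "count"]).reset_index()
    sb0 = np.full(p, 1e-4)
    for m in range(p):
        sub = means[means["test"] == m + 1]
        if len(sub) > 1:
            raw = sub["mean"].var(ddof=1) - sw0[m, m] / max(sub["count"].mean(), 1.0)
            sb0[m] = max(raw, 1e-4)
    return G0, sw0, sb0


def check_estimability(coverage_counts: np.ndarray) -> None:
    p = coverage_counts.shape[0]
    bad = [
        (i + 1, j + 1)
        for i in range(p)
        for j in range(i + 1, p)
        if coverage_counts[i, j] == 0
    ]
    if bad:
        raise EstimabilityError(
            "unrestricted within-study covariance is inestimable: test pair(s) "
            f"{bad} never administered in the same study"
        )
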