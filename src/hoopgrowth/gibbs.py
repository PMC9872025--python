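"""Blocked Gibbs sampler for Gaussian linear mixed models.

Model
-----
    y = X b + sum_k Z_k u_k + e,    e ~ N(0, sigma^2 I)

with independent group-level coefficient columns u_{k,c} ~ N(0, tau_{k,c}^2)
(diagonal group-level covariance), weakly informative priors

    b_j        ~ Normal(0, 5)
    tau_{k,c}  ~ Exponential(1)
    sigma      ~ half-Student-t(3, 0, 2.5)

Sampling scheme (one sweep):

1. Exact joint draw of *all* coefficients (b and every u) from their Gaussian
   full conditional.  One grouping factor may be designated "big" (typically
   the player factor, hundreds of levels): because its levels partition the
   rows, its precision block is block-diagonal and the joint draw is done via
   a Schur complement with batched per-level Cholesky factors, keeping the
   dense solve at the size of the remaining design.
2. Collapsed scale updates, block by block: because each grouping factor
   partitions the rows, the block's effects can be integrated out
   analytically (Woodbury identity per level), and each of its SDs tau is
   slice-sampled from the *marginal* conditional p(tau | y, rest-of-model)
   - no conditioning on the block's effects, hence no funnel-shaped
   tau/u coupling.  The block's effects are then redrawn exactly from
   their Gaussian conditional, which keeps the kernel a valid
   partially-collapsed Gibbs sampler.
3. sigma: slice-sampling update with the largest block's effects likewise
   integrated out (they dominate the sigma/effects coupling).

All randomness flows from one integer seed through per-chain
``numpy.random.Generator`` streams, so identical seeds give bit-identical
draws.  The sampler has no divergence concept (no trajectory integration);
the divergence count it reports is identically zero.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

FIXED_PRIOR_SD = 5.0
TAU_PRIOR_RATE = 1.0
SIGMA_PRIOR_DF = 3.0
SIGMA_PRIOR_SCALE = 2.5
_TINY = 1e-12


@dataclasses.dataclass
class RandomBlockDesign:
    """One grouping factor with (possibly several) varying coefficients.

    ``groups[i]`` indexes the level of row ``i``; ``covariates[i, c]`` is the
    within-block regressor for coefficient ``c`` (e.g. ``[1, mid, end]`` for a
    varying intercept plus two phase slopes).
    """

    name: str
    levels: list[str]
    groups: np.ndarray
    covariates: np.ndarray
    coef_names: list[str]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_coefs(self) -> int:
        return self.covariates.shape[1]


#: slice-sampling domain for log-scale parameters; the exponential /
#: half-Student-t priors put no appreciable mass outside it, and bounding the
#: domain keeps the marginal-likelihood algebra in a well-conditioned regime
LOG_SCALE_LO = np.log(1e-7)
LOG_SCALE_HI = np.log(1e3)


def slice_sample(logf: Callable[[float], float], x0: float, rng: np.random.Generator,
                 width: float = 1.0, max_steps: int = 50,
                 lo: float = -np.inf, hi: float = np.inf) -> float:
    """Univariate slice sampler with stepping-out and shrinkage (Neal 2003).

    ``lo``/``hi`` truncate the support; the interval never steps outside them.
    """
    x0 = min(max(x0, lo), hi)
    f0 = logf(x0)
    log_y = f0 - rng.exponential()
    u = rng.uniform()
    left = max(x0 - width * u, lo)
    right = min(left + width, hi)
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and left > lo and logf(left) > log_y:
        left = max(left - width, lo)
        j -= 1
    while k > 0 and right < hi and logf(right) > log_y:
        right = min(right + width, hi)
        k -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-13:  # degenerate slice; keep the current point
            return x0


def _log_half_student_t(x: float, df: float, scale: float) -> float:
    return -0.5 * (df + 1.0) * np.log1p((x / scale) ** 2 / df)


class GibbsLMM:
    """Gibbs sampler for one Gaussian mixed model.

    Parameters
    ----------
    X, x_names
        Fixed-effects design (n, p) and column names.
    blocks
        Random-effect blocks.  The block whose name equals ``big_block`` is
        handled with batched per-level factorizations; it must partition rows
        (every row belongs to exactly one of its levels).
    y
        Response vector (no missing values).
    fixed_tau
        Optional map ``"{block}__{coef}" -> value`` pinning a group SD (no
        update); used e.g. to verify the complete-pooling limit.
    """

    def __init__(
        self,
        X: np.ndarray,
        x_names: Sequence[str],
        blocks: Sequence[RandomBlockDesign],
        y: np.ndarray,
        big_block: str | None = None,
        fixed_tau: dict[str, float] | None = None,
        fixed_sigma: float | None = None,
        scale_sweeps: int = 3,
    ) -> None:
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite outcome values passed to the sampler")
        n = y.size
        self.y = y
        self.n = n
        self.fixed_tau = dict(fixed_tau or {})
        self.fixed_sigma = fixed_sigma
        self.scale_sweeps = int(scale_sweeps)

        self.big = None
        dense_blocks: list[RandomBlockDesign] = []
        for b in blocks:
            if big_block is not None and b.name == big_block:
                self.big = b
            else:
                dense_blocks.append(b)
        self.dense_blocks = dense_blocks

        # --- dense part F = [X | Z for each dense block], group-major columns
        cols: list[np.ndarray] = [X]
        names: list[str] = list(x_names)
        d_prior: list[float] = [1.0 / FIXED_PRIOR_SD**2] * X.shape[1]
        self._dense_slices: dict[str, tuple[int, RandomBlockDesign]] = {}
        self.n_fixed = X.shape[1]
        offset = X.shape[1]
        for b in dense_blocks:
            k, G = b.n_coefs, b.n_levels
            Z = np.zeros((n, G * k))
            rows = np.arange(n)
            for c in range(k):
                Z[rows, b.groups * k + c] = b.covariates[:, c]
            cols.append(Z)
            self._dense_slices[b.name] = (offset, b)
            for g in range(G):
                for c in range(k):
                    names.append(f"r_{b.name}[{b.levels[g]},{b.coef_names[c]}]")
            d_prior += [np.nan] * (G * k)  # filled per-sweep from tau
            offset += G * k
        F = np.concatenate(cols, axis=1)
        self.F = F
        self.f_names = names
        self.p_f = F.shape[1]
        self._d_fixed_part = np.array(d_prior)
        self.FtF = F.T @ F
        self.Fty = F.T @ y

        # --- big block: batched per-level sufficient statistics
        if self.big is not None:
            b = self.big
            k, G = b.n_coefs, b.n_levels
            self.B_pp = np.zeros((G, k, k))
            np.add.at(self.B_pp, b.groups, b.covariates[:, :, None] * b.covariates[:, None, :])
            self.M_fp = np.zeros((G, k, self.p_f))
            np.add.at(self.M_fp, b.groups, b.covariates[:, :, None] * F[:, None, :])
            self.bp = np.zeros((G, k))
            np.add.at(self.bp, b.groups, b.covariates * y[:, None])
            self.p_names = [
                f"r_{b.name}[{lv},{cn}]" for lv in b.levels for cn in b.coef_names
            ]
        else:
            self.p_names = []

        # --- scale parameter bookkeeping
        self.tau_keys: list[tuple[str, str]] = []
        for b in list(dense_blocks) + ([self.big] if self.big is not None else []):
            for cn in b.coef_names:
                self.tau_keys.append((b.name, cn))
        self.sd_names = [f"sd_{b}__{c}" for b, c in self.tau_keys]
        self.param_names = self.f_names + self.p_names + self.sd_names + ["sigma"]

    # ------------------------------------------------------------------
    def _joint_coef_draw(self, tau: dict[tuple[str, str], float], sigma: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Exact draw of (theta_f, theta_big) from the Gaussian full conditional."""
        inv_s2 = 1.0 / sigma**2
        d = self._d_fixed_part.copy()
        for name, (off, b) in self._dense_slices.items():
            prec = np.array([1.0 / max(tau[(name, cn)], _TINY) ** 2 for cn in b.coef_names])
            d[off: off + b.n_levels * b.n_coefs] = np.tile(prec, b.n_levels)

        A_ff = self.FtF * inv_s2
        A_ff[np.diag_indices_from(A_ff)] += d
        b_f = self.Fty * inv_s2

        if self.big is None:
            L = np.linalg.cholesky(A_ff)
            mean = np.linalg.solve(A_ff, b_f)
            z = rng.standard_normal(self.p_f)
            theta_f = mean + np.linalg.solve(L.T, z)
            return theta_f, np.zeros((0, 0))

        bb = self.big
        k, G = bb.n_coefs, bb.n_levels
        prec_p = np.array([1.0 / max(tau[(bb.name, cn)], _TINY) ** 2 for cn in bb.coef_names])
        A_pp = self.B_pp * inv_s2 + np.diag(prec_p)[None, :, :]
        M = self.M_fp * inv_s2                     # (G, k, p_f): rows of A_pf
        b_p = self.bp * inv_s2                     # (G, k)

        C = np.linalg.cholesky(A_pp)               # (G, k, k)
        N = np.linalg.solve(A_pp, M)               # A_pp^{-1} A_pf
        u = np.linalg.solve(A_pp, b_p[:, :, None])[:, :, 0]

        Mk = M.reshape(G * k, self.p_f)
        Nk = N.reshape(G * k, self.p_f)
        S = A_ff - Mk.T @ Nk
        b_s = b_f - Mk.T @ u.reshape(G * k)

        L = np.linalg.cholesky(S)
        mean_f = np.linalg.solve(S, b_s)
        theta_f = mean_f + np.linalg.solve(L.T, rng.standard_normal(self.p_f))

        mean_p = u - N @ theta_f
        z = rng.standard_normal((G, k, 1))
        CT = np.transpose(C, (0, 2, 1))
        theta_p = mean_p + np.linalg.solve(CT, z)[:, :, 0]
        return theta_f, theta_p

    # ------------------------------------------------------------------
    def _fitted(self, theta_f: np.ndarray, theta_p: np.ndarray) -> np.ndarray:
        fit = self.F @ theta_f
        if self.big is not None:
            fit = fit + np.einsum("nk,nk->n", self.big.covariates, theta_p[self.big.groups])
        return fit

    # ------------------------------------------------------------------
    def _block_theta(self, block: RandomBlockDesign, theta_f: np.ndarray,
                     theta_p: np.ndarray) -> np.ndarray:
        """Current effects of a block as a (levels, coefs) array."""
        if self.big is not None and block.name == self.big.name:
            return theta_p
        off, b = self._dense_slices[block.name]
        return theta_f[off: off + b.n_levels * b.n_coefs].reshape(b.n_levels, b.n_coefs)

    def _write_block_theta(self, block: RandomBlockDesign, values: np.ndarray,
                           theta_f: np.ndarray, theta_p: np.ndarray) -> None:
        if self.big is not None and block.name == self.big.name:
            theta_p[:, :] = values
        else:
            off, b = self._dense_slices[block.name]
            theta_f[off: off + b.n_levels * b.n_coefs] = values.reshape(-1)

    def _collapsed_block_update(
        self, block: RandomBlockDesign, tau: dict, sigma: float,
        theta_f: np.ndarray, theta_p: np.ndarray, resid: np.ndarray,
        rng: np.random.Generator, update_sigma: bool,
    ) -> tuple[np.ndarray, float]:
        """Marginal slice updates of the block's SDs (and optionally sigma),
        then an exact redraw of the block's effects.

        With the block's levels partitioning the rows, the residual vector
        excluding this block satisfies  r_g = V_g u_g + e_g  independently per
        level g, so integrating out u ~ N(0, diag(tau^2)) gives a marginal
        likelihood evaluable with batched k x k factorizations.
        """
        b = block
        k, G = b.n_coefs, b.n_levels
        u_cur = self._block_theta(b, theta_f, theta_p)
        contrib = np.einsum("nk,nk->n", b.covariates, u_cur[b.groups])
        r_excl = resid + contrib

        VtV = np.zeros((G, k, k))
        np.add.at(VtV, b.groups, b.covariates[:, :, None] * b.covariates[:, None, :])
        Vtr = np.zeros((G, k))
        np.add.at(Vtr, b.groups, b.covariates * r_excl[:, None])
        rr = float(r_excl @ r_excl)
        n = self.n

        # marginal log-likelihood pieces, with P_g = sigma^2 D^{-1} + V_g'V_g:
        #   -2 loglik = n log s2 + sum_g [log|D| + log|P_g| - k log s2]
        #               + (rr - sum_g Vtr_g' P_g^{-1} Vtr_g) / s2
        tau_vec = np.array([tau[(b.name, cn)] for cn in b.coef_names])
        s2 = sigma * sigma

        for ci, cn in enumerate(b.coef_names):
            sd_key = f"sd_{b.name}__{cn}"
            if sd_key in self.fixed_tau:
                tau_vec[ci] = self.fixed_tau[sd_key]
                tau[(b.name, cn)] = tau_vec[ci]
                continue
            # changing tau_ci from t0 to t perturbs P by a rank-one term
            # gamma(t) e_ci e_ci' with gamma = s2/t^2 - s2/t0^2; logdet and the
            # quadratic then follow from one factorization of the current P
            d = np.maximum(tau_vec, _TINY) ** 2
            t0 = max(tau_vec[ci], _TINY)
            P = VtV + np.diag(s2 / d)[None, :, :]
            C = np.linalg.cholesky(P)
            logdetP0 = 2.0 * float(np.sum(np.log(np.einsum("gii->gi", C))))
            e = np.zeros(k)
            e[ci] = 1.0
            a = np.linalg.solve(P, np.broadcast_to(e, (G, k))[:, :, None])[:, :, 0]
            alpha = a[:, ci]                       # e' P^{-1} e per level
            w0 = np.linalg.solve(P, Vtr[:, :, None])[:, :, 0]
            base_quad = float(np.einsum("gk,gk->", Vtr, w0))
            beta = np.einsum("gk,gk->g", Vtr, a)   # e' P^{-1} Vtr per level
            log_d_rest = float(np.sum(np.log(np.delete(d, ci))))
            # den(t) = 1 + gamma(t)*alpha rearranged as c0 + (s2/t^2)*alpha:
            # c0 = 1 - (s2/t0^2)*alpha is >= 0 exactly (alpha <= t0^2/s2) but
            # suffers cancellation for levels with no information on this
            # coefficient, so it is clamped at 0 and the decaying positive
            # term keeps den strictly positive and the algebra stable
            c0 = np.maximum(1.0 - (s2 / (t0 * t0)) * alpha, 0.0)

            def logf(x: float) -> float:
                # terms constant in tau (n log s2, -Gk log s2) are omitted
                t = np.exp(x)
                gamma = s2 / (t * t) - s2 / (t0 * t0)
                den = c0 + (s2 / (t * t)) * alpha
                safe = den > 0
                logdetP = logdetP0 + float(np.sum(np.log(den[safe])))
                ratio = np.zeros_like(beta)
                np.divide(beta * beta, den, out=ratio, where=safe)
                quad = base_quad - gamma * float(np.sum(ratio))
                ll = -0.5 * (G * (log_d_rest + 2.0 * np.log(t)) + logdetP
                             + (rr - quad) / s2)
                return ll - TAU_PRIOR_RATE * t + x

            tau_vec[ci] = float(np.exp(slice_sample(
                logf, np.log(max(tau_vec[ci], 1e-6)), rng,
                lo=LOG_SCALE_LO, hi=LOG_SCALE_HI)))
            tau[(b.name, cn)] = tau_vec[ci]

        if update_sigma and self.fixed_sigma is None:
            # P(s) = diag(1/sqrt(d)) (B + s^2 I) diag(1/sqrt(d)),
            # B = diag(sqrt(d)) VtV diag(sqrt(d)): one eigendecomposition makes
            # every sigma evaluation O(G k) scalar work
            d = np.maximum(tau_vec, _TINY) ** 2
            sq = np.sqrt(d)
            B = VtV * sq[None, :, None] * sq[None, None, :]
            lam, U = np.linalg.eigh(B)
            lam = np.maximum(lam, 0.0)  # clip tiny negative eigenvalues (B is psd)
            vt = np.einsum("gjk,gj->gk", U, Vtr * sq[None, :])
            vt2 = vt * vt
            log_d_sum = float(np.sum(np.log(d)))

            def logf_s(x: float) -> float:
                s = np.exp(x)
                ss = s * s
                logdetP = -G * log_d_sum + float(np.sum(np.log(lam + ss)))
                quad = float(np.sum(vt2 / (lam + ss)))
                ll = -0.5 * (n * np.log(ss) + G * log_d_sum + logdetP
                             - G * k * np.log(ss) + (rr - quad) / ss)
                return ll + _log_half_student_t(s, SIGMA_PRIOR_DF, SIGMA_PRIOR_SCALE) + x

            sigma = float(np.exp(slice_sample(logf_s, np.log(max(sigma, 1e-6)), rng,
                                              lo=LOG_SCALE_LO, hi=LOG_SCALE_HI)))
        elif update_sigma and self.fixed_sigma is not None:
            sigma = self.fixed_sigma

        # exact conditional redraw of the block's effects given the new scales
        d = np.maximum(tau_vec, _TINY) ** 2
        s2 = sigma * sigma
        Q = VtV / s2 + np.diag(1.0 / d)[None, :, :]
        C = np.linalg.cholesky(Q)
        mean = np.linalg.solve(Q, (Vtr / s2)[:, :, None])[:, :, 0]
        z = rng.standard_normal((G, k, 1))
        u_new = mean + np.linalg.solve(np.transpose(C, (0, 2, 1)), z)[:, :, 0]
        self._write_block_theta(b, u_new, theta_f, theta_p)
        resid = r_excl - np.einsum("nk,nk->n", b.covariates, u_new[b.groups])
        return resid, sigma

    def _update_sigma_plain(self, resid: np.ndarray, sigma: float,
                            rng: np.random.Generator) -> float:
        if self.fixed_sigma is not None:
            return self.fixed_sigma
        ss = float(resid @ resid)
        n = self.n

        def logf(x: float) -> float:
            s = np.exp(x)
            return -n * x - ss / (2.0 * s * s) + _log_half_student_t(s, SIGMA_PRIOR_DF, SIGMA_PRIOR_SCALE) + x

        return float(np.exp(slice_sample(logf, np.log(max(sigma, 1e-6)), rng,
                                         lo=LOG_SCALE_LO, hi=LOG_SCALE_HI)))

    # ------------------------------------------------------------------
    def sample(self, n_chains: int = 4, n_iter: int = 2000, n_warmup: int = 1000,
               seed: int = 0) -> dict[str, np.ndarray]:
        """Run the sampler; returns ``{parameter: (chains, kept_draws) array}``.

        ``n_iter`` counts total sweeps per chain, of which the first
        ``n_warmup`` are discarded.
        """
        if n_warmup >= n_iter:
            raise ValueError("warm-up length must be smaller than the iteration count")
        if n_chains < 1:
            raise ValueError("need at least one chain")
        kept = n_iter - n_warmup
        all_blocks = list(self.dense_blocks) + ([self.big] if self.big is not None else [])
        # sigma is updated jointly with the block that couples to it most
        # strongly (the big one when present)
        sigma_block = self.big.name if self.big is not None else (
            all_blocks[-1].name if all_blocks else None)

        out = np.empty((n_chains, kept, len(self.param_names)))
        y_sd = float(np.std(self.y)) or 1.0
        for chain in range(n_chains):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), chain]))
            tau = {key: float(0.5 * np.exp(0.5 * rng.standard_normal())) for key in self.tau_keys}
            for key in self.tau_keys:
                sd_key = f"sd_{key[0]}__{key[1]}"
                if sd_key in self.fixed_tau:
                    tau[key] = self.fixed_tau[sd_key]
            sigma = self.fixed_sigma if self.fixed_sigma is not None else float(
                y_sd * np.exp(0.3 * rng.standard_normal())
            )
            theta_f = np.zeros(self.p_f)
            theta_p = np.zeros((self.big.n_levels, self.big.n_coefs)) if self.big is not None else np.zeros((0, 0))

            for it in range(n_iter):
                theta_f, theta_p = self._joint_coef_draw(tau, sigma, rng)
                resid = self.y - self._fitted(theta_f, theta_p)
                for _ in range(self.scale_sweeps):
                    for b in all_blocks:
                        resid, sigma = self._collapsed_block_update(
                            b, tau, sigma, theta_f, theta_p, resid, rng,
                            update_sigma=(b.name == sigma_block),
                        )
                    if sigma_block is None:
                        sigma = self._update_sigma_plain(resid, sigma, rng)
                if it >= n_warmup:
                    j = it - n_warmup
                    row = out[chain, j]
                    row[: self.p_f] = theta_f
                    if self.big is not None:
                        row[self.p_f: self.p_f + theta_p.size] = theta_p.reshape(-1)
                    base = self.p_f + (theta_p.size if self.big is not None else 0)
                    for t, key in enumerate(self.tau_keys):
                        row[base + t] = tau[key]
                    row[-1] = sigma

        return {name: out[:, :, i].copy() for i, name in enumerate(self.param_names)}
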