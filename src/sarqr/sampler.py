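"""Metropolis–Hastings-within-Gibbs sampler with reversible-jump knot moves.

One sweep updates, in order: the latent mixing variables e (exact GIG draws);
the ALD scale delta0 (inverse gamma); the spatial coefficient rho (truncated-
Cauchy random-walk MH with an arctan truncation correction); the linear
coefficients beta (multivariate normal); then per varying coefficient j the
knot configuration (k_j, xi_j) by a reversible-jump birth/death/move step on
the gamma_j-collapsed marginal, gamma_j by composition from its conditional
normal, and tau_j (inverse gamma); finally tau0.

The movement step is a hit-and-run relocation of *all* knots: a uniform
direction on the unit sphere, a signed step from a Cauchy truncated to the
feasible interval, and an arctan ratio correcting the asymmetric truncation.
Proposal scales (sigma_rho and per-j sigma_move) adapt toward a 25%
acceptance rate during burn-in via Robbins–Monro recursions and are frozen
afterwards, so the retained chain is a fixed Markov kernel.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .ald import (
    LATENT_FLOOR,
    QuantileConstants,
    sample_gig,
    trunc_cauchy_rvs,
    trunc_cauchy_weight,
)
from .model import ChainState
from .splines import SplineState, basis_matrix

__all__ = ["GibbsSampler", "run_chain", "move_probabilities"]


def move_probabilities(k, max_knots):
    """(p_birth, p_death, p_move) at knot count k.

    (1/3, 1/3, 1/3) in the interior; birth-only at k=0 (a move with no knots
    is vacuous); no birth at the cap.
    """
    if k == 0:
        return (1.0, 0.0, 0.0) if max_knots > 0 else (0.0, 0.0, 0.0)
    if k >= max_knots:
        return 0.0, 0.5, 0.5
    return 1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0


def _invgamma(shape, scale, rng):
    """Draw from IG(shape, scale) with density ~ x^{-shape-1} exp(-scale/x)."""
    return scale / rng.gamma(shape, 1.0)


class GibbsSampler:
    """Mutable sampler bound to a :class:`~sarqr.model.QuantileSAR` model.

    Exposes every conditional update individually (used heavily by the
    distributional tests with frozen blocks) and a full :meth:`sweep`.
    """

    def __init__(self, model, rng, init=None, target_accept=0.25):
        self.model = model
        self.data = model.data
        self.priors = model.priors
        self.configs = model.configs
        self.qc = QuantileConstants.from_tau(model.tau)
        self.rng = rng
        self.target_accept = target_accept
        self.adapting = False
        self._adapt_count = {}
        self._pending = None

        d = self.data
        if not (np.isfinite(d.weights.rho_lower) and np.isfinite(d.weights.rho_upper)):
            raise ValueError(
                "weight matrix spectrum gives an unbounded rho support; "
                "sampling requires eigenvalues on both sides of zero"
            )
        self.Wy = d.weights.lag(d.y)
        self.state = self._initial_state(init)
        # per-block derived caches
        self._refresh_design()
        self._refresh_einv()
        self._refresh_ytilde()
        self.accept = {
            "rho": np.zeros(2, dtype=int),       # [accepts, proposals]
            "move": np.zeros(2, dtype=int),
            "birth": np.zeros(2, dtype=int),
            "death": np.zeros(2, dtype=int),
        }

    # ------------------------------------------------------------------
    # initialization and caches
    # ------------------------------------------------------------------
    def _initial_state(self, init):
        d, pr, rng = self.data, self.priors, self.rng
        wm = d.weights
        over = dict(init or {})
        rho = over.get("rho", rng.uniform(wm.rho_lower, wm.rho_upper))
        delta0 = over.get("delta0", float(np.clip(_invgamma(pr.r0 / 2, pr.s0_sq / 2, rng), 1e-2, 1e2)))
        tau0 = over.get("tau0", float(np.clip(_invgamma(pr.r_tau / 2, pr.s_tau_sq / 2, rng), 1e-3, 1e2)))
        beta = np.asarray(over.get("beta", rng.normal(0.0, np.sqrt(tau0), d.p)), dtype=float)
        e = np.asarray(over.get("e", np.maximum(rng.exponential(delta0, d.n), LATENT_FLOOR)), dtype=float)
        splines = over.get("splines")
        if splines is None:
            splines = []
            for cfg in self.configs:
                k = min(int(rng.poisson(cfg.poisson_mean)), cfg.max_knots)
                knots = self._draw_valid_knots(cfg, k, rng)
                tau_j = float(np.clip(_invgamma(pr.r_tau / 2, pr.s_tau_sq / 2, rng), 1e-3, 1e2))
                gamma = rng.normal(0.0, np.sqrt(tau_j), cfg.n_basis(knots.size))
                splines.append(SplineState(knots=knots, gamma=gamma, tau=tau_j))
        else:
            splines = [s.copy() for s in splines]
        sigma_rho = over.get("sigma_rho", 0.1 * (wm.rho_upper - wm.rho_lower))
        sigma_move = np.asarray(
            over.get("sigma_move", [0.1 * cfg.span for cfg in self.configs]), dtype=float
        )
        st = ChainState(rho=float(rho), beta=beta, delta0=float(delta0), tau0=float(tau0),
                        splines=splines, e=e, sigma_rho=float(sigma_rho), sigma_move=sigma_move)
        st.validate(wm)
        return st

    @staticmethod
    def _draw_valid_knots(cfg, k, rng):
        for k_try in range(k, -1, -1):
            for _ in range(50):
                knots = np.sort(rng.uniform(cfg.lower, cfg.upper, k_try))
                if cfg.validate_knots(knots):
                    return knots
        return np.empty(0)

    def _refresh_design(self):
        self.D = []
        self.fitted_j = []
        for j, (cfg, s) in enumerate(zip(self.configs, self.state.splines)):
            Dj = self.data.Z[:, j : j + 1] * basis_matrix(self.data.U[:, j], cfg, s.knots)
            self.D.append(Dj)
            self.fitted_j.append(Dj @ s.gamma)
        self.fitted = np.sum(self.fitted_j, axis=0) if self.fitted_j else np.zeros(self.data.n)

    def _refresh_einv(self):
        self.einv = 1.0 / (self.qc.m2 * self.state.delta0 * self.state.e)

    def _refresh_ytilde(self):
        self.y_tilde = self.data.y - self.state.rho * self.Wy

    # ------------------------------------------------------------------
    # conditional updates
    # ------------------------------------------------------------------
    def update_latent_e(self):
        """e_i ~ GIG(1/2, a_e, b_e) with a_e^2 = resid^2/(m2 delta0),
        b_e^2 = m1^2/(m2 delta0) + 2/delta0."""
        st, qc = self.state, self.qc
        resid = self.y_tilde - self.data.X @ st.beta - self.fitted
        md = qc.m2 * st.delta0
        a = np.abs(resid) / np.sqrt(md)
        b = np.sqrt(qc.m1**2 / md + 2.0 / st.delta0)
        st.e = sample_gig(0.5, a, np.full_like(a, b), self.rng)
        self._refresh_einv()

    def update_delta0(self):
        """delta0 ~ IG(r0~/2, s0~^2/2), r0~ = 3n + r0."""
        st, qc, pr = self.state, self.qc, self.priors
        n = self.data.n
        resid = self.y_tilde - self.data.X @ st.beta - self.fitted - qc.m1 * st.e
        s_tilde = pr.s0_sq + 2.0 * st.e.sum() + np.sum(resid**2 / (qc.m2 * st.e))
        st.delta0 = float(_invgamma((3 * n + pr.r0) / 2.0, s_tilde / 2.0, self.rng))
        self._refresh_einv()

    def _rho_quad_coefs(self):
        st, qc = self.state, self.qc
        c = self.data.y - self.data.X @ st.beta - self.fitted - qc.m1 * st.e
        ew = self.einv
        return (c @ (ew * c), c @ (ew * self.Wy), self.Wy @ (ew * self.Wy))

    def rho_logpost(self, rho):
        """Unnormalized log conditional of rho (uniform prior cancels)."""
        A, B, C = self._rho_quad_coefs()
        return self.data.weights.log_det(rho) - 0.5 * (A - 2 * rho * B + rho**2 * C)

    def update_rho(self):
        st = self.state
        wm = self.data.weights
        lo, hi = wm.rho_lower, wm.rho_upper
        sig = st.sigma_rho
        prop = trunc_cauchy_rvs(st.rho, sig, lo, hi, self.rng)
        A, B, C = self._rho_quad_coefs()

        def logpost(r):
            return wm.log_det(r) - 0.5 * (A - 2 * r * B + r * r * C)

        log_c = np.log(trunc_cauchy_weight(st.rho, sig, lo, hi)) - np.log(
            trunc_cauchy_weight(prop, sig, lo, hi)
        )
        log_alpha = logpost(prop) - logpost(st.rho) + log_c
        prob = min(1.0, np.exp(min(log_alpha, 0.0)))
        self.accept["rho"][1] += 1
        accepted = np.log(self.rng.random()) < log_alpha
        if accepted:
            st.rho = float(prop)
            self._refresh_ytilde()
            self.accept["rho"][0] += 1
        if self.adapting:
            st.sigma_rho = self._adapt_scale("rho", st.sigma_rho, prob, hi - lo)
        return accepted

    def _adapt_scale(self, key, current, prob, span):
        """Robbins–Monro step on a log proposal scale toward the target rate."""
        self._adapt_count[key] = self._adapt_count.get(key, 0) + 1
        gain = self._adapt_count[key] ** -0.6
        return float(np.clip(current * np.exp(gain * (prob - self.target_accept)),
                             1e-5 * span, 10.0 * span))

    def update_beta(self):
        """beta ~ N(beta_hat, Xi0^{-1}), Xi0 = I/tau0 + X' E^{-1} X."""
        st = self.state
        X = self.data.X
        if X.shape[1] == 0:
            return
        y_hat = self.y_tilde - self.qc.m1 * st.e - self.fitted
        Xw = X * self.einv[:, None]
        Xi0 = np.eye(X.shape[1]) / st.tau0 + X.T @ Xw
        L = cholesky(Xi0, lower=True)
        beta_hat = cho_solve((L, True), Xw.T @ y_hat)
        z = self.rng.standard_normal(X.shape[1])
        st.beta = beta_hat + solve_triangular(L.T, z, lower=False)

    # -- reversible-jump knot machinery --------------------------------
    def _block_stats(self, Dj, tau_j, y_star, t0=None):
        """Cholesky of Xi_j, gamma_hat, S_j, log|Xi_j| for one design block."""
        K = Dj.shape[1]
        Dw = Dj * self.einv[:, None]
        Xi = np.eye(K) / tau_j + Dj.T @ Dw
        rhs = Dw.T @ y_star
        for jitter in (0.0, 1e-10, 1e-8):
            try:
                L = cholesky(Xi + jitter * np.eye(K), lower=True)
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise np.linalg.LinAlgError("spline precision matrix not SPD (knot collision?)")
        gamma_hat = cho_solve((L, True), rhs)
        if t0 is None:
            t0 = y_star @ (self.einv * y_star)
        S = t0 - gamma_hat @ rhs
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return L, gamma_hat, S, logdet, t0

    def _y_star(self, j):
        st = self.state
        return (self.y_tilde - self.data.X @ st.beta - self.qc.m1 * st.e
                - (self.fitted - self.fitted_j[j]))

    def _design_block(self, j, knots):
        cfg = self.configs[j]
        return self.data.Z[:, j : j + 1] * basis_matrix(self.data.U[:, j], cfg, knots)

    def update_knots(self, j):
        """One birth/death/move step on the gamma_j-collapsed marginal of
        (k_j, xi_j); returns (move_type, accepted) and leaves the accepted
        block statistics cached for the subsequent gamma_j draw."""
        st = self.state
        cfg = self.configs[j]
        sp = st.splines[j]
        rng = self.rng
        k = sp.n_knots
        y_star = self._y_star(j)
        L, ghat, S, logdet, t0 = self._block_stats(self.D[j], sp.tau, y_star)
        self._pending = (j, self.D[j], L, ghat)

        pb, pd, pm = move_probabilities(k, cfg.max_knots)
        u = rng.random()
        move_type = "birth" if u < pb else ("death" if u < pb + pd else "move")
        if move_type == "birth":
            new = rng.uniform(cfg.lower, cfg.upper)
            cand = np.sort(np.append(sp.knots, new))
            if not cfg.validate_knots(cand):
                self.accept["birth"][1] += 1
                return move_type, False
            pd_new = move_probabilities(k + 1, cfg.max_knots)[1]
            log_prop = np.log(cfg.span * pd_new) - np.log((k + 1) * pb)
            log_prior = np.log(cfg.poisson_mean / cfg.span) - 0.5 * np.log(sp.tau)
            log_step = 0.0
        elif move_type == "death":
            idx = rng.integers(k)
            cand = np.delete(sp.knots, idx)
            pb_new = move_probabilities(k - 1, cfg.max_knots)[0]
            log_prop = np.log(k * pb_new) - np.log(cfg.span * pd)
            log_prior = -np.log(cfg.poisson_mean / cfg.span) + 0.5 * np.log(sp.tau)
            log_step = 0.0
        else:  # hit-and-run movement of all knots
            direction = rng.standard_normal(k)
            direction /= np.linalg.norm(direction)
            with np.errstate(divide="ignore"):
                lo_b = np.where(direction > 0, (cfg.lower - sp.knots) / direction,
                                np.where(direction < 0, (cfg.upper - sp.knots) / direction, -np.inf))
                hi_b = np.where(direction > 0, (cfg.upper - sp.knots) / direction,
                                np.where(direction < 0, (cfg.lower - sp.knots) / direction, np.inf))
            w1, w2 = lo_b.max(), hi_b.min()
            sig = st.sigma_move[j]
            omega = trunc_cauchy_rvs(0.0, sig, w1, w2, rng)
            cand = np.sort(sp.knots + omega * direction)
            if not cfg.validate_knots(cand):
                self._count_move(False, 0.0, j)
                return move_type, False
            log_prop = np.log(trunc_cauchy_weight(0.0, sig, w1, w2)) - np.log(
                trunc_cauchy_weight(0.0, sig, w1 - omega, w2 - omega)
            )
            log_prior = 0.0
            log_step = 0.0

        Dj_new = self._design_block(j, cand)
        L2, ghat2, S2, logdet2, _ = self._block_stats(Dj_new, sp.tau, y_star, t0)
        log_alpha = 0.5 * (logdet - logdet2) + 0.5 * (S - S2) + log_prior + log_prop + log_step
        prob = min(1.0, np.exp(min(log_alpha, 0.0)))
        accepted = np.log(rng.random()) < log_alpha
        if move_type == "move":
            self._count_move(accepted, prob, j)
        else:
            self.accept[move_type][1] += 1
            self.accept[move_type][0] += int(accepted)
        if accepted:
            sp.knots = cand
            self.D[j] = Dj_new
            self._pending = (j, Dj_new, L2, ghat2)
        return move_type, accepted

    def _count_move(self, accepted, prob, j):
        st = self.state
        self.accept["move"][1] += 1
        self.accept["move"][0] += int(accepted)
        if self.adapting:
            cfg = self.configs[j]
            st.sigma_move[j] = self._adapt_scale(f"move{j}", st.sigma_move[j], prob, cfg.span)

    def update_gamma(self, j):
        """gamma_j ~ N(gamma_hat_j, Xi_j^{-1}) by composition, reusing the
        block statistics of the just-updated knot configuration."""
        sp = self.state.splines[j]
        if self._pending is None or self._pending[0] != j:
            y_star = self._y_star(j)
            L, ghat, *_ = self._block_stats(self.D[j], sp.tau, y_star)
        else:
            _, _, L, ghat = self._pending
        z = self.rng.standard_normal(ghat.size)
        sp.gamma = ghat + solve_triangular(L.T, z, lower=False)
        self._pending = None
        new_fit = self.D[j] @ sp.gamma
        self.fitted = self.fitted + (new_fit - self.fitted_j[j])
        self.fitted_j[j] = new_fit

    def update_tau_j(self, j):
        sp = self.state.splines[j]
        pr = self.priors
        sp.tau = float(_invgamma((sp.n_basis + pr.r_tau) / 2.0,
                                 (pr.s_tau_sq + sp.gamma @ sp.gamma) / 2.0, self.rng))

    def update_tau0(self):
        st, pr = self.state, self.priors
        st.tau0 = float(_invgamma((self.data.p + pr.r_tau) / 2.0,
                                  (pr.s_tau_sq + st.beta @ st.beta) / 2.0, self.rng))

    # ------------------------------------------------------------------
    def sweep(self):
        """One full scan in the prescribed order: e; delta0; rho; beta;
        per j (k_j, xi_j) then gamma_j then tau_j; tau0."""
        self._pending = None
        self.update_latent_e()
        self.update_delta0()
        self.update_rho()
        self.update_beta()
        for j in range(self.data.q):
            self.update_knots(j)
            self.update_gamma(j)
            self.update_tau_j(j)
        self.update_tau0()

    def check_finite(self):
        st = self.state
        vals = [st.rho, st.delta0, st.tau0, *st.beta]
        for s in st.splines:
            vals.extend([s.tau, *s.gamma])
        if not np.all(np.isfinite(vals)) or not np.all(np.isfinite(st.e)):
            raise RuntimeError(
                "sampler diverged to a non-finite state: "
                f"rho={st.rho}, delta0={st.delta0}, tau0={st.tau0}, beta={st.beta}"
            )


def run_chain(model, n_iter, n_burn, seed_seq=None, seed=None, thin=1, adapt=True,
              target_accept=0.25, ngrid=100, monitor_points=10, store_splines=False,
              init=None):
    """Run one chain; returns a dict of retained draws and diagnostics.

    Deterministic given the seed.  Adaptation of the MH proposal scales is
    active only during burn-in.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)
    smp = GibbsSampler(model, rng, init=init, target_accept=target_accept)
    q = model.data.q
    grids = [np.linspace(cfg.lower, cfg.upper, ngrid) for cfg in model.configs]
    monitors = [np.linspace(cfg.lower, cfg.upper, monitor_points) for cfg in model.configs]
    eval_pts = [np.concatenate([g, m]) for g, m in zip(grids, monitors)]

    n_keep = (n_iter - n_burn) // thin
    out = {
        "rho": np.empty(n_keep),
        "beta": np.empty((n_keep, model.data.p)),
        "delta0": np.empty(n_keep),
        "tau0": np.empty(n_keep),
        "tau": np.empty((n_keep, q)),
        "k": np.empty((n_keep, q), dtype=int),
        "alpha": [np.empty((n_keep, ngrid)) for _ in range(q)],
        "alpha_monitor": [np.empty((n_keep, monitor_points)) for _ in range(q)],
        "grids": grids,
        "monitor_grids": monitors,
    }
    splines_log = [] if store_splines else None

    kept = 0
    burn_accept = None
    for it in range(n_iter):
        smp.adapting = adapt and it < n_burn
        smp.sweep()
        if it == n_burn - 1:
            burn_accept = {k: v.copy() for k, v in smp.accept.items()}
            smp.check_finite()
        if it >= n_burn and (it - n_burn) % thin == 0:
            st = smp.state
            out["rho"][kept] = st.rho
            out["beta"][kept] = st.beta
            out["delta0"][kept] = st.delta0
            out["tau0"][kept] = st.tau0
            for j in range(q):
                sp = st.splines[j]
                out["tau"][kept, j] = sp.tau
                out["k"][kept, j] = sp.n_knots
                vals = basis_matrix(eval_pts[j], model.configs[j], sp.knots) @ sp.gamma
                out["alpha"][j][kept] = vals[:ngrid]
                out["alpha_monitor"][j][kept] = vals[ngrid:]
            if splines_log is not None:
                splines_log.append([
                    {"knots": st.splines[j].knots.tolist(),
                     "gamma": st.splines[j].gamma.tolist()} for j in range(q)
                ])
            kept += 1
    smp.check_finite()

    post_accept = {}
    for key, (acc, tot) in smp.accept.items():
        b_acc, b_tot = burn_accept[key] if burn_accept is not None else (0, 0)
        post_accept[key] = {
            "accepted": int(acc - b_acc),
            "proposed": int(tot - b_tot),
            "rate": float((acc - b_acc) / max(tot - b_tot, 1)),
        }
    out["acceptance"] = post_accept
    out["tuning"] = {
        "sigma_rho": smp.state.sigma_rho,
        "sigma_move": smp.state.sigma_move.tolist(),
    }
    out["seed_state"] = repr(seed_seq)
    out["n_iter"], out["n_burn"], out["thin"] = n_iter, n_burn, thin
    if splines_log is not None:
        out["splines"] = splines_log
    return out
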