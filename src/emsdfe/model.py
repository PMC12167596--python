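"""Zero-inflated hierarchical Bayesian model of plant fitness, fit by
mean-field variational inference.

The observation model for plant l of subline k, line j, founder i is

    z = 0                          with probability 1 - p
    z ~ Normal(s, eta_i^2)         with probability p,      z = log10 weight
    p = 1 / (1 + exp(c * s + d)),  s = y_i + m_ijk + h_ijkl + b_block

with founder genetic values y_i (fixed effects under a wide normal prior),
subline maternal effects m ~ Normal(0, sd_m^2), block effects
b ~ Normal(0, sd_b^2), and founder-specific residual SDs eta_i.  For EMS
lines the mutational deviation h is decomposed, via the central limit
theorem for the compound Poisson sum over a Poisson(lambda) number of
mutations, into three normal terms tied to the DFE moments (mu_i, sigma_i):

    line term     ~ Normal(lambda * mu_i, 1.5   * lambda * (mu_i^2 + sigma_i^2))
    subline term  ~ Normal(0,             0.25  * lambda * (mu_i^2 + sigma_i^2))
    individual    ~ Normal(0,             0.125 * lambda * (mu_i^2 + sigma_i^2))

(coefficients for three selfing generations; general g uses the exact
dosage-chain moments).  Control lines have h = 0.  lambda and g are fixed
inputs, never estimated.

Inference maximizes the evidence lower bound over a fully factorized
Gaussian family on the unconstrained scale (positive scales log-
transformed), using reparameterization-gradient stochastic ascent (Adam)
with analytic gradients of the joint log density.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import ExperimentTable
from .moments import dosage_moments

__all__ = [
    "ModelConfig",
    "ParamSummary",
    "PosteriorSummary",
    "HierarchicalDFEModel",
    "build_model",
    "fit_variational",
    "posterior_credible_check",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelConfig:
    """Priors, fixed constants, and variational-inference settings."""

    # priors (SDs of zero-mean normals; half-normal scales for positives)
    y_prior_sd: float = 10.0
    mu_prior_sd: float = 0.05
    sigma_prior_scale: float = 0.05
    maternal_sd_prior_scale: float = 0.5
    block_sd_prior_scale: float = 0.5
    eta_prior_scale: float = 1.0
    c_prior_sd: float = 5.0
    d_prior_sd: float = 10.0
    # fixed constants of the breeding design (never estimated)
    lambda_mut: float = 25.0
    selfing_generations: int = 3
    # VI settings
    max_iter: int = 16_000
    min_iter: int = 4_000
    learning_rate: float = 0.02
    n_mc: int = 2
    tol: float = 5e-5
    window: int = 250
    # absolute ELBO-change floor (nats) below which window-to-window
    # differences are treated as Monte Carlo noise
    tol_abs: float = 1.0
    n_restarts: int = 1
    n_draws: int = 4_000
    seed: int = 0


@dataclass(frozen=True)
class ParamSummary:
    mean: float
    sd: float
    ci95: tuple[float, float]
    ci99: tuple[float, float]

    def interval(self, level: float) -> tuple[float, float]:
        if np.isclose(level, 0.95):
            return self.ci95
        if np.isclose(level, 0.99):
            return self.ci99
        raise ValueError(f"only 95% and 99% intervals are stored, got {level}")


@dataclass
class PosteriorSummary:
    """Posterior means, SDs and credible intervals from the fitted
    variational approximation, plus the optimization outcome."""

    params: dict[str, ParamSummary]
    elbo: float
    converged: bool
    n_iter: int
    elbo_trace: np.ndarray = field(repr=False)
    latent_means: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __getitem__(self, name: str) -> ParamSummary:
        return self.params[name]

    def to_json(self, path: str | Path) -> None:
        payload: dict[str, Any] = {
            "elbo": self.elbo,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "params": {
                k: {"mean": p.mean, "sd": p.sd, "ci95": list(p.ci95),
                    "ci99": list(p.ci99)}
                for k, p in self.params.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PosteriorSummary":
        d = json.loads(Path(path).read_text())
        params = {
            k: ParamSummary(p["mean"], p["sd"], tuple(p["ci95"]), tuple(p["ci99"]))
            for k, p in d["params"].items()
        }
        return cls(params=params, elbo=d["elbo"], converged=d["converged"],
                   n_iter=d["n_iter"], elbo_trace=np.zeros(0))


def posterior_credible_check(
    summary: PosteriorSummary, parameter: str, level: float, value: float
) -> bool:
    """True iff ``value`` lies outside the ``level`` credible interval."""
    if parameter not in summary.params:
        raise KeyError(f"unknown parameter {parameter!r}")
    lo, hi = summary.params[parameter].interval(level)
    return bool(value < lo or value > hi)


class HierarchicalDFEModel:
    """Index structure, data arrays, and the joint log density with its
    analytic gradient, for one experiment table."""

    def __init__(self, table: ExperimentTable, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        df = table.df.reset_index(drop=True)
        self.n_obs = len(df)

        # --- index maps -----------------------------------------------------
        self.founders = list(pd.unique(df["founder_id"]))
        f_lookup = {f: i for i, f in enumerate(self.founders)}
        self.f_idx = df["founder_id"].map(f_lookup).to_numpy()
        self.F = len(self.founders)

        sub_key = (df["founder_id"].astype(str) + "|" + df["line_id"].astype(str)
                   + "|" + df["subline_id"].astype(str))
        self.s_idx, sub_labels = pd.factorize(sub_key, sort=False)
        self.S = len(sub_labels)

        self.bl_idx, block_labels = pd.factorize(df["block_id"], sort=False)
        self.blocks = list(block_labels)
        self.B = len(block_labels)

        ems = df["ems_treated"].to_numpy(dtype=bool)
        self.ems = ems
        ems_founders = list(pd.unique(df.loc[ems, "founder_id"]))
        self.focal = [f for f in self.founders if f in ems_founders]
        focal_lookup = {f: i for i, f in enumerate(self.focal)}
        self.Ff = len(self.focal)
        for f in self.focal:
            has_control = (~df.loc[df["founder_id"] == f, "ems_treated"]).any()
            if not has_control:
                warnings.warn(
                    f"focal founder {f!r} has no control plants; its genetic "
                    "value is identified only through the EMS lines"
                )

        line_key = (df["founder_id"].astype(str) + "|" + df["line_id"].astype(str))
        l_codes, l_labels = pd.factorize(line_key[ems], sort=False)
        self.l_idx = l_codes  # per EMS plant
        self.L = len(l_labels)
        self.line_founder = np.array(
            [focal_lookup[lab.split("|")[0]] for lab in l_labels], dtype=np.int64
        )
        u_codes, u_labels = pd.factorize(sub_key[ems], sort=False)
        self.u_idx = u_codes
        self.U = len(u_labels)
        self.u_founder = np.array(
            [focal_lookup[lab.split("|")[0]] for lab in u_labels], dtype=np.int64
        )
        self.n_ems = int(ems.sum())
        self.v_founder = self.line_founder[self.l_idx]  # per EMS plant
        self.ems_pos = np.flatnonzero(ems)

        # --- observations ---------------------------------------------------
        self.surv = df["survived"].to_numpy(dtype=bool)
        w = df["dry_weight_mg"].to_numpy(dtype=float)
        self.z = np.log10(w[self.surv])
        self.f_surv = self.f_idx[self.surv]

        # --- dosage-moment coefficients for the h decomposition --------------
        g = cfg.selfing_generations
        dm = dosage_moments(g)
        if g >= 2:
            c1 = float(dm.cross_moment(1))
            c2 = float(dm.cross_moment(min(2, g)))
        else:
            c1 = c2 = float(dm.second)
        self.k_line = c1
        self.k_sub = c2 - c1
        self.k_ind = float(dm.second) - c2

        self.focal_founder_idx = np.array(
            [self.founders.index(f) for f in self.focal], dtype=np.int64
        )

        # --- centering structure ---------------------------------------------
        # Latent fields are centered within groups whose mean freedom is
        # confounded with a founder-level mean: maternal effects within
        # (founder x treatment), line and subline mutational terms within
        # founder, block effects globally.  The likelihood sees only the
        # centered deviations; the group-mean directions keep their N(0,1)
        # prior and are reinstated when summarizing y and mu, so the
        # reported marginals carry the full between-group uncertainty that
        # a factorized approximation would otherwise hide.
        sub_first = df.groupby(self.s_idx, sort=True).first()
        self.sub_founder = sub_first["founder_id"].map(f_lookup).to_numpy()
        self.sub_is_ems = sub_first["ems_treated"].to_numpy(dtype=bool)
        m_code = self.sub_founder * 2 + self.sub_is_ems.astype(np.int64)
        self.m_group, _ = pd.factorize(m_code, sort=True)
        self.n_m_groups = int(self.m_group.max()) + 1
        self.m_group_size = np.bincount(self.m_group, minlength=self.n_m_groups)
        self.a_group_size = np.bincount(self.line_founder, minlength=self.Ff)
        self.u_group_size = np.bincount(self.u_founder, minlength=self.Ff)

        # --- flat parameter layout -------------------------------------------
        # The DFE mean is carried as w = y + lambda * mu (the EMS line-level
        # mean), which the EMS data pin directly while the controls pin y;
        # the two are nearly independent a posteriori, so the factorized
        # approximation stays honest about Var(mu) = Var((w - y)/lambda).
        names = [
            ("y", self.F), ("w", self.Ff), ("lsig", self.Ff),
            ("lsd_m", 1), ("lsd_b", 1), ("leta", self.F),
            ("c", 1), ("d", 1),
            ("b", self.B), ("m", self.S),
            ("a", self.L), ("u", self.U), ("v", self.n_ems),
        ]
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in names:
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off

    # -------------------------------------------------------------------
    def init_loc(self) -> np.ndarray:
        """Moment-based starting point for the variational means."""
        cfg = self.config
        loc = np.zeros(self.dim)
        y0 = np.zeros(self.F)
        leta0 = np.full(self.F, np.log(0.3))
        ems_surv = self.ems[np.flatnonzero(self.surv)]  # per survivor
        for i in range(self.F):
            sel = self.f_surv == i
            zi = self.z[sel]
            # controls alone pin y; EMS survivors only as fallback
            zc = self.z[sel & ~ems_surv]
            if len(zc) >= 2:
                y0[i] = zc.mean()
            elif len(zi):
                y0[i] = zi.mean()
            if len(zi) >= 2:
                leta0[i] = np.log(max(zi.std(), 1e-2))
        loc[self.slices["y"]] = y0
        loc[self.slices["leta"]] = leta0
        loc[self.slices["lsig"]] = np.log(0.02)
        # seed the EMS line-level mean w at the EMS survivor mean
        w0 = np.zeros(self.Ff)
        for j, f in enumerate(self.focal):
            i = self.founders.index(f)
            ze = self.z[(self.f_surv == i) & ems_surv]
            w0[j] = ze.mean() if len(ze) >= 2 else y0[i]
        loc[self.slices["w"]] = w0
        loc[self.slices["lsd_m"]] = np.log(0.05)
        loc[self.slices["lsd_b"]] = np.log(0.05)
        # logistic curve through founder-level survival rates vs founder means
        rates = np.array([
            self.surv[self.f_idx == i].mean() for i in range(self.F)
        ])
        ok = (rates > 0.02) & (rates < 0.98)
        if ok.sum() >= 2 and np.ptp(y0[ok]) > 1e-6:
            t = np.log((1 - rates[ok]) / rates[ok])
            c0, d0 = np.polyfit(y0[ok], t, 1)
        else:
            c0, d0 = 0.0, 0.0
        loc[self.slices["c"]] = c0
        loc[self.slices["d"]] = d0
        return loc

    # -------------------------------------------------------------------
    def logp_and_grad(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log density (up to a constant) and its gradient.

        Operates on the unconstrained parameter vector.  Positive scales are
        log-parameterized (change-of-variables Jacobian included) and all
        random effects are non-centered: the vector stores standardized
        N(0, 1) latents, and the scale parameters enter the likelihood
        through the deterministic products ``m = sd_m * m_std`` etc.  The
        non-centered form removes the funnel geometry that defeats
        mean-field approximations of hierarchical scales.
        """
        cfg = self.config
        sl = self.slices
        y = th[sl["y"]]
        w = th[sl["w"]]
        lsig = np.clip(th[sl["lsig"]], -12.0, 5.0)
        lsd_m = float(np.clip(th[sl["lsd_m"]][0], -12.0, 5.0))
        lsd_b = float(np.clip(th[sl["lsd_b"]][0], -12.0, 5.0))
        leta = np.clip(th[sl["leta"]], -12.0, 5.0)
        c = float(th[sl["c"]][0])
        d = float(th[sl["d"]][0])
        b_std = th[sl["b"]]
        m_std = th[sl["m"]]
        a_std = th[sl["a"]]
        u_std = th[sl["u"]]
        v_std = th[sl["v"]]

        sigma = np.exp(lsig)
        sd_m = np.exp(lsd_m)
        sd_b = np.exp(lsd_b)
        eta = np.exp(leta)
        lam = cfg.lambda_mut

        grad = np.zeros_like(th)
        lp = 0.0

        def gmean(vals: np.ndarray, gidx: np.ndarray, size: np.ndarray) -> np.ndarray:
            return (np.bincount(gidx, weights=vals, minlength=len(size))
                    / size)[gidx]

        # group-centered latent fields (group means live in y and w)
        m_c = m_std - gmean(m_std, self.m_group, self.m_group_size)
        b_c = b_std - b_std.mean()

        # non-centered transforms of the mutational components
        if self.Ff:
            mu = (w - y[self.focal_founder_idx]) / lam
            q = mu ** 2 + sigma ** 2  # per focal founder
            sqV1 = np.sqrt(self.k_line * lam * q)
            sqV2 = np.sqrt(self.k_sub * lam * q)
            sqV3 = np.sqrt(self.k_ind * lam * q)
            a_c = a_std - gmean(a_std, self.line_founder, self.a_group_size)
            u_c = u_std - gmean(u_std, self.u_founder, self.u_group_size)
            a_val = w[self.line_founder] + sqV1[self.line_founder] * a_c
            u_val = sqV2[self.u_founder] * u_c
            v_val = sqV3[self.v_founder] * v_std

        # linear predictor: founder mean is y for controls, w (through the
        # line-level term a_val) for EMS plants
        s = y[self.f_idx] + sd_m * m_c[self.s_idx] + sd_b * b_c[self.bl_idx]
        if self.n_ems:
            s[self.ems_pos] += (a_val[self.l_idx] + u_val[self.u_idx] + v_val
                                - y[self.f_idx[self.ems_pos]])
        t = c * s + d

        # survival mixture: P(die) = sigmoid(t), P(survive) = sigmoid(-t)
        lp += -np.logaddexp(0.0, -t[~self.surv]).sum()
        lp += -np.logaddexp(0.0, t[self.surv]).sum()
        gt = np.empty(self.n_obs)
        gt[~self.surv] = expit(-t[~self.surv])
        gt[self.surv] = -expit(t[self.surv])

        # weight likelihood for survivors
        eta_s = eta[self.f_surv]
        resid = self.z - s[self.surv]
        lp += float(np.sum(-leta[self.f_surv] - 0.5 * (resid / eta_s) ** 2
                           - 0.5 * _LOG2PI))

        grad_s = gt * c
        grad_s[self.surv] += resid / eta_s ** 2
        grad[sl["c"]] = float(gt @ s)
        grad[sl["d"]] = float(gt.sum())
        grad[sl["leta"]] = np.bincount(
            self.f_surv, weights=(resid / eta_s) ** 2 - 1.0, minlength=self.F
        )

        # scatter the predictor gradient to its components (y: controls only)
        grad[sl["y"]] = np.bincount(self.f_idx[~self.ems],
                                    weights=grad_s[~self.ems], minlength=self.F)
        gm = np.bincount(self.s_idx, weights=grad_s, minlength=self.S)
        gb = np.bincount(self.bl_idx, weights=grad_s, minlength=self.B)
        grad[sl["m"]] = sd_m * (gm - gmean(gm, self.m_group, self.m_group_size)) \
            - m_std
        grad[sl["b"]] = sd_b * (gb - gb.mean()) - b_std
        grad[sl["lsd_m"]] = float(sd_m * (gm @ m_c))
        grad[sl["lsd_b"]] = float(sd_b * (gb @ b_c))
        lp += float(-0.5 * np.sum(m_std ** 2) - 0.5 * np.sum(b_std ** 2))

        # mutational components tied to (mu, sigma)
        if self.n_ems:
            gse = grad_s[self.ems_pos]
            ga = np.bincount(self.l_idx, weights=gse, minlength=self.L)  # d/d a_val
            gu = np.bincount(self.u_idx, weights=gse, minlength=self.U)
            gv = gse
            grad[sl["a"]] = sqV1[self.line_founder] \
                * (ga - gmean(ga, self.line_founder, self.a_group_size)) - a_std
            grad[sl["u"]] = sqV2[self.u_founder] \
                * (gu - gmean(gu, self.u_founder, self.u_group_size)) - u_std
            grad[sl["v"]] = gv * sqV3[self.v_founder] - v_std
            lp += float(-0.5 * np.sum(a_std ** 2) - 0.5 * np.sum(u_std ** 2)
                        - 0.5 * np.sum(v_std ** 2))
            # chain rule into (mu, lsig) through the scales: d sqrtV / d q =
            # sqrtV / (2q), dq/dmu = 2 mu, dq/dlsig = 2 sigma^2.
            ga_sc = np.bincount(self.line_founder, weights=ga * sqV1[self.line_founder] * a_c,
                                minlength=self.Ff)
            gu_sc = np.bincount(self.u_founder, weights=gu * sqV2[self.u_founder] * u_c,
                                minlength=self.Ff)
            gv_sc = np.bincount(self.v_founder, weights=gv * sqV3[self.v_founder] * v_std,
                                minlength=self.Ff)
            g_q = (ga_sc + gu_sc + gv_sc) / (2.0 * q)  # d lp / d q
            # d q / d mu = 2 mu, with d mu / d w = 1/lam, d mu / d y = -1/lam
            grad_dmu = g_q * 2.0 * mu  # d lp / d mu (variance channel)
            grad_w = np.bincount(self.line_founder, weights=ga, minlength=self.Ff)
            grad_w += grad_dmu / lam
            grad[sl["y"]][self.focal_founder_idx] += -grad_dmu / lam
            grad_lsig = g_q * 2.0 * sigma ** 2
        else:
            grad_w = np.zeros(0)
            grad_lsig = np.zeros(0)

        # priors on globals
        lp += float(-0.5 * np.sum(y ** 2) / cfg.y_prior_sd ** 2)
        grad[sl["y"]] += -y / cfg.y_prior_sd ** 2
        if self.Ff:
            lp += float(-0.5 * np.sum(mu ** 2) / cfg.mu_prior_sd ** 2)
            g_pr = -mu / cfg.mu_prior_sd ** 2
            grad_w += g_pr / lam
            grad[sl["y"]][self.focal_founder_idx] += -g_pr / lam
            lp += float(np.sum(-0.5 * sigma ** 2 / cfg.sigma_prior_scale ** 2 + lsig))
            grad_lsig += -sigma ** 2 / cfg.sigma_prior_scale ** 2 + 1.0
            grad[sl["w"]] = grad_w
            grad[sl["lsig"]] = grad_lsig
        lp += float(-0.5 * sd_m ** 2 / cfg.maternal_sd_prior_scale ** 2 + lsd_m)
        grad[sl["lsd_m"]] += -sd_m ** 2 / cfg.maternal_sd_prior_scale ** 2 + 1.0
        lp += float(-0.5 * sd_b ** 2 / cfg.block_sd_prior_scale ** 2 + lsd_b)
        grad[sl["lsd_b"]] += -sd_b ** 2 / cfg.block_sd_prior_scale ** 2 + 1.0
        lp += float(np.sum(-0.5 * eta ** 2 / cfg.eta_prior_scale ** 2 + leta))
        grad[sl["leta"]] += -eta ** 2 / cfg.eta_prior_scale ** 2 + 1.0
        lp += -0.5 * c ** 2 / cfg.c_prior_sd ** 2
        grad[sl["c"]] += -c / cfg.c_prior_sd ** 2
        lp += -0.5 * d ** 2 / cfg.d_prior_sd ** 2
        grad[sl["d"]] += -d / cfg.d_prior_sd ** 2

        return lp, grad


def build_model(
    table: ExperimentTable, config: ModelConfig | None = None
) -> HierarchicalDFEModel:
    """Construct the hierarchical model for an experiment table."""
    return HierarchicalDFEModel(table, config)


def _advi(
    model: HierarchicalDFEModel, cfg: ModelConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, float, bool, int, list[float]]:
    """One run of stochastic mean-field ELBO ascent.  Returns (loc, log_scale,
    smoothed final ELBO, converged flag, iterations, ELBO trace)."""
    rng = np.random.default_rng(seed)
    D = model.dim
    loc = model.init_loc()
    ls = np.full(D, -4.0)
    # standardized (non-centered) latents start near their N(0,1) prior width
    for name in ("b", "m", "a", "u", "v"):
        ls[model.slices[name]] = -0.7
    # Adam state
    m1 = np.zeros(2 * D)
    m2 = np.zeros(2 * D)
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    entropy_const = 0.5 * D * (1.0 + _LOG2PI)

    trace: list[float] = []
    window_vals: list[float] = []
    prev_window: float | None = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        g_loc = np.zeros(D)
        g_ls = np.zeros(D)
        elbo_acc = 0.0
        scale = np.exp(ls)
        for _ in range(cfg.n_mc):
            epsv = rng.standard_normal(D)
            theta = loc + scale * epsv
            lp, grad = model.logp_and_grad(theta)
            g_loc += grad
            g_ls += grad * epsv * scale
            elbo_acc += lp
        g_loc /= cfg.n_mc
        g_ls = g_ls / cfg.n_mc + 1.0  # entropy gradient
        elbo = elbo_acc / cfg.n_mc + ls.sum() + entropy_const

        g = np.concatenate([g_loc, g_ls])
        m1 = beta1 * m1 + (1 - beta1) * g
        m2 = beta2 * m2 + (1 - beta2) * g * g
        mhat = m1 / (1 - beta1 ** it)
        vhat = m2 / (1 - beta2 ** it)
        step = cfg.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
        loc += step[:D]
        ls = np.clip(ls + step[D:], -12.0, 3.0)

        window_vals.append(elbo)
        if it % cfg.window == 0:
            cur = float(np.mean(window_vals))
            trace.append(cur)
            window_vals = []
            if prev_window is not None and it >= cfg.min_iter:
                thresh = max(cfg.tol * (abs(prev_window) + 1.0), cfg.tol_abs)
                if abs(cur - prev_window) < thresh:
                    converged = True
                    break
            prev_window = cur
    final = trace[-1] if trace else float("nan")
    return loc, ls, final, converged, it, trace


def fit_variational(
    model: HierarchicalDFEModel, config: ModelConfig | None = None
) -> PosteriorSummary:
    """Fit the model by mean-field variational inference.

    Runs ``n_restarts`` independent optimizations (best final ELBO wins,
    ties broken by lowest restart index) and summarizes the winning
    approximation from ``n_draws`` posterior draws.  Non-convergence within
    ``max_iter`` is reported through the ``converged`` flag, not raised.
    """
    cfg = config or model.config
    best = None
    for r in range(cfg.n_restarts):
        out = _advi(model, cfg, seed=cfg.seed + r)
        if best is None or out[2] > best[2]:
            best = out
    loc, ls, elbo, converged, n_iter, trace = best
    if not converged:
        warnings.warn(f"variational fit did not converge in {n_iter} iterations")

    sl = model.slices
    rng = np.random.default_rng(cfg.seed + 10_000)
    draws = loc + np.exp(ls) * rng.standard_normal((cfg.n_draws, model.dim))

    def summarize(col: np.ndarray, positive: bool = False) -> ParamSummary:
        x = np.exp(col) if positive else col
        lo95, hi95 = np.percentile(x, [2.5, 97.5])
        lo99, hi99 = np.percentile(x, [0.5, 99.5])
        return ParamSummary(float(x.mean()), float(x.std()),
                            (float(lo95), float(hi95)), (float(lo99), float(hi99)))

    # Reconstruct the original (uncentered) parameterization per draw: the
    # group-mean directions of the latent fields were removed from the
    # likelihood, so y and w absorbed them; subtracting the (prior-
    # distributed) group means restores the honest marginals.
    lam = cfg.lambda_mut
    sd_m_d = np.exp(draws[:, sl["lsd_m"].start])
    sd_b_d = np.exp(draws[:, sl["lsd_b"].start])
    b_bar = draws[:, sl["b"]].mean(axis=1) if model.B else 0.0
    m_cols = draws[:, sl["m"]]

    def sub_mean(mask: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(mask)
        return m_cols[:, idx].mean(axis=1) if len(idx) else np.zeros(len(draws))

    y_rep = {}
    for i, f in enumerate(model.founders):
        m_bar = sub_mean((model.sub_founder == i) & ~model.sub_is_ems)
        y_rep[i] = (draws[:, sl["y"].start + i] - sd_m_d * m_bar - sd_b_d * b_bar)

    params: dict[str, ParamSummary] = {}
    for i, f in enumerate(model.founders):
        params[f"y[{f}]"] = summarize(y_rep[i])
    for j, f in enumerate(model.focal):
        i = int(model.focal_founder_idx[j])
        y_d = draws[:, sl["y"].start + i]
        w_d = draws[:, sl["w"].start + j]
        sig_d = np.exp(draws[:, sl["lsig"].start + j])
        q_d = ((w_d - y_d) / lam) ** 2 + sig_d ** 2
        a_bar = draws[:, sl["a"]][:, model.line_founder == j].mean(axis=1)
        u_bar = draws[:, sl["u"]][:, model.u_founder == j].mean(axis=1)
        m_bar_ems = sub_mean((model.sub_founder == i) & model.sub_is_ems)
        w_rep = (w_d
                 - np.sqrt(model.k_line * lam * q_d) * a_bar
                 - np.sqrt(model.k_sub * lam * q_d) * u_bar
                 - sd_m_d * m_bar_ems - sd_b_d * b_bar)
        # mu derives per draw from the EMS-level mean w = y + lambda * mu
        params[f"mu[{f}]"] = summarize((w_rep - y_rep[i]) / lam)
        params[f"sigma[{f}]"] = summarize(draws[:, sl["lsig"].start + j],
                                          positive=True)
    for i, f in enumerate(model.founders):
        params[f"eta[{f}]"] = summarize(draws[:, sl["leta"].start + i],
                                        positive=True)
    params["maternal_sd"] = summarize(draws[:, sl["lsd_m"].start], positive=True)
    params["block_sd"] = summarize(draws[:, sl["lsd_b"].start], positive=True)
    params["c"] = summarize(draws[:, sl["c"].start])
    params["d"] = summarize(draws[:, sl["d"].start])

    scales = {k: params[k].sd for k in ("maternal_sd", "block_sd")}
    for k, p in params.items():
        if k.startswith(("sigma[", "eta[")) or k in scales:
            if p.mean < 1e-6:
                warnings.warn(f"posterior for {k} is nearly degenerate (scale -> 0)")

    latent_means = {
        "block": loc[sl["b"]].copy(),
        "maternal": loc[sl["m"]].copy(),
        "h_line": loc[sl["a"]].copy(),
        "h_subline": loc[sl["u"]].copy(),
        "h_individual": loc[sl["v"]].copy(),
    }
    return PosteriorSummary(
        params=params,
        elbo=float(elbo),
        converged=bool(converged),
        n_iter=int(n_iter),
        elbo_trace=np.array(trace),
        latent_means=latent_means,
    )
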