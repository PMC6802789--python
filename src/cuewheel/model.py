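"""Hierarchical Bayesian model of RT, encoding probability and fidelity.

Three submodels share a subject grouping and a condition-cell factor:

* log RT ~ Normal(a_rt + b_rt[cell] + tau_rt * z_rt[subject], sigma)
* error ~ rho * VM(0, kappa) + (1 - rho) * Uniform, with
  logit(rho) = a_p + b_p[cell] + tau_p * z_p[subject] and
  log(kappa)  = a_k + b_k[cell] + tau_k * z_k[subject]

Condition cells use dummy coding against a reference cell (the invalid cue
by default) so the valid-invalid cueing effect is a single coefficient;
subject deviations are non-centred (z ~ N(0,1) scaled by a group SD).
Priors are weakly informative and configurable: Normal(0, 1) on condition
coefficients, half-Normal(1) on group SDs and the within-subject RT SD,
Normal(log 350 ms, 1) / Normal(2, 2) / Normal(log 8, 1) on the RT, logit-rho
and log-kappa intercepts.

The joint posterior is sampled with emcee's affine-invariant ensemble
sampler, with the log-posterior vectorized across walkers; walkers play the
role of chains for split-R-hat (computed via arviz). Condition-level
summaries are back-transformed draw-wise: rt_ms[cell] = exp(linear
predictor), rho[cell] = logistic(.), kappa[cell] = exp(.).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import _log_i0, fit_mle_cell
from ._angles import deg2rad

__all__ = ["ModelSpec", "PosteriorSamples", "HierarchicalCueingModel", "fit_posterior"]

_LOG_2PI = np.log(2.0 * np.pi)
_HALFNORMAL_LOGC = 0.5 * np.log(2.0 / np.pi)


def _default_priors() -> dict:
    return {
        "a_rt": (np.log(350.0), 1.0),   # log-ms
        "a_p": (2.0, 2.0),              # logit rho
        "a_k": (np.log(8.0), 1.0),      # log kappa
        "b": (0.0, 1.0),                # condition coefficients, all submodels
        "sd_scale": 1.0,                # half-Normal scale for sigma and taus
    }


@dataclass
class ModelSpec:
    """Model configuration: condition coding, priors and sampler settings."""

    reference: str | None = None          # reference cell; default: invalid cue
    hierarchical: bool = True
    random_slopes: bool = False           # per-subject condition effects (off by default)
    priors: dict = field(default_factory=_default_priors)
    n_walkers: int | None = None          # default: max(2 * ndim + 2, 64)
    n_steps: int = 4000
    n_burn: int = 2000
    thin: int = 8
    seed: int = 0
    progress: bool = False


@dataclass
class PosteriorSamples:
    """Named posterior draws with sampler diagnostics.

    ``derived`` maps condition-level names (``rt_ms[cell]``, ``rho[cell]``,
    ``kappa[cell]``) and latent population parameters to arrays of shape
    (n_chains, n_draws); walkers act as chains. ``diagnostics`` records
    split-R-hat per named quantity, the mean acceptance fraction and a
    divergence count (always 0: the ensemble sampler has no divergences;
    retained for schema compatibility with HMC-based workflows).
    """

    cells: list
    derived: dict
    diagnostics: dict
    n_subjects: int = 0
    n_trials: int = 0

    def names(self) -> list:
        return list(self.derived)

    def get(self, name: str) -> np.ndarray:
        """Flattened draws for one named quantity."""
        return np.asarray(self.derived[name]).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Tidy draw table: (parameter, chain, iteration, value)."""
        rows = []
        for name, arr in self.derived.items():
            arr = np.asarray(arr)
            c, d = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(c), d),
                        "iteration": np.tile(np.arange(d), c),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


class _LogPosterior:
    """Vectorized log-posterior over a (n_walkers, ndim) parameter block."""

    def __init__(self, clean: pd.DataFrame, cells: list, hierarchical: bool, priors: dict,
                 random_slopes: bool = False):
        self.cells = list(cells)
        self.C = len(self.cells)
        self.hier = hierarchical
        self.slopes = random_slopes and hierarchical and self.C > 1
        self.priors = priors

        subs = np.unique(clean["subject_id"].to_numpy())
        self.subjects = list(subs)
        self.S = len(subs)
        s_idx = np.searchsorted(subs, clean["subject_id"].to_numpy())
        c_map = {c: i for i, c in enumerate(self.cells)}
        c_idx = np.array([c_map[c] for c in clean["cell"]], dtype=int)

        # group = subject x cell; RT collapses to sufficient statistics
        g_idx = s_idx * self.C + c_idx
        self.G = self.S * self.C
        self.g_sub = np.arange(self.G) // self.C
        self.g_cell = np.arange(self.G) % self.C
        log_rt = clean["log_rt"].to_numpy(dtype=float)
        self.n_g = np.bincount(g_idx, minlength=self.G).astype(float)
        self.sum_g = np.bincount(g_idx, weights=log_rt, minlength=self.G)
        self.ss_g = np.bincount(g_idx, weights=log_rt**2, minlength=self.G)
        self.N = len(clean)

        self.cos_e = np.cos(deg2rad(clean["error_deg"].to_numpy(dtype=float)))
        self.trial_g = g_idx

        # parameter layout
        sizes = {
            "a_rt": 1, "b_rt": self.C - 1, "log_sigma": 1,
            "a_p": 1, "b_p": self.C - 1,
            "a_k": 1, "b_k": self.C - 1,
        }
        if hierarchical:
            sizes.update(
                log_tau_rt=1, z_rt=self.S,
                log_tau_p=1, z_p=self.S,
                log_tau_k=1, z_k=self.S,
            )
        if self.slopes:
            n_sl = self.S * (self.C - 1)
            sizes.update(
                log_tau_sl_rt=1, u_rt=n_sl,
                log_tau_sl_p=1, u_p=n_sl,
                log_tau_sl_k=1, u_k=n_sl,
            )
            # slope index per subject-x-cell group; reference cells carry none
            self.g_slope = np.where(
                self.g_cell > 0, self.g_sub * (self.C - 1) + self.g_cell - 1, 0
            )
            self.g_has_slope = (self.g_cell > 0).astype(float)
        self.slices: dict[str, slice] = {}
        off = 0
        for k, sz in sizes.items():
            self.slices[k] = slice(off, off + sz)
            off += sz
        self.ndim = off

    # -- helpers -----------------------------------------------------------
    def _cell_lin(self, a, b):
        """(W, C) linear predictor per cell from intercept + dummy coefs."""
        W = a.shape[0]
        lin = np.empty((W, self.C))
        lin[:, 0] = a[:, 0]
        if self.C > 1:
            lin[:, 1:] = a + b
        return lin

    def _group_lin(self, lin_cell, tau, z, tau_sl=None, u=None):
        """(W, G) linear predictor per subject-x-cell group."""
        out = lin_cell[:, self.g_cell]
        if self.hier:
            out = out + (tau[:, None] * z)[:, self.g_sub]
        if self.slopes and u is not None:
            out = out + (tau_sl[:, None] * u)[:, self.g_slope] * self.g_has_slope[None, :]
        return out

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        sl = self.slices
        a_rt, b_rt = theta[:, sl["a_rt"]], theta[:, sl["b_rt"]]
        log_sigma = theta[:, sl["log_sigma"]][:, 0]
        a_p, b_p = theta[:, sl["a_p"]], theta[:, sl["b_p"]]
        a_k, b_k = theta[:, sl["a_k"]], theta[:, sl["b_k"]]

        bad = log_sigma < np.log(1e-6)  # guard against sigma -> 0 blow-up
        sigma = np.exp(np.clip(log_sigma, np.log(1e-6), 5.0))

        if self.hier:
            tau_rt = np.exp(np.clip(theta[:, sl["log_tau_rt"]][:, 0], -15.0, 3.0))
            tau_p = np.exp(np.clip(theta[:, sl["log_tau_p"]][:, 0], -15.0, 3.0))
            tau_k = np.exp(np.clip(theta[:, sl["log_tau_k"]][:, 0], -15.0, 3.0))
            z_rt, z_p, z_k = theta[:, sl["z_rt"]], theta[:, sl["z_p"]], theta[:, sl["z_k"]]
        else:
            tau_rt = tau_p = tau_k = z_rt = z_p = z_k = None

        if self.slopes:
            tau_sl_rt = np.exp(np.clip(theta[:, sl["log_tau_sl_rt"]][:, 0], -15.0, 3.0))
            tau_sl_p = np.exp(np.clip(theta[:, sl["log_tau_sl_p"]][:, 0], -15.0, 3.0))
            tau_sl_k = np.exp(np.clip(theta[:, sl["log_tau_sl_k"]][:, 0], -15.0, 3.0))
            u_rt, u_p, u_k = theta[:, sl["u_rt"]], theta[:, sl["u_p"]], theta[:, sl["u_k"]]
        else:
            tau_sl_rt = tau_sl_p = tau_sl_k = u_rt = u_p = u_k = None

        # RT submodel via sufficient stats
        mu_g = self._group_lin(self._cell_lin(a_rt, b_rt), tau_rt, z_rt, tau_sl_rt, u_rt)
        sse = self.ss_g[None, :] - 2.0 * mu_g * self.sum_g[None, :] + self.n_g[None, :] * mu_g**2
        ll_rt = -self.N * (np.log(sigma) + 0.5 * _LOG_2PI) - 0.5 * sse.sum(axis=1) / sigma**2

        # mixture submodel
        lin_p = self._group_lin(self._cell_lin(a_p, b_p), tau_p, z_p, tau_sl_p, u_p)
        lin_k = np.clip(
            self._group_lin(self._cell_lin(a_k, b_k), tau_k, z_k, tau_sl_k, u_k), -20.0, 12.0
        )
        kappa_g = np.exp(lin_k)
        log_rho_g = -np.logaddexp(0.0, -lin_p)
        log_1m_g = -np.logaddexp(0.0, lin_p)
        log_norm_g = log_rho_g - _LOG_2PI - _log_i0(kappa_g)
        t1 = log_norm_g[:, self.trial_g] + kappa_g[:, self.trial_g] * self.cos_e[None, :]
        t2 = (log_1m_g - _LOG_2PI)[:, self.trial_g]
        ll_mix = np.logaddexp(t1, t2).sum(axis=1)

        # priors
        pr = self.priors
        lp = _normal_lp(a_rt[:, 0], *pr["a_rt"]) + _normal_lp(a_p[:, 0], *pr["a_p"])
        lp += _normal_lp(a_k[:, 0], *pr["a_k"])
        for b in (b_rt, b_p, b_k):
            if b.shape[1]:
                lp += _normal_lp(b, *pr["b"]).sum(axis=1)
        lp += _halfnormal_log_lp(log_sigma, pr["sd_scale"])
        if self.hier:
            for log_tau, z in (
                (np.log(tau_rt), z_rt), (np.log(tau_p), z_p), (np.log(tau_k), z_k)
            ):
                lp += _halfnormal_log_lp(log_tau, pr["sd_scale"])
                lp += _normal_lp(z, 0.0, 1.0).sum(axis=1)
        if self.slopes:
            for tau_sl, u in ((tau_sl_rt, u_rt), (tau_sl_p, u_p), (tau_sl_k, u_k)):
                lp += _halfnormal_log_lp(np.log(tau_sl), pr["sd_scale"])
                lp += _normal_lp(u, 0.0, 1.0).sum(axis=1)

        out = ll_rt + ll_mix + lp
        out[bad | ~np.isfinite(out)] = -np.inf
        return out


def _normal_lp(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _halfnormal_log_lp(log_s, scale):
    """Half-Normal(scale) prior on s, evaluated in log_s (Jacobian included)."""
    s = np.exp(np.clip(log_s, -40.0, 20.0))
    return _HALFNORMAL_LOGC - np.log(scale) - 0.5 * (s / scale) ** 2 + log_s


class HierarchicalCueingModel:
    """Bayesian mixed-effects model of cueing effects on RT, rho and kappa.

    scikit-learn style estimator: configure in ``__init__``, call
    :meth:`fit` with a clean modelling table (columns ``subject_id``,
    ``cell``, ``log_rt``, ``error_deg``), then read ``posterior_`` and
    ``diagnostics_``.

    Parameters mirror :class:`ModelSpec`; ``hierarchical=False`` drops the
    subject-level terms (useful for pooled fits on data without subject
    spread). Seeded runs with identical settings are bit-reproducible.
    """

    def __init__(
        self,
        reference: str | None = None,
        hierarchical: bool = True,
        random_slopes: bool = False,
        priors: dict | None = None,
        n_walkers: int | None = None,
        n_steps: int = 4000,
        n_burn: int = 2000,
        thin: int = 8,
        seed: int = 0,
        progress: bool = False,
    ):
        self.reference = reference
        self.hierarchical = hierarchical
        self.random_slopes = random_slopes
        self.priors = priors
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed
        self.progress = progress

    # sklearn-compatible param plumbing without inheriting array validation
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "reference", "hierarchical", "random_slopes", "priors", "n_walkers",
                "n_steps", "n_burn", "thin", "seed", "progress",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _ordered_cells(self, clean: pd.DataFrame) -> list:
        cells = sorted(set(map(str, clean["cell"])))
        ref = self.reference
        if ref is None:
            inv = [c for c in cells if c.startswith("invalid")]
            ref = inv[0] if inv else cells[0]
        if ref not in cells:
            raise ValueError(f"reference cell {ref!r} not present in data")
        return [ref] + [c for c in cells if c != ref]

    def _initial_point(self, clean: pd.DataFrame, lp: _LogPosterior) -> np.ndarray:
        """MLE-informed start: pooled per-cell mixture fits + RT cell means."""
        theta0 = np.zeros(lp.ndim)
        sl = lp.slices
        e_rad = deg2rad(clean["error_deg"].to_numpy(dtype=float))
        log_rt = clean["log_rt"].to_numpy(dtype=float)
        cell_arr = clean["cell"].to_numpy()
        lin_rt, lin_p, lin_k = [], [], []
        for c in lp.cells:
            m = cell_arr == c
            lin_rt.append(float(np.mean(log_rt[m])))
            if m.sum() >= 10:
                rho, kappa, _ = fit_mle_cell(e_rad[m], tol=1e-8, max_iter=200)
            else:
                rho, kappa = 0.9, 8.0
            rho = min(max(rho, 1e-3), 1.0 - 1e-3)
            lin_p.append(float(np.log(rho / (1.0 - rho))))
            lin_k.append(float(np.log(max(kappa, 0.1))))
        theta0[sl["a_rt"]] = lin_rt[0]
        theta0[sl["b_rt"]] = np.array(lin_rt[1:]) - lin_rt[0]
        theta0[sl["a_p"]] = np.clip(lin_p[0], -6.0, 6.0)
        theta0[sl["b_p"]] = np.clip(np.array(lin_p[1:]) - lin_p[0], -4.0, 4.0)
        theta0[sl["a_k"]] = lin_k[0]
        theta0[sl["b_k"]] = np.array(lin_k[1:]) - lin_k[0]
        resid_sd = float(np.std(log_rt)) or 0.1
        theta0[sl["log_sigma"]] = np.log(resid_sd)
        if lp.hier:
            # subject RT intercepts are well identified: start their
            # non-centred z's at the empirical subject deviations
            cell_mean = {c: m for c, m in zip(lp.cells, lin_rt)}
            resid = log_rt - np.array([cell_mean[c] for c in cell_arr])
            sub_arr = clean["subject_id"].to_numpy()
            dev = np.array(
                [float(np.mean(resid[sub_arr == s])) for s in lp.subjects]
            )
            tau0 = max(float(np.std(dev)), 0.02)
            theta0[sl["log_tau_rt"]] = np.log(tau0)
            theta0[sl["z_rt"]] = dev / tau0
            for name in ("log_tau_p", "log_tau_k"):
                theta0[sl[name]] = np.log(0.1)
        if lp.slopes:
            for name in ("log_tau_sl_rt", "log_tau_sl_p", "log_tau_sl_k"):
                theta0[sl[name]] = np.log(0.05)
        return theta0

    def fit(self, X: pd.DataFrame, y=None):
        import emcee

        clean = X
        if len(clean) == 0:
            raise ValueError("empty modelling dataset")
        if clean["subject_id"].nunique() < 2 and self.hierarchical:
            raise ValueError("hierarchical fit requires >= 2 subjects")
        counts = clean.groupby("cell").size()
        if (counts < 1).any():
            raise ValueError("every condition cell must be non-empty")
        cells = self._ordered_cells(clean)
        priors = dict(_default_priors())
        if self.priors:
            priors.update(self.priors)
        lp = _LogPosterior(clean, cells, self.hierarchical, priors,
                           random_slopes=self.random_slopes)

        ndim = lp.ndim
        n_walkers = self.n_walkers or max(2 * ndim + 2, 64)
        rng = np.random.default_rng(self.seed)
        theta0 = self._initial_point(clean, lp)
        p0 = theta0[None, :] + 0.02 * rng.standard_normal((n_walkers, ndim))

        # differential-evolution moves mix far better than the default
        # stretch move in the high-dimensional hierarchical posterior
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(n_walkers, ndim, lp, vectorize=True, moves=moves)
        sampler.random_state = np.random.RandomState(self.seed).get_state()
        sampler.run_mcmc(p0, self.n_steps, progress=self.progress)
        chain = sampler.get_chain(discard=self.n_burn, thin=self.thin)  # (d, w, ndim)
        if not np.isfinite(sampler.get_log_prob(discard=self.n_burn)).any():
            raise RuntimeError("all walkers non-finite after warmup: bad data or priors")
        chain = np.moveaxis(chain, 0, 1)  # (walkers, draws, ndim)

        self.cells_ = cells
        self.posterior_ = self._summarize(chain, lp)
        self.posterior_.n_subjects = lp.S
        self.posterior_.n_trials = lp.N
        self.diagnostics_ = self.posterior_.diagnostics
        self.diagnostics_["acceptance_fraction"] = float(sampler.acceptance_fraction.mean())
        self.diagnostics_["divergences"] = 0
        self.n_features_in_ = clean.shape[1]
        return self

    def _summarize(self, chain: np.ndarray, lp: _LogPosterior) -> PosteriorSamples:
        import arviz as az

        sl = lp.slices
        derived: dict[str, np.ndarray] = {}

        def cell_draws(a_key, b_key):
            a = chain[:, :, sl[a_key]][:, :, 0]
            out = [a]
            b = chain[:, :, sl[b_key]]
            for j in range(b.shape[2]):
                out.append(a + b[:, :, j])
            return out  # list of (walkers, draws) per cell, reference first

        for c, lin in zip(lp.cells, cell_draws("a_rt", "b_rt")):
            derived[f"rt_ms[{c}]"] = np.exp(lin)
        for c, lin in zip(lp.cells, cell_draws("a_p", "b_p")):
            derived[f"rho[{c}]"] = 1.0 / (1.0 + np.exp(-lin))
        for c, lin in zip(lp.cells, cell_draws("a_k", "b_k")):
            derived[f"kappa[{c}]"] = np.exp(lin)
        derived["sigma_log_rt"] = np.exp(chain[:, :, sl["log_sigma"]][:, :, 0])
        if lp.hier:
            for name in ("log_tau_rt", "log_tau_p", "log_tau_k"):
                derived[name.replace("log_", "")] = np.exp(chain[:, :, sl[name]][:, :, 0])

        rhat = {}
        for name, arr in derived.items():
            try:
                rhat[name] = float(az.rhat(az.convert_to_dataset(arr[:, :]))["x"].values)
            except Exception:
                rhat[name] = float("nan")
        diags = {"rhat": rhat, "rhat_max": float(np.nanmax(list(rhat.values())))}
        return PosteriorSamples(cells=list(lp.cells), derived=derived, diagnostics=diags)


def fit_posterior(clean: pd.DataFrame, spec: ModelSpec | None = None) -> PosteriorSamples:
    """Fit the hierarchical model per a :class:`ModelSpec`; returns draws."""
    spec = spec or ModelSpec()
    model = HierarchicalCueingModel(
        reference=spec.reference,
        hierarchical=spec.hierarchical,
        random_slopes=spec.random_slopes,
        priors=spec.priors,
        n_walkers=spec.n_walkers,
        n_steps=spec.n_steps,
        n_burn=spec.n_burn,
        thin=spec.thin,
        seed=spec.seed,
        progress=spec.progress,
    )
    model.fit(clean)
    return model.posterior_
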