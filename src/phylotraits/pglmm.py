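"""Phylogenetic multilevel model for log-transformed traits.

The model, fitted independently per trait, is

    log(Y_i) ~ Normal(mu_i, sigma)
    mu_ijk   = alpha0 + beta * site_i + a_plot[j] + a_species[k]

with a standard random intercept per plot, ``a_plot ~ Normal(0, tau_plot)``,
and a two-component species intercept ``a_species ~ MVN(0, Sigma_phyl)``
where ``Sigma_phyl`` has ``tau_phyl^2 + tau_ind^2`` on the diagonal and
``tau_phyl^2 * rho[m, n]`` off it: a Brownian-motion phylogeny effect plus a
phylogenetically independent species effect.  Site enters as a categorical
fixed effect with treatment contrasts (1000 m reference).

Because the response is Gaussian, all random effects can be marginalized
analytically: y ~ N(X theta, V) with

    V = Zp tau_plot^2 Zp' + Zs (tau_phyl^2 rho + tau_ind^2 I) Zs' + sigma^2 I.

Both backends work on this marginal likelihood — maximum likelihood by
multi-start quasi-Newton optimization, and Bayesian inference by
affine-invariant ensemble MCMC over (alpha0, beta, log tau_plot, log
tau_phyl, log tau_ind, log sigma) with weakly informative normal priors on
location parameters and half-t priors on the standard deviations.  The
likelihood is evaluated via the Woodbury identity on the low-rank random
effect structure, so each evaluation costs O((J+S)^3) instead of O(n^3).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .exceptions import DesignError, FitError, NumericalError, PhyloTraitsError
from .io import TraitTable, drop_missing_for_trait
from .phylo import PhyloCorrelation

#: Ridge added to the diagonal of V before any factorization.
RIDGE = 1e-8

VARIANCE_COMPONENTS = ("tau_plot", "tau_phyl", "tau_ind", "sigma")


# ---------------------------------------------------------------------------
# parameters and model frame


@dataclasses.dataclass
class PGLMMParams:
    """Parameter point for the marginal model."""

    alpha0: float
    beta: np.ndarray  # site contrasts, length = n_sites - 1
    tau_plot: float
    tau_phyl: float
    tau_ind: float
    sigma: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        for name in VARIANCE_COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[self.alpha0], self.beta])

    def to_dict(self) -> dict[str, float]:
        d = {"alpha0": self.alpha0}
        d.update({f"beta_{i}": float(b) for i, b in enumerate(self.beta)})
        d.update({k: float(getattr(self, k)) for k in VARIANCE_COMPONENTS})
        return d


@dataclasses.dataclass
class ModelFrame:
    """Response and design information for one trait.

    ``y`` is the log-transformed trait; ``X`` the fixed-effect design
    (intercept plus treatment contrasts); ``plot_idx``/``species_idx`` map
    each observation to its plot/species level; ``species`` gives the species
    order the correlation matrix must follow.
    """

    y: np.ndarray
    X: np.ndarray
    plot_idx: np.ndarray
    species_idx: np.ndarray
    species: list[str]
    plots: list[str]
    x_names: list[str]
    trait: str = ""
    n_dropped: int = 0
    site_of_obs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.plot_idx = np.asarray(self.plot_idx, dtype=int)
        self.species_idx = np.asarray(self.species_idx, dtype=int)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.plot_idx) != n or len(self.species_idx) != n:
            raise PhyloTraitsError("model frame dimensions are inconsistent")

    @property
    def n_obs(self) -> int:
        return len(self.y)


def prepare_response(table: TraitTable, trait: str) -> ModelFrame:
    """Build the model frame for one trait: natural-log response, site
    treatment contrasts (lowest elevation as reference), plot and species
    index maps.  Rows with a missing value in ``trait`` are dropped and
    counted."""
    df, n_dropped = drop_missing_for_trait(table, trait)
    species = sorted(df["species"].unique())
    sites = sorted(df["site"].unique())
    if len(species) < 2 or len(sites) < 2:
        raise DesignError(
            f"trait {trait!r}: need >=2 species and >=2 sites after filtering "
            f"(got {len(species)} species, {len(sites)} sites)"
        )
    plots = sorted(df["plot"].unique())
    y = np.log(df[trait].to_numpy(dtype=float))
    n = len(y)
    X = np.ones((n, len(sites)))
    x_names = ["alpha0"]
    site_arr = df["site"].to_numpy()
    for j, s in enumerate(sites[1:], start=1):
        X[:, j] = (site_arr == s).astype(float)
        x_names.append(f"site_{s}")
    sp_map = {s: i for i, s in enumerate(species)}
    pl_map = {p: i for i, p in enumerate(plots)}
    return ModelFrame(
        y=y,
        X=X,
        plot_idx=df["plot"].map(pl_map).to_numpy(),
        species_idx=df["species"].map(sp_map).to_numpy(),
        species=species,
        plots=plots,
        x_names=x_names,
        trait=trait,
        n_dropped=n_dropped,
        site_of_obs=site_arr,
    )


# ---------------------------------------------------------------------------
# marginal likelihood via the Woodbury identity


class _Precomp:
    """Sufficient statistics for fast marginal-likelihood evaluation.

    With U = [Zp | Zs] the (n x (J+S)) random-effect incidence matrix, every
    evaluation needs only U'U, U'X, U'y and the eigendecomposition of rho —
    all computed once per (frame, rho) pair.
    """

    def __init__(self, frame: ModelFrame, rho: np.ndarray):
        self.n = frame.n_obs
        self.p = frame.X.shape[1]
        self.J = len(frame.plots)
        self.S = len(frame.species)
        if rho.shape != (self.S, self.S):
            raise PhyloTraitsError(
                f"rho is {rho.shape} but frame has {self.S} species"
            )
        n, J, S = self.n, self.J, self.S
        k = J + S
        U = np.zeros((n, k))
        U[np.arange(n), frame.plot_idx] = 1.0
        U[np.arange(n), J + frame.species_idx] = 1.0
        self.G = U.T @ U
        self.UtX = U.T @ frame.X
        self.Uty = U.T @ frame.y
        self.XtX = frame.X.T @ frame.X
        self.Xty = frame.X.T @ frame.y
        self.yty = float(frame.y @ frame.y)
        lam, Q = np.linalg.eigh(0.5 * (rho + rho.T))
        if lam[0] < -1e-8:
            raise NumericalError(
                f"rho is not positive semidefinite (min eigenvalue {lam[0]:.3e})"
            )
        self.lam = np.clip(lam, 0.0, None)
        self.Q = Q

    def _w(self, tau_plot: float, tau_phyl: float, tau_ind: float) -> np.ndarray:
        """Symmetric square root of the random-effect covariance D."""
        k = self.J + self.S
        W = np.zeros((k, k))
        W[: self.J, : self.J] = np.eye(self.J) * tau_plot
        d = np.sqrt(tau_phyl**2 * self.lam + tau_ind**2)
        W[self.J :, self.J :] = (self.Q * d) @ self.Q.T
        return W

    def _factor(self, tau_plot, tau_phyl, tau_ind, sigma):
        s2e = sigma**2 + RIDGE
        W = self._w(tau_plot, tau_phyl, tau_ind)
        C = np.eye(self.J + self.S) + (W @ self.G @ W) / s2e
        try:
            cf = linalg.cho_factor(C, lower=True)
        except linalg.LinAlgError as exc:
            ev = float(np.linalg.eigvalsh(C)[0])
            raise NumericalError(
                f"covariance factorization failed (min eigenvalue {ev:.3e})"
            ) from exc
        logdet = self.n * math.log(s2e) + 2.0 * float(
            np.sum(np.log(np.diag(cf[0])))
        )
        return s2e, W, cf, logdet

    def loglik(self, theta: np.ndarray, tau_plot, tau_phyl, tau_ind, sigma) -> float:
        s2e, W, cf, logdet = self._factor(tau_plot, tau_phyl, tau_ind, sigma)
        r2 = self.yty - 2.0 * float(self.Xty @ theta) + float(theta @ self.XtX @ theta)
        u = self.Uty - self.UtX @ theta
        q = W @ u
        quad = (r2 - float(q @ linalg.cho_solve(cf, q)) / s2e) / s2e
        return -0.5 * (self.n * math.log(2.0 * math.pi) + logdet + quad)

    def gls(self, tau_plot, tau_phyl, tau_ind, sigma):
        """GLS fixed effects and their covariance at given variance parameters,
        plus the profile log-likelihood."""
        s2e, W, cf, logdet = self._factor(tau_plot, tau_phyl, tau_ind, sigma)
        WUX = W @ self.UtX
        WUy = W @ self.Uty
        xvx = (self.XtX - WUX.T @ linalg.cho_solve(cf, WUX) / s2e) / s2e
        xvy = (self.Xty - WUX.T @ linalg.cho_solve(cf, WUy) / s2e) / s2e
        cov_theta = np.linalg.inv(xvx)
        theta = cov_theta @ xvy
        ll = self.loglik(theta, tau_plot, tau_phyl, tau_ind, sigma)
        return theta, cov_theta, ll


def _get_precomp(frame: ModelFrame, rho: np.ndarray | PhyloCorrelation) -> _Precomp:
    if isinstance(rho, PhyloCorrelation):
        rho = rho.reorder(frame.species).rho if rho.species != frame.species else rho.rho
    rho = np.asarray(rho, dtype=float)
    cache = getattr(frame, "_precomp_cache", None)
    key = (rho.shape, rho.tobytes())
    if cache is None:
        cache = {}
        object.__setattr__(frame, "_precomp_cache", cache)
    if key not in cache:
        cache[key] = _Precomp(frame, rho)
    return cache[key]


def marginal_loglik(
    params: PGLMMParams, frame: ModelFrame, rho: np.ndarray | PhyloCorrelation
) -> float:
    """Marginal log-likelihood log N(y | X theta, V) of the model.

    Exact (up to the diagonal ridge of 1e-8) and invariant to observation
    order; evaluated through the Woodbury identity.
    """
    pre = _get_precomp(frame, rho)
    if len(params.theta) != pre.p:
        raise PhyloTraitsError(
            f"expected {pre.p - 1} site contrasts, got {len(params.beta)}"
        )
    return pre.loglik(
        params.theta, params.tau_plot, params.tau_phyl, params.tau_ind, params.sigma
    )


# ---------------------------------------------------------------------------
# priors


@dataclasses.dataclass
class PriorSpec:
    """Weakly informative priors: Normal(0, loc_scale) on intercept/contrasts,
    half-t(sd_df, sd_scale) on every standard deviation."""

    loc_scale: float = 5.0
    sd_df: float = 3.0
    sd_scale: float = 2.5

    def log_prior(self, theta: np.ndarray, log_sds: np.ndarray) -> float:
        lp = float(np.sum(stats.norm.logpdf(theta, 0.0, self.loc_scale)))
        taus = np.exp(log_sds)
        # half-t density on tau, plus log-jacobian of the log transform
        lp += float(
            np.sum(
                math.log(2.0)
                + stats.t.logpdf(taus / self.sd_scale, self.sd_df)
                - math.log(self.sd_scale)
                + log_sds
            )
        )
        return lp


# ---------------------------------------------------------------------------
# highest posterior density interval


def hdi(draws: Sequence[float] | np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (sorted-window
    method).  Requires at least 100 draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise PhyloTraitsError(f"hdi requires >=100 draws, got {n}")
    if not 0 < prob < 1:
        raise PhyloTraitsError("prob must be in (0, 1)")
    m = int(math.ceil(prob * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# variance partition


@dataclasses.dataclass
class VariancePartition:
    """Fractions of total log-scale variance by model component.

    The fixed-effect (site) variance is the variance of the fitted fixed
    effects over the realized design (Nakagawa–Schielzeth convention); the
    random components contribute their variance parameters; the total is the
    sum of all five terms.
    """

    f_site: float
    f_plot: float
    f_phyl: float
    f_species: float
    f_resid: float

    @property
    def explained(self) -> float:
        return 1.0 - self.f_resid

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "site": self.f_site,
                "plot": self.f_plot,
                "phylogeny": self.f_phyl,
                "species": self.f_species,
                "residual": self.f_resid,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        s = self.to_series()
        return pd.DataFrame({"component": s.index, "fraction": s.to_numpy()})


def _fractions(
    beta_cov_of_X: np.ndarray, theta: np.ndarray, tp, tf, ti, sg
) -> np.ndarray:
    v_site = float(theta @ beta_cov_of_X @ theta)
    comps = np.array([v_site, tp**2, tf**2, ti**2, sg**2], dtype=float)
    total = comps.sum()
    if total <= 0:
        raise NumericalError("total variance is zero; degenerate fit")
    return comps / total


# ---------------------------------------------------------------------------
# results objects


class PGLMMResults:
    """Common result surface for both backends."""

    method: str

    def __init__(self, model: "PhylogeneticMixedLM", params: PGLMMParams):
        self.model = model
        self.params = params

    @property
    def param_names(self) -> list[str]:
        return list(self.model.frame.x_names) + list(VARIANCE_COMPONENTS)

    def _design_cov(self) -> np.ndarray:
        X = self.model.frame.X
        Xc = X - X.mean(axis=0)
        return (Xc.T @ Xc) / X.shape[0]

    def variance_partition(self) -> VariancePartition:
        raise NotImplementedError

    def summary(self) -> str:
        raise NotImplementedError

    def plot_variance_partition(self, ax=None):
        """Horizontal bar chart of the variance fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 2.5))
        s = self.variance_partition().to_series()
        ax.barh(s.index[::-1], s.to_numpy()[::-1])
        ax.set_xlabel("fraction of total variance")
        ax.set_xlim(0, 1)
        ax.set_title(self.model.frame.trait or "trait")
        return ax


class PGLMMResultsML(PGLMMResults):
    """Maximum-likelihood fit: point estimates, SEs, log-likelihood."""

    method = "ml"

    def __init__(self, model, params, llf, converged, bse_theta, diagnostics):
        super().__init__(model, params)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.bse_theta = np.asarray(bse_theta, dtype=float)
        self.diagnostics = diagnostics

    def variance_partition(self) -> VariancePartition:
        p = self.params
        f = _fractions(
            self._design_cov(), p.theta, p.tau_plot, p.tau_phyl, p.tau_ind, p.sigma
        )
        return VariancePartition(*f)

    def param_table(self) -> pd.DataFrame:
        p = self.params
        est = np.concatenate([p.theta, [p.tau_plot, p.tau_phyl, p.tau_ind, p.sigma]])
        se = np.concatenate([self.bse_theta, np.full(4, np.nan)])
        return pd.DataFrame({"parameter": self.param_names, "estimate": est, "se": se})

    def summary(self) -> str:
        lines = [
            f"Phylogenetic mixed model (ML) — trait: {self.model.frame.trait or '?'}",
            f"n_obs={self.model.frame.n_obs}  n_species={len(self.model.frame.species)}"
            f"  n_plots={len(self.model.frame.plots)}",
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            "",
            self.param_table().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Variance partition:",
            self.variance_partition().to_series().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class PGLMMResultsMCMC(PGLMMResults):
    """Posterior draws, 95% HDIs and sampler diagnostics."""

    method = "mcmc"

    def __init__(self, model, draws, diagnostics, converged, prob=0.95):
        #: draws: dict name -> array (chain, draw) on the natural scale
        self.draws = draws
        self.diagnostics = diagnostics
        self.converged = bool(converged)
        self.prob = prob
        means = {k: float(np.mean(v)) for k, v in draws.items()}
        p = model.frame.X.shape[1]
        params = PGLMMParams(
            alpha0=means["alpha0"],
            beta=np.array([means[n] for n in model.frame.x_names[1:]]),
            tau_plot=means["tau_plot"],
            tau_phyl=means["tau_phyl"],
            tau_ind=means["tau_ind"],
            sigma=means["sigma"],
        )
        super().__init__(model, params)

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.draws[name]))

    def hdi(self, name: str, prob: float | None = None) -> tuple[float, float]:
        return hdi(self.draws[name].ravel(), prob or self.prob)

    def credibly_nonzero(self, name: str) -> bool:
        lo, hi = self.hdi(name)
        return lo > 0 or hi < 0

    def variance_partition(self) -> VariancePartition:
        """Per-draw fractions summarized by the posterior mean."""
        S = self._design_cov()
        names = self.param_names
        flat = {k: self.draws[k].ravel() for k in names}
        nd = len(flat["alpha0"])
        theta = np.column_stack([flat[n] for n in self.model.frame.x_names])
        v_site = np.einsum("ij,jk,ik->i", theta, S, theta)
        comps = np.column_stack(
            [
                v_site,
                flat["tau_plot"] ** 2,
                flat["tau_phyl"] ** 2,
                flat["tau_ind"] ** 2,
                flat["sigma"] ** 2,
            ]
        )
        frac = comps / comps.sum(axis=1, keepdims=True)
        return VariancePartition(*frac.mean(axis=0))

    def param_table(self) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            lo, hi = self.hdi(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.posterior_mean(name),
                    "hdi_low": lo,
                    "hdi_high": hi,
                    "rhat": self.diagnostics["rhat"].get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            f"Phylogenetic mixed model (MCMC) — trait: {self.model.frame.trait or '?'}",
            f"chains={d['chains']}  walkers/chain={d['nwalkers']}  draws/walker={d['iters']}"
            f"  warmup={d['warmup']}",
            f"mean acceptance fraction: {d['acceptance_fraction']:.3f}"
            f"   max split-Rhat: {d['max_rhat']:.4f}   converged: {self.converged}",
            "",
            self.param_table().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "Variance partition (posterior mean of per-draw fractions):",
            self.variance_partition().to_series().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def variance_partition(results: PGLMMResults) -> VariancePartition:
    """Variance decomposition of a fitted model (delegates to the results)."""
    return results.variance_partition()


# ---------------------------------------------------------------------------
# model class


class PhylogeneticMixedLM:
    """Phylogenetic multilevel model for one log-transformed trait.

    Parameters
    ----------
    frame : ModelFrame
        Response and design (see :func:`prepare_response`).
    rho : PhyloCorrelation or (S, S) array
        Phylogenetic correlation among the frame's species; reordered to the
        frame's species order automatically when a :class:`PhyloCorrelation`
        is given.
    priors : PriorSpec, optional
        Priors for the MCMC backend.

    Examples
    --------
    >>> frame = prepare_response(table, "sla")          # doctest: +SKIP
    >>> model = PhylogeneticMixedLM(frame, rho)         # doctest: +SKIP
    >>> res = model.fit(seed=1)                         # doctest: +SKIP
    >>> res.variance_partition().to_series()            # doctest: +SKIP
    """

    def __init__(
        self,
        frame: ModelFrame,
        rho: PhyloCorrelation | np.ndarray,
        priors: PriorSpec | None = None,
    ):
        self.frame = frame
        if isinstance(rho, PhyloCorrelation):
            if rho.species != frame.species:
                rho = rho.reorder(frame.species)
            self.rho = rho.rho
        else:
            self.rho = np.asarray(rho, dtype=float)
        self.priors = priors or PriorSpec()
        self._pre = _get_precomp(frame, self.rho)

    @classmethod
    def from_trait_table(
        cls,
        table: TraitTable,
        trait: str,
        tree_or_rho,
        priors: PriorSpec | None = None,
    ) -> "PhylogeneticMixedLM":
        """Build the model straight from a trait table and a phylogeny."""
        from .phylo import phylo_correlation

        frame = prepare_response(table, trait)
        if isinstance(tree_or_rho, (PhyloCorrelation, np.ndarray)):
            rho = tree_or_rho
        else:
            rho = phylo_correlation(tree_or_rho, frame.species)
        return cls(frame, rho, priors=priors)

    def loglike(self, params: PGLMMParams) -> float:
        return marginal_loglik(params, self.frame, self.rho)

    # -- ML backend --------------------------------------------------------

    def _profile_nll(self, z: np.ndarray) -> float:
        tp, tf, ti, sg = np.exp(z)
        try:
            _, _, ll = self._pre.gls(tp, tf, ti, sg)
        except NumericalError:
            return 1e12
        return -ll

    def fit(
        self,
        starts: int = 5,
        seed: int = 0,
        maxiter: int = 500,
        bounds: tuple[float, float] = (-12.0, 6.0),
    ) -> PGLMMResultsML:
        """Maximum-likelihood fit by L-BFGS-B on the log-SD scale with seeded
        multi-starts; ties broken by best log-likelihood.

        The response is mean-centered internally (the offset is restored in
        the intercept), so shifting all responses by a constant reproduces
        the same variance-parameter optimization to machine precision.
        """
        offset = float(np.mean(self.frame.y))
        centered = dataclasses.replace(self.frame, y=self.frame.y - offset)
        pre_saved, self._pre = self._pre, _Precomp(centered, self.rho)
        try:
            result = self._fit_centered(centered, starts, seed, maxiter, bounds)
        finally:
            self._pre = pre_saved
        result.params.alpha0 += offset
        # restore log-likelihood and GLS quantities on the original scale
        result.llf = self.loglike(result.params)
        return result

    def _fit_centered(self, frame, starts, seed, maxiter, bounds) -> PGLMMResultsML:
        y = frame.y
        resid_sd = float(np.std(y - frame.X @ np.linalg.lstsq(frame.X, y, rcond=None)[0]))
        resid_sd = max(resid_sd, 1e-3)
        z0 = np.log(np.array([0.3, 0.5, 0.5, 0.6]) * resid_sd)
        rng = np.random.default_rng(seed)
        best = None
        n_ok = 0
        for s in range(max(1, starts)):
            z_init = z0 if s == 0 else z0 + rng.normal(0.0, 1.0, size=4)
            res = optimize.minimize(
                self._profile_nll,
                np.clip(z_init, *bounds),
                method="L-BFGS-B",
                bounds=[bounds] * 4,
                # tight tolerances so refits of equivalent problems (e.g.
                # shifted responses) land on the same optimum
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            n_ok += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        tp, tf, ti, sg = np.exp(best.x)
        theta, cov_theta, ll = self._pre.gls(tp, tf, ti, sg)
        params = PGLMMParams(
            alpha0=float(theta[0]),
            beta=theta[1:],
            tau_plot=tp,
            tau_phyl=tf,
            tau_ind=ti,
            sigma=sg,
        )
        diagnostics = {
            "n_starts": starts,
            "n_converged_starts": int(n_ok),
            "optimizer_message": str(best.message),
            "log_sd_at_bound": bool(
                np.any(np.isclose(best.x, bounds[0])) or np.any(np.isclose(best.x, bounds[1]))
            ),
        }
        if n_ok == 0:
            diagnostics["best_point"] = params.to_dict()
            raise FitError(
                f"no optimizer start converged (best ll {ll:.3f}); diagnostics: {diagnostics}"
            )
        return PGLMMResultsML(
            self,
            params,
            llf=ll,
            converged=n_ok > 0,
            bse_theta=np.sqrt(np.diag(cov_theta)),
            diagnostics=diagnostics,
        )

    # -- MCMC backend ------------------------------------------------------

    def _log_posterior(self, phi: np.ndarray) -> float:
        p = self._pre.p
        theta, z = phi[:p], phi[p:]
        if np.any(z < -15) or np.any(z > 8):
            return -np.inf
        ll = self._pre.loglik(theta, *np.exp(z))
        if not np.isfinite(ll):
            return -np.inf
        return ll + self.priors.log_prior(theta, z)

    def fit_mcmc(
        self,
        chains: int = 2,
        iters: int = 10_000,
        warmup: int = 10_000,
        seed: int = 0,
        nwalkers: int = 16,
        target_accept: float = 0.99,
        rhat_max: float = 1.01,
        prob: float = 0.95,
    ) -> PGLMMResultsMCMC:
        """Bayesian fit by affine-invariant ensemble MCMC.

        ``chains`` independent walker ensembles are run for ``warmup`` +
        ``iters`` steps each; warmup is discarded.  Convergence is assessed
        by the rank-normalized split-Rhat statistic treating every walker as
        a chain; the result is flagged (``converged=False``) when the largest
        Rhat exceeds ``rhat_max``, never silently returned.  ``target_accept``
        is recorded for the configuration contract; the ensemble sampler has
        no step-size adaptation to apply it to.  Fully reproducible by seed.
        """
        import emcee

        if chains < 2:
            raise PhyloTraitsError("need chains >= 2 for convergence diagnostics")
        p = self._pre.p
        ndim = p + 4
        nwalkers = max(nwalkers, 2 * ndim + 2)

        ml = self.fit(starts=3, seed=seed)
        center = np.concatenate(
            [
                ml.params.theta,
                np.log(
                    np.maximum(
                        [
                            ml.params.tau_plot,
                            ml.params.tau_phyl,
                            ml.params.tau_ind,
                            ml.params.sigma,
                        ],
                        1e-3,
                    )
                ),
            ]
        )
        seeds = np.random.SeedSequence(seed).generate_state(2 * chains)
        chain_arrays = []
        accept = []
        # differential-evolution moves mix markedly better than the default
        # stretch move on the correlated (beta, log-sd) posterior
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        for c in range(chains):
            rng = np.random.default_rng(seeds[2 * c])
            p0 = center + 0.25 * rng.standard_normal((nwalkers, ndim))
            sampler = emcee.EnsembleSampler(nwalkers, ndim, self._log_posterior, moves=moves)
            sampler.random_state = np.random.RandomState(int(seeds[2 * c + 1])).get_state()
            state = sampler.run_mcmc(p0, warmup, store=False)
            sampler.reset()
            sampler.run_mcmc(state, iters)
            chain_arrays.append(sampler.get_chain())  # (iters, nwalkers, ndim)
            accept.append(float(np.mean(sampler.acceptance_fraction)))

        # (chains*nwalkers, iters, ndim): each walker treated as one chain
        stacked = np.concatenate(
            [np.moveaxis(a, 0, 1) for a in chain_arrays], axis=0
        )
        names = list(self.frame.x_names) + list(VARIANCE_COMPONENTS)
        draws: dict[str, np.ndarray] = {}
        for i, name in enumerate(names):
            vals = stacked[:, :, i]
            if i >= p:
                vals = np.exp(vals)
            draws[name] = vals

        rhat = {name: _split_rhat(draws[name]) for name in names}
        max_rhat = float(max(rhat.values()))
        diagnostics = {
            "chains": chains,
            "nwalkers": nwalkers,
            "iters": iters,
            "warmup": warmup,
            "seed": seed,
            "target_accept": target_accept,
            "acceptance_fraction": float(np.mean(accept)),
            "acceptance_by_chain": accept,
            "rhat": rhat,
            "max_rhat": max_rhat,
            "divergences": 0,  # ensemble moves have no divergence concept
        }
        return PGLMMResultsMCMC(
            self, draws, diagnostics, converged=max_rhat < rhat_max, prob=prob
        )


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Rank-normalized split-Rhat (delegates to arviz)."""
    import warnings as _warnings

    import arviz as az

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(chains_draws)).x)
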