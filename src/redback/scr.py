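"""Robust-design open-population spatial capture-recapture (SCR) model.

Individuals carry a latent activity center (AC) that is uniform over the
state space on entry and performs a bivariate-normal random walk (per-axis
SD tau) between primary sessions.  Conditional on being alive in a primary,
an individual is detected at board j on each secondary occasion as an
independent Bernoulli with half-normal detection probability

    p = lambda * exp(-d^2 / (2 sigma^2)),

where d is the AC-to-board distance.  Demography is closed within primaries
(the likelihood depends on the data only through per-primary binomial
detection counts); between primaries individuals survive with probability
Phi^(Delta_days/365) (annual survival powered down to the interval length).
Population size is estimated by data augmentation: M histories (observed
plus all-zero) are included with probability psi, and density is the
posterior alive count per unit state-space area, averaged over primaries.
Mean between-season dispersal is tau * sqrt(pi/2), the mean length of a
bivariate-normal displacement.

Sampling strategy: the latent AC path, death time and inclusion indicator
of every individual are marginalized analytically.  The AC path is
integrated over a regular grid by a hidden-Markov forward pass whose
transition kernel is a separable Gaussian blur (SD tau); death is an
absorbing state; the all-zero histories share one marginal likelihood.
What remains is a 5-parameter posterior explored by random-walk Metropolis
on (sigma, lambda) and (Phi, tau) with a collapsed-Gibbs update for psi.
Latent alive counts (for the density posterior) are re-sampled from their
conditional distribution at each saved iteration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit, logit

from .design import StudyDesign

__all__ = [
    "SCRParams",
    "CaptureTable",
    "SCRPosterior",
    "MCMCConfig",
    "PriorConfig",
    "detection_prob",
    "detection_loglik",
    "marginal_likelihood",
    "fit_scr",
    "compare_plots",
    "summarize_scr",
]

CAPTURE_COLUMNS = [
    "individual_id",
    "plot_id",
    "primary",
    "secondary",
    "board_x",
    "board_y",
    "svl_mm",
    "sex",
]


@dataclass(frozen=True)
class SCRParams:
    """Demographic and observation parameters of the robust-design SCR model.

    phi      annual survival probability, in [0, 1]
    sigma    space-use (movement) scale in meters
    lam      baseline per-board, per-occasion detection probability, in [0, 1]
    density  individuals per square meter of state space
    tau      per-axis SD (m) of the between-primary AC random walk
    """

    phi: float
    sigma: float
    lam: float
    density: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("sigma and tau must be non-negative")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def mean_dispersal(self) -> float:
        """Mean between-primary AC displacement: tau * sqrt(pi/2), meters."""
        return self.tau * math.sqrt(math.pi / 2.0)


class CaptureTable:
    """Long-format detections: one row per (individual, primary, secondary, board).

    Columns: individual_id, plot_id, primary (1-based), secondary (1-based
    within primary), board_x, board_y (m), svl_mm (optional, NaN allowed),
    sex (optional, '' allowed).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"capture table missing columns: {missing}")
        df = df.loc[:, CAPTURE_COLUMNS].reset_index(drop=True)
        key = ["individual_id", "primary", "secondary", "board_x", "board_y"]
        dup = df.duplicated(subset=key)
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise ValueError(
                f"duplicate (individual, occasion, board) rows at indices {rows}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def individuals(self) -> np.ndarray:
        return np.asarray(sorted(self.df["individual_id"].unique()))

    @property
    def n_individuals(self) -> int:
        return self.df["individual_id"].nunique()

    def validate_against(self, design: StudyDesign) -> None:
        """Check board membership and session indices against the design."""
        if len(self.df) == 0:
            return
        idx = design.board_index(self.df["board_x"].values, self.df["board_y"].values)
        if (idx < 0).any():
            bad = int(np.nonzero(idx < 0)[0][0])
            raise ValueError(
                f"row {bad}: board ({self.df['board_x'][bad]}, "
                f"{self.df['board_y'][bad]}) is not in the design"
            )
        prim = self.df["primary"].to_numpy()
        if prim.min() < 1 or prim.max() > design.n_primary:
            raise ValueError("primary index outside design bounds")
        nsec = np.asarray(design.secondaries_per_primary)
        sec = self.df["secondary"].to_numpy()
        if sec.min() < 1 or (sec > nsec[prim - 1]).any():
            raise ValueError("secondary index outside design bounds")

    def detection_counts(self, design: StudyDesign) -> tuple[np.ndarray, np.ndarray]:
        """Aggregate to per-primary binomial counts.

        Returns ``(ids, y)`` with ``y`` of shape (n_individuals, J, T): number
        of secondary occasions in primary t on which individual i was detected
        at board j.  Closure within primaries makes the likelihood depend on
        the data only through these counts.
        """
        self.validate_against(design)
        ids = self.individuals
        id_index = {v: k for k, v in enumerate(ids)}
        y = np.zeros((len(ids), design.n_boards, design.n_primary), dtype=np.int16)
        if len(self.df) == 0:
            return ids, y
        i = self.df["individual_id"].map(id_index).to_numpy()
        j = design.board_index(self.df["board_x"].values, self.df["board_y"].values)
        t = self.df["primary"].to_numpy() - 1
        np.add.at(y, (i, j, t), 1)
        return ids, y


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings (desk-scale defaults; scale up for production runs)."""

    n_chains: int = 2
    n_iter: int = 1500
    n_burn: int = 500
    thin: int = 1
    rhat_threshold: float = 1.05
    adapt_every: int = 50


@dataclass(frozen=True)
class PriorConfig:
    """Uniform priors on all top-level parameters (only the AC prior is
    dictated by the model; the rest are weakly informative by range)."""

    sigma_max: float = 20.0
    tau_max: float = 20.0
    # phi, lam, psi ~ Uniform(0, 1)


@dataclass
class SCRPosterior:
    """Posterior draws (chains x draws) with convergence diagnostics."""

    draws: dict[str, np.ndarray]
    n_alive: np.ndarray  # (chains, draws, T) latent alive count per primary
    area: float
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def flat(self, parameter: str) -> np.ndarray:
        if parameter not in self.draws:
            raise KeyError(
                f"parameter {parameter!r} not in posterior "
                f"(have {sorted(self.draws)})"
            )
        return self.draws[parameter].reshape(-1)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)


def detection_prob(d2: np.ndarray, sigma: float, lam: float) -> np.ndarray:
    """Half-normal detection probability from squared distance."""
    return lam * np.exp(-d2 / (2.0 * sigma**2))


def detection_loglik(
    ac: np.ndarray,
    boards: np.ndarray,
    y: np.ndarray,
    n_occasions: float,
    sigma: float,
    lam: float,
) -> np.ndarray:
    """Log-likelihood of one primary's detection counts given the AC.

    ``ac`` may be a single coordinate pair or an array of candidate ACs
    (n, 2); ``y`` holds per-board detection counts out of ``n_occasions``
    Bernoulli occasions.  The binomial coefficient is omitted (constant in
    the parameters).  Exposed for oracle tests of the marginal likelihood.
    """
    ac = np.atleast_2d(np.asarray(ac, dtype=float))
    d2 = ((ac[:, None, :] - boards[None, :, :]) ** 2).sum(-1)
    p = detection_prob(d2, sigma, lam)
    y = np.asarray(y, dtype=float)
    ll = y[None, :] * np.log(np.maximum(p, 1e-300)) + (n_occasions - y)[
        None, :
    ] * np.log1p(-p)
    return ll.sum(axis=1)


def _log_prior_death(phi: float, r: np.ndarray) -> np.ndarray:
    """log P(last primary alive = d), d = 0..T-1, for individuals entering at
    primary 1; ``r`` holds interval lengths in years."""
    T = len(r) + 1
    logphi_cum = np.concatenate([[0.0], np.cumsum(r) * np.log(max(phi, 1e-300))])
    lp = np.empty(T)
    for d in range(T - 1):
        lp[d] = logphi_cum[d] + np.log(max(1.0 - phi ** r[d], 1e-300))
    lp[T - 1] = logphi_cum[T - 1]
    return lp


class _AdaptiveMVN:
    """Adaptive-Metropolis proposal for a small parameter block.

    During burn-in the proposal covariance is re-estimated from the chain
    history (plus jitter) and the global scale tuned toward a target
    acceptance rate; both freeze after burn-in.
    """

    def __init__(self, chol: np.ndarray, target: float = 0.3):
        self.chol = np.asarray(chol, dtype=float)
        self.dim = len(self.chol)
        self.scale = 1.0
        self.target = target
        self.accepts = 0.0
        self.trials = 0.0
        self.history: list[np.ndarray] = []
        # variance floor (5% of the initial proposal scale per axis) so a
        # degenerate early history can never freeze the chain
        self._floor = 0.0025 * np.diag(self.chol @ self.chol.T)

    def propose(self, cur: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return cur + self.scale * (self.chol @ rng.normal(size=self.dim))

    def update(self) -> None:
        if self.trials:
            rate = self.accepts / self.trials
            self.scale = float(
                np.clip(self.scale * math.exp(0.7 * (rate - self.target)), 0.1, 10.0)
            )
            self.accepts = 0.0
            self.trials = 0.0
        if len(self.history) >= 60:
            X = np.asarray(self.history[-400:])
            cov = np.cov(X.T) + np.diag(self._floor)
            try:
                self.chol = np.linalg.cholesky(cov)
                self.scale = 2.4 / math.sqrt(self.dim)
            except np.linalg.LinAlgError:
                pass


class _MarginalSCR:
    """Grid-marginalized likelihood machinery for one dataset."""

    def __init__(
        self,
        y: np.ndarray,  # (n_det, J, T) counts
        design: StudyDesign,
        grid_cell: float,
    ):
        self.design = design
        self.y = y.astype(float)
        self.n_det, self.J, self.T = y.shape
        self.n_sec = np.asarray(design.secondaries_per_primary, dtype=float)
        self.r = design.intervals_days / 365.0
        xmin, xmax, ymin, ymax = design.bounds
        self.nx = max(2, int(round((xmax - xmin) / grid_cell)))
        self.ny = max(2, int(round((ymax - ymin) / grid_cell)))
        self.cell = grid_cell
        xs = xmin + (np.arange(self.nx) + 0.5) * (xmax - xmin) / self.nx
        ys = ymin + (np.arange(self.ny) + 0.5) * (ymax - ymin) / self.ny
        gx, gy = np.meshgrid(xs, ys)
        cells = np.column_stack([gx.ravel(), gy.ravel()])
        self.ncell = len(cells)
        self.d2 = (
            (cells[:, None, :] - design.board_positions[None, :, :]) ** 2
        ).sum(-1)  # (ncell, J)
        # sparse detection corrections: per (i, t) with detections
        self.hits_by_t: list[tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]] = []
        for t in range(self.T):
            rows = np.nonzero(y[:, :, t].sum(axis=1) > 0)[0]
            jj_list = [np.nonzero(y[i, :, t] > 0)[0] for i in rows]
            cnt_list = [y[i, jj, t].astype(float) for i, jj in zip(rows, jj_list)]
            self.hits_by_t.append((rows, jj_list, cnt_list))
        self.zero_mask = (y.sum(axis=1) == 0).astype(float)  # (n_det, T)

    # -- emissions ---------------------------------------------------------

    def emissions(self, sigma: float, lam: float) -> tuple[np.ndarray, list]:
        """Shared all-zero emission per (primary, cell), plus per-primary
        sparse corrections (rows, multiplicative factors) for individuals
        with detections in that primary."""
        p = detection_prob(self.d2, sigma, lam)  # (ncell, J)
        lp = np.log(np.maximum(p, 1e-300))
        l1p = np.log1p(-p)
        s0 = l1p.sum(axis=1)  # (ncell,)
        E0 = np.exp(self.n_sec[:, None] * s0[None, :])  # (T, ncell)
        corr = []
        for t in range(self.T):
            rows, jj_list, cnt_list = self.hits_by_t[t]
            if len(rows) == 0:
                corr.append((rows, None))
                continue
            C = np.empty((len(rows), self.ncell))
            for k, (jj, cnt) in enumerate(zip(jj_list, cnt_list)):
                C[k] = (cnt[None, :] * (lp[:, jj] - l1p[:, jj])).sum(axis=1)
            corr.append((rows, np.exp(C)))
        return E0, corr

    def _kernels(self, tau: float) -> tuple[np.ndarray, np.ndarray]:
        """Dense 1-D dispersal kernels (reflecting edges, mass-conserving
        approximation to unbounded Gaussian steps)."""
        s = tau / self.cell
        Ky = gaussian_filter1d(np.eye(self.ny), s, axis=0, mode="reflect")
        Kx = gaussian_filter1d(np.eye(self.nx), s, axis=0, mode="reflect")
        return Ky, Kx

    def _blur(self, F: np.ndarray, Ky: np.ndarray, Kx: np.ndarray) -> np.ndarray:
        """Separable dispersal blur via batched matrix products."""
        G = F.reshape(-1, self.ny, self.nx)
        G = np.matmul(np.matmul(Ky, G), Kx)
        return G.reshape(F.shape)

    # -- marginal likelihoods ----------------------------------------------

    def forward(
        self,
        E0: np.ndarray,
        corr: list,
        phi: float,
        tau: float,
        with_hits: bool = True,
    ) -> np.ndarray:
        """Marginal likelihood per history, integrating AC path and death.

        With ``with_hits`` the (n_det,) likelihoods of the observed histories
        are returned; without, the scalar all-zero-history likelihood.
        Binomial coefficients are omitted throughout.
        """
        Ky, Kx = self._kernels(tau)
        if with_hits:
            F = np.repeat(E0[0][None, :] / self.ncell, self.n_det, axis=0)
            rows, C = corr[0][0], corr[0][1]
            if len(rows):
                F[rows] *= C
            dead = np.zeros(self.n_det)
            for t in range(1, self.T):
                phi_t = phi ** self.r[t - 1]
                dead = (dead + (1.0 - phi_t) * F.sum(axis=1)) * self.zero_mask[:, t]
                F = phi_t * self._blur(F, Ky, Kx) * E0[t][None, :]
                rows, C = corr[t][0], corr[t][1]
                if len(rows):
                    F[rows] *= C
            return F.sum(axis=1) + dead
        F0 = E0[0] / self.ncell
        dead0 = 0.0
        for t in range(1, self.T):
            phi_t = phi ** self.r[t - 1]
            dead0 = dead0 + (1.0 - phi_t) * F0.sum()
            F0 = phi_t * self._blur(F0[None, :], Ky, Kx)[0] * E0[t]
        return np.asarray(F0.sum() + dead0)

    def survivor_partials(
        self, E0: np.ndarray, corr: list | None, tau: float
    ) -> np.ndarray:
        """A*[n, d]: likelihood of the history through primary d conditional
        on being alive through d (no survival factors), for death-time
        resampling.  ``corr=None`` gives the all-zero history row."""
        Ky, Kx = self._kernels(tau)
        if corr is None:
            A = np.empty((1, self.T))
            F = E0[0][None, :] / self.ncell
            A[0, 0] = F.sum()
            for t in range(1, self.T):
                F = self._blur(F, Ky, Kx) * E0[t][None, :]
                A[0, t] = F.sum()
            return A
        A = np.empty((self.n_det, self.T))
        F = np.repeat(E0[0][None, :] / self.ncell, self.n_det, axis=0)
        rows, C = corr[0][0], corr[0][1]
        if len(rows):
            F[rows] *= C
        A[:, 0] = F.sum(axis=1)
        for t in range(1, self.T):
            F = self._blur(F, Ky, Kx) * E0[t][None, :]
            rows, C = corr[t][0], corr[t][1]
            if len(rows):
                F[rows] *= C
            A[:, t] = F.sum(axis=1)
        return A

    def log_marginal(
        self,
        sigma: float,
        lam: float,
        phi: float,
        tau: float,
        psi: float,
        M: int,
        cache: dict | None = None,
    ) -> float:
        """Total log-likelihood of the augmented data set."""
        E0, corr = self.emissions(sigma, lam)
        L = self.forward(E0, corr, phi, tau)
        L0 = float(self.forward(E0, corr, phi, tau, with_hits=False))
        if cache is not None:
            cache["E0"], cache["corr"], cache["L"], cache["L0"] = E0, corr, L, L0
        ll = float(np.log(np.maximum(L, 1e-300)).sum()) + self.n_det * math.log(psi)
        ll += (M - self.n_det) * math.log((1.0 - psi) + psi * L0)
        return ll


def marginal_likelihood(
    data: CaptureTable,
    design: StudyDesign,
    params: SCRParams,
    grid_cell: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Marginal likelihood of each observed history (and of the all-zero
    history) under given parameters, integrating AC paths over a grid and
    death times analytically.  Binomial coefficients are omitted."""
    ids, y = data.detection_counts(design)
    mdl = _MarginalSCR(y, design, grid_cell)
    E0, corr = mdl.emissions(params.sigma, params.lam)
    L = mdl.forward(E0, corr, params.phi, params.tau)
    L0 = float(mdl.forward(E0, corr, params.phi, params.tau, with_hits=False))
    return L, L0


def fit_scr(
    data: CaptureTable,
    design: StudyDesign,
    mcmc: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
    M: int | None = None,
    max_density: float = 1.0,
    grid_cell: float = 1.0,
    seed: int = 0,
) -> SCRPosterior:
    """Fit the robust-design SCR model by MCMC with grid-marginalized ACs.

    Parameters
    ----------
    M
        Data-augmentation size.  Defaults to ``ceil(max_density * area)``,
        the state space filled at an ecological upper-bound density of
        ``max_density`` individuals per m^2.
    grid_cell
        Cell size (m) of the AC integration grid.
    """
    mcmc = mcmc or MCMCConfig()
    priors = priors or PriorConfig()
    rng = np.random.default_rng(seed)

    ids, y_obs = data.detection_counts(design)
    n_det = len(ids)
    if n_det == 0:
        raise ValueError("no detections: nothing to fit")
    if y_obs.sum(axis=(1, 2)).max() <= 1:
        raise ValueError(
            "no recaptured individual: the space-use scale sigma is "
            "unidentifiable without spatial recaptures"
        )

    area = design.area
    if M is None:
        M = int(math.ceil(max_density * area))
    if M <= n_det:
        raise ValueError(f"augmentation size M={M} must exceed n detected={n_det}")

    mdl = _MarginalSCR(y_obs, design, grid_cell)
    T = mdl.T
    r = mdl.r

    # moment-based starting values
    boards = design.board_positions
    wsum = y_obs.astype(float).sum(axis=2)  # (n, J)
    cent = (wsum @ boards) / wsum.sum(axis=1)[:, None]
    spread = []
    for i in range(n_det):
        jj = np.nonzero(wsum[i] > 0)[0]
        if len(jj) > 1:
            spread.append(((boards[jj] - cent[i]) ** 2).sum(-1).mean())
    sigma0 = float(np.clip(np.sqrt(np.mean(spread)) if spread else 2.0, 0.8, 10.0))
    lam0 = float(
        np.clip(
            y_obs.sum() / (n_det * mdl.n_sec.sum() * min(mdl.J, 2 * math.pi * sigma0**2)),
            1e-3,
            0.5,
        )
    )

    n_save = (mcmc.n_iter - mcmc.n_burn) // mcmc.thin
    names = ["phi", "sigma", "lam", "tau", "psi", "density", "dispersal"]
    all_draws = {k: np.empty((mcmc.n_chains, n_save)) for k in names}
    all_alive = np.empty((mcmc.n_chains, n_save, T))

    for chain in range(mcmc.n_chains):
        crng = np.random.default_rng(rng.integers(2**31 - 1))
        sigma = sigma0 * math.exp(crng.normal(0, 0.1))
        lam = lam0
        phi, tau = 0.95, max(1.0, sigma0 / 3)
        psi = float(np.clip(2.0 * n_det / M, 0.05, 0.95))

        cache: dict = {}
        cur = mdl.log_marginal(sigma, lam, phi, tau, psi, M, cache)

        # initial proposal directions: (log sigma, logit lam) along the
        # lam*sigma^2 ~ const ridge; (logit phi, log tau) independent
        obs_step = _AdaptiveMVN(np.array([[0.08, 0.0], [-0.16, 0.08]]))
        dem_step = _AdaptiveMVN(np.array([[0.3, 0.0], [0.0, 0.15]]))
        isave = 0
        for it in range(mcmc.n_iter):
            # --- (sigma, lambda) joint MH -------------------------------
            cur_obs = np.array([math.log(sigma), logit(lam)])
            prop = obs_step.propose(cur_obs, crng)
            sig_p, lam_p = math.exp(prop[0]), float(expit(prop[1]))
            if 0 < sig_p < priors.sigma_max:
                cache_p: dict = {}
                new = mdl.log_marginal(sig_p, lam_p, phi, tau, psi, M, cache_p)
                logr = new - cur
                logr += math.log(sig_p) - math.log(sigma)
                logr += math.log(lam_p) + math.log1p(-lam_p)
                logr -= math.log(lam) + math.log1p(-lam)
                if math.log(crng.random()) < logr:
                    sigma, lam, cur, cache = sig_p, lam_p, new, cache_p
                    obs_step.accepts += 1
            obs_step.trials += 1
            if it < mcmc.n_burn:
                obs_step.history.append([math.log(sigma), logit(lam)])

            # --- (phi, tau) joint MH (emissions reused) ------------------
            cur_dem = np.array([logit(phi), math.log(tau)])
            propd = dem_step.propose(cur_dem, crng)
            phi_p, tau_p = float(expit(propd[0])), math.exp(propd[1])
            if 0 < tau_p < priors.tau_max:
                E0, corr = cache["E0"], cache["corr"]
                L_p = mdl.forward(E0, corr, phi_p, tau_p)
                L0_p = float(mdl.forward(E0, corr, phi_p, tau_p, with_hits=False))
                new = float(np.log(np.maximum(L_p, 1e-300)).sum())
                new += n_det * math.log(psi)
                new += (M - n_det) * math.log((1 - psi) + psi * L0_p)
                logr = new - cur
                logr += math.log(phi_p) + math.log1p(-phi_p)
                logr -= math.log(phi) + math.log1p(-phi)
                logr += math.log(tau_p) - math.log(tau)
                if math.log(crng.random()) < logr:
                    phi, tau, cur = phi_p, tau_p, new
                    cache["L"], cache["L0"] = L_p, L0_p
                    dem_step.accepts += 1
            dem_step.trials += 1
            if it < mcmc.n_burn:
                dem_step.history.append([logit(phi), math.log(tau)])

            # --- psi (collapsed Gibbs via momentary inclusion draws) -----
            L0 = cache["L0"]
            q_inc = psi * L0 / (psi * L0 + (1.0 - psi))
            n_inc = int(crng.binomial(M - n_det, q_inc))
            psi = float(crng.beta(1 + n_det + n_inc, 1 + M - n_det - n_inc))
            cur = (
                float(np.log(np.maximum(cache["L"], 1e-300)).sum())
                + n_det * math.log(psi)
                + (M - n_det) * math.log((1 - psi) + psi * L0)
            )

            if it < mcmc.n_burn and (it + 1) % mcmc.adapt_every == 0:
                obs_step.update()
                dem_step.update()

            # --- record: resample latent alive counts --------------------
            if it >= mcmc.n_burn and (it - mcmc.n_burn) % mcmc.thin == 0:
                lpD = _log_prior_death(phi, r)
                # detected: P(D = d | y) over allowed death times
                A = mdl.survivor_partials(cache["E0"], cache["corr"], tau)
                zc = np.cumprod(mdl.zero_mask[:, ::-1], axis=1)[:, ::-1]
                allow = np.ones((n_det, T))
                allow[:, :-1] = zc[:, 1:]  # all-zero after d
                logw = lpD[None, :] + np.log(np.maximum(A, 1e-300))
                logw = np.where(allow > 0, logw, -np.inf)
                g = -np.log(-np.log(crng.random((n_det, T))))
                D_det = np.argmax(logw + g, axis=1)
                # augmented: include with prob q, death time from its
                # zero-history conditional
                A0 = mdl.survivor_partials(cache["E0"], None, tau)[0]
                logw0 = lpD + np.log(np.maximum(A0, 1e-300))
                pD0 = np.exp(logw0 - logw0.max())
                pD0 /= pD0.sum()
                q_inc = psi * cache["L0"] / (psi * cache["L0"] + 1 - psi)
                n_inc = int(crng.binomial(M - n_det, q_inc))
                D_aug = crng.multinomial(n_inc, pD0)
                alive_t = np.array(
                    [
                        int((D_det >= t).sum()) + int(D_aug[t:].sum())
                        for t in range(T)
                    ],
                    dtype=float,
                )
                all_draws["phi"][chain, isave] = phi
                all_draws["sigma"][chain, isave] = sigma
                all_draws["lam"][chain, isave] = lam
                all_draws["tau"][chain, isave] = tau
                all_draws["psi"][chain, isave] = psi
                all_draws["density"][chain, isave] = alive_t.mean() / area
                all_draws["dispersal"][chain, isave] = tau * math.sqrt(math.pi / 2)
                all_alive[chain, isave] = alive_t
                isave += 1

    post = SCRPosterior(draws=all_draws, n_alive=all_alive, area=area)
    _attach_diagnostics(post, mcmc.rhat_threshold)
    return post


def _attach_diagnostics(post: SCRPosterior, threshold: float) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(dict(post.draws))
        rh = az.rhat(ds)
        es = az.ess(ds)
    for k in post.draws:
        post.rhat[k] = float(rh[k].values)
        post.ess[k] = float(es[k].values)
    bad = {k: v for k, v in post.rhat.items() if np.isfinite(v) and v > threshold}
    if bad:
        msg = f"Rhat above {threshold}: " + ", ".join(
            f"{k}={v:.3f}" for k, v in bad.items()
        )
        post.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)


def compare_plots(
    post_a: SCRPosterior | dict[str, np.ndarray],
    post_b: SCRPosterior | dict[str, np.ndarray],
    parameter: str,
    seed: int = 0,
) -> float:
    """Pr(parameter_b > parameter_a) by pairing random posterior draws.

    This is the posterior-comparison probability reported alongside each
    parameter when two plots are fitted independently.
    """

    def _get(p, name):
        if isinstance(p, dict):
            if name not in p:
                raise KeyError(f"parameter {name!r} not in posterior")
            return np.asarray(p[name]).reshape(-1)
        return p.flat(name)

    a = _get(post_a, parameter)
    b = _get(post_b, parameter)
    rng = np.random.default_rng(seed)
    n = max(len(a), len(b), 10_000)
    av = rng.choice(a, n, replace=True)
    bv = rng.choice(b, n, replace=True)
    # ties (duplicated MH draws) count half, so identical posteriors give 0.5
    return float(np.mean(bv > av) + 0.5 * np.mean(bv == av))


def summarize_scr(post: SCRPosterior) -> pd.DataFrame:
    """Posterior mean, SD and central 95% credible interval per parameter."""
    if not post.draws or next(iter(post.draws.values())).size == 0:
        raise ValueError("empty posterior")
    rows = []
    for name in post.parameters:
        x = post.flat(name)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=0)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "rhat": post.rhat.get(name, np.nan),
                "ess": post.ess.get(name, np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
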