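"""Synthetic-data generators mirroring the field study's designs.

Every downstream stage (SCR fit, growth fit, clutch regression, projection)
can be exercised without any field data: capture histories are simulated
from the generative SCR model, recapture SVL series from the Fabens growth
model, and a clutch-size-vs-SVL table from a linear model with normal
residuals (a synthetic stand-in for the published regional clutch data).
Ground-truth parameters are retained so recovery tests can score coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign
from .growth import GrowthObservation, GrowthParams, fabens_update
from .scr import CAPTURE_COLUMNS, CaptureTable, SCRParams, detection_prob

__all__ = [
    "TruthParams",
    "SCRLatentTruth",
    "simulate_scr_history",
    "simulate_growth_series",
    "make_clutch_table",
]


@dataclass(frozen=True)
class TruthParams:
    """Bundle of generating parameters for simulation-recovery runs."""

    scr: SCRParams
    growth: GrowthParams
    seed: int = 0


@dataclass(frozen=True)
class SCRLatentTruth:
    """Latent state of one SCR simulation (for tests, never for fitting)."""

    n_individuals: int
    activity_centers: np.ndarray  # (N, T, 2)
    alive: np.ndarray  # (N, T) bool
    density: float  # realized N at entry / area


def simulate_scr_history(
    design: StudyDesign,
    truth: TruthParams,
    seed: int | None = None,
    plot_id: str = "mature",
    return_latent: bool = False,
) -> CaptureTable | tuple[CaptureTable, SCRLatentTruth]:
    """Simulate a robust-design SCR capture history.

    N = density x state-space area individuals are present from the first
    primary session with activity centers uniform over the state space.
    Between consecutive primaries each individual survives with probability
    Phi^(interval_days/365) and its AC takes a bivariate-normal step with
    per-axis SD tau.  Within each secondary occasion of a primary, detection
    at board j is an independent Bernoulli with half-normal probability
    lam * exp(-d^2/(2 sigma^2)).  Only detected individuals appear in the
    returned table.
    """
    p = truth.scr
    if p.density <= 0:
        raise ValueError("density must be positive")
    design.check_buffer(p.sigma)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    T = design.n_primary
    boards = design.board_positions
    xmin, xmax, ymin, ymax = design.bounds
    N = int(round(p.density * design.area))
    if N < 1:
        raise ValueError("density x area rounds to zero individuals")

    acs = np.empty((N, T, 2))
    acs[:, 0, 0] = rng.uniform(xmin, xmax, N)
    acs[:, 0, 1] = rng.uniform(ymin, ymax, N)
    alive = np.ones((N, T), dtype=bool)
    intervals = design.intervals_days
    for t in range(1, T):
        phi_t = p.phi ** (intervals[t - 1] / 365.0)
        alive[:, t] = alive[:, t - 1] & (rng.random(N) < phi_t)
        acs[:, t, :] = acs[:, t - 1, :] + rng.normal(0, p.tau, (N, 2))

    rows: list[tuple] = []
    for t in range(T):
        d2 = ((acs[:, t, None, :] - boards[None, :, :]) ** 2).sum(-1)
        pdet = detection_prob(d2, p.sigma, p.lam) * alive[:, t, None]
        for occ in range(design.secondaries_per_primary[t]):
            hit_i, hit_j = np.nonzero(rng.random((N, len(boards))) < pdet)
            for i, j in zip(hit_i, hit_j):
                rows.append(
                    (
                        f"ind{i:04d}",
                        plot_id,
                        t + 1,
                        occ + 1,
                        boards[j, 0],
                        boards[j, 1],
                        np.nan,
                        "",
                    )
                )
    table = CaptureTable(pd.DataFrame(rows, columns=CAPTURE_COLUMNS))
    if return_latent:
        latent = SCRLatentTruth(
            n_individuals=N,
            activity_centers=acs,
            alive=alive,
            density=N / design.area,
        )
        return table, latent
    return table


def simulate_growth_series(
    truth: TruthParams,
    n_individuals: int,
    capture_schedule: np.ndarray | list[float],
    seed: int | None = None,
    svl0_range: tuple[float, float] = (18.0, 40.0),
    sigma_obs: float = 0.5,
    p_male: float = 0.5,
    p_successional: float = 0.5,
) -> list[GrowthObservation]:
    """Simulate recapture SVL series under the Fabens growth model.

    Each individual is assigned a sex and plot (independent Bernoulli with
    the given proportions), an initial SVL uniform on ``svl0_range`` (which
    must sit inside the [10, 60] mm support), and successive SVLs follow the
    Fabens update applied to the previously recorded size plus Gaussian
    measurement noise of SD ``sigma_obs`` (set 0 for noise-free series).
    ``capture_schedule`` lists the between-capture intervals in days.
    """
    schedule = np.asarray(capture_schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("capture schedule must be non-empty")
    if np.any(schedule <= 0):
        raise ValueError("capture intervals must be positive")
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    lo, hi = svl0_range
    if lo < 10.0 or hi > 60.0 or lo >= hi:
        raise ValueError("svl0_range must be an interval within [10, 60] mm")

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    g = truth.growth
    out: list[GrowthObservation] = []
    for i in range(n_individuals):
        sex = "male" if rng.random() < p_male else "female"
        plot = "successional" if rng.random() < p_successional else "mature"
        K = g.K(plot, sex)
        L = g.L(sex)
        svl = [float(rng.uniform(lo, hi))]
        for dt in schedule:
            expected = fabens_update(svl[-1], L, K, dt)
            svl.append(float(expected + rng.normal(0, sigma_obs)))
        out.append(
            GrowthObservation(
                individual_id=f"g{i:04d}",
                sex=sex,
                plot=plot,
                svl=np.asarray(svl),
                intervals_days=schedule.copy(),
            )
        )
    return out


def make_clutch_table(
    n: int,
    intercept: float = -3.0,
    slope: float = 0.22,
    residual_sd: float = 1.5,
    svl_range: tuple[float, float] = (34.0, 52.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic clutch-size-vs-SVL table (stand-in for regional clutch data).

    clutch = intercept + slope * SVL + Normal(0, residual_sd), floored at 1
    egg.  SVLs are uniform over ``svl_range`` (reproductive female sizes).
    The generating parameters are recorded in ``DataFrame.attrs`` for
    recovery tests.
    """
    if n < 3:
        raise ValueError("need n >= 3 rows to fit a line")
    if slope < 0:
        raise ValueError("slope must be non-negative (larger females lay more)")
    rng = np.random.default_rng(seed)
    svl = rng.uniform(svl_range[0], svl_range[1], n)
    clutch = intercept + slope * svl + rng.normal(0, residual_sd, n)
    clutch = np.maximum(clutch, 1.0)
    df = pd.DataFrame({"svl_mm": svl, "clutch_size": clutch})
    df.attrs["truth"] = {
        "intercept": intercept,
        "slope": slope,
        "residual_sd": residual_sd,
    }
    return df
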