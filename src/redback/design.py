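"""Study design: cover-board array geometry and robust-design session calendar.

The field layout is an array of 50 wooden cover boards on a 5 x 10 grid at
1-m spacing, sampled in spring and fall seasons (primary sessions) with 2-3
repeat visits (secondary occasions) inside each season.  Demography is open
between primary sessions and closed within them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StudyDesign", "default_board_grid", "default_primary_dates"]


def default_board_grid() -> np.ndarray:
    """5 x 10 board grid at 1-m spacing (50 boards), origin at the SW corner."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(10.0))
    return np.column_stack([xs.ravel(), ys.ravel()])


def default_primary_dates() -> tuple[float, ...]:
    """Day stamps of the six seasonal primary sessions (spring/fall, 3 years).

    Mid-points of the spring (Mar 15 - May 15) and fall (Sep 15 - Oct 15)
    sampling windows, measured in days from Jan 1 of the first year.
    """
    return (105.0, 273.0, 470.0, 638.0, 835.0, 1003.0)


@dataclass(frozen=True)
class StudyDesign:
    """Board coordinates, session structure, and the rectangular state space.

    Parameters
    ----------
    board_positions
        ``(J, 2)`` board coordinates in meters.
    n_primary
        Number of open primary sessions.
    secondaries_per_primary
        Closed repeat visits within each primary (2 or 3 in the field design).
    primary_dates
        Day stamps of each primary session; consecutive differences give the
        survival/dispersal interval lengths in days.
    buffer
        Width (m) of the state-space margin around the board bounding box.
        Must be generous relative to the movement scale sigma (>= 2.5 sigma)
        so that truncating activity centers at the edge is negligible.
    """

    board_positions: np.ndarray = field(default_factory=default_board_grid)
    n_primary: int = 6
    secondaries_per_primary: tuple[int, ...] = (3, 3, 3, 3, 3, 3)
    primary_dates: tuple[float, ...] = field(default_factory=default_primary_dates)
    buffer: float = 10.5

    def __post_init__(self) -> None:
        boards = np.asarray(self.board_positions, dtype=float)
        if boards.ndim != 2 or boards.shape[1] != 2:
            raise ValueError("board_positions must be an (J, 2) array")
        if len(np.unique(boards, axis=0)) != len(boards):
            raise ValueError("board positions must be unique")
        object.__setattr__(self, "board_positions", boards)
        if self.n_primary < 1:
            raise ValueError("need at least one primary session")
        if len(self.secondaries_per_primary) != self.n_primary:
            raise ValueError("secondaries_per_primary must have n_primary entries")
        if any(k < 1 for k in self.secondaries_per_primary):
            raise ValueError("each primary needs >= 1 secondary occasion")
        if len(self.primary_dates) != self.n_primary:
            raise ValueError("primary_dates must have n_primary entries")
        if self.n_primary > 1 and np.any(np.diff(self.primary_dates) <= 0):
            raise ValueError("between-primary intervals must be strictly positive")
        if self.buffer <= 0:
            raise ValueError("buffer must be positive")

    # ---- derived geometry -------------------------------------------------

    @property
    def intervals_days(self) -> np.ndarray:
        """Lengths (days) of the n_primary - 1 between-primary intervals."""
        return np.diff(np.asarray(self.primary_dates, dtype=float))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """State-space rectangle ``(xmin, xmax, ymin, ymax)`` in meters."""
        b = self.board_positions
        return (
            float(b[:, 0].min() - self.buffer),
            float(b[:, 0].max() + self.buffer),
            float(b[:, 1].min() - self.buffer),
            float(b[:, 1].max() + self.buffer),
        )

    @property
    def area(self) -> float:
        """State-space area in square meters."""
        xmin, xmax, ymin, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    @property
    def n_boards(self) -> int:
        return len(self.board_positions)

    def check_buffer(self, sigma: float, factor: float = 2.5) -> None:
        """Refuse configurations where the state space is too tight for sigma."""
        if self.buffer < factor * sigma:
            raise ValueError(
                f"state-space buffer {self.buffer:.2f} m is below {factor} x sigma "
                f"({factor * sigma:.2f} m); widen the buffer to avoid edge bias"
            )

    def board_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map board coordinates to row indices of ``board_positions``.

        Returns -1 for coordinates that match no board.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(len(x), -1, dtype=int)
        for j, (bx, by) in enumerate(self.board_positions):
            hit = np.isclose(x, bx) & np.isclose(y, by)
            out[hit] = j
        return out
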