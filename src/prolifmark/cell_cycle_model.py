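"""Cell-cycle phase-occupancy model linking proliferation markers.

Under asynchronous steady state, the fraction of cycling cells caught in
mitosis at a fixed instant equals the fraction of the cycle spent there,
``N_m / N_c = T_m / T_c`` with ``T_c = T_m + T_i``.  Because PhH3 marks
mitotic cells and MIB-1 marks all cycling cells, the expected count ratio is

    PhH3 / MIB-1 = T_m / (T_m + T_i)

which depends only on phase durations, not on the proliferating fraction.
When interphase ``T_i`` lengthens across tumors (e.g. aneuploidy stretching
S phase) while ``T_m`` stays fixed, the two markers decouple.

Tumor growth is projected as ``N = N0 * (1 + P)**(dt / T_c)``: in one cycle a
fraction ``P`` of cells divides, multiplying the population by ``1 + P``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from prolifmark.errors import InvalidParameterError

__all__ = [
    "CellCycleDurations",
    "GrowthParams",
    "MarkerFractions",
    "phh3_mib1_ratio",
    "relative_ratio_change",
    "decoupling_curve",
    "grow",
    "expected_marker_fractions",
]


def _require_finite_nonneg(name: str, value: float) -> float:
    if not math.isfinite(value) or value < 0:
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class CellCycleDurations:
    """Durations of the cell-cycle phases, in hours.

    Parameters
    ----------
    t_g1, t_s, t_g2 : float
        Interphase components, each >= 0.
    t_m : float
        Mitosis duration, > 0.
    """

    t_g1: float
    t_s: float
    t_g2: float
    t_m: float

    def __post_init__(self) -> None:
        _require_finite_nonneg("t_g1", self.t_g1)
        _require_finite_nonneg("t_s", self.t_s)
        _require_finite_nonneg("t_g2", self.t_g2)
        if not math.isfinite(self.t_m) or self.t_m <= 0:
            raise InvalidParameterError(f"t_m must be finite and > 0, got {self.t_m!r}")

    @property
    def t_i(self) -> float:
        """Interphase duration: G1 + S + G2 (hours)."""
        return self.t_g1 + self.t_s + self.t_g2

    @property
    def t_c(self) -> float:
        """Total cell-cycle duration: interphase + mitosis (hours)."""
        return self.t_i + self.t_m

    @classmethod
    def from_interphase(cls, t_m: float, t_i: float) -> "CellCycleDurations":
        """Build durations from (T_m, T_i), lumping interphase into G1."""
        _require_finite_nonneg("t_i", t_i)
        return cls(t_g1=t_i, t_s=0.0, t_g2=0.0, t_m=t_m)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the exponential growth projection.

    n0 is the initial cell count (> 0), p the proliferating fraction in
    [0, 1], delta_t the elapsed time in hours (>= 0), and t_c the cell-cycle
    duration in hours (> 0).
    """

    n0: float
    p: float
    delta_t: float
    t_c: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.n0) or self.n0 <= 0:
            raise InvalidParameterError(f"n0 must be > 0, got {self.n0!r}")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError(f"p must lie in [0, 1], got {self.p!r}")
        _require_finite_nonneg("delta_t", self.delta_t)
        if not math.isfinite(self.t_c) or self.t_c <= 0:
            raise InvalidParameterError(f"t_c must be > 0, got {self.t_c!r}")


@dataclass(frozen=True)
class MarkerFractions:
    """Expected fractions of all cells positive for each marker."""

    f_mib1: float
    f_phh3: float
    f_mitotic: float


def phh3_mib1_ratio(d: CellCycleDurations) -> float:
    """Expected PhH3/MIB-1 count ratio, T_m / (T_m + T_i).

    Lies in (0, 1]; equals 1 only when interphase vanishes, and is strictly
    decreasing in T_i at fixed T_m.
    """
    return d.t_m / (d.t_m + d.t_i)


def relative_ratio_change(d_ref: CellCycleDurations, d_new: CellCycleDurations) -> float:
    """Signed relative change of the PhH3/MIB-1 ratio between two duration sets.

    Returns ``1 - ratio(d_new) / ratio(d_ref)``, so a positive value is a
    relative *decrease* in PhH3 staining relative to MIB-1.
    """
    return 1.0 - phh3_mib1_ratio(d_new) / phh3_mib1_ratio(d_ref)


def decoupling_curve(t_m: float, t_i_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Evaluate the ratio T_m/(T_m + T_i) over a grid of interphase durations.

    Returns (t_i, ratio) pairs in grid order; along a sorted grid the ratio is
    monotonically non-increasing.
    """
    grid = list(t_i_grid)
    if not grid:
        raise InvalidParameterError("t_i_grid must be nonempty")
    return [
        (float(t_i), phh3_mib1_ratio(CellCycleDurations.from_interphase(t_m, t_i)))
        for t_i in grid
    ]


def decoupling_curve_to_csv(path, t_m: float, t_i_grid: Sequence[float]) -> None:
    """Write the decoupling curve as a two-column CSV (t_i_hours, ratio)."""
    rows = decoupling_curve(t_m, t_i_grid)
    with open(path, "w") as fh:
        fh.write("t_i_hours,ratio\n")
        for t_i, r in rows:
            fh.write(f"{t_i},{r}\n")


def grow(g: GrowthParams) -> float:
    """Expected cell count after delta_t hours: ``n0 * (1 + p)**(delta_t / t_c)``.

    Each completed cycle multiplies the population by (1 + p): the
    non-proliferating fraction persists while the proliferating fraction
    doubles.  Reduces to n0 when p = 0 or delta_t = 0.
    """
    return g.n0 * (1.0 + g.p) ** (g.delta_t / g.t_c)


def expected_marker_fractions(
    d: CellCycleDurations,
    p: float,
    mib1_sensitivity: float = 1.0,
    phh3_window: float | None = None,
    mitvis_window: float | None = None,
) -> MarkerFractions:
    """Expected marker-positive fractions of all cells in a tumor.

    ``p`` is the proliferating (cycling) fraction.  MIB-1 stains cycling
    cells with probability ``mib1_sensitivity``; PhH3 and morphologically
    visible mitoses occupy time windows of the given lengths (hours, both
    defaulting to T_m) within the cycle:

        f_mib1    = p * mib1_sensitivity
        f_phh3    = p * phh3_window / t_c
        f_mitotic = p * mitvis_window / t_c

    With the defaults, f_phh3 / f_mib1 equals ``phh3_mib1_ratio(d)``.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p must lie in [0, 1], got {p!r}")
    if not 0.0 <= mib1_sensitivity <= 1.0:
        raise InvalidParameterError(
            f"mib1_sensitivity must lie in [0, 1], got {mib1_sensitivity!r}"
        )
    if phh3_window is None:
        phh3_window = d.t_m
    if mitvis_window is None:
        mitvis_window = d.t_m
    for name, w in (("phh3_window", phh3_window), ("mitvis_window", mitvis_window)):
        _require_finite_nonneg(name, w)
        if w > d.t_c:
            raise InvalidParameterError(f"{name} ({w} h) exceeds the cycle duration {d.t_c} h")
    return MarkerFractions(
        f_mib1=p * mib1_sensitivity,
        f_phh3=p * phh3_window / d.t_c,
        f_mitotic=p * mitvis_window / d.t_c,
    )
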