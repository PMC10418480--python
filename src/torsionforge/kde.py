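"""Score-weighted circular kernel density estimation for torsion angles.

The density of each backbone torsion is estimated with a power-raised
cosine kernel on the circle,

    K(alpha, alpha_j) = cos^k( Delta(alpha, alpha_j) * pi/360 )

where Delta is the circular distance in degrees (in [0, 180]).  The
exponent k sets the kernel width w through k = 1 + 1/tan^2(w/2), and w
itself is tied to the ensemble size by the Scott-style rule
w = 2*pi*N^(-1/3).  Each conformer contributes with a Boltzmann-like
weight c_j = exp(-s_j/s_ref) derived from its total Rosetta score s_j,
so poorly scored models are suppressed smoothly rather than cut off.

All public angles are in degrees; the kernel-width relation (k from w)
is in radians, matching the two unit conventions of the printed method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import DihedralSampleSet, ScoreTable, wrap_angle

DEFAULT_S_REF = 10.0
DEFAULT_GRID_STEP = 1.0


class KDEError(ValueError):
    """Raised for invalid kernel configuration or inputs."""


def circular_delta(a, b):
    """Circular distance between angles in degrees, in [0, 180].

    Broadcasts over array inputs; both arguments are wrapped first.
    """
    d = np.abs(wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
    # wrap_angle puts the difference in [-180, 180); |.| is already <= 180
    if d.ndim == 0:
        return float(d)
    return d


def width_from_ensemble_size(N: int) -> float:
    """Kernel width w = 2*pi*N^(-1/3) in radians (Scott-style rule)."""
    if N < 1:
        raise KDEError(f"ensemble size must be >= 1, got {N}")
    return 2.0 * np.pi * float(N) ** (-1.0 / 3.0)


def exponent_from_width(w: float) -> float:
    """Kernel exponent k = 1 + 1/tan^2(w/2) for w in (0, pi] radians."""
    if not 0.0 < w <= np.pi:
        raise KDEError(f"kernel width must be in (0, pi], got {w}")
    t = np.tan(w / 2.0)
    return 1.0 + 1.0 / (t * t)


def width_from_exponent(k: float) -> float:
    """Inverse of :func:`exponent_from_width`: w = 2*arctan(1/sqrt(k-1))."""
    if k < 1.0:
        raise KDEError(f"kernel exponent must be >= 1, got {k}")
    if k == 1.0:
        return float(np.pi)
    return float(2.0 * np.arctan(1.0 / np.sqrt(k - 1.0)))


def kernel_value(alpha, alpha_j, k: float):
    """Cosine-power kernel value in [0, 1]; broadcasts over inputs."""
    if k < 1.0:
        raise KDEError(f"kernel exponent must be >= 1, got {k}")
    delta = circular_delta(alpha, alpha_j)
    return np.cos(np.asarray(delta) * np.pi / 360.0) ** k


@dataclass(frozen=True)
class CircularKernelConfig:
    """Kernel width/exponent pair plus the ensemble size that produced it."""

    width_w: float
    exponent_k: float
    N: int

    def __post_init__(self):
        if not 0.0 < self.width_w <= np.pi:
            raise KDEError(f"width must be in (0, pi], got {self.width_w}")
        expected_k = exponent_from_width(self.width_w)
        if not np.isclose(self.exponent_k, expected_k, rtol=1e-9, atol=1e-9):
            raise KDEError(
                f"inconsistent kernel config: k={self.exponent_k} but width "
                f"{self.width_w} implies k={expected_k}"
            )

    @classmethod
    def from_ensemble_size(cls, N: int) -> "CircularKernelConfig":
        """Derive (w, k) from the ensemble size via the width rule.

        For N <= 8 the rule gives w >= pi, outside the kernel's validity
        range, and a :class:`KDEError` is raised (pass an explicit width
        instead for such tiny ensembles).
        """
        w = width_from_ensemble_size(N)
        if w > np.pi:
            raise KDEError(
                f"ensemble of N={N} models gives width {w:.3f} > pi; "
                "supply width_w explicitly via from_width"
            )
        return cls(width_w=w, exponent_k=exponent_from_width(w), N=N)

    @classmethod
    def from_width(cls, w: float, N: int) -> "CircularKernelConfig":
        return cls(width_w=w, exponent_k=exponent_from_width(w), N=N)

    @property
    def width_deg(self) -> float:
        return float(np.degrees(self.width_w))


@dataclass
class WeightSet:
    """Per-model score weights c_j = exp(-s_j/s_ref) and their sum C."""

    s_ref: float
    model_ids: list
    c: np.ndarray

    @property
    def C(self) -> float:
        return float(np.sum(self.c))

    def weights_for(self, model_ids) -> np.ndarray:
        lut = {str(m): w for m, w in zip(self.model_ids, self.c)}
        try:
            return np.array([lut[str(m)] for m in model_ids], dtype=float)
        except KeyError as exc:
            raise KDEError(f"model {exc.args[0]!r} has no weight") from exc


def score_weights(scores: ScoreTable, s_ref: float = DEFAULT_S_REF) -> WeightSet:
    """Convert total scores into multiplicative weights.

    Lower (better) scores get exponentially larger weights; a score
    difference of ``s_ref`` corresponds to an e-fold weight change.
    """
    if s_ref <= 0:
        raise KDEError(f"s_ref must be positive, got {s_ref}")
    model_ids = list(scores.entries)
    s = np.array([scores.entries[m] for m in model_ids], dtype=float)
    if np.any(np.abs(s) / s_ref > 700.0):
        raise KDEError(
            "score magnitudes overflow exp(-s/s_ref); rescale scores or "
            "increase s_ref"
        )
    c = np.exp(-s / s_ref)
    return WeightSet(s_ref=s_ref, model_ids=model_ids, c=c)


@dataclass
class TorsionPDF:
    """Score-weighted circular density of one torsion on a uniform grid.

    ``grid_deg`` covers [-180, 180) (periodic; the wrap point is implied).
    If ``normalized``, the trapezoidal integral around the circle is 1
    (per-degree measure).
    """

    residue_index: int
    angle_kind: str
    grid_deg: np.ndarray
    density: np.ndarray
    normalized: bool
    config: CircularKernelConfig
    samples_deg: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)
    norm: float = 1.0  # multiplicative constant applied to the raw kernel sum

    def circular_integral(self) -> float:
        """Trapezoidal integral of the density over one full turn (degrees)."""
        g = np.append(self.grid_deg, self.grid_deg[0] + 360.0)
        d = np.append(self.density, self.density[0])
        return float(np.trapezoid(d, g))

    def argmax_deg(self) -> float:
        return float(self.grid_deg[int(np.argmax(self.density))])

    def __call__(self, alpha) -> np.ndarray:
        """Evaluate the (possibly normalized) density at arbitrary angles."""
        raw = _kernel_sum(np.atleast_1d(np.asarray(alpha, dtype=float)),
                          self.samples_deg, self.weights,
                          self.config.exponent_k)
        return raw * self.norm


def _kernel_sum(alpha_deg: np.ndarray, samples_deg: np.ndarray,
                weights: np.ndarray, k: float) -> np.ndarray:
    """(1/C) * sum_j c_j K(alpha, alpha_j), vectorized over the grid."""
    delta = np.abs(wrap_angle(alpha_deg[:, None] - samples_deg[None, :]))
    kern = np.cos(delta * (np.pi / 360.0)) ** k
    return kern @ weights / np.sum(weights)


def make_grid(grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform grid over [-180, 180) with the given step (must divide 360)."""
    n = 360.0 / grid_step
    if abs(n - round(n)) > 1e-9:
        raise KDEError(f"grid step {grid_step} does not divide 360 evenly")
    return -180.0 + grid_step * np.arange(int(round(n)))


def weighted_pdf(samples: DihedralSampleSet, weights: WeightSet,
                 config: CircularKernelConfig,
                 grid_step: float = DEFAULT_GRID_STEP,
                 normalize: bool = True) -> TorsionPDF:
    """Score-weighted circular KDE of one torsion angle.

    Evaluates P(alpha) = (1/C) sum_j c_j cos^k(Delta(alpha, alpha_j) pi/360)
    on a uniform grid over [-180, 180).  With ``normalize`` the density is
    rescaled to unit circular (trapezoidal) integral in the per-degree
    measure; the flag is recorded because energies derived later differ
    only by an additive constant between the two conventions.
    """
    if len(samples) == 0:
        raise KDEError("empty dihedral sample set")
    w = weights.weights_for(samples.model_ids)
    grid = make_grid(grid_step)
    density = _kernel_sum(grid, samples.angles_deg, w, config.exponent_k)
    pdf = TorsionPDF(
        residue_index=samples.residue_index,
        angle_kind=samples.angle_kind,
        grid_deg=grid,
        density=density,
        normalized=False,
        config=config,
        samples_deg=samples.angles_deg.copy(),
        weights=w / np.sum(w),
    )
    if normalize:
        integral = pdf.circular_integral()
        if integral <= 0:
            raise KDEError(
                f"degenerate density for residue {samples.residue_index} "
                f"{samples.angle_kind}: zero integral"
            )
        pdf.density = pdf.density / integral
        pdf.norm = 1.0 / integral
        pdf.normalized = True
    return pdf
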