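"""Knowledge-based torsion potentials by Boltzmann inversion.

Each torsion density P_i(alpha) is inverted into an energy profile

    E_i(alpha) = -f_i * ln P_i(alpha)

with the force-scaling factor f_i chosen so that the standard deviation
of the resulting profile is a fixed multiple of the standard deviation
of the backbone proper-dihedral term of the reference force field
(AMBER-ff99SBildnp* style cosine series).  The default multiples are
14.77 for phi and 5.30 for psi, which put the knowledge-based terms on
the magnitude scale an MD engine expects from its own torsion terms.
Forces are the analytic negative derivative of the energy, obtained in
closed form through the kernel sum, so emitted energy/force tables are
consistent to machine precision rather than to a finite-difference
approximation.

No explicit kT appears: the temperature factor of the Boltzmann
inversion is absorbed into f_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kde import TorsionPDF, wrap_angle

PHI_RATIO = 14.77
PSI_RATIO = 5.30
DEFAULT_RATIOS = {"phi": PHI_RATIO, "psi": PSI_RATIO}
DEFAULT_FLOOR_FRACTION = 1e-8

DEG2RAD = np.pi / 180.0


class PEFError(ValueError):
    """Raised for degenerate profiles or invalid scaling inputs."""


@dataclass(frozen=True)
class ReferenceTermSpec:
    """Cosine-series proper-dihedral term of the reference force field.

    ``terms`` is a list of (multiplicity n, half-amplitude V_n/2 in
    kJ/mol, phase gamma_n in degrees), i.e. the potential is
    sum_n (V_n/2) * (1 + cos(n*theta - gamma_n)).
    """

    angle_kind: str
    terms: tuple[tuple[int, float, float], ...]

    def __post_init__(self):
        for n, _, _ in self.terms:
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise PEFError(f"multiplicity must be a positive integer, got {n!r}")

    def std(self) -> float:
        return reference_term_std(self)


def reference_term_std(spec: ReferenceTermSpec) -> float:
    """Standard deviation of the cosine series over a uniform angle.

    Terms sharing a multiplicity are combined as phasors; distinct
    multiplicities are orthogonal, so the variance is the quadrature sum
    A_n^2/2 of the combined amplitudes (the additive 1 in each term only
    shifts the mean).
    """
    phasors: dict[int, complex] = {}
    for n, half_v, gamma_deg in spec.terms:
        phasors[int(n)] = phasors.get(int(n), 0j) + half_v * np.exp(
            -1j * np.radians(gamma_deg)
        )
    variance = sum(abs(z) ** 2 / 2.0 for z in phasors.values())
    return float(np.sqrt(variance))


def boltzmann_invert(pdf: TorsionPDF,
                     floor_fraction: float = DEFAULT_FLOOR_FRACTION) -> tuple[np.ndarray, float]:
    """Unscaled energy profile U = -ln(max(P, eps)) on the PDF grid.

    ``floor_fraction`` sets the density floor eps as a fraction of the
    peak density, bounding the energy in unsampled regions (where the
    force is then zero) instead of letting it diverge.  Returns the
    profile and the absolute floor used.
    """
    if floor_fraction <= 0:
        raise PEFError("floor_fraction must be positive")
    peak = float(np.max(pdf.density))
    if peak <= 0:
        raise PEFError(
            f"all-zero density for residue {pdf.residue_index} {pdf.angle_kind}"
        )
    floor_eps = floor_fraction * peak
    return -np.log(np.maximum(pdf.density, floor_eps)), floor_eps


@dataclass
class TorsionPEF:
    """Scaled torsion potential and analytic force for one residue/kind.

    ``energy`` is in kJ/mol on ``grid_deg`` (minimum shifted to zero);
    ``force`` is -dE/d(alpha) in kJ/mol/rad.  ``f_i`` is the applied
    scaling factor, ``ratio`` the target std multiple and ``std_ref``
    the reference-term standard deviation in kJ/mol.
    """

    residue_index: int
    angle_kind: str
    grid_deg: np.ndarray
    energy: np.ndarray
    force: np.ndarray
    f_i: float
    std_ref: float
    ratio: float
    floor_eps: float
    pdf: TorsionPDF
    energy_offset: float  # E(alpha) = f_i * U(alpha) - energy_offset

    def argmin_deg(self) -> float:
        return float(self.grid_deg[int(np.argmin(self.energy))])

    def energy_at(self, alpha) -> np.ndarray:
        """Analytic energy at arbitrary angles (same floor contract)."""
        p = self.pdf(np.atleast_1d(np.asarray(alpha, dtype=float)))
        return self.f_i * -np.log(np.maximum(p, self.floor_eps)) - self.energy_offset

    def force_at(self, alpha) -> np.ndarray:
        """Analytic force -dE/d(alpha) in kJ/mol/rad at arbitrary angles."""
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        p = self.pdf(alpha)
        dp = _density_derivative_per_deg(self.pdf, alpha)
        out = np.where(p > self.floor_eps,
                       self.f_i * dp / np.maximum(p, self.floor_eps) / DEG2RAD,
                       0.0)
        return out


def _density_derivative_per_deg(pdf: TorsionPDF, alpha_deg: np.ndarray) -> np.ndarray:
    """dP/d(alpha) in density-units per degree, from the kernel closed form."""
    k = pdf.config.exponent_k
    diff = wrap_angle(alpha_deg[:, None] - pdf.samples_deg[None, :])
    delta = np.abs(diff)
    x = delta * (np.pi / 360.0)
    # d/d(alpha) cos^k(x) = -k cos^(k-1)(x) sin(x) * (pi/360) * sign(diff)
    dkern = -k * np.cos(x) ** (k - 1.0) * np.sin(x) * (np.pi / 360.0) * np.sign(diff)
    return (dkern @ pdf.weights) * pdf.norm


def scale_pef(pdf: TorsionPDF, *, ratio: float | None = None,
              std_ref: float | None = None,
              reference: ReferenceTermSpec | None = None,
              floor_fraction: float = DEFAULT_FLOOR_FRACTION) -> TorsionPEF:
    """Build the scaled potential and analytic force for one torsion.

    The scaling factor is f_i = ratio * std_ref / std(U), where std is
    the population standard deviation over the uniform grid, so that
    std(E) = ratio * std_ref exactly.  ``std_ref`` may be given directly
    or derived from a :class:`ReferenceTermSpec`; there is deliberately
    no built-in default, because the choice of reference term belongs to
    the force field being patched.
    """
    if ratio is None:
        if pdf.angle_kind not in DEFAULT_RATIOS:
            raise PEFError(
                f"no default scaling ratio for angle kind {pdf.angle_kind!r}; "
                "omega is excluded from potential export"
            )
        ratio = DEFAULT_RATIOS[pdf.angle_kind]
    if std_ref is None:
        if reference is None:
            raise PEFError("supply std_ref or a ReferenceTermSpec")
        std_ref = reference_term_std(reference)
    if std_ref <= 0:
        raise PEFError(f"std_ref must be positive, got {std_ref}")
    if ratio <= 0:
        raise PEFError(f"scaling ratio must be positive, got {ratio}")

    profile, floor_eps = boltzmann_invert(pdf, floor_fraction)
    std_u = float(np.std(profile))
    # np.std of a constant array returns O(eps) noise, not exactly zero
    if std_u <= 1e-12 * max(1.0, abs(float(np.mean(profile)))):
        raise PEFError(
            f"degenerate (flat) profile for residue {pdf.residue_index} "
            f"{pdf.angle_kind}: cannot scale a uniform distribution"
        )
    f_i = ratio * std_ref / std_u
    energy = f_i * profile
    offset = float(np.min(energy))
    energy = energy - offset

    pef = TorsionPEF(
        residue_index=pdf.residue_index,
        angle_kind=pdf.angle_kind,
        grid_deg=pdf.grid_deg,
        energy=energy,
        force=np.zeros_like(energy),
        f_i=f_i,
        std_ref=float(std_ref),
        ratio=float(ratio),
        floor_eps=floor_eps,
        pdf=pdf,
        energy_offset=offset,
    )
    pef.force = pef.force_at(pdf.grid_deg)
    return pef
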