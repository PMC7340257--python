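"""Auxiliary biophysical computations around the screening pipeline.

Four small, self-contained analyses:

* **Enzyme kinetics** - Hanes-Woolf linearisation of Michaelis-Menten
  initial-velocity data ([S]/v vs [S]; slope = 1/Vmax, intercept =
  Km/Vmax), as used for DCPIP-reported 2-oxoacid decarboxylase activity.
* **Thermal stability (DSF)** - Boltzmann sigmoid fit of a SYPRO-Orange
  melt curve; Tm is the transition midpoint, and variant destabilisation
  is reported as a Tm shift against a reference.
* **SAXS Guinier analysis** - linear fit of ln I(q) vs q^2 in the low-angle
  window q*Rg <= 1.3 giving the radius of gyration Rg and forward
  scattering I(0).
* **Megacomplex stoichiometry** - mass arithmetic for candidate
  E1/E2 copy-number models of the 2-oxoadipate dehydrogenase megacomplex
  (24-mer acyltransferase core engaging E1 dimers) against a
  solution-scattering mass estimate.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from Bio.SeqUtils import molecular_weight

__all__ = [
    "KineticsResult",
    "MeltResult",
    "GuinierResult",
    "ComplexComponent",
    "ComplexModel",
    "michaelis_menten",
    "hanes_woolf_fit",
    "dcpip_initial_velocity",
    "boltzmann",
    "boltzmann_fit",
    "delta_tm",
    "guinier_fit",
    "mass_from_sequence",
    "masses_from_fasta",
    "complex_mass",
    "enumerate_stoichiometry",
    "NOMINAL_E1_PROTOMER_DA",
    "NOMINAL_E2_PROTOMER_DA",
]

# Nominal stand-in protomer masses for the catalytic constructs (synthetic
# placeholders: literature-typical average masses for the ~875-residue E1
# decarboxylase construct and the ~386-residue E2 acyltransferase construct;
# use mass_from_sequence on real construct sequences when available).
NOMINAL_E1_PROTOMER_DA = 97_000.0
NOMINAL_E2_PROTOMER_DA = 41_000.0


# ---------------------------------------------------------------------------
# Enzyme kinetics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class KineticsResult:
    """Hanes-Woolf fit: Km (mM), Vmax (umol min^-1 mg^-1), line and r^2."""

    km: float
    vmax: float
    slope: float
    intercept: float
    r_squared: float


def michaelis_menten(s, km: float, vmax: float):
    """v = Vmax [S] / (Km + [S])."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def hanes_woolf_fit(s, v) -> KineticsResult:
    """Km and Vmax from the Hanes-Woolf linearisation.

    Ordinary least squares of [S]/v on [S]; Vmax = 1/slope,
    Km = intercept/slope.  Points with v <= 0 are excluded with a warning;
    at least 3 usable points with distinct [S] are required.  A
    non-positive slope or a negative intercept means the data do not
    describe a saturating enzyme ("no saturating fit").
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.shape != v.shape:
        raise ValueError("S and v must have the same length")
    usable = v > 0
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} point(s) with v <= 0", RuntimeWarning
        )
    s, v = s[usable], v[usable]
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 usable points with distinct [S]")

    y = s / v
    slope, intercept = np.polyfit(s, y, 1)
    if slope <= 0:
        raise ValueError("no saturating fit (Hanes-Woolf slope <= 0)")
    tol = 1e-10 * float(np.max(np.abs(y)))
    if intercept < -tol:
        raise ValueError("no saturating fit (negative Hanes-Woolf intercept)")
    if intercept <= tol:
        warnings.warn("intercept ~ 0: Km -> 0 (enzyme saturated at all [S])",
                      RuntimeWarning)
        intercept = max(intercept, 0.0)

    fit = slope * s + intercept
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return KineticsResult(
        km=float(intercept / slope),
        vmax=float(1.0 / slope),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
    )


def dcpip_initial_velocity(
    delta_od_per_min: float,
    protein_mg: float,
    extinction_mM_cm: float = 21.0,
    path_cm: float = 0.78,
    well_volume_ul: float = 300.0,
) -> float:
    """Convert a DCPIP absorbance slope to specific activity.

    v = (dOD/dt) / (eps * l) * V / m, in umol min^-1 mg^-1.  The default
    extinction coefficient is a literature-typical placeholder for DCPIP
    near 600 nm, not an asserted assay constant - pass the value measured
    for your instrument/buffer.
    """
    warnings.warn(
        "dcpip_initial_velocity uses a placeholder extinction coefficient; "
        "supply the value calibrated for your assay",
        RuntimeWarning,
    )
    if protein_mg <= 0 or extinction_mM_cm <= 0 or path_cm <= 0:
        raise ValueError("protein mass, extinction and path must be > 0")
    conc_mM_per_min = delta_od_per_min / (extinction_mM_cm * path_cm)
    umol_per_min = conc_mM_per_min * (well_volume_ul * 1e-6) * 1e3
    return umol_per_min / protein_mg


# ---------------------------------------------------------------------------
# Differential scanning fluorimetry
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MeltResult:
    """Boltzmann melt fit: Tm (degC), transition width, baselines, window."""

    tm: float
    width: float
    f_low: float
    f_high: float
    window: tuple
    rmse: float


def boltzmann(t, f_low: float, f_high: float, tm: float, width: float):
    """F(T) = F_low + (F_high - F_low) / (1 + exp((Tm - T)/width))."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        return f_low + (f_high - f_low) / (1.0 + np.exp((tm - t) / width))


def boltzmann_fit(temperatures, fluorescence) -> MeltResult:
    """Fit a single unfolding transition to a melt curve.

    The fitting window is auto-trimmed from the curve's global minimum to
    its global maximum, excluding the post-maximum aggregation decay that
    dye-based melts show at high temperature.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.ndim != 1 or t.shape != f.shape or t.size < 10:
        raise ValueError("need equal-length 1-D arrays with >= 10 points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperatures must be strictly ascending")

    i_lo = int(np.argmin(f))
    i_hi = int(np.argmax(f))
    if i_hi <= i_lo:
        raise ValueError("no rising transition (global max precedes global min)")
    tw = t[i_lo : i_hi + 1]
    fw = f[i_lo : i_hi + 1]
    if tw.size < 5:
        raise ValueError("fewer than 5 points in the transition window")

    half = fw[0] + 0.5 * (fw[-1] - fw[0])
    tm0 = float(tw[int(np.argmin(np.abs(fw - half)))])
    p0 = [float(fw[0]), float(fw[-1]), tm0, max((tw[-1] - tw[0]) / 10.0, 0.1)]
    try:
        popt, _ = curve_fit(boltzmann, tw, fw, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Boltzmann fit did not converge: {err}") from err
    f_low, f_high, tm, width = (float(x) for x in popt)
    if not (tw[0] <= tm <= tw[-1]):
        raise RuntimeError(
            f"fitted Tm {tm:.2f} degC lies outside the window "
            f"[{tw[0]:.2f}, {tw[-1]:.2f}]"
        )
    rmse = float(np.sqrt(np.mean((boltzmann(tw, *popt) - fw) ** 2)))
    return MeltResult(tm=tm, width=abs(width), f_low=f_low, f_high=f_high,
                      window=(float(tw[0]), float(tw[-1])), rmse=rmse)


def delta_tm(variant: MeltResult, reference: MeltResult) -> float:
    """Tm shift of a variant against the reference, in degC."""
    return variant.tm - reference.tm


# ---------------------------------------------------------------------------
# SAXS Guinier analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GuinierResult:
    """Guinier fit: Rg (A), I(0), window used and number of points."""

    rg: float
    i0: float
    q_max: float
    n_points: int
    slope: float


def _guinier_coeffs(qw: np.ndarray, iw: np.ndarray, curvature: bool):
    """ln I regressed on q^2 (optionally + q^4); returns (slope, intercept).

    The q^4 term absorbs the leading systematic deviation from the ideal
    Gaussian inside the admissible window (a solid sphere fitted over
    q*Rg <= 1.3 with a straight line is biased high by ~2% in Rg); the
    Guinier slope is then the q^2 coefficient.
    """
    x = qw**2
    y = np.log(iw)
    slope, intercept = np.polyfit(x, y, 1)
    if curvature:
        coeffs = np.polyfit(x, y, 2)  # y ~ c2 x^2 + c1 x + c0
        # keep the corrected slope only when it stays in the Guinier regime
        if coeffs[1] < 0:
            return float(coeffs[1]), float(coeffs[2])
    return float(slope), float(intercept)


def guinier_fit(
    q, intensity, qrg_max: float = 1.3, min_points: int = 5, max_iter: int = 50
) -> GuinierResult:
    """Radius of gyration and forward scattering by Guinier approximation.

    Fits ln I against q^2 over the low-angle window, iterating the window
    (fit, update Rg, re-window to q*Rg <= qrg_max) until stable; when the
    window holds enough points a q^4 curvature term is included and the
    Guinier slope taken from the q^2 coefficient.  Rg = sqrt(-3 * slope),
    I0 = exp(intercept).  A non-negative slope (e.g. aggregation upturn)
    means there is no Guinier regime.
    """
    q = np.asarray(q, dtype=float)
    i = np.asarray(intensity, dtype=float)
    if q.shape != i.shape or q.ndim != 1:
        raise ValueError("q and I must be equal-length 1-D arrays")
    ok = (q > 0) & (i > 0)
    q, i = q[ok], i[ok]
    order = np.argsort(q)
    q, i = q[order], i[order]
    if q.size < min_points:
        raise ValueError(f"need >= {min_points} positive-intensity points")

    def fit_window(n: int):
        qw, iw = q[:n], i[:n]
        slope, intercept = _guinier_coeffs(qw, iw, curvature=n >= 2 * min_points)
        if slope >= 0:
            raise ValueError("no Guinier regime (non-negative low-q slope)")
        return slope, intercept

    n = q.size
    seen = {n}
    for _ in range(max_iter):
        slope, intercept = fit_window(n)
        rg = float(np.sqrt(-3.0 * slope))
        new_n = int(np.searchsorted(q * rg, qrg_max, side="right"))
        new_n = min(max(new_n, min_points), q.size)
        if new_n == n:
            break
        n = new_n
        if n in seen:  # window cycling: accept the current one
            break
        seen.add(n)

    slope, intercept = fit_window(n)
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    return GuinierResult(
        rg=rg, i0=i0, q_max=float(q[n - 1]), n_points=n, slope=float(slope)
    )


# ---------------------------------------------------------------------------
# Stoichiometry mass modelling
# ---------------------------------------------------------------------------

class ComplexComponent(tuple):
    """(name, protomer_mass_da, copies)."""

    def __new__(cls, name: str, protomer_mass_da: float, copies: int):
        if protomer_mass_da <= 0:
            raise ValueError("protomer mass must be > 0")
        if copies < 0 or int(copies) != copies:
            raise ValueError("copies must be a nonnegative integer")
        return super().__new__(cls, (name, float(protomer_mass_da), int(copies)))

    name = property(lambda self: self[0])
    protomer_mass_da = property(lambda self: self[1])
    copies = property(lambda self: self[2])


@dataclasses.dataclass(frozen=True)
class ComplexModel:
    components: tuple

    @property
    def total_mass(self) -> float:
        return complex_mass(self.components)


def mass_from_sequence(sequence: str) -> float:
    """Average molecular mass (Da) of a one-letter amino-acid sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    for pos, letter in enumerate(sequence):
        if letter.upper() not in standard:
            raise ValueError(f"unknown residue {letter!r} at position {pos}")
    return float(
        molecular_weight(sequence.upper(), seq_type="protein", monoisotopic=False)
    )


def masses_from_fasta(path) -> dict[str, float]:
    """Average mass (Da) per record of a protein FASTA file."""
    from Bio import SeqIO

    return {
        record.id: mass_from_sequence(str(record.seq))
        for record in SeqIO.parse(str(path), "fasta")
    }


def complex_mass(components: Sequence[ComplexComponent] | ComplexModel) -> float:
    """Total mass = sum of copies x protomer mass over all components."""
    if isinstance(components, ComplexModel):
        components = components.components
    return float(sum(c.protomer_mass_da * c.copies for c in components))


def enumerate_stoichiometry(
    e1_protomer_mass: float,
    e2_protomer_mass: float,
    target_mass: float,
    e2_copies: int = 24,
    max_e1_dimers: int = 12,
    e1_name: str = "E1",
    e2_name: str = "E2",
) -> list[tuple[ComplexModel, float]]:
    """Rank candidate megacomplex models by closeness to a target mass.

    The acyltransferase core is fixed at ``e2_copies`` protomers (eight
    trimers); the decarboxylase is counted in dimers from 0 to
    ``max_e1_dimers``.  Eight dimers (16 protomers) correspond to one dimer
    per trimer building block.  Returns (model, |total - target|) sorted by
    error, ties broken toward fewer E1 copies.
    """
    if e1_protomer_mass <= 0 or e2_protomer_mass <= 0:
        raise ValueError("protomer masses must be > 0")
    out = []
    for dimers in range(max_e1_dimers + 1):
        model = ComplexModel(
            components=(
                ComplexComponent(e1_name, e1_protomer_mass, 2 * dimers),
                ComplexComponent(e2_name, e2_protomer_mass, e2_copies),
            )
        )
        out.append((model, abs(model.total_mass - target_mass)))
    out.sort(key=lambda me: (me[1], me[0].components[0].copies))
    return out
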