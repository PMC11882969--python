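"""Noncompartmental pharmacokinetics and in vitro ADME arithmetic.

The NCA here is the standard model-free summary of a concentration-time
profile: Cmax/Tmax read off the observations, AUC by the linear trapezoid,
the terminal elimination rate λz by log-linear regression on the last
quantifiable points, half-life ln2/λz, and AUC extrapolated to infinity as
AUC_last + C_last/λz.  Below-LLOQ handling follows bioanalytical practice:
values under the limit of quantitation become zero for AUC purposes but are
treated as missing when estimating the terminal slope, which would
otherwise be biased by censored values.

Also here: equilibrium-dialysis protein binding / recovery / stability
ratios, microsomal decay kinetics (kel, T1/2, intrinsic clearance at the
incubation protein concentration), and monolayer permeability with the
P-gp efflux ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "DialysisAreas",
    "NCAResult",
    "PKError",
    "PKProfile",
    "apply_lloq",
    "decay_kinetics",
    "nca",
    "papp_efflux",
    "protein_binding",
    "recovery",
    "stability",
]

MICROSOMAL_PROTEIN_MG_PER_ML = 0.42  # incubation protein concentration


class PKError(ValueError):
    pass


@dataclass
class PKProfile:
    """Concentration-time series for one animal/compartment.

    Concentrations are ng/mL for plasma and CSF, ng/g for brain; ``lloq``
    is in the same units.  ``route`` is "bolus" or "extravascular".
    """

    compartment: str
    times: np.ndarray  # min
    concentrations: np.ndarray
    lloq: float = 0.0
    route: str = "extravascular"
    units: str = "ng/mL"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.concentrations.size:
            raise PKError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise PKError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise PKError("times must be >= 0")
        if self.route not in ("bolus", "extravascular"):
            raise PKError(f"unknown route {self.route!r}")
        neg = self.concentrations < 0
        if np.any(neg & ~(self.concentrations < self.lloq)):
            raise PKError("negative concentrations above LLOQ are invalid")

    @property
    def below_lloq(self) -> np.ndarray:
        return self.concentrations < self.lloq


def apply_lloq(profile: PKProfile, purpose: str) -> PKProfile:
    """Censor below-LLOQ values for a given downstream purpose.

    ``purpose="auc"``: below-LLOQ concentrations are set to zero (they
    contribute no exposure).  ``purpose="t_half"``: below-LLOQ values are
    marked missing (NaN) so the terminal log-linear regression never sees
    them.
    """
    if purpose not in ("auc", "t_half"):
        raise PKError(f"unknown purpose {purpose!r}")
    conc = profile.concentrations.copy()
    mask = profile.below_lloq
    conc[mask] = 0.0 if purpose == "auc" else np.nan
    return replace(profile, times=profile.times.copy(), concentrations=conc)


@dataclass
class NCAResult:
    compartment: str
    cmax: float | None
    tmax: float | None
    auc_last: float | None
    lambda_z: float | None = None
    t_half: float | None = None
    auc_inf: float | None = None
    n_lambda_points: int = 0
    status: str = "ok"


def _terminal_slope(times, conc, n_points):
    """Log-linear OLS on the last ``n_points`` quantifiable concentrations."""
    ok = np.isfinite(conc) & (conc > 0)
    t, c = times[ok], conc[ok]
    if t.size < n_points:
        return None, 0, "fewer than %d quantifiable points" % n_points
    t, c = t[-n_points:], c[-n_points:]
    res = stats.linregress(t, np.log(c))
    if res.slope >= 0:
        return None, n_points, "non-negative terminal slope"
    return -res.slope, n_points, "ok"


def nca(
    profile: PKProfile,
    n_lambda_points: int = 3,
    lambda_mode: str = "last-points",
) -> NCAResult:
    """Noncompartmental analysis of one profile.

    AUC_last uses the linear trapezoid over quantifiable points (below-LLOQ
    as zero); λz comes from log-linear regression on terminal quantifiable
    points (below-LLOQ as missing), either the last ``n_lambda_points``
    (default 3) or, with ``lambda_mode="best-r2"``, the 3..n-point tail
    with the best adjusted R².  When λz is unestimable (too few points or a
    non-negative slope) AUC_last is still returned and the status says why.
    """
    auc_prof = apply_lloq(profile, "auc")
    t, c = auc_prof.times, auc_prof.concentrations
    if np.all(c <= 0):
        return NCAResult(profile.compartment, None, None, None,
                         status="no quantifiable concentrations")
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = float(np.trapezoid(c, t))

    th_prof = apply_lloq(profile, "t_half")
    if lambda_mode == "last-points":
        lam, npts, why = _terminal_slope(th_prof.times, th_prof.concentrations,
                                         n_lambda_points)
    elif lambda_mode == "best-r2":
        lam, npts, why = None, 0, "fewer than 3 quantifiable points"
        ok = np.isfinite(th_prof.concentrations) & (th_prof.concentrations > 0)
        tt, cc = th_prof.times[ok], np.log(th_prof.concentrations[ok])
        best = -np.inf
        for k in range(3, tt.size + 1):
            res = stats.linregress(tt[-k:], cc[-k:])
            if res.slope >= 0:
                continue
            adj = 1 - (1 - res.rvalue**2) * (k - 1) / (k - 2)
            if adj > best:
                best, lam, npts, why = adj, -res.slope, k, "ok"
    else:
        raise PKError(f"unknown lambda_mode {lambda_mode!r}")

    if lam is None:
        return NCAResult(profile.compartment, cmax, tmax, auc_last,
                         n_lambda_points=npts,
                         status=f"lambda_z unestimable: {why}")
    quant = c[c > 0]
    c_last = float(quant[-1])
    return NCAResult(
        compartment=profile.compartment,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        lambda_z=float(lam),
        t_half=float(np.log(2) / lam),
        auc_inf=auc_last + c_last / float(lam),
        n_lambda_points=npts,
    )


# --------------------------------------------------------------------------
# equilibrium dialysis ratios


@dataclass(frozen=True)
class DialysisAreas:
    """Analyte/internal-standard peak-area ratios from dialysis samples."""

    buffer: float
    plasma: float
    stability_sample: float = float("nan")
    recovery_sample: float = float("nan")

    def __post_init__(self):
        for name in ("buffer", "plasma"):
            if getattr(self, name) < 0:
                raise PKError(f"area ratio {name} must be >= 0")


def protein_binding(d: DialysisAreas) -> float:
    """Percent bound: (1 - buffer/plasma) * 100."""
    if d.plasma == 0:
        raise PKError("protein_binding: zero plasma area ratio")
    return (1.0 - d.buffer / d.plasma) * 100.0


def recovery(d: DialysisAreas) -> float:
    """Percent recovery: (buffer + plasma) / stability sample * 100."""
    if d.stability_sample == 0 or not np.isfinite(d.stability_sample):
        raise PKError("recovery: invalid stability-sample area ratio")
    return (d.buffer + d.plasma) / d.stability_sample * 100.0


def stability(d: DialysisAreas) -> float:
    """Percent stability: recovery sample / stability sample * 100."""
    if d.stability_sample == 0 or not np.isfinite(d.stability_sample):
        raise PKError("stability: invalid stability-sample area ratio")
    if not np.isfinite(d.recovery_sample):
        raise PKError("stability: missing recovery-sample area ratio")
    return d.recovery_sample / d.stability_sample * 100.0


# --------------------------------------------------------------------------
# microsomal / plasma decay kinetics


@dataclass
class DecayResult:
    kel: float | None  # 1/min
    t_half: float | None  # min
    clint: float | None  # µL/min/mg protein
    status: str = "ok"


def decay_kinetics(
    times: np.ndarray,
    ln_area: np.ndarray,
    protein_conc: float = MICROSOMAL_PROTEIN_MG_PER_ML,
) -> DecayResult:
    """First-order decay from a ln(response) vs time plot.

    kel is minus the OLS slope; T1/2 = ln2/kel; intrinsic clearance is
    kel normalized to the incubation protein concentration (mg/mL),
    reported in µL/min/mg.  A non-negative slope means no measurable decay.
    """
    times = np.asarray(times, dtype=float)
    ln_area = np.asarray(ln_area, dtype=float)
    if times.size < 3:
        raise PKError("decay_kinetics needs >= 3 time points")
    if protein_conc <= 0:
        raise PKError("protein concentration must be positive")
    res = stats.linregress(times, ln_area)
    if res.slope >= 0:
        return DecayResult(None, None, None, status="no measurable decay")
    kel = -res.slope
    return DecayResult(
        kel=float(kel),
        t_half=float(np.log(2) / kel),
        clint=float(kel / protein_conc * 1000.0),
    )


# --------------------------------------------------------------------------
# monolayer permeability


@dataclass
class PappResult:
    papp_ab: float | None  # cm/s
    papp_ba: float | None
    efflux_ratio: float | None
    status: str = "ok"


def _papp_one_direction(times_s, receiver_amounts, area_cm2, donor_conc0):
    """Papp = (dQ/dt) / (A * C0) from linear-phase receiver accumulation."""
    times_s = np.asarray(times_s, dtype=float)
    q = np.asarray(receiver_amounts, dtype=float)
    if times_s.size < 2:
        raise PKError("permeability needs >= 2 sampling times")
    res = stats.linregress(times_s, q)
    return res.slope / (area_cm2 * donor_conc0)


def papp_efflux(
    times_s: np.ndarray,
    receiver_ab: np.ndarray,
    receiver_ba: np.ndarray,
    area_cm2: float,
    donor_conc0: float,
) -> PappResult:
    """Bidirectional apparent permeability and the efflux ratio B→A / A→B.

    Amounts and C0 must share a consistent amount unit; times in seconds
    give Papp in cm/s.  A zero A→B permeability leaves the ratio undefined
    with an explicit status.
    """
    if area_cm2 <= 0 or donor_conc0 <= 0:
        raise PKError("area and donor concentration must be positive")
    papp_ab = _papp_one_direction(times_s, receiver_ab, area_cm2, donor_conc0)
    papp_ba = _papp_one_direction(times_s, receiver_ba, area_cm2, donor_conc0)
    if papp_ab == 0:
        return PappResult(float(papp_ab), float(papp_ba), None,
                          status="efflux ratio undefined: zero A->B Papp")
    return PappResult(float(papp_ab), float(papp_ba), float(papp_ba / papp_ab))
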