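"""Concentration-response fitting and pharmacology arithmetic.

Covers the in vitro quantitation used when triaged docking hits become
compounds: four-parameter logistic (4PL) fits of concentration-response
data, single-point hit calling at >50 % radioligand displacement,
Cheng-Prusoff conversion of IC50 to Ki, lipophilic ligand efficiency,
the CNS multiparameter-optimization desirability score, plate-readout
percent-activity and universal-BRET standardization, and the pathway-wise
signaling-bias arithmetic Δlog(Emax/EC50) with its SEM propagation and
relative efficacy RE = 10^Δlog.

Conventions: concentrations are molar, responses percent of control,
logs are base 10, ΔΔG uses R = 1.987e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BRETCalibration",
    "ConcResponse",
    "CurveFit",
    "HitCall",
    "MPODescriptors",
    "PathwayEfficacy",
    "PharmError",
    "PlateReadout",
    "call_hits",
    "cns_mpo",
    "combined_sem",
    "delta_log_emax_ec50",
    "fit_4pl",
    "fold_change_and_ddg",
    "ki_cheng_prusoff",
    "lle",
    "percent_activity",
    "relative_efficacy",
    "sem_of_log_ratio",
    "ubret",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)


class PharmError(ValueError):
    pass


# --------------------------------------------------------------------------
# containers


@dataclass
class ConcResponse:
    """Replicate-resolved concentration-response data for one compound."""

    compound_id: str
    pathway: str
    concentrations: np.ndarray  # molar, ascending
    responses: np.ndarray  # (n_replicates, n_concentrations), % of control

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(self.concentrations <= 0):
            raise PharmError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise PharmError("concentrations must be strictly ascending")
        if self.responses.shape[1] != self.concentrations.size:
            raise PharmError("responses shape does not match concentrations")

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[0]


@dataclass
class CurveFit:
    """Result of a 4PL fit; parameters are None when not converged."""

    compound_id: str
    pathway: str
    converged: bool
    ec50: float | None = None
    emax: float | None = None
    hill: float | None = None
    baseline: float | None = None
    se_log10_ec50: float | None = None
    se_emax: float | None = None
    se_hill: float | None = None
    se_baseline: float | None = None
    message: str = ""

    def ec50_ci95(self) -> tuple[float, float]:
        """95 % confidence interval for EC50 (log-normal parameterization)."""
        if not self.converged or self.se_log10_ec50 is None:
            raise PharmError("no converged fit to take a CI from")
        l = math.log10(self.ec50)
        return (10 ** (l - 1.96 * self.se_log10_ec50),
                10 ** (l + 1.96 * self.se_log10_ec50))


@dataclass(frozen=True)
class PlateReadout:
    mean_rlu_test: float
    mean_rlu_vehicle: float
    mean_max_cp: float
    mean_rlu_cp: float


@dataclass(frozen=True)
class BRETCalibration:
    A: float  # BRET ratio of negative control transfection
    B: float  # BRET ratio of positive control transfection

    def __post_init__(self):
        if self.B == self.A:
            raise PharmError("BRET calibration requires B != A")


@dataclass(frozen=True)
class PathwayEfficacy:
    """Per-pathway Emax/EC50 summary across n independent experiments."""

    pathway: str
    emax: float  # % of control
    ec50: float  # molar
    n: int = 1
    sd_log_ratio: float = 0.0  # SD of log10(Emax/EC50) across experiments

    def __post_init__(self):
        if self.n < 1:
            raise PharmError("n must be >= 1")
        if self.emax <= 0 or self.ec50 <= 0:
            raise PharmError("emax and ec50 must be positive for log(Emax/EC50)")

    @property
    def log_emax_ec50(self) -> float:
        return math.log10(self.emax / self.ec50)

    @property
    def sem(self) -> float:
        return sem_of_log_ratio(self.sd_log_ratio, self.n)


@dataclass(frozen=True)
class MPODescriptors:
    clogp: float
    clogd: float
    mw: float
    tpsa: float
    hbd: float
    pka: float
    provenance: str = "unspecified"

    def __post_init__(self):
        for name in ("clogp", "clogd", "mw", "tpsa", "hbd", "pka"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise PharmError(f"MPO descriptor {name} is missing")
        if self.mw <= 0 or self.hbd < 0:
            raise PharmError("invalid MPO descriptor values")


# --------------------------------------------------------------------------
# 4PL fitting


def _logistic(logc, baseline, emax, log_ec50, hill):
    return baseline + (emax - baseline) / (1.0 + 10 ** (hill * (log_ec50 - logc)))


def fit_4pl(
    data: ConcResponse,
    mode: str = "agonist",
    pool_replicates: bool = True,
) -> CurveFit:
    """Four-parameter logistic fit on log10 concentration.

    response = baseline + (Emax - baseline) / (1 + (EC50/c)^hill); for
    ``mode="inhibition"`` the top plateau sits at low concentration (the
    same model with Emax below baseline).  Fits are to pooled replicate
    points by default; set ``pool_replicates=False`` to fit replicate means.
    Non-convergence (including unidentifiable flat data) is reported on the
    returned object, never silently extrapolated.
    """
    if mode not in ("agonist", "inhibition"):
        raise PharmError(f"unknown mode {mode!r}")
    if np.unique(data.concentrations).size < 4:
        raise PharmError("need >= 4 distinct concentrations for a 4PL fit")

    logc = np.log10(data.concentrations)
    if pool_replicates:
        x = np.tile(logc, data.n_replicates)
        y = data.responses.ravel()
    else:
        x, y = logc, data.responses.mean(axis=0)

    if np.ptp(y) < 1e-9:
        return CurveFit(data.compound_id, data.pathway, converged=False,
                        message="flat response; EC50 unidentifiable")

    lo, hi = float(y.min()), float(y.max())
    mid = 0.5 * (logc.min() + logc.max())
    if mode == "agonist":
        p0 = (lo, hi, mid, 1.0)
    else:
        p0 = (hi, lo, mid, 1.0)
    span = hi - lo
    bounds = (
        [lo - span, lo - span, logc.min() - 3.0, 0.05],
        [hi + span, hi + span, logc.max() + 3.0, 10.0],
    )
    try:
        popt, pcov = optimize.curve_fit(
            _logistic, x, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return CurveFit(data.compound_id, data.pathway, converged=False,
                        message=f"no convergence: {exc}")
    if not np.all(np.isfinite(pcov)):
        return CurveFit(data.compound_id, data.pathway, converged=False,
                        message="singular covariance; parameters unidentifiable")
    se = np.sqrt(np.diag(pcov))
    baseline, emax, log_ec50, hill = popt
    return CurveFit(
        data.compound_id,
        data.pathway,
        converged=True,
        ec50=float(10 ** log_ec50),
        emax=float(emax),
        hill=float(hill),
        baseline=float(baseline),
        se_baseline=float(se[0]),
        se_emax=float(se[1]),
        se_log10_ec50=float(se[2]),
        se_hill=float(se[3]),
    )


# --------------------------------------------------------------------------
# hit calling


@dataclass
class HitCall:
    hits: list[str]
    n_total: int
    rate_percent: float | None
    suspect: list[str] = field(default_factory=list)
    status: str = "ok"


def call_hits(
    displacement: dict[str, float], threshold: float = 50.0
) -> HitCall:
    """Single-point hit calling: hit iff displacement strictly > threshold %.

    A value of exactly 50 % is not a hit.  Values outside [-50, 150] % are
    flagged as suspect but still classified.  An empty input yields an
    undefined rate with an explicit status rather than a zero.
    """
    if not displacement:
        return HitCall(hits=[], n_total=0, rate_percent=None, status="empty input")
    hits, suspect = [], []
    for cid, v in displacement.items():
        if not -50.0 <= v <= 150.0:
            suspect.append(cid)
        if v > threshold:
            hits.append(cid)
    rate = 100.0 * len(hits) / len(displacement)
    return HitCall(hits=hits, n_total=len(displacement), rate_percent=rate,
                   suspect=suspect)


# --------------------------------------------------------------------------
# affinity / efficiency metrics


def ki_cheng_prusoff(ic50: float, radioligand_conc: float, kd: float) -> float:
    """Ki = IC50 / (1 + L/Kd) for competition binding at radioligand conc L."""
    if ic50 <= 0:
        raise PharmError("IC50 must be positive")
    if radioligand_conc < 0:
        raise PharmError("radioligand concentration must be >= 0")
    if kd <= 0:
        raise PharmError("Kd must be positive")
    return ic50 / (1.0 + radioligand_conc / kd)


def lle(p_activity: float, clogp: float) -> float:
    """Lipophilic ligand efficiency: pIC50 (or pKi) minus cLogP."""
    if not (np.isfinite(p_activity) and np.isfinite(clogp)):
        raise PharmError("LLE inputs must be finite")
    return p_activity - clogp


def fold_change_and_ddg(
    ki_a: float, ki_b: float, temperature: float = 298.15
) -> tuple[float, float]:
    """Affinity fold change and binding free-energy difference.

    Returns (ki_a/ki_b, RT ln(ki_b/ki_a)) in kcal/mol; an affinity
    improvement (ki_b < ki_a) gives a fold > 1 and a negative ΔΔG.
    """
    if ki_a <= 0 or ki_b <= 0:
        raise PharmError("Ki values must be positive")
    fold = ki_a / ki_b
    ddg = GAS_CONSTANT_KCAL * temperature * math.log(ki_b / ki_a)
    return fold, ddg


# --------------------------------------------------------------------------
# CNS MPO (published desirability scheme; six piecewise-linear transforms)

# (low_knot, high_knot) of monotone-decreasing ramps: T0 = 1 below low,
# 0 above high
_MPO_RAMPS = {
    "clogp": (3.0, 5.0),
    "clogd": (2.0, 4.0),
    "mw": (360.0, 500.0),
    "hbd": (0.5, 3.5),
    "pka": (8.0, 10.0),
}
# TPSA uses a hump: 0 below 20, 1 on [40, 90], 0 above 120
_MPO_TPSA = (20.0, 40.0, 90.0, 120.0)


def _ramp_down(x: float, lo: float, hi: float) -> float:
    return float(np.interp(x, [lo, hi], [1.0, 0.0]))


def cns_mpo(d: MPODescriptors) -> float:
    """CNS multiparameter-optimization score in [0, 6].

    Sum of six desirability transforms: monotone-decreasing ramps for
    cLogP (1 at <= 3, 0 at >= 5), cLogD (2/4), MW (360/500), HBD (0.5/3.5)
    and pKa (8/10), plus a hump for TPSA (0 at <= 20, 1 on 40-90, 0 at
    >= 120).  Scores are only comparable when descriptor provenance (the
    estimator that produced cLogP/cLogD/pKa) is recorded alongside.
    """
    t = sum(
        _ramp_down(getattr(d, name), lo, hi)
        for name, (lo, hi) in _MPO_RAMPS.items()
    )
    a, b, c, e = _MPO_TPSA
    t += float(np.interp(d.tpsa, [a, b, c, e], [0.0, 1.0, 1.0, 0.0]))
    return t


# --------------------------------------------------------------------------
# plate readouts


def percent_activity(p: PlateReadout, denominator: str = "as-printed") -> float:
    """Percent agonist activity relative to the reference agonist.

    ``denominator="as-printed"`` implements the published form
    100 * (test - vehicle) / (max_ref - RLU_ref) verbatim; the alternate
    ``"max-minus-vehicle"`` uses (max_ref - vehicle), selectable because
    the printed denominator is unusual and the intent is not guessed.
    """
    if denominator == "as-printed":
        den = p.mean_max_cp - p.mean_rlu_cp
    elif denominator == "max-minus-vehicle":
        den = p.mean_max_cp - p.mean_rlu_vehicle
    else:
        raise PharmError(f"unknown denominator choice {denominator!r}")
    if den == 0:
        raise PharmError("percent_activity: zero denominator")
    return 100.0 * (p.mean_rlu_test - p.mean_rlu_vehicle) / den


def ubret(raw_ratio: float, cal: BRETCalibration) -> float:
    """Universal BRET: ((ratio - A) / (B - A)) * 10,000."""
    return (raw_ratio - cal.A) / (cal.B - cal.A) * 10_000.0


# --------------------------------------------------------------------------
# signaling bias


def delta_log_emax_ec50(test: PathwayEfficacy, ref: PathwayEfficacy) -> float:
    """Δlog(Emax/EC50) of a test compound versus the reference agonist."""
    if test.pathway != ref.pathway:
        raise PharmError(
            f"pathway mismatch: {test.pathway!r} vs {ref.pathway!r}"
        )
    return test.log_emax_ec50 - ref.log_emax_ec50


def sem_of_log_ratio(sd: float, n: int) -> float:
    """SEM = sigma / sqrt(n)."""
    if n < 1:
        raise PharmError("n must be >= 1")
    if sd < 0:
        raise PharmError("sd must be >= 0")
    return sd / math.sqrt(n)


def combined_sem(sem_test: float, sem_ref: float) -> float:
    """SEM of a difference of independent log-ratios (quadrature sum)."""
    if sem_test < 0 or sem_ref < 0:
        raise PharmError("SEMs must be >= 0")
    return math.hypot(sem_test, sem_ref)


def relative_efficacy(delta_log: float) -> float:
    """RE = 10^Δlog(Emax/EC50)."""
    if not np.isfinite(delta_log):
        raise PharmError("delta_log must be finite")
    return 10.0 ** delta_log


def bias_table(
    test: dict[str, PathwayEfficacy],
    ref: dict[str, PathwayEfficacy],
    ttest: bool = False,
):
    """Tidy per-pathway bias summary (pathway, Δlog, SEM, RE).

    Mirrors the radar-plot table: for each pathway present in both maps the
    Δlog(Emax/EC50) vs the reference, its propagated SEM and the relative
    efficacy.  With ``ttest=True`` a standard two-tailed Welch t statistic
    on the Δlog values is appended (a convenience, nothing bespoke).
    """
    import pandas as pd

    rows = []
    for pathway in sorted(set(test) & set(ref)):
        t, r = test[pathway], ref[pathway]
        dl = delta_log_emax_ec50(t, r)
        sem = combined_sem(t.sem, r.sem)
        row = {
            "pathway": pathway,
            "delta_log_emax_ec50": dl,
            "sem": sem,
            "relative_efficacy": relative_efficacy(dl),
        }
        if ttest:
            tt = stats.ttest_ind_from_stats(
                t.log_emax_ec50, t.sd_log_ratio, t.n,
                r.log_emax_ec50, r.sd_log_ratio, r.n,
                equal_var=False,
            )
            row["t_stat"], row["p_value"] = float(tt.statistic), float(tt.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
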