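"""Ellman cholinesterase-assay analysis and simulation.

The Ellman assay follows cholinesterase activity colorimetrically: the
enzyme hydrolyses acetylthiocholine, the released thiocholine cleaves DTNB,
and the yellow TNB anion is read at 405 nm. An inhibitor lowers the initial
rate of absorbance increase; percent inhibition against an uninhibited
control, measured over a dilution series, yields an IC50 by log-logistic
regression.

This module implements that analysis chain — progress-curve slope →
blank-corrected percent inhibition → IC50 ± SE — together with a
Michaelis–Menten simulator of the microplate protocol (200 µL final volume,
405 nm, 25 °C, 5 min kinetic reads, three technical replicates) so the
whole pipeline is testable without laboratory data.

Units: substrate and Km in mM, inhibitor concentrations in µM, time in
seconds, absorbance in AU, rates in AU/min, enzyme activity in U/mL
(1 U/mL = 1 µmol·min⁻¹·mL⁻¹ ≡ 1 mM/min of product in the well).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, NoTransitionError, PlateError

ROLES = ("test", "blank", "positive-control", "negative-control")

#: Long-format plate CSV columns.
PLATE_COLUMNS = ["well", "role", "conc_uM", "time_s", "abs405"]


@dataclass(frozen=True)
class AssayConditions:
    """Physical parameters of the microplate Ellman assay.

    Defaults reproduce the protocol geometry this package targets: 50 µL
    inhibitor dilution + 100 µL substrate/chromogen mix + 50 µL enzyme
    = 200 µL final volume, giving final (in-well) concentrations of 0.5 mM
    acetylthiocholine (from a 1 mM mix), 0.25 mM DTNB (from 0.5 mM) and
    0.001875 U/mL enzyme (from 0.0075 U/mL stock). The TNB extinction
    coefficient (13,600 M⁻¹cm⁻¹ at 405 nm) and the effective path length of
    200 µL in a 96-well plate (0.58 cm) are standard literature values; Km
    defaults to 0.1 mM, an order-of-magnitude typical value for
    cholinesterase/acetylthiocholine. All are overridable.
    """

    substrate_mM: float = 0.5
    chromogen_mM: float = 0.25
    enzyme_U_per_mL: float = 0.001875
    final_volume_uL: float = 200.0
    path_length_cm: float = 0.58
    extinction_M_cm: float = 13600.0
    km_mM: float = 0.1
    duration_s: float = 300.0
    read_interval_s: float = 15.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise DataError(f"AssayConditions.{name} must be positive, got {value}")

    @property
    def vmax_mM_per_min(self) -> float:
        # 1 U/mL of enzyme produces 1 mM/min of thiocholine (hence TNB) in-well
        return self.enzyme_U_per_mL

    def rate_to_AU_per_min(self, v_mM_per_min: float) -> float:
        """Beer–Lambert conversion: product formation rate → dA/dt at 405 nm."""
        return self.extinction_M_cm * self.path_length_cm * v_mM_per_min * 1e-3


@dataclass
class ProgressCurve:
    """One well's kinetic trace: absorbance at 405 nm versus time."""

    well: str
    times_s: np.ndarray
    absorbance: np.ndarray
    conc_uM: float = 0.0
    role: str = "test"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.role not in ROLES:
            raise PlateError(f"well {self.well}: unknown role {self.role!r}")
        if self.times_s.size < 3:
            raise PlateError(f"well {self.well}: need >= 3 time points, got {self.times_s.size}")
        if self.times_s.size != self.absorbance.size:
            raise PlateError(f"well {self.well}: time/absorbance length mismatch")
        if np.any(self.times_s < 0) or np.any(np.diff(self.times_s) <= 0):
            raise PlateError(f"well {self.well}: times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise PlateError(f"well {self.well}: non-finite absorbance")
        if self.conc_uM < 0:
            raise PlateError(f"well {self.well}: negative inhibitor concentration")


@dataclass
class PlateAssay:
    """A set of progress curves plus optional ground truth and warnings."""

    curves: list[ProgressCurve]
    ground_truth: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``well,role,conc_uM,time_s,abs405``."""
        frames = [
            pd.DataFrame(
                {
                    "well": c.well,
                    "role": c.role,
                    "conc_uM": c.conc_uM,
                    "time_s": c.times_s,
                    "abs405": c.absorbance,
                }
            )
            for c in self.curves
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PlateAssay":
        missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
        if missing:
            raise PlateError(f"plate table missing columns: {', '.join(missing)}")
        curves = []
        for well, grp in frame.groupby("well", sort=False):
            grp = grp.sort_values("time_s")
            roles = grp["role"].unique()
            concs = grp["conc_uM"].unique()
            if len(roles) != 1 or len(concs) != 1:
                raise PlateError(f"well {well}: inconsistent role or concentration annotations")
            curves.append(
                ProgressCurve(
                    well=str(well),
                    times_s=grp["time_s"].to_numpy(),
                    absorbance=grp["abs405"].to_numpy(),
                    conc_uM=float(concs[0]),
                    role=str(roles[0]),
                )
            )
        return cls(curves=curves)

    def write_csv(self, path, truth_sidecar: bool = True) -> None:
        """Write the long-format CSV (and a ground-truth JSON sidecar if any)."""
        self.to_frame().to_csv(path, index=False)
        if truth_sidecar and self.ground_truth is not None:
            sidecar = str(path) + ".truth.json"
            with open(sidecar, "w") as fh:
                json.dump(self.ground_truth, fh, indent=2, sort_keys=True)

    @classmethod
    def read_csv(cls, path) -> "PlateAssay":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and design of a simulated inhibition plate.

    Either ``ic50_uM`` or ``ki_uM`` fixes the inhibitor strength; with an
    IC50 the equivalent Ki follows from the inhibition mode at the assay's
    substrate concentration (Cheng–Prusoff for competitive inhibition,
    identity for noncompetitive). The same seed always reproduces the same
    plate; each well draws noise from its own deterministic substream.
    """

    ic50_uM: float | None = None
    ki_uM: float | None = None
    mode: str = "competitive"  # or "noncompetitive"
    concentrations_uM: tuple[float, ...] = tuple(1000.0 / 2**k for k in range(8))
    replicates: int = 3
    noise_sd_AU: float = 0.005
    seed: int = 0
    baseline_AU: float = 0.05
    conditions: AssayConditions = field(default_factory=AssayConditions)

    def __post_init__(self) -> None:
        if self.mode not in ("competitive", "noncompetitive"):
            raise DataError(f"unknown inhibition mode {self.mode!r}")
        if (self.ic50_uM is None) == (self.ki_uM is None):
            raise DataError("specify exactly one of ic50_uM or ki_uM")
        if any(c < 0 for c in self.concentrations_uM):
            raise DataError("inhibitor concentrations must be non-negative")
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")
        if self.noise_sd_AU < 0:
            raise DataError("noise standard deviation must be >= 0")

    @property
    def cheng_prusoff_factor(self) -> float:
        cond = self.conditions
        return 1.0 + cond.substrate_mM / cond.km_mM if self.mode == "competitive" else 1.0

    @property
    def true_ki_uM(self) -> float:
        if self.ki_uM is not None:
            return self.ki_uM
        return self.ic50_uM / self.cheng_prusoff_factor

    @property
    def true_ic50_uM(self) -> float:
        if self.ic50_uM is not None:
            return self.ic50_uM
        return self.ki_uM * self.cheng_prusoff_factor


def inhibited_velocity_mM_per_min(
    conc_uM: float, ki_uM: float, mode: str, cond: AssayConditions
) -> float:
    """Michaelis–Menten rate under reversible inhibition.

    v = Vmax·[S] / (Km·α + [S]·α′) with α = 1 + I/Ki and α′ = 1
    (competitive) or α′ = α (noncompetitive).
    """
    alpha = 1.0 + conc_uM / ki_uM
    s, km = cond.substrate_mM, cond.km_mM
    if mode == "competitive":
        return cond.vmax_mM_per_min * s / (km * alpha + s)
    return cond.vmax_mM_per_min * s / ((km + s) * alpha)


def simulate_plate(spec: SimulationSpec) -> PlateAssay:
    """Simulate an Ellman inhibition plate under the given spec.

    Each well's trace is A(t) = A₀ + ε·l·v·t + N(0, σ²) per read, with v
    from :func:`inhibited_velocity_mM_per_min`. Blanks carry no enzyme
    (flat baseline + noise); negative controls are uninhibited enzyme
    wells. Chromogen background hydrolysis is folded into the constant A₀.
    A spec implying >10% substrate depletion over the run attaches a
    warning rather than failing.
    """
    cond = spec.conditions
    times = np.arange(0.0, cond.duration_s + 0.5 * cond.read_interval_s, cond.read_interval_s)
    ki = spec.true_ki_uM

    # deterministic per-well substreams, stable under well ordering
    n_wells = spec.replicates * (2 + len(spec.concentrations_uM))
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(n_wells)]
    stream_iter = iter(streams)

    def trace(slope_AU_per_min: float, rng: np.random.Generator) -> np.ndarray:
        clean = spec.baseline_AU + slope_AU_per_min * times / 60.0
        if spec.noise_sd_AU > 0:
            return clean + rng.normal(0.0, spec.noise_sd_AU, size=times.size)
        return clean

    curves: list[ProgressCurve] = []
    for r in range(1, spec.replicates + 1):
        curves.append(
            ProgressCurve(f"BLK{r}", times, trace(0.0, next(stream_iter)), 0.0, "blank")
        )
    v0 = inhibited_velocity_mM_per_min(0.0, ki, spec.mode, cond)
    for r in range(1, spec.replicates + 1):
        curves.append(
            ProgressCurve(
                f"CTRL{r}",
                times,
                trace(cond.rate_to_AU_per_min(v0), next(stream_iter)),
                0.0,
                "negative-control",
            )
        )
    for i, conc in enumerate(spec.concentrations_uM, start=1):
        v = inhibited_velocity_mM_per_min(conc, ki, spec.mode, cond)
        slope = cond.rate_to_AU_per_min(v)
        for r in range(1, spec.replicates + 1):
            curves.append(ProgressCurve(f"C{i}R{r}", times, trace(slope, next(stream_iter)), conc, "test"))

    plate = PlateAssay(
        curves=curves,
        ground_truth={
            "mode": spec.mode,
            "ki_uM": ki,
            "ic50_uM": spec.true_ic50_uM,
            "cheng_prusoff_factor": spec.cheng_prusoff_factor,
            "noise_sd_AU": spec.noise_sd_AU,
            "seed": spec.seed,
            "concentrations_uM": list(spec.concentrations_uM),
            "replicates": spec.replicates,
        },
    )
    depletion = v0 * (cond.duration_s / 60.0) / cond.substrate_mM
    if depletion > 0.10:
        msg = (
            f"substrate depletion {100 * depletion:.1f}% over the run exceeds 10%; "
            "the linear-regime progress-curve model is inaccurate"
        )
        plate.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return plate


def initial_rate(curve: ProgressCurve, window_s: float | None = None) -> float:
    """Initial reaction rate in AU/min: OLS slope of absorbance vs time.

    ``window_s`` restricts the fit to t ≤ window (default: whole trace).
    A decreasing trace yields a negative rate with a warning.
    """
    if window_s is not None:
        mask = curve.times_s <= window_s
        t, a = curve.times_s[mask], curve.absorbance[mask]
    else:
        t, a = curve.times_s, curve.absorbance
    if t.size < 3:
        raise PlateError(f"well {curve.well}: fewer than 3 points in the rate window")
    slope_per_s = np.polyfit(t, a, 1)[0]
    rate = slope_per_s * 60.0
    if rate < 0:
        warnings.warn(f"well {curve.well}: decreasing absorbance (rate {rate:.4g} AU/min)", stacklevel=2)
    return float(rate)


def percent_inhibition(rate_test: float, rate_uninhibited: float) -> float:
    """Percent inhibition: 100 · (1 − v_test / v_control)."""
    if not rate_uninhibited > 0:
        raise DataError(
            f"uninhibited rate must be positive, got {rate_uninhibited} (assay failure)"
        )
    return 100.0 * (1.0 - rate_test / rate_uninhibited)


@dataclass
class InhibitionResult:
    """Dose-response analysis outcome.

    ``censored`` is ``"gt:<c_max>"`` when the top tested concentration never
    reaches 50% inhibition — the assay's "no activity" reading — in which
    case ``ic50_uM`` is None. Percent-inhibition values are stored as
    fitted, never clipped. ``ki_uM`` is an optional annotation (e.g. from a
    simulator's ground truth); it is never inferred from the fit.
    """

    concentrations_uM: np.ndarray
    inhibition_pct: np.ndarray
    ic50_uM: float | None
    ic50_se_uM: float | None
    hill: float | None
    rmse: float | None
    converged: bool
    censored: str | None = None
    ki_uM: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "conc_uM": [float(c) for c in self.concentrations_uM],
            "inhibition_pct": [float(i) for i in self.inhibition_pct],
            "ic50_uM": self.ic50_uM,
            "ic50_se_uM": self.ic50_se_uM,
            "hill": self.hill,
            "rmse": self.rmse,
            "n_points": int(len(self.concentrations_uM)),
            "converged": self.converged,
            "censored": self.censored,
        }


def _loglogistic(conc: np.ndarray, log_ic50: float, hill: float, bottom: float, top: float):
    # increasing sigmoid: bottom at c -> 0, top at c -> inf
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + np.exp(-hill * (np.log(conc) - log_ic50)))


def fit_ic50(
    concentrations_uM,
    inhibition_pct,
    weights=None,
    fix_bottom: float | None = 0.0,
    fix_top: float | None = 100.0,
) -> InhibitionResult:
    """Fit a log-logistic dose-response curve and extract IC50 ± SE.

    The default model is the four-parameter log-logistic with bottom fixed
    at 0% and top at 100% (pass ``fix_bottom=None`` / ``fix_top=None`` to
    release them), fitted by unweighted least squares on (log IC50, Hill
    slope); the IC50 standard error comes from the covariance of the
    log-IC50 parameter by the delta method. ``weights`` are per-point
    standard deviations (as scipy's ``sigma``).

    Data never reaching 50% inhibition at the top concentration give a
    censored ``"gt:<c_max>"`` result; data above 50% everywhere raise
    :class:`NoTransitionError`.
    """
    conc = np.asarray(concentrations_uM, dtype=float)
    inh = np.asarray(inhibition_pct, dtype=float)
    if conc.shape != inh.shape:
        raise DataError("concentration and inhibition arrays differ in length")
    order = np.argsort(conc)
    conc, inh = conc[order], inh[order]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[order]
    positive = conc > 0
    conc_fit, inh_fit = conc[positive], inh[positive]
    w_fit = weights[positive] if weights is not None else None
    if len(np.unique(conc_fit)) < 4:
        raise DataError("need >= 4 distinct positive concentrations to fit an IC50")

    c_max = float(conc_fit.max())
    if inh_fit[conc_fit == c_max].mean() < 50.0:
        return InhibitionResult(
            concentrations_uM=conc_fit,
            inhibition_pct=inh_fit,
            ic50_uM=None,
            ic50_se_uM=None,
            hill=None,
            rmse=None,
            converged=False,
            censored=f"gt:{c_max:g}",
        )
    if np.min(inh_fit) > 50.0:
        raise NoTransitionError(
            "no transition observed: inhibition exceeds 50% at every tested concentration"
        )

    # initial IC50 guess: first crossing of 50% by log-linear interpolation
    above = np.nonzero(inh_fit >= 50.0)[0]
    i = above[0]
    if i == 0:
        log_c50 = np.log(conc_fit[0])
    else:
        x0, x1 = np.log(conc_fit[i - 1]), np.log(conc_fit[i])
        y0, y1 = inh_fit[i - 1], inh_fit[i]
        log_c50 = x0 + (50.0 - y0) * (x1 - x0) / max(y1 - y0, 1e-12)

    free: list[str] = ["log_ic50", "hill"]
    p0 = [log_c50, 1.0]
    if fix_bottom is None:
        free.append("bottom")
        p0.append(float(np.min(inh_fit)))
    if fix_top is None:
        free.append("top")
        p0.append(float(np.max(inh_fit)))

    def model(c, *params):
        kw = dict(zip(free, params))
        return _loglogistic(
            c,
            kw["log_ic50"],
            kw["hill"],
            kw.get("bottom", fix_bottom),
            kw.get("top", fix_top),
        )

    try:
        popt, pcov = curve_fit(
            model, conc_fit, inh_fit, p0=p0, sigma=w_fit, absolute_sigma=False, maxfev=10000
        )
    except RuntimeError:
        return InhibitionResult(
            concentrations_uM=conc_fit,
            inhibition_pct=inh_fit,
            ic50_uM=None,
            ic50_se_uM=None,
            hill=None,
            rmse=None,
            converged=False,
        )

    ic50 = float(np.exp(popt[0]))
    var_log = float(pcov[0, 0])
    se = ic50 * np.sqrt(var_log) if np.isfinite(var_log) and var_log >= 0 else None
    residuals = inh_fit - model(conc_fit, *popt)
    return InhibitionResult(
        concentrations_uM=conc_fit,
        inhibition_pct=inh_fit,
        ic50_uM=ic50,
        ic50_se_uM=se,
        hill=float(popt[1]),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        converged=True,
    )


def blank_correct(plate: PlateAssay) -> PlateAssay:
    """Subtract the mean blank drift (offset + slope) from every trace.

    The blank wells' average linear trend — chromogen background plus any
    instrument drift — is removed from all wells. Applying the correction
    twice changes nothing beyond the first pass (the corrected blanks
    average to a zero trend), so the operation is idempotent.
    """
    blanks = [c for c in plate.curves if c.role == "blank"]
    if not blanks:
        raise PlateError("plate has no blank wells")
    slopes = [np.polyfit(b.times_s, b.absorbance, 1) for b in blanks]
    mean_slope = float(np.mean([s[0] for s in slopes]))
    mean_offset = float(np.mean([s[1] for s in slopes]))
    corrected = [
        replace(c, absorbance=c.absorbance - (mean_offset + mean_slope * c.times_s))
        for c in plate.curves
    ]
    return PlateAssay(curves=corrected, ground_truth=plate.ground_truth, warnings=list(plate.warnings))


def analyze_plate(
    plate: PlateAssay,
    conditions: AssayConditions | None = None,
    window_s: float | None = None,
    fix_bottom: float | None = 0.0,
    fix_top: float | None = 100.0,
) -> InhibitionResult:
    """Full plate analysis: blank correction → rates → inhibition → IC50.

    Requires blank wells and uninhibited negative-control wells. Technical
    replicates are averaged per concentration; the result is independent of
    row order in the input file. ``conditions`` is accepted for interface
    symmetry with the simulator (the analysis itself is purely empirical).
    """
    del conditions  # analysis uses only the measured traces
    roles = {c.role for c in plate.curves}
    if "blank" not in roles:
        raise PlateError("plate has no blank wells (role 'blank')")
    if "negative-control" not in roles:
        raise PlateError("plate has no uninhibited control wells (role 'negative-control')")

    corrected = blank_correct(plate)
    control_rates = [
        initial_rate(c, window_s) for c in corrected.curves if c.role == "negative-control"
    ]
    rate_ctrl = float(np.mean(control_rates))

    by_conc: dict[float, list[float]] = {}
    for c in corrected.curves:
        if c.role == "test":
            by_conc.setdefault(c.conc_uM, []).append(initial_rate(c, window_s))
    if not by_conc:
        raise PlateError("plate has no test wells")

    concs = np.array(sorted(by_conc))
    inhibitions = np.array(
        [percent_inhibition(float(np.mean(by_conc[c])), rate_ctrl) for c in concs]
    )
    result = fit_ic50(concs, inhibitions, fix_bottom=fix_bottom, fix_top=fix_top)
    if plate.ground_truth is not None:
        result.ki_uM = plate.ground_truth.get("ki_uM")
    return result
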