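"""Binding kinetics and thermodynamics for 1:1 protein–peptide recognition.

SPR sensorgrams are analysed with the classic two-step 1:1 Langmuir scheme:
the dissociation phase is fitted to a single exponential,
``R(t) = R0·exp(-koff·(t - t0)) + baseline``, and the association phase to
``R(t) = Req·(1 - exp(-kobs·t))`` with the pseudo-first-order relation
``kobs = kon·C + koff``, so ``kon = (kobs - koff)/C``. Per-injection
estimates are aggregated as mean ± SEM, with the complex half-life
``t1/2 = ln 2 / koff`` and the kinetic ``KD = koff/kon``.

ITC-derived parameters (N, KD, ΔH at temperature T) are converted with
``ΔG = R·T·ln KD = ΔH - T·ΔS`` and compared across variants through
``ΔΔG = ΔG_mut - ΔG_WT``; an affinity fold-change f maps to a ΔΔG magnitude
``R·T·ln f`` (affinity gains stabilize: negative ΔΔG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "Sensorgram",
    "DissociationFit",
    "AssociationFit",
    "KineticParameters",
    "BindingThermodynamics",
    "fit_dissociation",
    "fit_association",
    "fit_injection",
    "aggregate_kinetics",
    "thermodynamics_from_itc",
    "ddg",
    "fold_change_to_ddg",
    "ddg_to_fold_change",
    "flag_biphasic_isotherm",
]

#: gas constant in kcal·mol⁻¹·K⁻¹
GAS_CONSTANT_KCAL = 1.9872e-3
#: 25 °C, the temperature of the binding experiments
STANDARD_TEMPERATURE_K = 298.15


# ---------------------------------------------------------------------------
# Sensorgram container
# ---------------------------------------------------------------------------


@dataclass
class Sensorgram:
    """A single-injection SPR trace (response in RU; 1 RU = 1 pg·mm⁻²)."""

    time: np.ndarray
    response: np.ndarray
    concentration: float
    assoc_start: float
    assoc_end: float
    dissoc_end: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")
        if not self.assoc_start <= self.assoc_end <= self.dissoc_end:
            raise ValueError("phase boundaries must be contiguous")

    @property
    def association(self) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time >= self.assoc_start) & (self.time < self.assoc_end)
        return self.time[m], self.response[m]

    @property
    def dissociation(self) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time >= self.assoc_end) & (self.time <= self.dissoc_end)
        return self.time[m], self.response[m]

    def to_frame(self) -> pd.DataFrame:
        phase = np.where(self.time < self.assoc_end, "association",
                         "dissociation")
        return pd.DataFrame(
            {
                "time_s": self.time,
                "response_RU": self.response,
                "conc_M": self.concentration,
                "phase": phase,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Sensorgram":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        assoc = df["phase"] == "association"
        assoc_end = (
            float(t[~assoc].min()) if (~assoc).any() else float(t[-1])
        )
        return cls(
            time=t,
            response=df["response_RU"].to_numpy(dtype=float),
            concentration=float(df["conc_M"].iloc[0]),
            assoc_start=float(t[0]),
            assoc_end=assoc_end,
            dissoc_end=float(t[-1]),
        )


# ---------------------------------------------------------------------------
# Phase fits
# ---------------------------------------------------------------------------


@dataclass
class DissociationFit:
    koff: float
    amplitude: float
    baseline: float
    residual_rms: float
    flagged: bool
    message: str = ""


@dataclass
class AssociationFit:
    kobs: float
    kon: float
    req: float
    residual_rms: float
    valid: bool
    message: str = ""
    kon_variance: float = float("nan")


def fit_dissociation(
    sensorgram: Sensorgram, fit_baseline: bool = True
) -> DissociationFit:
    """Single-exponential fit of the dissociation phase.

    The optional constant baseline absorbs instrument drift; disable it for
    noiseless synthetic traces to recover the rate to machine precision.
    """
    t, y = sensorgram.dissociation
    if t.size < 5:
        raise ValueError("dissociation phase needs at least 5 points")
    t0 = t[0]
    decay = y[0] - y[-1]
    if decay <= 0:
        return DissociationFit(
            koff=float("nan"), amplitude=0.0, baseline=float(y.mean()),
            residual_rms=float(np.std(y)), flagged=True,
            message="non-decaying dissociation signal",
        )
    koff0 = max(1e-6, math.log(max(y[0], 1e-12) / max(y[-1], 1e-12))
                / max(t[-1] - t0, 1e-12))

    if fit_baseline:
        def model(tt, r0, k, b):
            return r0 * np.exp(-k * (tt - t0)) + b

        p0 = [decay, koff0, y[-1]]
    else:
        def model(tt, r0, k):
            return r0 * np.exp(-k * (tt - t0))

        p0 = [y[0], koff0]
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return DissociationFit(
            koff=float("nan"), amplitude=float("nan"),
            baseline=float("nan"), residual_rms=float("nan"),
            flagged=True, message=f"fit failed: {exc}",
        )
    resid = y - model(t, *popt)
    koff = float(popt[1])
    flagged = not (koff > 0 and math.isfinite(koff))
    return DissociationFit(
        koff=koff,
        amplitude=float(popt[0]),
        baseline=float(popt[2]) if fit_baseline else 0.0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        flagged=flagged,
        message="koff estimate <= 0" if flagged else "",
    )


def fit_association(sensorgram: Sensorgram, koff: float) -> AssociationFit:
    """Pseudo-first-order association fit; kon = (kobs - koff)/C."""
    if not koff > 0:
        raise ValueError("koff must be positive")
    t, y = sensorgram.association
    if t.size < 5:
        raise ValueError("association phase needs at least 5 points")
    t0 = t[0]

    def model(tt, req, kobs):
        return req * (1.0 - np.exp(-kobs * (tt - t0)))

    p0 = [max(y.max(), 1e-9), max(koff * 2.0, 1e-4)]
    popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000)
    req, kobs = float(popt[0]), float(popt[1])
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if kobs <= koff:
        return AssociationFit(
            kobs=kobs, kon=float("nan"), req=req, residual_rms=rms,
            valid=False, message="kobs <= koff: kon undefined",
        )
    c = sensorgram.concentration
    kon = (kobs - koff) / c
    # per-injection uncertainty of kon, used for inverse-variance averaging
    kon_var = float(pcov[1, 1]) / c**2 if np.isfinite(pcov[1, 1]) else float("nan")
    return AssociationFit(kobs=kobs, kon=kon, req=req, residual_rms=rms,
                          valid=True, kon_variance=kon_var)


def fit_injection(
    sensorgram: Sensorgram, fit_baseline: bool = True
) -> tuple[DissociationFit, AssociationFit | None]:
    """Dissociation first, then association constrained by the fitted koff."""
    dis = fit_dissociation(sensorgram, fit_baseline=fit_baseline)
    if dis.flagged:
        return dis, None
    return dis, fit_association(sensorgram, dis.koff)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class KineticParameters:
    """Mean ± SEM kinetics over independent injections."""

    kon: float
    kon_sem: float
    koff: float
    koff_sem: float
    kd_kinetic: float
    t_half: float
    n_injections: int

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0):
            raise ValueError("rates must be positive")
        assert abs(self.t_half * self.koff - math.log(2)) < 1e-9
        assert abs(self.kd_kinetic - self.koff / self.kon) <= 1e-12 * self.kd_kinetic


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


def aggregate_kinetics(
    fits: Sequence[tuple[DissociationFit, AssociationFit | None]],
    weight_kon: bool = True,
) -> KineticParameters:
    """Average per-injection rate constants; t1/2 and KD from the means.

    kon estimates from low-concentration injections are intrinsically noisy
    (kobs − koff is small there), so by default the per-injection kon values
    are combined with inverse-variance weights from the association fit;
    ``weight_kon=False`` gives the plain mean. Weights also fall back to the
    plain mean when any fit lacks a finite variance. koff is always a plain
    mean over injections.
    """
    koffs = np.array(
        [d.koff for d, _ in fits if not d.flagged and math.isfinite(d.koff)]
    )
    valid_assoc = [a for _, a in fits if a is not None and a.valid]
    kons = np.array([a.kon for a in valid_assoc])
    if koffs.size < 2 or kons.size < 2:
        raise ValueError("need at least 2 valid injections")
    variances = np.array([a.kon_variance for a in valid_assoc])
    koff = float(koffs.mean())
    if weight_kon and np.all(np.isfinite(variances)) and np.all(variances > 0):
        w = 1.0 / variances
        kon = float(np.average(kons, weights=w))
        kon_sem = float(math.sqrt(1.0 / w.sum()))
    else:
        kon = float(kons.mean())
        kon_sem = _sem(kons)
    return KineticParameters(
        kon=kon,
        kon_sem=kon_sem,
        koff=koff,
        koff_sem=_sem(koffs),
        kd_kinetic=koff / kon,
        t_half=math.log(2) / koff,
        n_injections=int(max(koffs.size, kons.size)),
    )


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------


@dataclass
class BindingThermodynamics:
    """One-set-of-sites binding thermodynamics (energies in kcal/mol)."""

    n_sites: float
    kd: float
    dh: float
    temperature: float = STANDARD_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL
    dg: float = field(init=False)
    tds: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("KD must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.dg = self.gas_constant * self.temperature * math.log(self.kd)
        self.tds = self.dh - self.dg
        assert abs(self.dg - (self.dh - self.tds)) < 1e-9

    def ddg_vs(self, reference: "BindingThermodynamics") -> float:
        """ΔΔG = ΔG(self) - ΔG(reference); positive destabilizes."""
        return self.dg - reference.dg


def thermodynamics_from_itc(
    n_sites: float,
    kd: float,
    dh: float,
    temperature: float = STANDARD_TEMPERATURE_K,
) -> BindingThermodynamics:
    """Convert fitted ITC parameters (N, KD in M, ΔH in kcal/mol) to ΔG/TΔS."""
    return BindingThermodynamics(n_sites=n_sites, kd=kd, dh=dh,
                                 temperature=temperature)


def ddg(dg_mut: float, dg_wt: float) -> float:
    """ΔΔG = ΔG_mut − ΔG_WT in kcal/mol."""
    return dg_mut - dg_wt


def fold_change_to_ddg(
    fold: float,
    temperature: float = STANDARD_TEMPERATURE_K,
    stabilizing: bool = False,
) -> float:
    """ΔΔG from an affinity fold-change: magnitude R·T·ln(fold).

    ``stabilizing=True`` marks an affinity *increase* (KD_mut < KD_WT) and
    returns a negative ΔΔG; otherwise the fold is a loss of affinity and the
    sign is positive.
    """
    if fold <= 0:
        raise ValueError("fold change must be positive")
    mag = GAS_CONSTANT_KCAL * temperature * math.log(fold)
    return -mag if stabilizing else mag


def ddg_to_fold_change(
    ddg_value: float, temperature: float = STANDARD_TEMPERATURE_K
) -> float:
    """Inverse of :func:`fold_change_to_ddg` (uses the magnitude)."""
    return math.exp(abs(ddg_value) / (GAS_CONSTANT_KCAL * temperature))


def flag_biphasic_isotherm(
    injection_heats: Sequence[float], rel_tol: float = 0.05
) -> bool:
    """Flag titration isotherms a one-set-of-sites model cannot describe.

    A simple 1:1 exothermic titration releases monotonically decreasing heat
    magnitudes as the sites saturate; a biphasic isotherm shows a secondary
    rise. The check flags any increase in |heat| along the titration larger
    than ``rel_tol`` of the full range.
    """
    q = np.abs(np.asarray(injection_heats, dtype=float))
    if q.size < 3:
        raise ValueError("need at least 3 injections")
    scale = float(q.max() - q.min())
    if scale == 0:
        return False
    rises = np.diff(q)
    return bool(np.any(rises > rel_tol * scale))
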