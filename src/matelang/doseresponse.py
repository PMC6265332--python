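"""Dose-response analysis of peptide-GPCR activation from plate-reader data.

Workflow: correct raw OD for photodetector saturation, normalize fluorescence
per OD, then fit a four-parameter logistic (4PL) on the log10-dose axis.
Water controls (dose 0) cannot sit on a log axis, so they anchor the basal
parameter and the remaining three parameters (maximal, EC50, Hill) are fitted
to the nonzero doses.

The fitting surface follows the Model/Results convention: build a
:class:`DoseResponse` from arrays or a long-format DataFrame, call
``fit()``, and read estimates and diagnostics off the returned
:class:`DoseResponseResults` (or print ``summary()``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .curves import DetectorModel, FourPL

__all__ = [
    "DetectorModel",
    "FourPL",
    "correct_od",
    "normalize",
    "make_dose_ladder",
    "DoseResponse",
    "DoseResponseResults",
    "fit_4pl",
    "fold_activation",
    "ReceptorClass",
    "classify_receptor",
    "HitRate",
    "hit_rate",
]

#: long-format measurement schema shared with the synthetic plate generator
MEASUREMENT_COLUMNS = ["receptor", "ligand", "dose_nM", "replicate", "od_raw", "fluor_raw"]


def correct_od(od_raw, detector: DetectorModel):
    """Correct measured OD for photodetector saturation (measured -> true OD)."""
    return detector.correct(od_raw)


def normalize(measurements: pd.DataFrame, detector: DetectorModel) -> pd.DataFrame:
    """Per-OD normalization of raw fluorescence.

    Corrects ``od_raw`` through the detector model and divides ``fluor_raw``
    by the true OD.  Replicates stay as separate rows.  Rows whose true OD is
    not positive are dropped with a warning.
    """
    out = measurements.copy()
    out["od_true"] = detector.correct(out["od_raw"].to_numpy())
    bad = out["od_true"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} rows with non-positive true OD")
        out = out[~bad].copy()
    out["fluor_per_od"] = out["fluor_raw"] / out["od_true"]
    return out


def make_dose_ladder(start: float, factor: float, n: int) -> list[float]:
    """Geometric dilution series: ``n`` doses descending from ``start`` (nM)
    by ``factor`` per step, plus a trailing water control (0)."""
    if start <= 0:
        raise ValueError("start dose must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 1:
        raise ValueError("need at least one dose")
    return [start / factor**i for i in range(n)] + [0.0]


# ---------------------------------------------------------------------------
# 4PL model / results
# ---------------------------------------------------------------------------

class DoseResponse:
    """Four-parameter logistic dose-response model for one receptor-ligand pair.

    Parameters
    ----------
    doses : array-like
        Doses in nM; zeros are water controls and anchor the basal level.
    responses : array-like
        Per-OD normalized fluorescence, one entry per well.

    Examples
    --------
    >>> res = DoseResponse(doses, responses).fit()
    >>> res.ec50, res.hill
    """

    def __init__(self, doses, responses, *, receptor: str = "", ligand: str = ""):
        self.doses = np.asarray(doses, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if not np.any(self.doses == 0):
            raise ValueError("water-control rows (dose 0) are required")
        self.receptor = receptor
        self.ligand = ligand

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        receptor: str | None = None,
        ligand: str | None = None,
        dose_col: str = "dose_nM",
        response_col: str = "fluor_per_od",
    ) -> "DoseResponse":
        """Build from a long-format normalized table (see :func:`normalize`)."""
        sub = df
        if receptor is not None:
            sub = sub[sub["receptor"] == receptor]
        if ligand is not None:
            sub = sub[sub["ligand"] == ligand]
        if sub.empty:
            raise ValueError("no rows for the requested receptor/ligand")
        return cls(
            sub[dose_col].to_numpy(),
            sub[response_col].to_numpy(),
            receptor=receptor or "",
            ligand=ligand or "",
        )

    def fit(
        self,
        hill_bounds: tuple[float, float] = (0.1, 10.0),
        min_distinct_doses: int = 5,
    ) -> "DoseResponseResults":
        """Fit the 4PL. Never raises on optimizer failure; check ``converged``."""
        nz = self.doses > 0
        water = self.responses[~nz]
        d, y = self.doses[nz], self.responses[nz]
        basal = float(np.mean(water))
        distinct = np.unique(d)
        if distinct.size < min_distinct_doses:
            raise ValueError(
                f"need >= {min_distinct_doses} distinct nonzero doses, got {distinct.size}"
            )

        span = float(np.max(self.responses) - np.min(self.responses))
        scale = max(abs(float(np.max(self.responses))), 1.0)
        if span <= 1e-12 * scale:
            # flat plate: nothing to fit
            return DoseResponseResults(
                model=self,
                params=FourPL(basal, basal + 1e-300, 1.0, 1.0),
                basal=basal,
                maximal=basal,
                ec50=math.nan,
                hill=math.nan,
                fold_change=1.0,
                converged=False,
                degenerate=True,
                residual_norm=0.0,
                message="degenerate: all responses identical",
            )

        logd = np.log10(d)

        def model(x, maximal, log_ec50, hill):
            return basal + (maximal - basal) / (1.0 + 10.0 ** (hill * (log_ec50 - x)))

        p0 = [float(np.max(y)), float(np.mean(logd)), 1.0]
        lo = [basal, float(logd.min() - 3.0), hill_bounds[0]]
        hi = [10.0 * max(float(np.max(y)), abs(basal), 1.0), float(logd.max() + 3.0), hill_bounds[1]]
        p0 = [min(max(v, a), b) for v, a, b in zip(p0, lo, hi)]
        try:
            popt, _ = curve_fit(
                model, logd, y, p0=p0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
            converged, message = True, "converged"
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            popt, converged, message = p0, False, f"optimizer failure: {exc}"
        maximal, log_ec50, hill = (float(v) for v in popt)
        ec50 = 10.0**log_ec50
        resid = y - model(logd, *popt)
        fold = fold_activation_from_arrays(self.doses, self.responses)
        return DoseResponseResults(
            model=self,
            params=FourPL(basal, max(maximal, basal + 1e-300), ec50, hill),
            basal=basal,
            maximal=maximal,
            ec50=ec50,
            hill=hill,
            fold_change=fold,
            converged=converged,
            degenerate=False,
            residual_norm=float(np.linalg.norm(resid)),
            message=message,
        )


@dataclass
class DoseResponseResults:
    """Estimates and diagnostics from a 4PL fit.

    ``fold_change`` is the screening statistic (best dose-group mean over the
    water mean); the fitted ``maximal`` is reported separately.
    """

    model: DoseResponse
    params: FourPL
    basal: float
    maximal: float
    ec50: float
    hill: float
    fold_change: float
    converged: bool
    degenerate: bool
    residual_norm: float
    message: str = ""

    def predict(self, dose):
        return self.params.response(dose)

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit",
            "=" * 42,
        ]
        if self.model.receptor or self.model.ligand:
            lines.append(f"pair:          {self.model.receptor} / {self.model.ligand}")
        lines += [
            f"basal:         {self.basal:.6g} afu/OD (water-anchored)",
            f"maximal:       {self.maximal:.6g} afu/OD",
            f"EC50:          {self.ec50:.6g} nM",
            f"Hill:          {self.hill:.6g}",
            f"fold change:   {self.fold_change:.6g}",
            f"residual norm: {self.residual_norm:.6g}",
            f"converged:     {self.converged}" + ("  (degenerate)" if self.degenerate else ""),
        ]
        return "\n".join(lines)


def fit_4pl(doses, responses) -> DoseResponseResults:
    """Functional wrapper around ``DoseResponse(doses, responses).fit()``."""
    return DoseResponse(doses, responses).fit()


# ---------------------------------------------------------------------------
# Screening statistics and classification
# ---------------------------------------------------------------------------

def fold_activation_from_arrays(doses, responses) -> float:
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    water = responses[doses == 0]
    if water.size == 0:
        raise ValueError("water controls (dose 0) required")
    water_mean = float(np.mean(water))
    if water_mean <= 0:
        raise ValueError("water-control mean must be positive")
    best = max(
        float(np.mean(responses[doses == d])) for d in np.unique(doses[doses > 0])
    )
    return best / water_mean


def fold_activation(measurements: pd.DataFrame, response_col: str = "fluor_per_od") -> float:
    """Maximum dose-group mean normalized fluorescence over the water mean."""
    return fold_activation_from_arrays(
        measurements["dose_nM"].to_numpy(), measurements[response_col].to_numpy()
    )


@dataclass(frozen=True)
class ReceptorClass:
    """On/off screening call for one receptor."""

    label: str  # "functional" | "non_functional" | "constitutive"
    signal_difference: float  # mean(on) - mean(off), afu/OD
    sd_units: float  # signal difference in pooled-SD units
    responsive: bool = True


def classify_receptor(
    on: Sequence[float],
    off: Sequence[float],
    cohort_basals: Sequence[float],
    sd_multiplier: float = 3.0,
    basal_fold: float = 3.0,
) -> ReceptorClass:
    """Classify a receptor from single-dose on/off replicates.

    ``non_functional`` if the on-off signal difference is below
    ``sd_multiplier`` pooled standard deviations; ``constitutive`` if the
    peptide-free signal exceeds ``basal_fold`` times the cohort's median basal
    level (this takes precedence for responsive receptors); ``functional``
    otherwise.  Requires >= 3 replicates per condition.
    """
    on = np.asarray(on, dtype=float)
    off = np.asarray(off, dtype=float)
    if on.size < 3 or off.size < 3:
        raise ValueError("need >= 3 replicates per condition")
    diff = float(on.mean() - off.mean())
    pooled_var = (
        (on.size - 1) * on.var(ddof=1) + (off.size - 1) * off.var(ddof=1)
    ) / (on.size + off.size - 2)
    pooled_sd = math.sqrt(pooled_var)
    responsive = diff >= sd_multiplier * pooled_sd
    sd_units = diff / pooled_sd if pooled_sd > 0 else math.inf * np.sign(diff or 1.0)

    central_basal = float(np.median(np.asarray(cohort_basals, dtype=float)))
    high_basal = off.mean() > basal_fold * central_basal
    if high_basal and responsive:
        label = "constitutive"
    elif not responsive:
        label = "non_functional"
    else:
        label = "functional"
    return ReceptorClass(label, diff, float(sd_units), responsive)


class HitRate(NamedTuple):
    value: float  # unrounded percent
    rounded: int  # half-up to nearest integer, for reporting


def hit_rate(classes: Sequence[ReceptorClass], include_constitutive: bool = False) -> HitRate:
    """Percent of screened receptors that are functional.

    With ``include_constitutive=True``, responsive constitutive receptors
    count as hits as well.
    """
    if not classes:
        raise ValueError("empty screen")
    hits = sum(
        c.label == "functional"
        or (include_constitutive and c.label == "constitutive" and c.responsive)
        for c in classes
    )
    pct = 100.0 * hits / len(classes)
    return HitRate(pct, int(math.floor(pct + 0.5)))
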