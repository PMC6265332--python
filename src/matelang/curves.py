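"""Shared response-curve primitives: the four-parameter logistic (4PL) and the
plate-reader photodetector saturation model.

The 4PL is the standard pharmacological dose-response model

    f(d) = basal + (maximal - basal) / (1 + (ec50 / d)**hill)

with ``f(0) = basal`` by continuity. All doses are in nM; responses are in
arbitrary fluorescence units per OD (afu/OD) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FourPL", "DetectorModel"]


@dataclass(frozen=True)
class FourPL:
    """Four-parameter logistic dose-response curve.

    Parameters
    ----------
    basal : float
        Response at zero dose (afu/OD).
    maximal : float
        Response at saturating dose (afu/OD).
    ec50 : float
        Dose giving half-maximal response (nM); must be positive.
    hill : float
        Hill slope; > 1 is switch-like, < 1 is graded.
    """

    basal: float
    maximal: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be positive, got {self.hill}")

    def response(self, dose):
        """Evaluate the curve at ``dose`` (scalar or array, nM); dose 0 -> basal."""
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(d > 0, 1.0 / (1.0 + (self.ec50 / np.where(d > 0, d, 1.0)) ** self.hill), 0.0)
        out = self.basal + (self.maximal - self.basal) * frac
        return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out

    def activity(self, dose):
        """Normalized activity in [0, 1]: (response - basal) / (maximal - basal)."""
        span = self.maximal - self.basal
        if span <= 0:
            d = np.asarray(dose, dtype=float)
            return 0.0 if d.ndim == 0 else np.zeros_like(d)
        resp = self.response(dose)
        return (resp - self.basal) / span

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.basal, self.maximal, self.ec50, self.hill)


@dataclass(frozen=True)
class DetectorModel:
    """Photodetector saturation model for plate-reader optical density.

    A measured OD underestimates the true OD near the detector ceiling.  The
    correction is

        A_true = k * A_meas / (A_sat - A_meas)

    where ``a_sat`` is the saturation value of the photodetector and ``k`` the
    true OD at which the detector reads half of saturation.  ``saturate`` is
    the exact forward transform (true -> measured), the inverse of the
    correction, used by the synthetic plate generator.
    """

    a_sat: float
    k: float

    def __post_init__(self) -> None:
        if self.a_sat <= 0 or self.k <= 0:
            raise ValueError("a_sat and k must be positive")

    def correct(self, od_raw):
        """Measured OD -> true OD. Strictly increasing on [0, a_sat)."""
        od = np.asarray(od_raw, dtype=float)
        if np.any(od < 0):
            raise ValueError("od_raw must be non-negative")
        if np.any(od >= self.a_sat):
            raise ValueError("detector saturated: od_raw >= a_sat")
        out = self.k * od / (self.a_sat - od)
        return float(out) if np.ndim(od_raw) == 0 else out

    def saturate(self, od_true):
        """True OD -> measured OD (forward detector transform)."""
        od = np.asarray(od_true, dtype=float)
        if np.any(od < 0):
            raise ValueError("od_true must be non-negative")
        out = self.a_sat * od / (self.k + od)
        return float(out) if np.ndim(od_true) == 0 else out
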