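"""Peptide-signal interdependent communities.

Each member strain carries an essential gene under receptor control, so its
growth requires a peptide secreted by another member.  In an interdependent
ring of N strains the secretion edges form a single directed cycle: strain i
secretes the peptide required by its neighbor, and dropping any one member
starves the cycle and collapses the community.

The simulator is a minimal mechanistic model for structural prediction
(persist vs collapse), not quantitative trajectory fitting: logistic growth
gated by a Hill function of the required peptide, constitutive secretion
proportional to cell density, and batch dilution events that reset cells and
peptide pools by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .doseresponse import DoseResponse, DoseResponseResults

__all__ = [
    "DependentStrain",
    "CommunityModel",
    "CommunityValidation",
    "CommunityTrajectory",
    "validate_interdependence",
    "fit_growth_ec50",
    "simulate_community",
]


@dataclass(frozen=True)
class DependentStrain:
    """A strain whose growth requires an externally supplied peptide.

    ``growth_ec50`` (nM) and ``growth_hill`` shape the Hill gate on growth;
    ``max_growth_rate`` is per hour; ``secretion_gain`` is nM peptide per OD
    per hour from the constitutive secretion cassette; ``leak`` is the
    peptide-free basal growth rate fraction (default 0 = strict dependence).
    """

    id: str
    receptor: str
    required_peptide: str
    secreted_peptide: str
    growth_ec50: float = 1.0
    growth_hill: float = 2.0
    max_growth_rate: float = 0.45
    secretion_gain: float = 50.0
    leak: float = 0.0

    def __post_init__(self) -> None:
        if self.growth_ec50 <= 0:
            raise ValueError("growth_ec50 must be positive")
        if not 0 <= self.leak < 1:
            raise ValueError("leak must be in [0, 1)")

    def growth_fraction(self, peptide_conc: float) -> float:
        """Hill gate in [0, 1] on the growth rate."""
        p = max(float(peptide_conc), 0.0)
        h, e = self.growth_hill, self.growth_ec50
        gate = p**h / (p**h + e**h) if p > 0 else 0.0
        return self.leak + (1.0 - self.leak) * gate


@dataclass
class CommunityModel:
    """Interdependent strain community with a batch dilution schedule.

    ``dilution_schedule`` lists (time h, dilution factor) events; a factor of
    0.05 means a 1:20 transfer.  ``carrying_capacity`` caps total density
    (logistic crowding), as batch cultures saturate near OD 1.
    """

    strains: list
    dilution_schedule: list = field(default_factory=list)
    seed_densities: dict = field(default_factory=dict)
    carrying_capacity: float = 1.0
    extinction_od: float = 1e-4

    def __post_init__(self) -> None:
        ids = [s.id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate strain ids")
        for t, f in self.dilution_schedule:
            if not 0 < f <= 1:
                raise ValueError("dilution factors must be in (0, 1]")


@dataclass
class CommunityValidation:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_interdependence(c: CommunityModel) -> CommunityValidation:
    """Check the dependency structure of a community.

    Every required peptide must be secreted by exactly one other member; a
    strain secreting its own required peptide is a self-feeding violation; and
    the secretion digraph must form a single Hamiltonian cycle (ring
    interdependence).
    """
    violations: list[tuple[str, str]] = []
    secretors: dict[str, list[str]] = {}
    for s in c.strains:
        secretors.setdefault(s.secreted_peptide, []).append(s.id)

    successor: dict[str, str] = {}
    for s in c.strains:
        if s.required_peptide == s.secreted_peptide:
            violations.append(("self-feeding", f"strain {s.id} secretes its own required peptide"))
            continue
        sources = [sid for sid in secretors.get(s.required_peptide, []) if sid != s.id]
        if not sources:
            violations.append(
                ("missing-source", f"required peptide {s.required_peptide} of {s.id} is not secreted by any other member")
            )
        elif len(sources) > 1:
            violations.append(
                ("multiple-sources", f"peptide {s.required_peptide} secreted by several members: {sources}")
            )
        else:
            successor[sources[0]] = s.id  # producer feeds s

    n = len(c.strains)
    if not violations:
        # walk the cycle from the first strain
        start = c.strains[0].id
        seen = [start]
        cur = start
        while cur in successor and successor[cur] not in seen:
            cur = successor[cur]
            seen.append(cur)
        closed = successor.get(cur) == start
        if not (closed and len(seen) == n):
            violations.append(("broken-cycle", "secretion edges do not form a single Hamiltonian cycle"))
    return CommunityValidation(violations)


def fit_growth_ec50(doses, densities) -> DoseResponseResults:
    """4PL fit of endpoint culture density against peptide dose.

    Same machinery as the fluorescence dose-response fit: zero-peptide wells
    anchor the no-growth baseline and the fit is on the log10-dose axis.
    """
    return DoseResponse(doses, densities).fit(min_distinct_doses=5)


@dataclass
class CommunityTrajectory:
    """Simulated density and peptide time courses."""

    times: np.ndarray
    densities: pd.DataFrame  # columns = strain ids
    peptides: pd.DataFrame  # columns = peptide ids
    extinct: dict  # strain id -> bool (below extinction threshold at t_end)
    collapsed: bool  # any member extinct at t_end

    def persisted(self) -> bool:
        return not self.collapsed


def simulate_community(
    c: CommunityModel,
    t_end: float,
    dropout: str | None = None,
    dt: float = 0.05,
) -> CommunityTrajectory:
    """Deterministic discrete-time simulation of an interdependent community.

    Per step: each strain grows at ``max_growth_rate x Hill(required peptide)``
    scaled by logistic crowding; peptide pools gain ``secretion_gain x
    density x dt`` from their constitutive producer and are reset (multiplied)
    by the factor of each dilution event, as is every strain density.
    """
    strains = [s for s in c.strains if s.id != dropout]
    if dropout is not None and len(strains) == len(c.strains):
        raise KeyError(f"unknown dropout strain {dropout!r}")
    peptide_ids = sorted({s.secreted_peptide for s in strains} | {s.required_peptide for s in strains})

    dens = {s.id: float(c.seed_densities.get(s.id, 0.02)) for s in strains}
    peps = {p: 0.0 for p in peptide_ids}

    events = sorted(c.dilution_schedule)
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt

    dens_hist = {s.id: [dens[s.id]] for s in strains}
    peps_hist = {p: [0.0] for p in peptide_ids}

    next_event = 0
    for step in range(1, n_steps + 1):
        t = step * dt
        total = sum(dens.values())
        crowding = max(0.0, 1.0 - total / c.carrying_capacity)
        new_dens = {}
        for s in strains:
            rate = s.max_growth_rate * s.growth_fraction(peps[s.required_peptide]) * crowding
            new_dens[s.id] = dens[s.id] * (1.0 + rate * dt)
        for s in strains:
            peps[s.secreted_peptide] += s.secretion_gain * dens[s.id] * dt
        dens = new_dens
        # apply any dilution events that have come due
        while next_event < len(events) and events[next_event][0] <= t + 1e-12:
            factor = events[next_event][1]
            dens = {k: v * factor for k, v in dens.items()}
            peps = {k: v * factor for k, v in peps.items()}
            next_event += 1
        for k in dens_hist:
            dens_hist[k].append(dens[k])
        for k in peps_hist:
            peps_hist[k].append(peps[k])

    densities = pd.DataFrame(dens_hist, index=times)
    peptides = pd.DataFrame(peps_hist, index=times)
    extinct = {sid: bool(densities[sid].iloc[-1] < c.extinction_od) for sid in dens_hist}
    return CommunityTrajectory(
        times=times,
        densities=densities,
        peptides=peptides,
        extinct=extinct,
        collapsed=any(extinct.values()),
    )
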