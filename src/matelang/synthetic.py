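"""Synthetic ground-truth generators for every pipeline input.

Stands in for genome databases and plate-reader output: pre-pro pheromone
precursors with configurable repeat architecture, plate measurements drawn
from known 4PL curves and passed through a saturating detector, activation
matrices with planted orthogonal channel subsets, and interdependent ring
communities.  Every generator takes an explicit seed and carries its ground
truth alongside the artifact, so downstream inference can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curves import DetectorModel, FourPL
from .interdependence import CommunityModel, DependentStrain
from .mining import CANONICAL_RESIDUES, PeptideCandidate, validate_protein

__all__ = [
    "PrecursorSpec",
    "PrecursorResult",
    "PlateSimConfig",
    "MatrixSimConfig",
    "MatrixResult",
    "generate_precursor",
    "generate_plate_data",
    "generate_crosstalk_matrix",
    "generate_community",
    "write_precursor_fasta",
]

# pre/pro filler alphabets: the pre region is hydrophobic-rich (inference only
# reads architecture, never pre content); the pro region is polar filler.
_PRE_ALPHABET = "LIVFAMWS"
_PRO_ALPHABET = "STNQGPDH"


@dataclass(frozen=True)
class PrecursorSpec:
    """Architecture of a synthetic pre-pro pheromone precursor."""

    peptide_seq: str
    n_repeats: int = 3
    pre_len: int = 19
    pro_len: int = 40
    kex2_motif: str = "KR"
    ste13_repeats: tuple = ("EA", "EA")
    seed: int = 0

    def __post_init__(self) -> None:
        validate_protein(self.peptide_seq, name="peptide_seq")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if len(self.kex2_motif) != 2:
            raise ValueError("kex2_motif must be a dipeptide")
        for r in self.ste13_repeats:
            if len(r) != 2:
                raise ValueError("ste13 spacers must be dipeptides")

    @property
    def block(self) -> str:
        """One repeat block: Kex2 motif + Ste13 spacers + mature peptide."""
        return self.kex2_motif + "".join(self.ste13_repeats) + self.peptide_seq

    @property
    def expected_length(self) -> int:
        return self.pre_len + self.pro_len + self.n_repeats * len(self.block)


class PrecursorResult(NamedTuple):
    sequence: str
    truth: PeptideCandidate
    warnings: list


def _random_protein(rng: np.random.Generator, alphabet: str, length: int, forbid: str) -> str:
    """Random filler avoiding accidental occurrences of ``forbid`` dipeptides."""
    letters = list(alphabet)
    out: list[str] = []
    while len(out) < length:
        aa = letters[rng.integers(len(letters))]
        if out and (out[-1] + aa) == forbid:
            continue
        out.append(aa)
    return "".join(out)


def generate_precursor(spec: PrecursorSpec) -> PrecursorResult:
    """Assemble a precursor: pre + pro + n_repeats x (Kex2 + Ste13 run + peptide).

    The ground truth records the mature peptide and the 1-based coordinates of
    each repeat.  If the peptide itself contains the Kex2 motif a warning flag
    is attached, since inference will split such a repeat.
    """
    rng = np.random.default_rng(spec.seed)
    pre = _random_protein(rng, _PRE_ALPHABET, spec.pre_len, spec.kex2_motif)
    pro = _random_protein(rng, _PRO_ALPHABET, spec.pro_len, spec.kex2_motif)
    blocks = spec.block * spec.n_repeats
    sequence = pre + pro + blocks

    spacer = len(spec.kex2_motif) + 2 * len(spec.ste13_repeats)
    spans = []
    offset = spec.pre_len + spec.pro_len
    for i in range(spec.n_repeats):
        start0 = offset + i * len(spec.block) + spacer
        spans.append((start0 + 1, start0 + len(spec.peptide_seq)))

    warns = []
    if spec.kex2_motif in spec.peptide_seq:
        warns.append(
            f"peptide contains internal Kex2 motif {spec.kex2_motif!r}: inference may split the repeat"
        )
    truth = PeptideCandidate(
        sequence=spec.peptide_seq,
        rank=1,
        support=spec.n_repeats,
        spans=tuple(spans),
        boundary_ambiguous=False,
        n_terminal_extension=0,
    )
    assert len(sequence) == spec.expected_length
    return PrecursorResult(sequence, truth, warns)


def write_precursor_fasta(results: Sequence[PrecursorResult], path, truth_path=None) -> None:
    """Write precursors as protein FASTA, optionally with a JSON truth sidecar."""
    records = [
        SeqRecord(Seq(r.sequence), id=f"precursor_{i}", description="synthetic pre-pro pheromone")
        for i, r in enumerate(results)
    ]
    SeqIO.write(records, path, "fasta")
    if truth_path is not None:
        doc = [
            {
                "id": f"precursor_{i}",
                "peptide": r.truth.sequence,
                "support": r.truth.support,
                "spans": list(map(list, r.truth.spans)),
                "warnings": r.warnings,
            }
            for i, r in enumerate(results)
        ]
        with open(truth_path, "w") as fh:
            json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------------------
# Plate data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateSimConfig:
    """Generative twin of the plate assay.

    Raw fluorescence is the 4PL response at each dose times the true OD with
    multiplicative Gaussian noise (CV scales with signal, floored at 0); raw
    OD is the detector-saturated image of the true OD.
    """

    true_params: FourPL
    detector: DetectorModel = DetectorModel(a_sat=2.0, k=1.0)
    noise_cv: float = 0.0
    n_replicates: int = 3
    dose_ladder: tuple = ()
    true_od: float = 1.0
    receptor_id: str = "R1"
    ligand_id: str = "L1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(d < 0 for d in self.dose_ladder):
            raise ValueError("doses must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")


def generate_plate_data(cfg: PlateSimConfig) -> pd.DataFrame:
    """Long-format measurement table (water controls carry dose 0).

    Columns: receptor, ligand, dose_nM, replicate, od_raw, fluor_raw.
    Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    doses = list(cfg.dose_ladder)
    if 0.0 not in doses:
        doses = doses + [0.0]
    rows = []
    od_raw = cfg.detector.saturate(cfg.true_od)
    for d in doses:
        mean = cfg.true_params.response(d) * cfg.true_od
        for rep in range(1, cfg.n_replicates + 1):
            eps = rng.normal(0.0, cfg.noise_cv) if cfg.noise_cv > 0 else 0.0
            rows.append(
                {
                    "receptor": cfg.receptor_id,
                    "ligand": cfg.ligand_id,
                    "dose_nM": d,
                    "replicate": rep,
                    "od_raw": od_raw,
                    "fluor_raw": max(mean * (1.0 + eps), 0.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Crosstalk matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixSimConfig:
    """Activation matrix with a planted fully orthogonal channel subset.

    Cross-activation values fall in ``crosstalk_range`` (percent), matching
    the 16-100% band typical of real cross-activations; the sub-threshold
    background is uniform below the 15% call threshold.
    """

    n_pairs: int = 12
    planted_orthogonal: int = 7
    crosstalk_density: float = 0.2
    crosstalk_range: tuple = (16.0, 100.0)
    background_max: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_orthogonal > self.n_pairs:
            raise ValueError("planted_orthogonal cannot exceed n_pairs")
        if not 0 <= self.crosstalk_density <= 1:
            raise ValueError("crosstalk_density must be a fraction")
        lo, hi = self.crosstalk_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("crosstalk_range must lie within [0, 100]")


class MatrixResult(NamedTuple):
    matrix: "object"  # ActivationMatrix (forward ref; avoids circular import at type time)
    planted: list  # indices of the planted orthogonal subset


def generate_crosstalk_matrix(cfg: MatrixSimConfig) -> MatrixResult:
    """Receptor x ligand percent-activation matrix with known ground truth.

    Cognate diagonal is 100%.  Rows of the planted subset get only
    sub-threshold background off the diagonal; remaining off-diagonal cells
    become cross-activations (drawn from ``crosstalk_range``) with probability
    ``crosstalk_density``, sub-threshold background otherwise.
    """
    from .orthogonality import ActivationMatrix  # local import avoids a cycle

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    planted = sorted(rng.choice(n, size=cfg.planted_orthogonal, replace=False).tolist())
    planted_set = set(planted)

    values = rng.uniform(0.0, cfg.background_max, size=(n, n))
    values = np.nextafter(values, -np.inf)  # keep background strictly below the bound
    lo, hi = cfg.crosstalk_range
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if i in planted_set:
                continue  # planted rows stay clean
            if rng.random() < cfg.crosstalk_density:
                values[i, j] = rng.uniform(lo, hi)
    np.fill_diagonal(values, 100.0)
    ids = [f"pair_{i:02d}" for i in range(n)]
    return MatrixResult(ActivationMatrix(ids, values, test_dose=10_000.0), planted)


# ---------------------------------------------------------------------------
# Interdependent communities
# ---------------------------------------------------------------------------

def generate_community(
    n_members: int = 3,
    growth_ec50: float = 1.0,
    growth_hill: float = 2.0,
    max_growth_rate: float = 0.45,
    secretion_gain: float = 50.0,
    leak: float = 0.0,
    seed_density: float = 0.02,
    dilution_factor: float = 0.05,
    dilution_interval: float = 12.0,
    n_dilutions: int = 10,
) -> CommunityModel:
    """A ring-interdependent community: strain i secretes the peptide required
    by strain i+1 (mod n), seeded equally, with periodic batch dilutions.

    Defaults mirror the study conditions: low-nanomolar growth EC50, yeast-like
    maximal growth rate (~1.5 h doubling), 1:20 dilutions every 12 h, and seed
    density 0.02 OD per member.
    """
    if n_members < 2:
        raise ValueError("interdependence needs >= 2 members")
    strains = []
    for i in range(n_members):
        nxt = (i + 1) % n_members
        strains.append(
            DependentStrain(
                id=f"c{i + 1}",
                receptor=f"g{i + 1}",
                required_peptide=f"p{i + 1}",
                secreted_peptide=f"p{nxt + 1}",
                growth_ec50=growth_ec50,
                growth_hill=growth_hill,
                max_growth_rate=max_growth_rate,
                secretion_gain=secretion_gain,
                leak=leak,
            )
        )
    schedule = [
        (dilution_interval * (k + 1), dilution_factor) for k in range(n_dilutions)
    ]
    return CommunityModel(
        strains=strains,
        dilution_schedule=schedule,
        seed_densities={s.id: seed_density for s in strains},
    )
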