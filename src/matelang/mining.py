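"""Genome mining of mating peptide-GPCR components.

Receptor catalog curation, pairwise sequence identity, intracellular-loop motif
scoring, and inference of mature peptide pheromones from pre-pro precursor
sequences.

Precursor model
---------------
Alpha-factor-like pheromone precursors carry an N-terminal secretion (pre)
region and a pro region, followed by repeats of the mature peptide.  Each
repeat is introduced by a dibasic Kex2 protease site (canonically ``KR``)
and an optional run of Ste13 dipeptides (``EA``-type spacers).  Maturation is
modeled as: cleavage C-terminal of every Kex2 motif, carboxypeptidase-style
trimming of a terminal Kex2 motif left on a segment, then removal of the
leading Ste13 dipeptide run.  All residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

__all__ = [
    "CANONICAL_RESIDUES",
    "ReceptorRecord",
    "PrecursorRecord",
    "ProcessingSite",
    "PeptideCandidate",
    "MiningConfig",
    "MotifMatch",
    "InferenceWarning",
    "filter_receptor_catalog",
    "percent_identity",
    "score_loop_motifs",
    "detect_processing_sites",
    "infer_mature_peptides",
    "enumerate_ligand_variants",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InferenceWarning(UserWarning):
    """Raised (as a warning) when peptide inference hits a degenerate input."""


def validate_protein(seq: str, *, name: str = "sequence") -> None:
    """Reject empty sequences or non-canonical residues (reports 1-based position)."""
    if not seq:
        raise ValueError(f"{name} is empty")
    for i, aa in enumerate(seq, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(f"{name} has non-canonical residue {aa!r} at position {i}")


@dataclass(frozen=True)
class ReceptorRecord:
    """A candidate Ste2-like GPCR with its annotation."""

    id: str
    species: str
    sequence: str
    family_tags: frozenset = frozenset()
    lineage: tuple = ()
    is_fragment: bool = False

    def __post_init__(self) -> None:
        validate_protein(self.sequence, name=f"receptor {self.id}")


@dataclass(frozen=True)
class PrecursorRecord:
    """A pheromone pre-pro precursor protein."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        validate_protein(self.sequence, name=f"precursor {self.id}")


@dataclass(frozen=True)
class ProcessingSite:
    """A protease recognition site; ``position`` is the 1-based index of the
    LAST residue of the motif."""

    kind: str  # "kex2" | "ste13"
    position: int
    motif: str


@dataclass(frozen=True)
class PeptideCandidate:
    """A mature-peptide candidate inferred from a precursor.

    ``support`` counts identical repeats; ``spans`` are 1-based inclusive
    coordinates of each occurrence; ``n_terminal_extension`` is the number of
    residues this candidate adds upstream of the rank-1 candidate (0 if it is
    not an N-terminal extension of it).
    """

    sequence: str
    rank: int
    support: int
    spans: tuple
    boundary_ambiguous: bool = False
    n_terminal_extension: int = 0


@dataclass(frozen=True)
class MiningConfig:
    kex2_motifs: frozenset = frozenset({"KR"})
    ste13_dialect: frozenset = frozenset({"EA", "DA", "AA"})
    length_range: tuple = (9, 14)
    max_alternates: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo <= 0 or lo > hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        for m in self.kex2_motifs | self.ste13_dialect:
            if len(m) != 2:
                raise ValueError(f"motifs must be dipeptides, got {m!r}")


# ---------------------------------------------------------------------------
# Receptor catalog curation
# ---------------------------------------------------------------------------

def filter_receptor_catalog(
    records: Sequence[ReceptorRecord],
    kingdom: str = "Fungi",
    min_len: int = 200,
    max_len: int = 600,
) -> tuple[list[ReceptorRecord], list[tuple[str, str]]]:
    """Keep full-length receptors from the requested kingdom.

    Returns ``(kept, exclusion_log)`` where the log holds one
    ``(record id, reason)`` entry per dropped record.  Input order is
    preserved; records without taxonomy are dropped with reason
    ``"no taxonomy"``.
    """
    kept: list[ReceptorRecord] = []
    log: list[tuple[str, str]] = []
    for rec in records:
        if not rec.lineage:
            log.append((rec.id, "no taxonomy"))
        elif kingdom not in rec.lineage:
            log.append((rec.id, f"not {kingdom}"))
        elif rec.is_fragment:
            log.append((rec.id, "fragment"))
        elif not (min_len <= len(rec.sequence) <= max_len):
            log.append((rec.id, "length out of range"))
        else:
            kept.append(rec)
    return kept, log


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

def percent_identity(
    a: str,
    b: str,
    gap_open: float = 2.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent identity from an end-to-end (global) pairwise alignment.

    Identity = identical columns / total alignment columns x 100, gaps
    counting as columns.  Scoring is match +1 / mismatch -1 with affine gap
    penalties ``-(gap_open)`` to open and ``-(gap_extend)`` to extend.
    """
    validate_protein(a, name="sequence a")
    validate_protein(b, name="sequence b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return 100.0 * matches / len(s1)


# ---------------------------------------------------------------------------
# Intracellular loop motif scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    score: float
    position: int  # 1-based start of the best window; 0 if sequence shorter than motif


def _column_weight(column, residue: str) -> float:
    if isinstance(column, str):
        return 1.0 if (column == "X" or column == residue) else 0.0
    if isinstance(column, Mapping):
        return float(column.get(residue, 0.0))
    # a set/sequence of allowed residues
    return 1.0 if residue in column else 0.0


def score_loop_motifs(
    receptor: ReceptorRecord,
    motif_set: Mapping[str, Sequence],
) -> list[MotifMatch]:
    """Score position-weight motif patterns against a receptor sequence.

    Each motif is a sequence of columns; a column is a residue character
    ('X' = wildcard), a set of allowed residues, or a residue->weight mapping.
    The window score is the mean column weight; the best window per motif is
    reported.  This is report-only: no filtering is applied.
    """
    seq = receptor.sequence
    out: list[MotifMatch] = []
    for motif_id, columns in motif_set.items():
        w = len(columns)
        if w == 0 or w > len(seq):
            out.append(MotifMatch(motif_id, 0.0, 0))
            continue
        best_score, best_pos = -1.0, 1
        for start in range(len(seq) - w + 1):
            score = sum(
                _column_weight(col, seq[start + j]) for j, col in enumerate(columns)
            ) / w
            if score > best_score:
                best_score, best_pos = score, start + 1
        out.append(MotifMatch(motif_id, best_score, best_pos))
    return out


# ---------------------------------------------------------------------------
# Processing-site detection and peptide inference
# ---------------------------------------------------------------------------

def detect_processing_sites(
    precursor: PrecursorRecord, cfg: MiningConfig | None = None
) -> list[ProcessingSite]:
    """Locate Kex2 and Ste13 processing sites.

    All Kex2 motif occurrences are reported.  A Ste13 site is reported as the
    maximal run of dialect dipeptides immediately following a Kex2 site (one
    site per run, covering the whole run), never as separate dipeptides.
    """
    cfg = cfg or MiningConfig()
    seq = precursor.sequence
    sites: list[ProcessingSite] = []
    kex2_ends: list[int] = []  # 0-based index of last motif residue
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        if di in cfg.kex2_motifs:
            sites.append(ProcessingSite("kex2", i + 2, di))
            kex2_ends.append(i + 1)
    for end in kex2_ends:
        run_start = end + 1
        j = run_start
        while seq[j : j + 2] in cfg.ste13_dialect:
            j += 2
        if j > run_start:
            sites.append(ProcessingSite("ste13", j, seq[run_start:j]))
    sites.sort(key=lambda s: (s.position, s.kind))
    return sites


def _segments_after_kex2(seq: str, cfg: MiningConfig):
    """Split after each Kex2 motif. Yields (start0, fragment) for every segment
    following a Kex2 site; the leading pre+pro segment is not yielded."""
    ends = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i : i + 2] in cfg.kex2_motifs
    ]
    for n, e in enumerate(ends):
        start = e + 1
        stop = ends[n + 1] + 1 if n + 1 < len(ends) else len(seq)
        if start < stop:
            yield start, seq[start:stop]


def _strip_ste13_run(fragment: str, cfg: MiningConfig) -> tuple[str, int]:
    """Remove the leading run of Ste13 dialect dipeptides; returns
    (core, run length in dipeptides)."""
    run = 0
    while fragment[2 * run : 2 * run + 2] in cfg.ste13_dialect:
        run += 1
    return fragment[2 * run :], run


def infer_mature_peptides(
    precursor: PrecursorRecord, cfg: MiningConfig | None = None
) -> list[PeptideCandidate]:
    """Infer ranked mature-peptide candidates from a precursor.

    The precursor is segmented at Kex2 sites (cleavage after the motif; a
    terminal Kex2 motif left on a segment is trimmed).  Each segment is
    stripped of its leading Ste13 run to give the core candidate; identical
    cores pool their support.  Segments whose Ste13 run is absent, or shorter
    than the longest run seen in the precursor, additionally emit the
    unstripped segment flagged ``boundary_ambiguous``.  Candidates outside
    ``cfg.length_range`` are dropped.  Ranking is by support (descending),
    ties broken by earliest first span.
    """
    cfg = cfg or MiningConfig()
    seq = precursor.sequence

    raw_segments = list(_segments_after_kex2(seq, cfg))
    if not raw_segments:
        warnings.warn(
            f"no Kex2 site found in precursor {precursor.id}; nothing to infer",
            InferenceWarning,
            stacklevel=2,
        )
        return []

    # trim a trailing Kex2 motif (it signals the next cleavage, and is removed
    # from the mature peptide by carboxypeptidase trimming)
    segments = []
    for start0, frag in raw_segments:
        if frag[-2:] in cfg.kex2_motifs:
            frag = frag[:-2]
        if frag:
            segments.append((start0, frag))

    stripped = [(s, *_strip_ste13_run(f, cfg)) for s, f in segments]
    ref_run = max((r for _, _, r in stripped), default=0)

    # pool candidates: sequence -> [spans, ambiguous]
    pool: dict[str, list] = {}

    def _add(seq_start0: int, cand: str, ambiguous: bool) -> None:
        span = (seq_start0 + 1, seq_start0 + len(cand))  # 1-based inclusive
        entry = pool.setdefault(cand, [[], False])
        entry[0].append(span)
        entry[1] = entry[1] or ambiguous

    for (frag_start0, frag), (_, core, run) in zip(segments, stripped):
        if not core:
            continue
        # the stripped core is only ambiguous when no segment shows a Ste13 run
        _add(frag_start0 + 2 * run, core, ref_run == 0)
        if 0 < run < ref_run or (run == 0 < ref_run and frag != core):
            _add(frag_start0, frag, True)

    lo, hi = cfg.length_range
    items = [
        (cand, spans, amb)
        for cand, (spans, amb) in pool.items()
        if lo <= len(cand) <= hi
    ]
    items.sort(key=lambda it: (-len(it[1]), min(s for s, _ in it[1])))

    candidates: list[PeptideCandidate] = []
    top_seq = items[0][0] if items else ""
    for rank, (cand, spans, amb) in enumerate(items, start=1):
        ext = 0
        if rank > 1 and cand.endswith(top_seq) and len(cand) > len(top_seq):
            ext = len(cand) - len(top_seq)
        candidates.append(
            PeptideCandidate(
                sequence=cand,
                rank=rank,
                support=len(spans),
                spans=tuple(sorted(spans)),
                boundary_ambiguous=amb,
                n_terminal_extension=ext,
            )
        )
    return candidates


def enumerate_ligand_variants(
    candidate: PeptideCandidate,
    mode: str,
    precursor: PrecursorRecord | None = None,
    max_alternates: int = 3,
) -> list[str]:
    """Generate ligand variants for receptor-response tuning.

    ``n_extension`` prepends 1..max_alternates residues found immediately
    upstream of the candidate's first span in the precursor (truncated with a
    warning if the precursor start is reached).  ``alanine_scan`` substitutes
    A at every non-alanine position, one variant per position, N- to
    C-terminal order.
    """
    if mode == "alanine_scan":
        return [
            candidate.sequence[:i] + "A" + candidate.sequence[i + 1 :]
            for i, aa in enumerate(candidate.sequence)
            if aa != "A"
        ]
    if mode == "n_extension":
        if precursor is None:
            raise ValueError("n_extension mode requires the precursor context")
        start0 = candidate.spans[0][0] - 1
        variants = []
        for k in range(1, max_alternates + 1):
            if start0 - k < 0:
                warnings.warn(
                    "extension reaches beyond precursor start; variant set truncated",
                    InferenceWarning,
                    stacklevel=2,
                )
                break
            variants.append(precursor.sequence[start0 - k : start0] + candidate.sequence)
        return variants
    raise ValueError(f"unknown variant mode {mode!r}")
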