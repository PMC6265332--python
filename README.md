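# matelang

A toolkit for building intercellular signaling languages from fungal mating
peptide–GPCR pairs. Ascomycete fungi mate using secreted peptide pheromones
(9–14 residues, typified by the 13-mer *S. cerevisiae* α-factor) sensed by
Ste2-like G-protein-coupled receptors. Because both the peptide and the
receptor are genetically encoded, and peptide precursors share a conserved
pre-pro architecture, large numbers of naturally orthogonal peptide–receptor
pairs can be mined from genomes and reassembled into synthetic cell–cell
communication channels in yeast. `matelang` implements the computational
backbone of that workflow for synthetic biologists:

1. **Genome mining** (`matelang.mining`) — curate receptor candidates,
   compute percent identity by global alignment, and infer mature peptides
   from pre-pro precursors: the precursor is cleaved after every dibasic Kex2
   motif (`KR`), a terminal motif is trimmed, and the leading run of Ste13
   dipeptides (`EA`/`DA`/`AA`) is stripped from each repeat; identical repeats
   pool their support. Ambiguous boundaries yield near-cognate alternates;
   alanine scans and N-terminal extensions enumerate ligand variants.
2. **Dose-response** (`matelang.doseresponse`) — correct plate-reader OD for
   photodetector saturation, `A_true = k·A_meas/(A_sat − A_meas)`, normalize
   fluorescence per OD, and fit the four-parameter logistic

   `f(d) = basal + (maximal − basal) / (1 + (EC50/d)^h)`

   on the log10-dose axis, with water controls anchoring the basal level.
   Receptors are classified functional / non-functional (signal difference
   < 3 pooled SD) / constitutive (basal > 3× cohort median).
3. **Orthogonality** (`matelang.orthogonality`) — normalize receptor × ligand
   activation matrices (row maximum → 100%), call crosstalk at ≥ 15%
   activation, and select the **maximum** set of mutually orthogonal channels
   by exact branch-and-bound over the conflict graph, with an independently
   verified certificate.
4. **Communication** (`matelang.communication`) — enumerate all n(n−1)
   two-cell links over a channel set, compose sender/receiver 4PL transfer
   functions through a secretion gain, and validate/simulate ring, bus, and
   tree topologies (OR-gate nodes express two receptors) to steady state,
   including single-node dropout controls.
5. **Interdependence** (`matelang.interdependence`) — validate communities in
   which each strain's growth requires a peptide secreted by another member
   (essential gene under receptor control), fit growth EC50s, and simulate
   persistence vs collapse under batch dilution.
6. **Synthetic data** (`matelang.synthetic`) — generate every input with
   known ground truth: precursors with configurable repeat architecture,
   plate measurements from 4PL curves through the saturating detector,
   activation matrices with planted orthogonal subsets, and ring-dependent
   communities.

## Worked example

```python
from matelang import *
from matelang.synthetic import (PrecursorSpec, generate_precursor,
                                PlateSimConfig, generate_plate_data,
                                MatrixSimConfig, generate_crosstalk_matrix)

# infer the mature pheromone from a 4-repeat precursor
seq, truth, _ = generate_precursor(
    PrecursorSpec(peptide_seq="WHWLQLKPGQPMY", n_repeats=4, seed=7))
cand = infer_mature_peptides(PrecursorRecord("Xy.MFalpha", "X. yeastii", seq))[0]
print(f"top candidate: {cand.sequence}  support={cand.support}")

# fit a noisy dose-response plate (11 fivefold dilutions from 40 uM)
det = DetectorModel(a_sat=2.0, k=1.0)
cfg = PlateSimConfig(true_params=FourPL(120.0, 1600.0, 1.25, 1.0), detector=det,
                     noise_cv=0.05, seed=1,
                     dose_ladder=tuple(d for d in make_dose_ladder(40000, 5, 11) if d > 0))
res = DoseResponse.from_dataframe(normalize(generate_plate_data(cfg), det)).fit()
print(res.summary())

# select the largest orthogonal channel set from a 12x12 activation matrix
m, planted = generate_crosstalk_matrix(MatrixSimConfig(n_pairs=12, planted_orthogonal=7, seed=1))
chosen = select_orthogonal_channels(classify_crosstalk(m, threshold=15.0))
print(f"selected {chosen.size} channels (certificate={chosen.certificate})")
print("links from 8 channels:", len(enumerate_links([f"pair{i}" for i in range(8)])))
```

prints

```
top candidate: WHWLQLKPGQPMY  support=4
4PL dose-response fit
==========================================
basal:         126.705 afu/OD (water-anchored)
maximal:       1610.73 afu/OD
EC50:          1.31017 nM
Hill:          0.975374
fold change:   12.9426
residual norm: 206.172
converged:     True
selected 8 channels (certificate=True)
links from 8 channels: 56
```

The inferred candidate is exactly the peptide planted in the precursor, with
support 4 (one per repeat). The fit recovers the generating parameters
(basal 120, maximal 1600, EC50 1.25 nM, Hill 1.0) within the 5% measurement
noise. Channel selection returns a certified orthogonal set at least as large
as the planted one, and 8 channels support 8×7 = 56 directed two-cell links.

A thin CLI wraps the same functions: `matelang synth|mine|fit|ortho|net|community --help`.

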