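# Methods

## Scope and model

`capriq` implements the standard CAPRI protocol for judging a predicted
("model") protein assembly against an experimentally determined
("target") reference, plus the DockQ score that consolidates the same
measurements into one continuous number, plus the aggregation machinery
used in community rounds: assessment units (AUs) over grouped
interfaces and weighted group scores across targets.

The unit of evaluation is an *interface*: an interacting pair of chains
in the target. All higher-level scores are built from per-interface
measurements.

### Per-interface metrics

Let the *receptor* be the chain of the pair with more residues (ties
broken by lexicographic chain id — L_rms is asymmetric, so the
convention must be fixed; it is applied and reported consistently).
All distance computations use heavy atoms only; hydrogens are stripped
at parse time.

- **Native contacts**: residue pairs, one residue per chain, with any
  heavy-atom pair within the contact threshold (default 5 Å — the
  established community convention and the DockQ default; the threshold
  is configurable). **fnat** is the fraction of native contacts whose
  mapped residue pair is also in contact in the model. The denominator
  is always the target's contact count: contacts whose residues are
  unresolved in the model count as missed, so truncation cannot inflate
  recall.
- **L_rms**: the receptor backbone (N, CA, C, O) of the common residue
  set is superposed by least squares (Kabsch, proper rotations only);
  the RMSD of the model's ligand backbone under that transform — with
  no re-fit — is reported.
- **i_rms**: interface residues are defined on the *target only* (any
  heavy atom within 10 Å of the partner chain); the backbone atoms of
  those residues, on both chains, are superposed model↔target and the
  fit residual is i_rms. Defining the residue set on the target keeps
  the measure comparable across models; recomputing it per model is
  possible in principle but would make i_rms values incomparable, so it
  is not done.
- **S_rms**: side-chain heavy atoms of the interface residues evaluated
  under the i_rms backbone transform (no re-fit). Undefined — flagged,
  not an error — when the interface shares no side-chain atoms (e.g.
  all-glycine).
- **Clashes**: inter-chain heavy-atom pairs strictly below 3 Å. The
  disqualification rule is batch-relative (count > batch mean + 2 SD),
  since "too many" has no published absolute value; a configurable
  absolute cap serves single-model runs. Disqualified models are forced
  to the Incorrect category.

### Classification and DockQ

The four categories come from the canonical CAPRI threshold table
(inclusive boundaries):

| category   | fnat ≥ | and ( L_rms ≤ | or i_rms ≤ ) |
|------------|--------|---------------|--------------|
| High       | 0.5    | 1.0 Å         | 1.0 Å        |
| Medium     | 0.3    | 5.0 Å         | 2.0 Å        |
| Acceptable | 0.1    | 10.0 Å        | 4.0 Å        |

DockQ = (fnat + s(L_rms, d1) + s(i_rms, d2)) / 3 with
s(r, d) = 1/(1 + (r/d)²), d1 = 8.5 Å, d2 = 1.5 Å. The constants are
previously optimised values and are not refitted here. There is no
strict correspondence between DockQ and the categories; the package
flags models near the 0.23 incorrect cutoff diagnostically but never
lets DockQ alter a category.

### Assemblies, chain mapping, AUs

For multi-chain targets each chain pair with at least one native
contact is an interface. The model→target chain assignment is searched
over all bijections that respect sequence-equivalence classes
(exhaustively while the permutation count stays within a configurable
budget, default 8! = 40320; beyond that, identity-within-class plus
single transpositions — a greedy fallback adequate for the sizes this
package targets). The assignment maximising summed interface quality
(category first, DockQ as tie-break) is kept. Non-assessable interfaces
(no common residues, chains missing) score Incorrect with a flag rather
than raising, so one bad chain cannot void an assembly.

Symmetry-equivalent interfaces are grouped automatically by
chain-label-free contact fingerprints (Jaccard ≥ 0.7, compared in both
receptor/ligand orientations) within equivalence classes; curated AU
definitions for the split real targets ship as explicit YAML
configuration instead of being inferred. An AU scores

Score_AU = 1·n_ACC + 2·n_MED + 3·n_HIGH, normalised by the number K of
interface groups; its DockQ is the mean over groups of the best
per-group DockQ. Counting is *exclusive* — each group once, in its best
category. The alternative cumulative reading (one High model
incrementing all three counters) would break the Score_AU ≤ 3K bound
and disagree with the group-level score's per-target contribution, so
the exclusive reading is used. AUs may span several related targets
(the RuvB/RuvA family); the best member over all member targets
represents the AU.

### Group ranking

A group's best model per AU is chosen among its top-n ranked
submissions (n = 5 by default, n = 1 for the top-1 analysis): highest
category, then highest DockQ, then lowest submission rank. Score_G sums
the category weights (1/2/3) over AUs, with multi-interface AUs
contributing their normalised AU score. The ΣDockQ ranking instead sums
the best *DockQ* in the pool regardless of category — deliberately, so
that sub-cutoff models still contribute, which is the documented
contrast between the two rankings. Z-score ranking standardises scores
per AU across groups (missing submissions enter as 0 before
standardisation; zero-variance AUs contribute Z = 0 to avoid division
by zero and carry no ranking information), truncates negative Z to 0,
and ranks by per-group sums with lexicographic tie-break for
deterministic output. Standardising per AU and summing matches the
customary practice for this style of ranking; whether the standardised
quantity is DockQ or the CAPRI contribution is a caller choice, DockQ
by default.

## Structure I/O

Parsing and writing go through gemmi (PDB and mmCIF; chains identified
by author asym id). At parse time: hydrogens dropped, waters and
non-protein entities discarded, altloc duplicates collapsed to the
highest-occupancy conformer (ties by altloc letter), first model only.
Non-standard residues (MSE, SEP, …) map to their parent amino acid for
alignment purposes.

Residue correspondence uses global sequence alignment (Biopython's
PairwiseAligner; match +1, mismatch −1, gap open −2, extend −0.5, free
end gaps) rather than author numbering, because predicted models are
routinely renumbered. Only identically aligned residues pair — model
and target share the construct sequence, so a substitution indicates a
wrong chain mapping, and below 30% identity the mapping is rejected
outright. The batch mode intersects the per-model common sets so all
models of one target are measured on identical residues; per-model
sets are the default since a single-model call cannot know the batch.

## The synthetic generator

Toy chains are ideal α-helices (rise 1.5 Å/residue, twist 100°/residue,
CA radius 2.3 Å) with schematic backbone offsets and short side chains
cycling through six residue types (Gly, Ala, Ser, Val, Asp, Leu). Side
chains extend along a fixed per-chain direction pointing *away* from
the binding partner; the interface forms through the dense, regular
backbone envelope. This choice is deliberate: it makes contact counts
stable across symmetries (C2, C3, C6, asymmetric) at one default axis
separation (8 Å, giving ≥ 10 contacts per declared interface and a
clash-free reference) and gives every metric an analytic handle — a
pure ligand translation by t yields L_rms = |t| exactly, side-chain
jitter of σ per coordinate yields S_rms ≈ σ√3.

Decoys perturb the last chain (rigid rotation about its centroid, then
translation, then optional side-chain jitter and C-terminal
truncation). Expected metrics stored with each decoy are computed by
the module's own brute-force oracles — dense all-pairs contact
enumeration and a superposition routed through scipy's rotation
alignment — kept deliberately independent of the metrics module they
validate. The decoy ladder rejection-samples translation/rotation
magnitudes per intended category and discards any sample whose label
would flip under a ±5% relative perturbation of its metrics, keeping
truth labels stable against floating-point detail near thresholds.

What the generator does **not** emulate: real side-chain chemistry and
packing, loop flexibility, realistic contact-map topology, partial
interface formation, or the error characteristics of any actual
prediction method. Passing tests therefore demonstrate the correctness
of the measurement and aggregation machinery, not performance claims
about real predicted complexes.

The packaged metadata (37 targets in five categories; AU configurations
splitting T203 and T204 into two AUs each and grouping the
T219/T220/T221 family into AU219 — nine member interfaces in three
groups — and AU220) is a transcription, checksummed at load; size and
buried-surface-area columns are inert metadata, never recomputed.

## Numerical choices and problem sizes

- Kabsch via SVD with the determinant sign correction; reflections
  excluded; collinear point sets rejected (second singular value
  ≤ 1e-10 of the largest).
- Neighbour search uses scipy's cKDTree; exact at the query radius, so
  results are identical to all-pairs enumeration (asserted in tests).
- The clash rule is "strictly below 3 Å", implemented with a 1e-9
  radius back-off on the tree count.
- Default test and acceptance problem sizes — 20-residue chains, 200
  random decoys, ladders of 5 per category, 100 simulated manifests —
  were chosen to exercise every code path at comfortable desk scale
  while keeping metric values far from degenerate regimes.

## Known limitations

- The greedy chain-mapping fallback beyond the permutation budget is
  not guaranteed optimal for very large homo-oligomers (> 8 copies of
  one class).
- Interfaces are protein–protein only; nucleic acids, glycans and
  other ligands are discarded at parse time.
- The batch clash-disqualification rule needs a batch; single-model
  runs disqualify only via the configurable absolute cap.
- Alternative classification tables can be configured but the shipped
  table is the only one exercised by the test suite.
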