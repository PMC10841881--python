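# capriq

Quality assessment of predicted protein assemblies, the way the CAPRI
community evaluates blind-prediction rounds: per-interface metrics, the
four-category quality classification, the continuous DockQ score,
multi-interface assessment-unit (AU) aggregation, and predictor-group
ranking.

## Who this is for

Structural bioinformaticians who need to judge predicted models of
protein complexes against an experimental reference — whether for a
docking benchmark, for in-house model selection, or to reproduce the
mechanics of a community assessment. The package reads standard PDB and
mmCIF files, handles homo-oligomer chain-label ambiguity, and scales
from a single dimer to a batch of hexamer submissions.

## The measures

For an evaluated interface between a *receptor* chain and a *ligand*
chain (larger chain first, ties by chain id), against the reference
("target") structure:

- **fnat** — the fraction of the target's native residue–residue
  contacts (any heavy-atom pair < 5 Å) recalled by the model.
- **L_rms** — backbone RMSD of the ligand after least-squares (Kabsch)
  superposition of the receptor backbone over the common residue set.
- **i_rms** — backbone RMSD over the interface residues (any heavy atom
  within 10 Å of the partner chain, defined on the target), after
  superposing those residues themselves.
- **S_rms** — RMSD of interface side-chain heavy atoms under the i_rms
  backbone fit (reported, never used for classification).
- **clashes** — inter-chain heavy-atom pairs below 3 Å; models with
  excessive clash counts (relative to the batch) are disqualified.

Models are classified **High / Medium / Acceptable / Incorrect** from
(fnat, L_rms, i_rms) by the standard CAPRI threshold table, and scored
continuously by

    DockQ = ( fnat + 1/(1+(L_rms/d1)²) + 1/(1+(i_rms/d2)²) ) / 3

with d1 = 8.5 Å and d2 = 1.5 Å. For higher-order assemblies, interfaces
are enumerated per chain pair, symmetry-equivalent copies are grouped
(best replica represents the group), and an AU scores

    Score_AU = 1·n_ACC + 2·n_MED + 3·n_HIGH        (normalised by K groups)

with each group counted once in its best category. Groups of predictors
are ranked across targets/AUs by the analogous weighted score, by the
sum of per-AU best DockQ values, or by positive-truncated Z-scores.

Because the original submission corpus is not distributable, the
package carries a synthetic generator: ideal-helix toy complexes (C2,
C3, C6 or asymmetric), decoys with analytically known metrics (a pure
ligand translation by *t* has L_rms = |t| exactly), graded decoy
ladders per category, and simulated submission manifests.

## Worked example

```sh
$ capriq simulate --n-per-category 1 --out fixtures
wrote 4 decoys + truth.json to fixtures
$ capriq --output-dir out assess fixtures/decoy_001.pdb fixtures/target.pdb
target_id  interface_id  group  model_rank  fnat  lrms    irms    srms    clashes  n_common  category  dockq   disqualified
target     A:B           -      1           0.8   3.9112  1.2689  1.3783  0        40        Medium    0.7360  False
```

Reading the row: the decoy recalls 80% of the 15 native contacts, its
ligand sits 3.91 Å from the reference placement after the receptor fit,
and the interface deviates by 1.27 Å — a Medium-quality model by the
CAPRI table, DockQ 0.74. The same calls are available in Python:

```python
from capriq import (DecoySpec, make_decoy, build_correspondence,
                    native_contacts, compute_metrics, classify, dockq)

model, target, expected = make_decoy(DecoySpec(ligand_translation=(3, 0, 0)))
corr = build_correspondence(model, target, {"A": "A", "B": "B"})
iface = native_contacts(target, "A", "B")
m = compute_metrics(model, target, corr, iface)
print(expected.lrms)                 # 3.0 — exact for a pure translation
print(classify(m).category.name)     # Medium (fnat drops with the shift)
print(round(dockq(m.fnat, m.lrms, m.irms).value, 4))   # 0.7965
```

`capriq batch` evaluates a manifest of (group, target, rank, model
path) rows, and `capriq rank` turns the resulting metrics table into
ranked per-role TSVs plus a per-AU quality matrix.

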