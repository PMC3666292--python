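# sspipe — protein secondary-structure prediction from PSSM profiles and physicochemical features

`sspipe` predicts the three-state secondary structure (helix **H**, sheet
**E**, coil **C**) of a protein chain from its sequence, for structural
bioinformaticians who want a transparent, fully testable re-implementation of
the classic PSSM + SVM pipeline rather than a black-box server.

The method, end to end:

1. **Features.** Each residue *i* is encoded from a sliding window of
   WS residues (WS odd, 7–19) centred on it. The window contributes the
   WS normalized rows (20 values each) of the chain's position-specific
   scoring matrix (PSSM, the L×20 log-odds profile from an iterative
   homology search), and the central residue contributes six scalars: its
   conformation parameters S<sub>iH</sub>, S<sub>iE</sub>, S<sub>iC</sub>
   (the propensities S<sub>ij</sub> = a<sub>ij</sub>/a<sub>i</sub> estimated
   from the training set), its net charge, Kyte–Doolittle hydropathy and
   side-chain mass, each scaled to [0, 1]. The feature dimension is
   20·WS + 6 (266 at the default WS = 13).
2. **Classifier.** A one-vs-one SVM: three binary RBF-kernel machines
   (H/E, E/C, C/H) with max-wins voting, the conventional label mapping
   (H, E, C) → (−1, +1, +2), and deterministic tie-breaking. Cost C and
   kernel width γ are selected by exhaustive grid search over
   C ∈ {2⁰…2⁵} × γ ∈ {2⁻⁶…2⁻¹} per window size, scored by three-fold
   cross-validated Q3 with folds that partition whole chains.
3. **Filter.** A consensus rule pass exploiting run-length physics (a helix
   needs ≥ 3 contiguous residues, a sheet ≥ 2): an H without H on both
   sides, or an E without E on either side, is replaced by the majority
   state of the 7-residue segment around it; coil is never touched.
4. **Scoring.** Q3 (per-residue accuracy), per-class precision/recall with
   the pooled confusion matrix, and both segment-overlap scores SOV94 and
   SOV99, which reward contiguous, correctly placed segments and penalize
   fragmented predictions.

Because real PSSMs require a PSI-BLAST search against the nr database, the
package ships a synthetic-data module (`sspipe.simulate`) that generates
chains with segmental H/E/C structure, class-conditional residue
composition, and PSSM-like profiles — every stage is exercisable offline.
Estimators follow scikit-learn conventions (`fit`/`predict`/`get_params`).

## Worked example

```python
from sspipe import SimSpec, simulate, SecondaryStructurePredictor

data = simulate(SimSpec(n_chains=60, length_range=(25, 50), seed=21))
train, test = data[:42], data[42:]
model = SecondaryStructurePredictor(window_size=9).fit(
    [c for c, _, _ in train], [s for _, s, _ in train],
    {c.id: p for c, _, p in train})

chain, truth, profile = test[0]
pred = model.predict([chain], {chain.id: profile})[chain.id]
print("chain ", chain.sequence)
print("true  ", truth.states)
print("pred  ", pred.states)
print(model.score_report(
    [c for c, _, _ in test], [s for _, s, _ in test],
    {c.id: p for c, _, p in test}))
```

prints

```
chain  ILPEWSDTNPFSIVPPKMKHPSCTTQPYGIVE
true   EECCCCCCCCCCEECCEEECCCEEHHHCCEEC
pred   HHCHCCCCCCCCEECCCCCCCCCCCCCHCCEC
Q3      67.43
SOV94   78.02
SOV99   59.20
N      651
        pred H  pred E  pred C
actual H    139      17      65
actual E     41      55      62
actual C     24       3     245
H: precision 68.14  recall 62.90
E: precision 73.33  recall 34.81
C: precision 65.86  recall 90.07
```

Q3 = 67.43 means 67.43 % of the 651 held-out residues are labelled
correctly (the majority-class baseline for this split is ~45 %); SOV99 is
lower than Q3 because fragmented segments are penalized, and the confusion
matrix shows the typical pattern — coil recalled well, sheet hardest.

The same pipeline is available from the shell:

```bash
sspipe simulate --n 200 --seed 7 -o simdata/
sspipe train simdata/chains.fasta simdata/chains.ss3 --pssm-dir simdata/pssm -o model.bin
sspipe predict simdata/chains.fasta --model model.bin --pssm-dir simdata/pssm -o pred.ss3
sspipe evaluate simdata/chains.ss3 pred.ss3
```

plus `reduce` (8-state → 3-state, five conventions), `pssm-synth`,
`encode`, `gridsearch` and `filter`. Real inputs are standard FASTA,
plain-text structure strings (`<id> <states>` per line) and PSI-BLAST
ASCII PSSM files.

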