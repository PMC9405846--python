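# aptaselex

**In silico SELEX: rational design and screening of RNA aptamers for
small-molecule targets.**

Aptamers — short single-stranded oligonucleotides whose folded 3-D shape
binds a specific target — are classically isolated by SELEX (systematic
evolution of ligands by exponential enrichment), an iterative wet-lab
protocol that takes weeks to months. `aptaselex` implements the fully
computational alternative for small-molecule analytes (for example ammonium,
NH₄⁺, against methylamine interferents): a candidate funnel that starts from
a random RNA pool and ends with a short, ranked list of selective aptamer
candidates.

The funnel has four stages:

1. **Library generation** — *n* unique random RNA sequences (default 27 nt,
   i.i.d. uniform over {A, C, G, U}), deduplicated exactly.
2. **Thermodynamic filtering** — each candidate is folded to its
   minimum-free-energy (MFE) secondary structure (ViennaRNA nearest-neighbor
   model, 37 °C); survivors must satisfy ΔG < −5 kcal/mol *and* have at most
   20 unpaired nucleotides.
3. **Binding prediction** — a two-branch 1-D convolutional network scores
   each (aptamer, target) pair. The aptamer enters as a 100 × 4 padded
   one-hot matrix (A→1000, C→0100, G→0010, U→0001), the target as its
   166-bit MACCS structural-key fingerprint computed from SMILES. Each
   branch applies three convolution layers (32/64/96 filters) with
   max-pooling; the aggregated branch features feed three fully connected
   layers (1050/1050/512, dropout 0.1) into a sigmoid output
   p(bind) ∈ [0, 1]. Candidates with p ≥ 0.5 survive.
4. **Selectivity ranking** — docking free energies (kcal/mol; ingested from
   score tables, e.g. AutoDock Vina output averaged over replicate runs)
   against the positive target and negative interferents are combined by a
   two-threshold rule: keep candidates binding the analyte strongly
   (E⁺ ≤ −6.6) but every interferent weakly (E⁻ ≥ −5.5), ranked by E⁺
   ascending.

Because curated aptamer–small-molecule training corpora are not publicly
deposited, the package ships a synthetic-data generator with a *planted*
binding rule (motif present AND binder-pool target ⇒ binder) whose Bayes
optimum is known analytically, so model training is testable as parameter
recovery. A molecular-dynamics module computes the conformation metrics
used to interpret aptamer sensor responses: radius of gyration (Rg), RMSD
with Kabsch superposition, and per-atom/per-residue RMSF.

## Worked example

```python
from aptaselex.library import LibraryConfig, generate_library
from aptaselex.structure import FilterPolicy, ViennaRNAEngine, filter_library
from aptaselex.synthdata import SynthSpec, generate_binding_dataset
from aptaselex.encoding import assemble_dataset
from aptaselex.model import ModelConfig, build_model, train, evaluate
from aptaselex.screening import screen_library

lib = generate_library(LibraryConfig(n_candidates=10_000, length=27, seed=1))
survivors, stats = filter_library(lib, FilterPolicy(), ViennaRNAEngine())
print(f"filter: {stats.n_survivors}/{stats.n_input} "
      f"(survival {stats.survival_fraction:.3f})")

df = generate_binding_dataset(SynthSpec(n_pos=300, n_neg=400, seed=1))
train_set, test_set = assemble_dataset(df, seed=1)
cfg = ModelConfig(seed=1)
model, _ = train(build_model(cfg), train_set, cfg)
rep = evaluate(model, test_set)
print(f"model: acc {rep.acc:.3f} sen {rep.sen:.3f} spe {rep.spe:.3f}")

kept = screen_library(model, [s for s, _ in survivors][:2000], "[NH4+]")
print(f"screen: {len(kept)}/2000 candidates at p >= 0.5")
```

prints (a few minutes on one CPU):

```
filter: 1849/10000 (survival 0.185)
model: acc 0.971 sen 1.000 spe 0.950
screen: 128/2000 candidates at p >= 0.5
```

Read: ~19 % of random 27-mers fold stably enough (ΔG < −5 kcal/mol) while
keeping ≤ 20 accessible nucleotides; the model recovers the planted binding
rule at 97 % held-out accuracy (sensitivity 1.0, specificity 0.95); of the
filtered candidates, 6–7 % are predicted to bind ammonium at the 0.5
threshold. The same pipeline is available from a shell via the `aptaselex`
CLI (`generate`, `filter`, `synth`, `train`, `tune`, `screen`, `rank`,
`traj` — see `aptaselex --help`).

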