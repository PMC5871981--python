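# sfbench

Similarity-cutoff learning-curve benchmarks for protein–ligand
binding-affinity scoring functions.

## The problem

A scoring function (SF) maps a 3D protein–ligand complex to a predicted
binding affinity (pKd/pKi, the −log₁₀ of the molar constant). Its
*scoring power* is the Pearson correlation Rp between predicted and
measured affinities on a fixed, diverse test set of crystal complexes.
A recurring debate asks whether machine-learning SFs owe their scoring
power entirely to training complexes whose proteins resemble the test
proteins. The standard probe is a **similarity-cutoff benchmark**: given a
train × test protein-similarity matrix `S ∈ [0,1]` and an ascending cutoff
schedule, training complex `i` is retained at cutoff `c` iff

    max_j S[i, j] ≤ c

(a single above-cutoff test protein removes it; ties are retained). The
retained sets are nested, so training every SF on every set and plotting
test Rp against the number of training samples yields a learning curve
per SF: a classical linear SF saturates after a few hundred dissimilar
complexes, while a random-forest SF keeps climbing as similar proteins
are admitted.

`sfbench` is for computational chemists and method developers who want to
run this analysis — on their own descriptor tables and similarity
matrices, or entirely self-contained on a synthetic benchmark with the
same statistical structure (protein families, family-clustered
similarity, family-structured descriptors, partially nonlinear
descriptor→affinity mapping).

## What's inside

| module        | role |
|---------------|------|
| `structio`    | heavy-atom PDB / SDF (V2000) readers and writers, rotatable-bond count |
| `descriptors` | 36 element-pair contact counts (12 Å), 6 Vina-style empirical terms, a 4-term classical surrogate; descriptor CSV I/O |
| `partition`   | similarity matrices, cutoff schedules, nested training sets, retention reports |
| `regress`     | deterministic MLR (bit-identical refits) and seeded random forests; the 10-repeat protocol |
| `evaluate`    | Pearson Rp, repeat summaries, gap ratio, learning-curve tables and plots |
| `synthdata`   | the synthetic benchmark generator (complexes, affinities, similarity, split) |
| `pipeline`    | end-to-end runs (synthetic or from files) with manifests; `sfbench` CLI |

The default SF roster mirrors the canonical comparison: **X-Score**
(4 terms, MLR), **RF::X-Score** (same 4 terms, RF), **RF-Score**
(36 counts, RF), **RF-Score-v3** (42 features, RF) — 500 trees, ⌈p/3⌉
features per split, 10 instances per cell with seeds `base_seed + r`.

## Worked example

```python
from sfbench import RunConfig, run

result = run(RunConfig(mode="synthetic", seed=1, out_dir="demo_run"))
summary = result["curve"].to_summary_frame()
print(summary[summary.sf.isin(["X-Score", "RF-Score-v3"])]
      .pivot(index="cutoff", columns="sf", values="mean_rp"))
```

prints (abridged; 13 cutoffs in the full table):

```
sf      RF-Score-v3  X-Score
cutoff
0.35          0.609    0.568
0.45          0.786    0.548
0.65          0.786    0.548
0.80          0.805    0.559
0.90          0.844    0.589
0.95          0.857    0.594
```

Read it as the two learning curves. At cutoff 0.35 only 31 training
complexes remain, all from protein families unrelated to the test set:
the linear SF already sits at Rp ≈ 0.57 and never moves far from it
(0.594 with 832 complexes — extra similar proteins cannot help a
saturated 4-parameter model). The forest starts lower-powered on 31
samples but climbs monotonically to 0.857 as same-family complexes are
admitted, overtaking the linear SF and still rising at the largest set.
The run directory also contains `stability_report.json`:

```json
"RF-Score-v3": {"n_train": 832, "median_rp": 0.857,
                "range_rp": 0.005, "gap_ratio_vs_X-Score": 55.7}
```

i.e. the 10-repeat stochastic variability of the forest (0.005 in Rp) is
~56× smaller than its median advantage over the deterministic comparator
— the reason this analysis reports repeat ranges instead of p-values.

The same pipeline runs from files (`mode="files"` with a structures
directory, an affinity CSV and a similarity CSV); an exported synthetic
benchmark (`sfbench generate`) rerun in files mode reproduces the
synthetic-mode outputs byte for byte.

### Command line

```bash
sfbench generate --seed 3 --out bench/            # benchmark to disk
sfbench features --proteins bench/proteins --ligands bench/ligands \
        --scheme rf_v3 --out descriptors.csv      # descriptor CSV
sfbench partition --similarity bench/similarity.csv --cutoffs 0.3,0.6,0.95
sfbench run --config run.yaml --seed 7            # full pipeline
sfbench report --run-dir demo_run --out curve.png # Rp vs n_train plot
```

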