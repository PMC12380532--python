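# bidkit

Toolkit for **B-cell immunodominance (ID) analysis and prediction** from
antibody–antigen complex structures.

Antibody responses are hierarchical: some antigen surface regions are bound
by many different antibodies (immunodominant), others rarely. `bidkit`
quantifies this per residue, characterizes what distinguishes strongly from
weakly immunodominant surface, and trains a graph-attention regressor to
predict the score from structure — useful, for example, when prioritizing
conserved but subdominant regions for vaccine design.

## The method

1. **Curation and scoring.** Complexes are quality-filtered (resolution
   ≤ 3.0 Å, R-factor ≤ 0.25, antigen ≥ 50 aa, antibody redundancy removed at
   99% identity). Antigen chains are clustered at ≥ 0.70 sequence identity;
   clusters with ≥ 4 complexes are kept and aligned. In each complex, antigen
   residues with any heavy atom within 6 Å of an antibody heavy atom are
   epitopes. Mapped onto the cluster MSA, each column of the representative
   sequence gets an **ID score**

   ```
   ID(i) = (# rows epitope-flagged at column i) / (# rows in the MSA)  ∈ [0, 1]
   ```

   Representatives with MSA depth ≥ 10 form the test set; depth 4–9 trains.

2. **Statistics.** Per protein, residues with ID ≥ 0.5·max(ID) are *high*,
   those with 0 < ID < 0.2·max(ID) *weak*. On surface residues (RSA ≥ 0.10)
   and 10 Å surface patches, continuous features (nine AAIndex-style scales,
   RSA, protrusion, depth, conservation, neighbor-ID) are compared with
   Welch's t-test, compositional features with a Mann–Whitney U on
   per-protein proportions, all Benjamini–Hochberg corrected at α = 0.05.

3. **Prediction.** The antigen is a residue graph (10 Å Cα edges) with
   pluggable node embeddings (one-hot, or precomputed matrices such as
   protein-language-model outputs). A 3-layer multi-head graph-attention
   network with a fully connected head (2048-512-128 / 128-32-1, 8 heads,
   Adam, MSE) regresses per-residue ID; Spearman correlation is the main
   evaluation criterion.

A fully synthetic generator (`bidkit.synthetic`) emulates the data regime —
clustered homologous antigens, pseudo-antibody footprints with controllable
reuse, planted-signal embeddings — so the entire pipeline is testable
without downloading any structures.

## Worked example

```python
import numpy as np
from bidkit import (SyntheticConfig, generate_cluster, annotate_epitopes,
                    compute_id_profile, assign_groups)
from bidkit.benchmarks import pipeline_profile

records, truth = generate_cluster(SyntheticConfig(seed=1), "demo", depth=10)
profile = pipeline_profile(records, "demo")       # annotate -> map -> score
print(len(profile), profile.msa_depth)            # 120 10
print(np.array_equal(profile.epitope_counts, truth.epitope_counts))  # True
print(profile.scores.max())                       # 0.8
print(dict(zip(*np.unique(assign_groups(profile.scores), return_counts=True))))
# {'high': 3, 'neither': 109, 'weak': 8}
```

Ten synthetic complexes of one 120-residue antigen are scored through the
full pipeline; the profile equals the generator's ground truth exactly, the
strongest position was an epitope in 8 of 10 complexes (ID 0.8), 3 residues
are highly immunodominant (ID ≥ 0.5·max = 0.4) and 8 weakly
(0 < ID < 0.2·max = 0.16).

Training and prediction use the statsmodels-style model/results pair:

```python
from bidkit import GATRegressor, GATConfig
results = GATRegressor(train_graphs, val_graphs, GATConfig.reduced(seed=1)).fit()
print(results.summary())
pred = results.predict(test_graph)                # per-residue scores
```

The same stages are scriptable: `bidkit simulate | curate | score |
featurize | stats | train | predict` (see `bidkit --help`).

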