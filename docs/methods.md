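# Methods

## Immunodominance scoring

A cluster is a set of complexes whose antigen chains share ≥ 0.70 global
sequence identity — operationally, the same antigen bound by different
antibodies. Epitopes are annotated per complex with a closed 6 Å heavy-atom
cutoff (hydrogens are dropped at parse time; altlocs resolve to the highest
occupancy). Masks are mapped onto the cluster MSA by walking non-gap
positions, and the ID score of a column is the number of epitope-flagged
rows divided by the MSA depth. Scores are stored together with their integer
numerators so identities can be checked in exact rational arithmetic:
`sum(scores) * depth == total flags` holds exactly, and every score lies in
[0, 1] by construction.

Two denominator conventions exist for columns where some rows are gapped:
dividing by all rows (default) or only by rows with a residue at the column.
Both are implemented (`compute_id_profile(denominator=...)`); the default is
the literal reading of the formula. Columns gapped in the representative are
dropped, so profiles live on the representative's residues. A single antigen
appearing in several complexes contributes one MSA row per complex.

Clustering is a deterministic greedy incremental scheme (longest-first,
join the first representative at ≥ 0.70 identity, identity = matches /
alignment length under global alignment); externally computed cluster tables
are ingested via TSV when fidelity to a specific external tool matters. MSAs
are assembled with a center-star aligner (pairwise global alignments to the
representative, "once a gap, always a gap" merge), which is exact for the
point-mutant clusters the generator produces and adequate for close
homologs; externally built alignments can be read from aligned FASTA.

Quality filtering keeps complexes with resolution ≤ 3.0 Å, R-factor ≤ 0.25
and all antigen chains ≥ 50 residues; records missing metadata are excluded
with a logged reason. Antibody redundancy is removed greedily in order of
ascending resolution, dropping a record when its concatenated antibody
sequence exceeds 0.99 identity to a retained one. Representatives with MSA
depth ≥ 10 are test data, 4–9 train data; anything below 4 violates the
cluster-size invariant and is an error.

## Surface features

* **RSA** — Shrake–Rupley SASA with a deterministic Fibonacci sphere
  (probe 1.4 Å, 960 points by default; the point lattice makes results
  bit-reproducible), normalized by the Tien et al. (2013) theoretical
  maximum ASA per amino acid. SASA is computed on the antigen chain in
  isolation so the bound antibody does not bury its own epitope. Values can
  slightly exceed 1 on very exposed residues of small peptides. Surface
  means RSA ≥ 0.10 (closed).
* **Secondary structure** — a built-in 3-state dihedral assignment
  (helix: φ ∈ [−100, −30], ψ ∈ [−80, 0]; strand: φ ∈ [−180, −45],
  ψ ≥ 45 or ≤ −135; runs shorter than 3 collapse to coil), plus an adapter
  collapsing external DSSP 8-state output (H,G,I → helix; E,B → strand).
* **Protrusion / depth proxies** — protrusion is one minus the normalized
  heavy-atom count within 10 Å of the residue centroid; depth is the
  distance from the centroid to the nearest solvent-accessible atom. These
  are documented geometric stand-ins exposing the same monotone signal as
  dedicated surface-topography tools, and externally computed values can be
  substituted.
* **Physico-chemical scales** — one fixed published AAIndex entry per
  feature: KYTJ820101 (hydrophobicity), ZIMJ680104 (isoelectric point),
  GRAR740103 (residue volume), CHAM810101 (steric), CHAM820101
  (polarizability), FAUJ880109 (H-bond donors), GRAR740102 (polarity),
  FAUJ880111/FAUJ880112 (positive/negative charge). Nonstandard residues
  ('X') get NaN and are excluded from scale-based statistics; the table is
  overridable.
* **Conservation** — normalized Shannon entropy of each MSA column (gaps
  excluded), scaled to [0, 1]; a monotone stand-in for phylogeny-aware
  conservation scores, which can be supplied externally instead.
* **Patches** — one patch per surface residue: all surface residues within
  10 Å Cα–Cα of the center (a flag switches to minimal heavy-atom distance).
  Patch features are arithmetic means over members (center included);
  **neighbor-ID** is the members' mean ID excluding the center and is
  undefined (NaN) for singleton patches.

## Statistical analysis

Groups are defined per protein relative to its maximum ID: high when
ID ≥ 0.5·max, weak when 0 < ID < 0.2·max (zero is never weak). Continuous
features are compared with Welch's two-sample t-test on residues pooled
across test proteins (a per-protein-means mode exists, since pooling treats
residues of one protein as exchangeable); compositional features compare
per-protein category proportions with a Mann–Whitney U (normal
approximation, tie and continuity corrections — implemented directly and
verified against an independent reference implementation to 1e-8). All raw
p-values at one level (residue or patch) form a single Benjamini–Hochberg
family (backed by statsmodels, verified against the step-up definition);
significance is adjusted p ≤ 0.05. Zero-variance features are flagged
untestable and excluded from the family rather than diluting it.

## Graph-attention regressor

Nodes are residues, edges connect Cα pairs ≤ 10 Å (consecutive residues are
always linked; self-loops are added only at message-passing time). Three
attention layers use additive attention per head over each node's
neighborhood including itself (LeakyReLU slope 0.2 on the logits, softmax
per node); heads are concatenated in layers 1–2 and averaged in layer 3,
whose per-head width equals the layer output so the averaged output feeds
the FC head — the canonical choice for a GAT output layer. ELU follows the
first two GAT layers and the hidden FC layer; the output is an unbounded
regression score, clipped to [0, 1] only for reporting.

The full recipe is dims 2048-512-128, FC 128-32-1, 8 heads, Adam at 1e-6,
MSE, batches of 4 graphs (batch loss = mean over all nodes in the batch),
200 epochs, returning the snapshot with the lowest validation loss; the
validation split is a seeded 10% of training graphs. No dropout or weight
decay by default (both would be config additions). The network is pure
NumPy with hand-written backpropagation, verified against central finite
differences; training is exactly reproducible per seed. Model files are
JSON (config echo, input-dim fingerprint, parameters), which keeps re-runs
byte-identical.

Synthetic-scale experiments use `GATConfig.reduced()`: dims 32-16-8,
2 heads, FC 8-8-1, learning rate 7e-3, 200 epochs. The small widths keep a
full 5-replicate ablation within minutes on one CPU; the learning rate was
chosen for that width (the 1e-6 of the full recipe is matched to the
2048-wide network and barely moves the small one).

## Synthetic data

The generator emulates the curated-data regime: antigens of 120 residues
(range configurable, ≥ 50), clusters of 4–15 complexes, point mutations at
rate 0.05 (safely above the 0.70 clustering identity), 2–4 antibody
footprints of 9 Å radius reused with probability 0.6. Backbones are either a
solenoid ("helix_bundle": a minor helix wound on a rising helical axis,
giving 3.8 Å Cα spacing, a buried core of roughly a third of residues, and
RSA spanning the full range) or a compact self-avoiding random walk; both
are decorated with pseudo N/C/O/Cβ atoms. Pseudo-antibodies are seeded atom
clouds slid along the footprint's outward normal to a ~4 Å closest approach;
every member's epitope mask is *computed* from those atoms with the same
6 Å rule the pipeline uses, so the generator's ground-truth ID profile is an
exact rational target for the pipeline (the central oracle of the test
suite). Footprint centers are sampled on surface residues only, matching the
analysis' surface restriction. Reused footprints keep their antibody
placement, so full reuse yields ID exactly 1 on the footprint.

What the generator does **not** emulate: real immunoglobulin geometry,
sequence evolution beyond i.i.d. substitutions, conformational change on
binding, or crystallographic artifacts. Passing tests therefore certify the
pipeline's internal contracts and statistical calibration, not performance
on experimental structures.

In embedding-aware mode each representative carries a planted latent: per-
residue Gaussian vectors smoothed twice over 10 Å neighborhoods (spatially
clustered, like real learned embeddings), emitted with Gaussian jitter
(sd 0.1). The regression target is `sigmoid(3.5 (Az·w) + 14 (A·rsa − 0.22))`
with corpus-wide unit weights `w` and `A` one further neighborhood
averaging — a known function of the latent field plus a patch-exposure term.
This makes parameter recovery well-posed (a trained model must invert a
fixed map on held-out clusters), gives structure-derived embeddings partial
signal, one-hot encodings essentially none, and both components the spatial
clustering that neighborhood attention exploits; the two coefficients were
set so the latent term carries the larger variance share, mirroring the
intended ablation ordering (combined best, embeddings ≫ one-hot).

## Numerical choices and edge cases

* Epitope boundary is closed (≤ 6.0 Å); distances via a KD-tree, verified
  against an all-pairs scan.
* ID profiles with no epitopes at all yield all-*neither* group labels with
  a warning; proteins with constant targets are excluded from macro-averaged
  metrics and flagged.
* Constant predictions have undefined correlations (NaN) but well-defined
  R²; single-class label sets make classification metrics NaN.
* MCC's reporting threshold defaults to the MCC-maximizing value on the data
  at hand (pass an explicit threshold, e.g. tuned on validation data, for
  honest test reporting).
* Greedy tie-breaks: clustering visits sequences longest-first then
  lexicographic; redundancy filtering visits records by ascending
  resolution then id.
* All randomness flows through seeded `numpy` generators; every CLI stage
  re-run with the same seed and inputs is byte-identical.

## Known limitations

The built-in aligner, clustering, secondary-structure assignment and
geometric proxies are deliberately simple, deterministic stand-ins with
adapter seams for external tools; they are not drop-in numerical
replacements for those tools' outputs. The statistical analysis pools
residues by default, which understates between-protein variation (the
per-protein mode is the conservative alternative). Training the full-size
network on real corpora is supported by the code but not exercised by the
synthetic experiments, which use the reduced configuration.
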