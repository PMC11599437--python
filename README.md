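# esoxtrace

Otolith-microchemistry life-history reconstruction, growth modelling and
ecotype delimitation for coastal northern pike (*Esox lucius*).

## Scientific problem

Pike in brackish coastal waters are a mosaic of life histories: some fish
live their whole lives in freshwater, some are resident in brackish water,
some spawn in freshwater streams and feed at sea (anadromous-like), and some
move between habitats throughout life. These behaviours leave a chemical
record in the otolith: strontium-to-calcium ratios (Sr:Ca) track ambient
salinity along the growth axis, while oxygen stable isotopes (δ¹⁸O) track a
mixture of salinity and temperature. Given laser-ablation Sr:Ca transects and
spot-sampled δ¹⁸O values from annulus-aligned otolith sections, plus genetic
assignment probabilities (Q-matrices) for the same fish, the package answers:

1. **What life-history phenotype is each fish?** Both by unsupervised
   clustering of whole Sr:Ca trajectories and by an explicit, auditable
   decision framework based on natal origin and habitat-shift counts.
2. **Does habitat use affect growth?** Via mixed models on annual increment
   widths and a hierarchical von Bertalanffy model on back-calculated radii.
3. **Are the phenotypes genetically distinct ecotypes?** Via PERMANOVA on
   genotype assignment probabilities across phenotypes.

## What is implemented

| Module | Contents |
| --- | --- |
| `transect_io` | Transect containers and CSV I/O, Sr:Ca/δ¹⁸O channel pairing by window means, salinity correction of δ¹⁸O (pooled regression on Sr:Ca, residual = thermal proxy), annual means, life-stage features |
| `dtw_core` | Sakoe–Chiba-banded dynamic time warping on multivariate annual series, Ward clustering via Lance–Williams updates, six cluster-validity indices, majority-vote selection of the number of clusters |
| `phenotyper` | Rule-based phenotype assignment (natal origin + excursion counts with run-length filtering), leave-one-out LDA jackknife validation, chi-square frequency tests |
| `growthmod` | Linear mixed models for log annual increments (age, age², thermal proxy, salinity, sex, phenotype; fish-level random intercept), likelihood-ratio term tests respecting marginality, Nakagawa R², hierarchical von Bertalanffy growth model fitted by random-walk MCMC with gamma group-level priors |
| `genetics` | Q-matrix I/O (CSV and STRUCTURE outfiles), threshold genotype assignment, Euclidean PERMANOVA with permutation p-values, pairwise tests with Benjamini–Hochberg correction, ecotype delimitation by merging indistinguishable phenotypes |
| `synthgen` | Synthetic study generator with planted phenotypes, genotype–phenotype coupling and known growth parameters, used for validation throughout |
| `pipeline` | Deterministic end-to-end pipeline with per-stage derived seeds and a SHA-256 artifact manifest |
| `cli` | `esoxtrace simulate / run / phenotype / growth / genetics / report` |

## Worked example

```python
import esoxtrace as ex
from esoxtrace import transect_io, dtw_core, phenotyper, genetics

# 1. simulate a study population with known ground truth
ds = ex.simulate_population(ex.SynthConfig(seed=42))

# 2. pair channels and remove the salinity component of d18O
paired = {f: transect_io.pair_channels(t) for f, t in ds.transects.items()}
corrected, (b0, b1) = transect_io.correct_temperature_proxy(paired)
print(f"pooled correction: d18O = {b0:.3f} + {b1:.3f} * Sr:Ca")

# 3. cluster the chemistry trajectories and pick k by CVI vote
series = dtw_core.build_multiseries(corrected)
dmat = dtw_core.distance_matrix(series, window_frac=0.05)
k, report = dtw_core.select_k(None, dmat=dmat)
print(f"selected k = {k}, votes = {report.votes}")

# 4. rule-based phenotype calls
annual = transect_io.annual_means_table(corrected)
calls = phenotyper.assign_phenotypes(annual, ds.fish)
df = phenotyper.calls_to_frame(calls)
print(df["phenotype"].value_counts().to_dict())

# 5. jackknife validation of the phenotype labels
feats = transect_io.stage_features_table(annual)
rate, conf = phenotyper.jackknife_lda(feats, df.set_index("fish_id")["phenotype"])
print(f"jackknife reclassification rate: {rate:.3f}")

# 6. do the phenotypes differ in genetic ancestry?
Y = ds.qmatrix[["q1", "q2", "q3", "q4"]].to_numpy()
res = genetics.permanova(
    Y, df.set_index("fish_id").loc[ds.qmatrix["fish_id"], "phenotype"],
    n_perm=9999, seed=1)
print(f"PERMANOVA: pseudo-F = {res.pseudo_f:.2f}, R2 = {res.r2:.3f}, p = {res.p:.4f}")
```

Output:

```
pooled correction: d18O = -3.659 + 0.181 * Sr:Ca
selected k = 4, votes = {4: 4, 10: 1, 3: 1}
{'FW_RESIDENT': 20, 'ANADROMOUS': 20, 'BRACKISH_RESIDENT': 20, 'CROSS_HABITAT': 20}
jackknife reclassification rate: 1.000
PERMANOVA: pseudo-F = 18.66, R2 = 0.424, p = 0.0001
```

The same analysis is available end to end from the command line:

```bash
esoxtrace simulate --seed 7 --out data/        # write synthetic inputs
esoxtrace run --config config.yaml --inputs data/ --out results/
esoxtrace report --manifest results/manifest.json
```

Re-running `esoxtrace run` with the same configuration and seed reproduces
every artifact byte-for-byte; the manifest hash certifies it.

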