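# txdynamics

Transcriptome dynamics of developmental time courses from bulk RNA-seq
count matrices.

Given a gene × library table of tag counts, a sample sheet mapping
libraries to ordered developmental stages (days after anthesis, DAA) and
replicates, and (optionally) a many-to-many gene → category annotation
map, `txdynamics` answers the questions a fruit-development (or any
staged) transcriptome study asks:

* **Which genes change between consecutive stages?**  An exact
  negative-binomial test between the two replicate groups of each
  consecutive interval (library sizes equalized by NB quantile matching,
  common and per-gene dispersions estimated by conditional maximum
  likelihood with empirical-Bayes shrinkage), followed by Storey q-values
  at a 1% FDR.
* **What patterns do they follow?**  Each gene's per-interval call —
  significant **D**ecrease, **S**teady, or significant **I**ncrease — is
  combined over the k intervals into one of 3^k patterns
  (DDD = 1 … SSS = 14 … III = 27 for k = 3), and the pattern census drives
  transition probabilities P(next state | current state), per-interval
  marginals, per-day change rates and cross-census correlations.
* **How diverse and specialized is each stage?**  Shannon entropy
  H_i = −Σ_j p_ij log2 p_ij of the stage's relative expression
  frequencies, the effective gene number G = 2^H, per-gene specificity
  S_j = (1/t) Σ_i (p_ij/p̄_j) log2(p_ij/p̄_j) ∈ [0, log2 t], and stage
  specialization δ_i = Σ_j p_ij S_j.
* **How many genes did the sampling miss?**  Per-stage richness via the
  Chao estimator S_chao = S_obs + f1²/(2 f2) and Good's sample coverage
  Ĉ = 1 − f1/N with the scaled mRNA-pool size M̂ = N/Ĉ.
* **What do gene groups do?**  Count-conserving weighted aggregation:
  a gene in k categories contributes count/k to each, unannotated genes
  form an untested "offset" row, column totals are preserved exactly, and
  the aggregated matrix goes through the same test/pattern machinery.

A synthetic-data generator draws NB counts with planted D/S/I patterns,
heavy-tailed baseline abundances and redundant category maps, so the whole
pipeline is testable without any sequencing data.

## Worked example

```sh
txdynamics simulate --n-genes 2000 --reads-per-stage 5e5 --seed 7 --out-dir sim
txdynamics run --counts sim/counts.tsv --design sim/design.tsv \
    --categories sim/categories.tsv --out-dir out
python - <<'EOF'
import json
s = json.load(open("out/summary.json"))
g = s["genes"]
print("genes:", g["n_units"], "changed:", g["n_changed_units"],
      "changes:", g["n_total_changes"])
print("P(S at 20-40 | D at 10-20) =",
      round(g["transitions"]["pair_1_to_2"]["D"]["S"], 4))
EOF
```

prints

```
genes: 2000 changed: 177 changes: 217
P(S at 20-40 | D at 10-20) = 0.9714
```

meaning that of the 2,000 simulated genes, 177 changed significantly in at
least one of the three intervals (217 significant changes in total; at
this shallow depth only the stronger-expressed half of the planted ~17%
non-steady genes reach significance), and a gene that decreased in the
first interval held steady in the second 97% of the time.
`out/` also contains the per-stage richness table (`richness.tsv`),
diversity/specialization statistics (`infostats.tsv`), per-gene test
results (`dge.tsv`), the 27-cell pattern census (`pattern_census.tsv`),
the detection Venn partition (`venn.tsv`) and category-level results when
a map is given.

A census-only mode reproduces all pattern arithmetic from a 27-row census
TSV alone — no sequencing data involved:

```sh
txdynamics summary src/txdynamics/data/pattern_census_fruit.tsv \
    --column genes --durations 10,20,20
```

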