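# trnkit

Topological analysis of bacterial transcriptional regulatory networks (TRNs):
degree distributions and scale-free tail fits, shortest-path-association
module detection, and a feed-forward motif census against a degree-preserving
null model.

A TRN is a directed graph whose edges run from a regulator — a DNA-binding
transcription factor (TF) or a sigma factor — to the gene it controls.
Curated databases (DBTBS for *Bacillus subtilis*, RegulonDB for *E. coli*)
export these networks as interaction tables with evidence annotations.
`trnkit` is for computational biologists who want to go from such a table to
the standard structural characterization of the network:

- **Global topology.** In/out degree distributions P(k), the log-log
  complementary cumulative distribution CCDF(k) = Pr[K ≥ k], least-squares
  straight-line fits of power-law (log CCDF vs log k) versus exponential
  (log CCDF vs k) models compared by R², and the mean local clustering
  coefficient. For a power law P(k) ∝ k^(−γ) the CCDF slope is −(γ−1), so
  the implied P(k) exponent is reported as slope − 1.
- **Modules.** On the regulator-only subnetwork (housekeeping sigma factor
  excluded, since a hub wired to half the genome fuses everything into one
  mega-module), all-pairs shortest-path lengths d_ij give the association
  s_ij = 1/d_ij² (1 for adjacent pairs, 0 for unreachable ones). Regulators
  are grouped by average-linkage (UPGMA) hierarchical clustering of the
  association matrix, with Girvan–Newman edge-betweenness communities as the
  alternative method and ARI/NMI-based comparison of any two partitions
  (including externally produced ones).
- **Motifs.** Feed-forward loops FF (A→B, B→C, A→C; A the master regulator,
  B the local regulator, C the target) and complex feed-forwards CFF (an FF
  whose regulators also form a two-node feedback circuit A⇄B), matched as
  induced subgraphs. Over-representation is tested against random networks
  from repeated degree-preserving double-edge swaps, with pseudocounted
  empirical p-values (significant below 0.01). Per-regulator master/local
  role profiles, per-pair target counts, and the fraction of motifs embedded
  within a single module (versus mediating inter-module cross-talk) complete
  the census.

A seeded synthetic generator produces networks with the structure these
analyses assume — planted regulator modules, power-law target fan-out,
a sigA-like mega-hub, planted FF/CFF motifs, strong/weak evidence labels —
together with the ground truth, so the whole pipeline is testable end to end
without any external data.

## Worked example

```python
import trnkit as tk

net, truth = tk.generate(tk.SyntheticSpec(seed=1))
strong = tk.filter_by_evidence(net, {"strong"})
sub = tk.extract_regulator_subnetwork(strong, exclude=["sigA"])
part = tk.hclust_modules(tk.association_matrix(sub), cut=9)
sig = tk.motif_significance(strong, n_random=200, n_swaps_per_edge=10, seed=1)
emb = tk.embedding_fractions(tk.enumerate_motifs(strong), part)
```

printing each stage gives:

```
network: 235 nodes, 464 edges
strong-evidence: 229 nodes, 439 edges
hub sigA: out-degree 110 (46.8% of the network)
out-degree CCDF: power-law R^2=0.820 (implied P(k) exponent -2.15),
                 exponential R^2=0.472 -> power_law
mean clustering coefficient: 0.341
regulator subnetwork: 70 nodes, 133 edges
modules: 9 at the cut, 0 isolated singletons
FF: observed 132, null 67.7+/-10.4, p=0.0050
CFF: observed 14, null 0.2+/-0.4, p=0.0050
embedded FF 100%, CFF 100%
module-recovery ARI vs planted truth: 1.000
```

Reading the numbers: the generated network's out-degree tail is better
explained by a power law than by an exponential (R² 0.82 vs 0.47) with an
implied P(k) exponent near the generator's −2.1; the housekeeping hub
reaches ~47% of all genes in one step; cutting the association dendrogram
into nine modules recovers the planted module structure exactly (ARI 1.0);
both motif classes are flagged significant (the smallest attainable p at
200 randomizations is (1+0)/(1+200) ≈ 0.005); and every motif's two
regulators lie in the same module, i.e. there is no inter-module cross-talk
at this seed.

The same workflow runs from the shell on any interaction table:

```sh
trn simulate --spec spec.yaml -o net.tsv --truth truth.json
trn load net.tsv --strong-only --exclude sigA --subnetwork -o sub.tsv
trn stats net.tsv --direction out --report stats.json --plot ccdf.png
trn modules sub.tsv --method hclust --cut 9 -o partition.tsv --tree tree.nwk
trn motifs net.tsv --partition partition.tsv --n-random 1000 -o motifs.json
trn run --config cfg.yaml        # the whole pipeline, one JSON report
```

The input dialect is a tab-separated edge list with columns
`regulator  target  regulator_class  mode  evidence` (header optional,
`#` comments allowed); partitions are TSV `gene  module` files, so outputs
of external community-detection tools can be compared directly with
`trn compare`.

## Layout

| module | contents |
|---|---|
| `trnkit.network_io` | TSV/GraphML parsing, evidence filtering, regulator subnetwork |
| `trnkit.topology_stats` | degree histograms, clustering, CCDF, tail fits |
| `trnkit.module_detection` | association matrix, UPGMA and Girvan–Newman modules, partition comparison |
| `trnkit.motif_census` | FF/CFF enumeration, switching null, embedding and roles |
| `trnkit.synthetic_networks` | seeded generator with planted ground truth |
| `trnkit.pipeline` / `trnkit.cli` | orchestration and the `trn` command |

See `docs/methods.md` for the modelling choices, defaults and limitations.
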