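# mycnet

Tools for decoding Myc-centred transcriptional regulatory networks from
expression profiling data, as used in studies of lung adenocarcinoma driven by
c-Myc over-expression. The package chains four analysis stages, each usable on
its own:

1. **Differential expression with detection calls** (`mycnet.expression`) —
   genes pass when |mean fold change| ≥ FC₀, the unpaired two-sided Welch
   t-test gives p ≤ p₀, and the change-call concordance (fraction of all
   cross-group sample pairings agreeing in direction) reaches c₀. Two shipped
   profiles: tumor (FC ≥ 3, p ≤ 0.05, 100 % concordance) and transgenic
   non-tumor (FC ≥ 2.5, p ≤ 0.05, ≥ 87.5 %). Fold changes are signed
   (−4.9 means 4.9-fold down).
2. **MATCH-style promoter scanning** (`mycnet.pwm`) — promoters are the window
   −1000..+100 bp around the TSS; a PWM position i carries the information
   weight I(i) = Σ_b f(i,b)·ln(4 f(i,b)), a window scores
   mss = (Current − Min)/(Max − Min) with Current = Σᵢ I(i)·f(i, bᵢ), and the
   core similarity (css) restricts the same score to the five most conserved
   consecutive positions. Both strands are scanned; YES (regulated) and NO
   (background, Myc-site-free) gene sets and per-matrix Fisher enrichment are
   built on top.
3. **Composite-module discovery** (`mycnet.modules`) — a genetic algorithm
   searches for small sets of matrices (Myc + 2 partners by default) with
   per-component score cutoffs and one pairwise distance bound whose joint
   promoter occurrence separates YES from NO genes; fitness is the pooled-sd
   t-like separation of module scores minus a complexity penalty.
4. **Master-regulator search** (`mycnet.regulators`) — candidates are ranked
   by a decay-weighted reachability score over directed paths of length ≤ 4
   to the input gene set, with permutation Z-scores and Benjamini–Hochberg
   FDR.

A synthetic-data module (`mycnet.simulate`) generates all four inputs
(expression + calls, promoter FASTA + TSS annotation, JASPAR-style matrix
library led by an E-box Myc matrix, directed interaction network) with planted
ground truth, so the whole chain is testable without external downloads.

## Worked example

Run the full pipeline on synthetic inputs with planted truth:

```bash
mycnet run --seed 7 --outdir out
```

This simulates 300 genes (30 with a planted 3-fold effect), 130 promoters
(the 30 foreground genes carry a planted Myc + 2-partner module within
100 bp), and a 300-node network with a hub wired to two-thirds of the planted
genes, then executes every stage. The printed summary ends with (abridged):

```json
"cma": {
  "components": ["M_001", "M_002", "M_MYC"],
  "max_pair_distance": 100,
  "coverage_n": 15, "coverage_pct": 100,
  "planted_recovered": true
},
"mr": {
  "top": {"node": "HUB", "score": 0.209631, "z": 6.239,
          "pct_of_inputs": 87.0, "passes": true},
  "planted_recovered": true
}
```

The GA recovered exactly the planted matrix triple (at the planted 100-bp
distance bound) and the module fits 100 % of the detected foreground genes;
the planted hub ranks first with score 0.21 (above the 0.2 cutoff), Z = 6.2
and it reaches 87 % of the input genes within four steps. Stage outputs
(`deg.tsv`, `hits.tsv`, `enrichment.tsv`, `module.json`,
`master_regulators.tsv`, `truth.json`, `summary.json`) land in `out/`.

Library use mirrors the CLI:

```python
from mycnet import simulate_expression, compute_deg, TUMOR_CRITERIA

expr, truth = simulate_expression(300, 10, 1.585, frac_deg=0.1, seed=7)
degs = compute_deg(expr, "control", "case", TUMOR_CRITERIA)
```

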