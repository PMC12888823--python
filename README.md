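# splicecontrol

Identify the transcription factors that *drive* alternative-splicing change
during the epithelial–mesenchymal transition (EMT), starting from nothing
but cross-sectional bulk expression panels.

Bulk cohorts give one snapshot per patient: a matrix of alternative-splicing
(AS) quantifications, one of RNA-binding-protein (RBP) expression and one of
transcription-factor (TF) expression, plus an epithelial/mesenchymal label.
The temporal order of the transition is lost. `splicecontrol` rebuilds it
and turns the static panels into a dynamic, controllable model of the
TF → RBP → AS regulatory cascade:

1. **Pseudotime** — samples are joined into a k-nearest-neighbour similarity
   graph on TF expression; each sample's score is the probability that a
   weight-proportional random walk reaches the mesenchymal anchor before the
   epithelial one (a harmonic function solved as one sparse linear system).
2. **Trend selection** — every feature is scored by |OLS slope| / residual
   SD along pseudotime; the top-k AS events, RBPs and TFs enter the model.
3. **Network inference** — along pseudotime the layers obey mass-action
   kinetics:

   ```
   dX_i/ds = Σ_{j≠i} a_ij X_i X_j + Σ_l b_il X_i Y_l − d_i  X_i    (AS)
   dY_l/ds = Σ_{k≠l} c_lk Y_l Y_k + Σ_p e_lp Y_l Z_p − d′_l Y_l    (RBP)
   dZ_p/ds = Σ_{q≠p} g_pq Z_p Z_q                    − d″_p Z_p    (TF)
   ```

   Each node's derivative is regressed on the product terms its equation
   allows; a Bayesian Lasso Gibbs sampler (Laplace shrinkage prior) yields
   posterior coefficients, and an edge is called when its 90% credible
   interval excludes zero. The layer hierarchy is structural: forbidden
   couplings never enter a design matrix.
4. **Target control** — the called network defines dx/dt = Ax + Bu, y = Cx
   with AS events as outputs (targets O) and TFs as allowed inputs (U). A
   driver set K ⊆ U is feasible when rank [CB, CAB, …, CA^(N−1)B] = |O|
   (checked generically by random instantiation of the edge pattern).
   Branch-and-bound finds a minimum K; sampling over all alternative optimal
   sets gives each TF a control frequency, and TFs above 0.5 are reported as
   key regulators.

A seeded synthetic benchmark (the same mass-action system forward-simulated,
shuffled and optionally corrupted by multiplicative noise) validates every
stage against ground truth.

## Worked example

```bash
python examples/02_infer_regulatory_network.py
```

```
candidate edges: 49  (all layer-allowed pairs)
called edges:    27  (90% credible interval excludes 0)
true edges:      21
ROC AUC of |posterior mean| vs truth: 0.889

strongest five called edges (sign +1 activating, -1 repressive):
    TF2 -> RBP1  coef=+1.202 sign=+1
    AS5 -> AS4   coef=-1.138 sign=-1
    AS2 -> AS3   coef=+1.040 sign=+1
    AS3 -> AS2   coef=+0.986 sign=+1
   RBP1 -> RBP2  coef=-0.955 sign=-1
```

A panel of 2 TFs, 3 RBPs and 5 AS events was simulated over 100 shuffled
samples; after pseudotime recovery (Spearman ρ = 1.000 against the hidden
time axis, see `examples/01_…`), the Bayesian Lasso ranks the 49 candidate
couplings so that true edges score far above absent ones (AUC 0.889), and
the signs of the strongest calls match the generating coefficients. The
other examples show pseudotime recovery, driver-TF ranking
(`examples/03_…` prints the minimum driver set and per-TF control
frequencies) and the noise-robustness sweep.

The same stages are available as a CLI for file-based work:

```bash
splicecontrol simulate --seed 3 --out panel/
splicecontrol pseudotime --tf-matrix panel/tf_matrix.tsv --labels panel/phenotype.tsv --out scores.tsv
splicecontrol infer --panel panel/ --scores scores.tsv --out edges.tsv
splicecontrol control --edges edges.tsv --targets targets.txt --constraints tfs.txt --out control.json
splicecontrol run --seed 7 --out run/        # full pipeline + report.json
```

## Layout

```
src/splicecontrol/   io, simulate, pseudotime, trends, netinfer, control,
                     metrics, pipeline, cli
examples/            one short narrative script per capability
tests/               unit, property and acceptance suites
docs/methods.md      model, assumptions, parameter choices, limitations
```
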