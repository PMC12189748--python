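# gexgan

Graph-informed adversarial synthesis of gene expression data.

Transcriptomic studies are chronically short of shareable samples: acquisition
is expensive, cohorts are imbalanced, and privacy rules restrict distribution.
Generative models can fill the gap with synthetic expression profiles, but
generators that treat genes as unstructured feature vectors routinely lose the
thing that makes expression data biological — the dependency structure among
genes. `gexgan` is for computational biologists and ML researchers who want to
train, evaluate, and stress-test a generator that injects that structure as a
prior.

## The method

The core model is a conditional Wasserstein GAN with gradient penalty whose
generator performs message passing over a prior gene graph G = (V, E): a gene
co-expression network (undirected, edges where |pearson(g_i, g_j)| ≥ 0.8/0.9)
or a signed regulatory network (directed, +1 activation / −1 repression). A
latent draw z ~ N(0, I) concatenated with learned covariate embeddings is
mapped to one scalar per gene, h0 = σ(W_I [z, c] + b_I), and L = 4 rounds of
message passing refine the node values into a synthetic profile:

* GraphConv update: h_i ← σ(h_i W1 + Σ_{j∈N(i)} A_{j,i} h_j W2)
* heterophily-aware update: degree-normalized 1-hop and 2-hop aggregates,
  concatenated per layer with the ego embedding kept separate, plus a readout
  over all intermediate representations — appropriate for regulatory graphs,
  where a repressor and its target are dissimilar by design.

An MLP critic scores samples; training minimizes the WGAN-GP objective

    E[D(G(z|c))] − E[D(x|c)] + λ E[(‖∇_x̂ D(x̂)‖₂ − 1)²]

with λ = 10, Adam(1e-4, β₁=0.5, β₂=0.9), batch 32. Baselines (plain GAN,
graph-free WGAN-GP, CVAE), graph builders, a linear-SEM simulator with
planted signed networks, and the full evaluation suite (manifold
precision/recall at t = 10, gene–gene correlation preservation,
real-vs-synthetic detectability in full and PC space, TSTR utility, per-gene
KS and 2-Wasserstein statistics) are included. The networks run on a small
built-in numpy autodiff engine with second-order gradients for the penalty
term. See `docs/methods.md` for conventions and design choices.

## Worked example

`examples/02_train_graph_generator.py` trains the graph-informed generator
and the graph-free WGAN-GP baseline on a simulated 50-gene / 500-sample study
with a planted signed regulatory network (200 epochs, desk-scale learning
rate), then scores 350 generated samples:

```
graph-informed  precision 0.920  recall 0.926  correlation 0.922  (final W estimate +0.248)
graph-free      precision 0.934  recall 0.714  correlation 0.806  (final W estimate +0.078)
```

Precision is the fraction of synthetic samples inside the real data manifold
(union of 10th-nearest-neighbor spheres), recall the fraction of real samples
covered by the synthetic manifold, and correlation the Pearson agreement
between the two gene–gene correlation matrices. The graph prior buys ~0.2 of
recall and ~0.1 of correlation preservation at comparable precision — the
generator covers the data modes instead of collapsing onto the easy ones, and
it reproduces pairwise gene structure the dense baseline loses.

The other examples show graph construction and planted-edge recovery (`01`),
the full evaluation report with TSTR utility (`03`), and the
high-precision/zero-recall mode-collapse signature (`04`). Each prints a
short interpretation with its numbers.

## Command line

The same pipeline is available as a CLI:

```
gexgan simulate --profile small --out study/
gexgan build-graph --expression study/expression.tsv --threshold 0.8 --out graph/
gexgan train --expression study/expression.tsv --covariates study/covariates.tsv \
             --graph study/ --model graph_wgan_gp --epochs 200 --out run/
gexgan generate --checkpoint run/final --n 350 \
                --training-covariates study/covariates.tsv --out synthetic.tsv
gexgan evaluate --real study/expression.tsv --synthetic synthetic.tsv --out eval/
```

Every command writes a resolved-config JSON next to its outputs and never
mutates its inputs.

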