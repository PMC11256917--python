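# Methods

## Model

The classifier maps a drug graph and a protein graph to an interaction
probability in four stages.

**Graph construction.** Drug graphs come from SMILES via RDKit: one node
per heavy atom with nine categorical attributes (element ≤ 100, chirality,
degree, formal charge, attached-H count, radical electrons, hybridization
∈ {sp, sp², sp³, sp³d, sp³d², other}, aromaticity, ring membership), one
edge per bond with four attributes (type, direction, stereochemistry,
conjugation); out-of-vocabulary values map to a final "other" slot.  Protein
graphs come from PDB files via Biopython: nodes are polymer residues (20
canonical types + unknown) of the first model, all chains concatenated in
file order; edges are within-chain sequence-adjacent pairs plus pairs with
Cα–Cα distance strictly below a cutoff (default 8 Å, configurable), with
contacts allowed across chains.  Residues lacking a Cα keep their node but
contribute no contact edges.  Pocket annotations, when supplied, are stored
as a binary per-residue attribute; they never enter the model and exist only
so interpretability can be scored against them.

**Tokenization.** Categorical indices are embedded (attribute embeddings
summed for drugs) and refined by a stack of single-head graph-attention
layers, each wrapped in a residual addition so that zeroed attention weights
reduce the stack to the identity — the guard against over-smoothing tiny
molecules.  A DiffPool step then forms substructure tokens: S =
softmax(XW), T = SᵀX, A′ = SᵀAS.  Drugs are pooled once to 8 tokens;
proteins pass through a cascade of strictly decreasing scales (default
1024/512/256/128), message passing running only before the first pooling.
Any scale larger than the current graph is clamped to it, so short proteins
degrade gracefully (consecutive equal effective scales become learned
square refinements).  The optional DiffPool auxiliary terms (link
reconstruction ‖A − SSᵀ‖²/N² and assignment entropy) are added with weight
10⁻³ by default and can be switched off.

**Election.** At every protein scale an independent selector computes
scaled-dot-product cross attention of protein tokens (queries) over drug
tokens (keys/values), multiplies the attended context element-wise into the
protein tokens, scores each modulated token with a two-layer network, and
softmaxes the scores across tokens.  The top ceil(k%·T) tokens are elected
(k = 30 by default; ties to the lower index; at least one).  Election is
hard and non-differentiable, so a straight-through correction keeps the
score network trainable: the forward value of an elected token is exactly
the token, while its backward value carries the relevance weight; the stage
vector additionally retains the softmax-weighted sum over *all* tokens in
the computation graph (value-neutral at the forward pass), so every token's
score receives gradient and election can in principle migrate to better
tokens rather than only reinforcing the initial draw.  Elected tokens are
summed into per-scale stage vectors and stacked across scales into the
protein representation.

**Decoding and head.** Drug tokens (projected 80→256 by default) attend to
the stacked protein tokens through a post-norm transformer decoder (3
layers, 8 heads, no positional encodings, no causal mask — token sets are
unordered, and permuting protein tokens provably leaves the output
unchanged).  The decoder output F is normalized by a softmax over all its
entries into weights w, modulated as F′ = w ⊙ F, flattened row-major, and
classified by a one-hidden-layer MLP with a sigmoid.  The softmax axis is
configurable (`global` default, `row` alternative) because the single-index
normalization admits both readings; drugs smaller than the token count
produce fewer decoder rows, and the flattened feature is zero-padded to the
fixed head width.

**Loss and optimization.** L = BCE + w·CL/B with w = 0.01, where CL =
Σᵢ yᵢ‖v_d,i − v_p,i‖² is summed over the batch (B) and averaged over protein
scales; dividing by B keeps w meaningful at any batch size.  By default only
interacting pairs are penalized (`positives_only`); `all_pairs` exists for
the corresponding ablation.  Training uses Adam at lr 0.001 with the
exponential schedule lr_e = 0.001·0.9ᵉ, batch 128, early stopping on
validation AUROC (patience 10, max 100 epochs by default), and restores the
best-validation weights.  Every random choice — initialization, shuffling,
noise, random election — derives from the config seed, so runs are bitwise
reproducible on one machine.

**Batching.** Graphs are grouped by their clamped token-count signature
(drug token count, effective protein scales), padded within the group, and
masked: padded nodes keep only a self-loop in attention and are zeroed out
of the pooling assignment, so a pair's score is independent of how the pair
list is partitioned into batches.

## Parameter choices that matter

| parameter | default | why |
| --- | --- | --- |
| hidden dim | 80 | token width of the extraction stage |
| GAT layers | 3 | enough mixing without over-smoothing |
| drug tokens | 8 | fixed micro-molecule scale |
| protein scales | 1024/512/256/128 | macro-molecule cascade |
| top-k % | 30 | fraction of tokens elected per scale |
| decoder | 3 layers, 8 heads, 256 hidden | interaction decoding capacity |
| CL weight w | 0.01 | balances similarity constraint vs BCE |
| lr, decay, batch | 0.001, 0.9/epoch, 128 | optimization defaults |
| contact cutoff | 8 Å | standard residue-contact radius |
| embedding init | uniform ±0.15 | see below |

Embedding tables are initialized uniform ±0.15 rather than Glorot.  Node
features are summed twice — across attribute tables and across soft clusters
during pooling — so Glorot-scale entries make token sums, and hence the
squared-distance complementary loss, start in the hundreds; the small scale
keeps stage vectors O(1) at initialization, which both stabilizes the loss
balance and lets the similarity constraint actually close.  All weight
matrices are Glorot-uniform; single-head GAT attention uses node features
only (a config flag could add bond terms; bond attributes are parsed and
stored but do not enter attention by default, the smallest reading of the
featurization).

## Synthetic benchmark

The generator emulates the two graph kinds end to end.  Drugs are random
connected atom-graphs (spanning tree + shortcuts, 10–24 atoms) with valid
categorical features; they are *feature-valid, not chemically valid* — no
valence model is enforced, and none is needed to exercise the pipeline.
Proteins are compact 3-D Cα walks (3.8 Å steps confined near the origin,
48–72 residues by default) whose contact graph at 8 Å mixes short- and
long-range edges like a folded chain; edges are derived from the
coordinates, so they are consistent with them by construction.

The planted signal is a two-entry motif library: drug motifs are 4-atom
paths of boron/silicon or selenium/phosphorus; protein motifs are 12-residue
TRP/CYS or HIS/MET runs, both alphabets disjoint from the host distributions.
80% of molecules carry one motif; a pair is labelled interacting exactly
when the two motifs come from the same library entry, and labels are flipped
independently with probability 0.05.  Because the label is a function of the
*combination*, a model must relate substructures across the pair — marginal
memorization of either molecule cannot solve the task, which is what makes
the benchmark a real test of interaction decoding (and makes the
decoder-free ablation measurably worse).  Planted residues populate
`pocket_labels` and the site table, giving an exact target for the
interpretability evaluation.

What passing these tests does *not* show: performance on real chemistry
(realistic motif statistics, conformational effects, binding physics),
robustness to PDB pathologies beyond missing Cα atoms, or transfer across
protein families.  The synthetic study validates mechanics — extraction,
election, decoding, backtracking, optimization — not chemical accuracy.

## Study sizes used by the tests and the acceptance script

Training studies run at reduced widths chosen once for desk-scale CPU:
hidden 32, protein scales 64/32/16/8, decoder 64, head 64, float32
arithmetic.  The planted-signal study uses 2000 pairs (80 drugs × 60
proteins), an 80/20 train/test split with 12.5% of train held out for
validation, 15 epochs max with patience 4, three seeds, for the full model
and the `no_mmsid` / `no_topk` ablations.  The overfit sanity run uses 64
noise-free pairs of smaller molecules (16–24 residues, 8–14 atoms),
single-pair batches for 120 epochs, pooling regularizers off — it checks
that the optimizer can drive the core loss (BCE + w·CL) to ~0 on memorizable
data, which regularizer floors would otherwise mask.  Binding-site
enrichment compares elected-token residues at the finest scale (scale 0, the
largest cluster count) against planted sites over up to 40 positive held-out
pairs with a 499-draw permutation null.

## Numerical and degenerate-input policy

- Probabilities come from logits through a clipped sigmoid; BCE is computed
  in the numerically stable logit form.
- Softmax is always max-shifted; masked attention uses an additive −10⁹,
  which underflows to exact zeros after the shift, making padding exact.
- Ties: token election breaks toward the lower index (stable sort); hard
  backtracking uses argmax, which also prefers the lower cluster index.
- Fractional election counts round up and never drop below one token.
- Single-class metric inputs give NaN for rank metrics (undefined, not 0).
- Empty graphs, unparseable SMILES, non-binary labels and unresolvable ids
  raise typed errors naming the offending input or row.

## Known limitations

Interpretability at desk scale is the least robust property.  In short
reduced-width training runs the selection scores remain close to uniform —
their only gradient sources are the straight-through terms and the weakly
weighted (w = 0.01) complementary loss — so which tokens are elected is
shaped more by the learned pooling assignments than by score separation.
Binding-site enrichment of the elected residues is significant under the
study conditions the test suite fixes, but it varies with the generator and
model seeds; treat the desk-scale enrichment result as evidence that the
backtracking machinery works end to end, not as a general guarantee that
short training runs localize binding sites.  Further limitations:

- Dense adjacency everywhere: memory grows as N² per graph; proteins beyond
  a few thousand residues would need a sparse path.
- The CPU autodiff engine favours clarity over throughput; batched float32
  training covers the desk-scale studies but is orders of magnitude from a
  GPU stack.
- Single-head GAT and node-feature-only attention are the minimal reading;
  bond-feature attention terms and multi-head GAT are natural extensions.
- Hard election is straight-through; no Gumbel or annealed-k relaxation.
- mmCIF input, 3-D drug conformers, and protonation states are out of scope.
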