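# bsdti — binding-site-aware drug–target interaction prediction

`bsdti` predicts whether a small molecule interacts with a protein (a binary
drug–target interaction, DTI) from the two molecular graphs alone, and
points at the protein substructure — the putative binding site — that drove
the prediction.  It is aimed at computational chemists and method developers
who want an interpretable, substructure-level DTI classifier that runs on
plain CPU, plus a fully synthetic benchmark generator for testing such
models without downloading external data.

## The model

Drugs and targets differ in molecular size by orders of magnitude; treating
them at one common scale blurs exactly the local structure that binds.  The
model therefore works at *differential* scales:

- **Graphs.** A drug is an atom graph G_d built from SMILES (categorical
  atom/bond attributes); a protein is a residue graph G_p built from a PDB
  file (residue-type nodes; edges = chain adjacency ∪ Cα contacts < 8 Å).
- **Tokenization (MSGN).** A stack of residually connected graph-attention
  layers, f⁽ⁱ⁺¹⁾ = GATᵢ(G, f⁽ⁱ⁾) + f⁽ⁱ⁾, updates node features; DiffPool
  then compresses the graph into substructure tokens T = S᷀ᵀf with a learned
  soft assignment S.  Drugs get a fixed 8 tokens; proteins a cascade of
  scales [1024, 512, 256, 128] by repeated pooling.
- **Election (CASS).** At every protein scale, cross attention (queries =
  protein tokens, keys/values = drug tokens) modulates the protein tokens,
  a scoring network softmaxes them into a relevance distribution S′, and the
  top k% = 30% of tokens are elected.  Elected tokens of all scales are
  stacked into the protein representation T_P.
- **Decoding (MMSID).** A 3-layer, 8-head transformer decoder (drug tokens
  attending to T_P, no positions, no causal mask) produces the interaction
  feature F; w = softmax(F) over all entries, F′ = w ⊙ F, and a one-hidden-
  layer MLP on flatten(F′) yields ŷ = P(interaction).
- **Loss.** L = BCE + w·CL with w = 0.01, where the complementary loss
  CL = Σᵢ yᵢ·‖v_d,i − v_p,i‖² pulls the summed drug and elected-protein
  stage vectors together on interacting pairs only.
- **Interpretability.** Composing the argmax of the pooling assignments maps
  any token back to its residues; the residues behind the elected tokens are
  the model's binding-site hypothesis, exportable as CSV and UCSF-Chimera
  `defattr` annotations.

Because no GPU stack is assumed, the package carries its own small
reverse-mode autodiff engine on NumPy (`bsdti._tensor`, `bsdti._nn`) —
layers, Adam, and the exponential schedule lr_e = 0.001·0.9ᵉ are all inside
and fully seeded.

## Worked example

```bash
python examples/train_predict.py
```

trains on 1000 synthetic pairs with a planted motif-matching rule (a pair
interacts iff drug and protein carry motifs from the same library entry —
neither molecule alone is informative) and prints:

```
 epoch       lr  train_loss  train_auroc  val_auroc  val_auprc  val_bce
    12 0.000282    0.409884     0.961441   0.898583   0.875461 0.345838
    13 0.000254    0.381240     0.966210   0.897194   0.866923 0.347229
    14 0.000229    0.368650     0.968901   0.901084   0.874985 0.347206

held-out AUROC 0.944  AUPRC 0.962  F1 0.942  MCC 0.882
early recognition: RE 0.5% = 54.2, RE 5% = 18.5
drug_id protein_id  label  probability  prediction
  D0032      P0018      1     0.950699           1
  D0021      P0045      0     0.047936           0
```

Held-out AUROC well above 0.5 means the model recovered the planted
interaction rule from graph structure; the RE columns are ROC enrichment
(TPR at a small FPR divided by that FPR), the early-recognition statistic
used in virtual screening.  `examples/explain_binding_site.py` continues
this run and shows the elected residues overlapping the planted site.

Other entry points: `examples/build_graphs.py` (SMILES/PDB ingestion),
`examples/simulate_dataset.py` (the generator), and a CLI —
`bsdti simulate|train|predict|explain` — for shell use; run directories
hold a config snapshot, seed, metrics CSV and weights.

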