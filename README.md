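# gofuse

Protein function prediction from sequence **and** structure, with
residue-level interpretability. `gofuse` assigns Gene Ontology (GO) term
probabilities to a protein chain by fusing two views of the molecule:

* a **sequence view** — per-residue language-model embeddings
  M ∈ ℝ^{L×1280} passed through gated multiscale convolutions (kernels
  3/5/7, GLU gating) and a DCT-based frequency-domain channel attention,
  giving X ∈ ℝ^{L×512};
* a **structure view** — the CA–CA contact graph (edge iff distance < 10 Å)
  encoded by a 3-layer GCN and a 3-layer GAT in parallel, concatenated to
  Y ∈ ℝ^{L×512}.

The two views interact through bidirectional two-head cross-attention
(queries from one modality, keys/values from the other:
softmax(QKᵀ/√d_k)V per head and direction), are pooled over residues, and a
linear layer with sigmoid produces per-term probabilities. Evaluation
follows the CAFA conventions — protein-centric **Fmax**, information-content
weighted **Smin**, micro-**AUPR** — and the retained cross-attention weights
yield per-residue saliency scores that can be validated against binding-site
annotations by ROC AUC.

The package is aimed at method developers and computational biologists who
want a fully inspectable, CPU-runnable implementation of this
sequence+structure fusion architecture: every numeric kernel (GCN/GAT
message passing, DCT attention, cross-attention, the CAFA metrics) is
implemented in numpy/scipy on a small built-in autodiff engine and verified
against brute-force oracles, and a deterministic synthetic data generator
makes the entire pipeline testable without downloading structures, ontology
releases, or language-model weights.

## Worked example

`examples/train_and_explain.py` generates a miniature planted dataset
(20 proteins, 4 leaf terms), trains for five epochs, and evaluates:

```text
trained 5 epochs (best validation loss at epoch 5)
held-out Fmax = 0.911 at threshold 0.16
held-out Smin = 0.895   AUPR = 0.918
saliency AUC vs planted binding sites over 3 held-out proteins: mean 0.843
```

Fmax is the best harmonic mean of protein-centric precision and recall over
a score-threshold sweep; Smin measures the remaining IC-weighted semantic
distance between predicted and true term sets (0 is perfect); the saliency
AUC asks whether residues receiving high cross-attention coincide with the
planted binding-site residues (0.5 is chance). `examples/contact_map.py` and
`examples/ontology_ic.py` demonstrate the structural and ontology primitives
on their own.

The same pipeline is available as a CLI for shell use:

```bash
gofuse make-synthetic --n 40 --seed 1 --out data/
gofuse train --data data/ --lr 3e-4 --batch-size 8 --epochs 20 --out run/
gofuse evaluate --model run/model.npz --data data/ --out run/eval.json
gofuse explain --model run/model.npz --data data/ --protein syn0003 --out run/
```

`explain` writes a per-residue saliency TSV and a copy of the protein's PDB
file with saliency stamped into the B-factor column for structure viewers.
Real inputs drop in the same way: `build-graph` parses PDB/mmCIF chains and
`embed`/precomputed HDF5 matrices supply the L×1280 embeddings.

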