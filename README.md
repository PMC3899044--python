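# parsimotif

De novo discovery of DNA binding motifs **with intra-motif dependencies**,
built around inhomogeneous parsimonious Markov models learned inside a
ZOOPS mixture by MAP-EM — the model class used to show that the human
insulator protein CTCF's ~20-bp core motif is poorly described by
independent nucleotide frequencies, especially at its 3′ end.

## Who this is for

Regulatory genomicists who have ChIP-seq-derived positive and control
sequence sets (or want matched synthetic benchmarks) and ask: *does
modelling dependencies between neighbouring motif positions improve motif
discovery, where do those dependencies live, and what do they look like?*

## The model

A sequence either contains no binding site (probability 1 − γ) and is
emitted by a homogeneous order-2 flanking Markov model λ, or it contains
exactly one site of width W = 20 at a uniform start ℓ on either strand
(ZOOPS).  The site is emitted by an **inhomogeneous parsimonious Markov
model**: one *parsimonious context tree* (PCT) per position i, of depth
min(i − 1, 4).  A PCT partitions the context alphabet at every layer; its
leaves carry Dirichlet-smoothed conditional distributions
θ.  One leaf per tree ⇒ PWM; complete trees ⇒ full order-4 inhomogeneous
Markov model; the structure prior ∝ κ^{#leaves} (exposed as log₂ κ)
interpolates between them.  Structures are learned by an exact
dynamic program over alphabet set-partitions maximizing

  Σ_leaves log DirMult(N_leaf | α_leaf) + L(τ)·ln κ,

and the whole model (θ, γ and the tree structures) is fitted by a
monotone MAP-EM.  Discovered motifs are then used for threshold-based
site prediction, and predicted sites are characterized by order-k mutual
information (G-test, χ² with (4−1)(4^k−1) df) and *conditional sequence
logos* aligned to the PCT leaves.

See `docs/methods.md` for the full account.

## Worked example

```python
from parsimotif import MotifDiscovery, make_benchmark, train_background
from parsimotif.simulate import BenchmarkConfig

# synthetic benchmark: planted CTCF-like motif with 3' dependencies
dataset, truth = make_benchmark(BenchmarkConfig(n_pos=300, n_neg=600), seed=11)
train_pos = dataset.subset("positive", "train")
train_neg = dataset.subset("negative", "train")

bg = train_background(train_pos, train_neg, order=2)  # background = flanking
result = MotifDiscovery(train_pos, width=20, max_order=4,
                        log2_kappa=-4.5, flanking=bg).fit(restarts=2, seed=7)
print(result.summary())
```

prints

```
ZOOPS motif discovery results
==============================================
sequences:            200
motif width:          20
max context order:    4
log2 kappa:           -4.5
ess:                  4
gamma (occurrence):   0.9178
strand prob (fwd):    0.5
total PCT leaves:     74
EM restarts:          2 (best: #0)
EM iterations:        25 (converged)
log joint posterior:  -142708.602
----------------------------------------------
leaves per position:  1 2 2 1 3 2 3 3 2 2 2 1 1 2 5 4 6 11 11 10
```

Reading it: the EM estimates that ~92% of the training sequences contain a
site (γ; the generator planted sites in 90%).  The motif needs only 74
leaves instead of the 4,181 of a full order-4 model — position 1 has a
single leaf by construction, the conserved core positions keep 1–3 leaves
(barely any context dependence), while the unconserved 3′ positions 17–20
grow the deepest trees (6–11 leaves): exactly where the generator planted
its strong dependencies.  Scoring the held-out split with this model
against the background gives a sensitivity of 0.72 at 99% specificity
(`sensitivity_at_specificity`), versus 0.67 for the PWM limit
(`log2_kappa=-1000`) at these sizes.

Downstream, `result.predict_sites(test_pos, test_neg, alpha=1e-4)` returns
individual site calls, and `parsimotif.stats.mi_profile` /
`conditional_logo` quantify and visualize where the dependencies live.

The same stages are available as a CLI:
`parsimotif simulate | prep | discover | classify | cv-kappa | predict |
stats | experiment-{cv,test,sites}`.

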