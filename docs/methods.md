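# Methods

## Scope and data model

`tsppi` implements the computational core of a tissue/tumor-specific
protein-interaction analysis pipeline as a reusable library:

1. **Integration.** Several interaction datasets (gene pairs, optionally
   weighted in [0, 1]) are merged into one *global gene-interaction
   network* by edge union.  Each edge records the weight reported by
   every dataset, the average weight over reporting datasets, and the
   *dataset coverage* — the fraction of integrated datasets reporting
   the edge.  Several expression matrices (genes × tissues/tumors) are
   normalized independently and combined into one positive *expression
   score* per (gene, condition), the mean of the normalized values over
   the datasets reporting that pair.
2. **TS-PPI construction.** A tissue-specific PPI network for condition
   c is the subgraph of the global network induced by the genes with an
   expression score in c, so both endpoints of every retained edge are
   expressed there.  Node weights are expression scores; edges keep
   their average weight and coverage.  Optional filters restrict the
   gene list, the contributing datasets, and apply inclusive (≥)
   thresholds on expression score, edge weight and coverage.
3. **Differential local alignment.** Given N TS-PPI networks, a
   stochastic seed-and-extend search extracts sets of conserved
   connected subnetworks, one per network, whose aligned genes maximize
   cross-network expression divergence.

## The divergence score

For genes A, B with expression scores Expr(A), Expr(B):

    LogFold(A, B) = | log2( Expr(A) / Expr(B) ) |

For an alignment column G = {G_1, …, G_N} (one gene per network):

    MaxLogFold(G) = max over pairs (G_i, G_j) of LogFold(G_i, G_j)
                  = LogFold(max weight, min weight)

An alignment A = {A_1, …, A_w} of w columns is summarized by the average
of MaxLogFold over its columns and by the *Index of Structural
Conservation*

    ISC = (# column pairs whose edge exists in all N networks)
          / (# column pairs whose edge exists in ≥ 1 network),

with 0/0 defined as 0.  ISC ranks alignments (higher is better), with
ties broken by average MaxLogFold, then size, then a lexicographic key
on member labels so the total order is deterministic.

## The stochastic search

Two nodes of different networks may be aligned when they are homologs.
The default scheme is **label identity** (same gene symbol, score 1.0);
alternatively a homology file assigns explicit positive scores to
cross-network node pairs.  Many-to-many mappings are never produced: a
node joins at most one column.

A candidate column is scored by

    similarity(G) = (ε + MaxLogFold(G)) · hom(G) · topo(G)

where `hom` is the mean pairwise homology score and `topo` is 1 plus the
number of already-aligned columns connected to G by an edge present in
every network.  The ε guard (default 0.01) keeps equal-expression
columns sampleable; raw MaxLogFold (no ε) is used for thresholding,
removal and reporting.  Expression values at or below 1e-6 are clamped
before ratios so degenerate scores cannot produce infinities.

**Bootstrap.** Seed candidates are nodes with homologs in every network
and degree ≥ σ.  A Gibbs chain over candidate columns starts from a
uniformly random column and repeatedly re-draws the member of one
randomly chosen network proportionally to similarity.  Under label
identity a column is determined by its shared label, so a member
replacement re-snaps the entire column — each move is a block redraw;
with a homology table the move is the strict single-site update.  The
chain is considered converged when the state is unchanged for

    k = max k' : ((N−1)/N)^k' > α

consecutive iterations — the longest run for which the probability that
some network was never re-sampled still exceeds α (strict inequality;
smaller α means a longer, more careful chain).  When the similarity
distribution is diffuse this stopping event can be astronomically rare,
so a hard cap of `max_gibbs_iterations` (default 50·k) ends the chain at
its current state; because the per-move distribution is unchanged while
the alignment is fixed, the cap does not bias which column is returned.

**Iterative phase.** `refine_iterations` rounds of extension followed by
one removal, plus a final extension.  Extension repeatedly Gibbs-samples
one column whose member in each network is an unused neighbor of that
network's aligned subgraph, and accepts it only while the alignment's
*average* MaxLogFold stays at or above `max_logfold_threshold`; the
first rejection (or an exhausted frontier) ends the extension, so
per-network connectivity holds by construction.  Removal deletes the
column with minimal MaxLogFold, skipping columns whose deletion would
disconnect any per-network subnetwork (the output contract requires
connected subnetworks) and breaking ties lexicographically.

**Post-processing.** `attempts` independent seeded runs are collected;
alignments below `min_alignment_size` are dropped, the rest are ranked,
and a greedy sweep keeps an alignment only if its average per-network
node overlap, |A ∩ B| / min(|A|, |B|) averaged over networks, with every
previously kept alignment is ≤ `overlap_threshold`.

### A consequence of the average-based acceptance rule

Because extension gates on the *average* MaxLogFold, a strong core of
w_p columns at fold δ tolerates roughly

    m ≈ w_p (δ − t) / (t − f̄_bg)

additional background columns (background mean fold f̄_bg) before the
average drops to the threshold t.  On data where a divergent module sits
in a weakly divergent neighborhood the reported alignments therefore
recover the module completely (high recall) but pad it with adjacent
background genes until the average sits just above t (modest precision).
The `evaluate` command and `tsppi.score_recovery` report precision,
recall and F1 separately so this behavior is visible; raising
`max_logfold_threshold` or post-filtering columns by their individual
fold tightens the output.  An alternative per-column acceptance rule
(accept only columns whose own MaxLogFold exceeds the threshold) would
invert this trade-off, but the average rule is the method's definition
and is what this package implements.

## Parameters

| name | default | meaning |
|---|---|---|
| `sigma` | 1 | minimum degree of seed candidates |
| `alpha` | 0.05 | Gibbs convergence probability threshold; sets k (k=4 for N=2, k=10 for N=4) |
| `overlap_threshold` | 0.5 | maximum average node overlap between kept alignments |
| `refine_iterations` | 10 | extension+removal rounds per attempt |
| `min_alignment_size` | 3 | smallest reported alignment |
| `max_logfold_threshold` | 0.6 | minimum average MaxLogFold maintained during extension; for log-scale expression data values in 0.2–1 are sensible |
| `attempts` | 50 | independent seeded runs pooled before ranking (package addition) |
| `epsilon` | 0.01 | similarity guard added to MaxLogFold during sampling (package addition) |
| `max_gibbs_iterations` | 50·k | hard cap on one Gibbs chain (package addition) |
| `seed` | 0 | single RNG threaded through all stochastic steps |

Integration conventions: an unweighted dataset contributes weight 1.0 to
an edge's average (the "certain interaction" reading — also the only
convention under which merged averages can reach 1.0 for edges reported
solely by unweighted sources); the log2 transform uses a pseudo-count
offset of 1.0 by default; quantile normalization follows the sorted-mean
construction with ties receiving the mean of the rank means they span,
which makes the procedure idempotent; datasets that are already
normalized are passed through untouched.

## Synthetic instances

`tsppi.synthetic.generate` emulates the target use case — N conditions
(e.g. a normal tissue and several tumor grades) sharing one interactome
— with exact ground truth.  A single backbone graph (Barabási–Albert
scale-free by default, attachment 2, n = 300 genes; optionally
Erdős–Rényi) is shared by all networks, so label-identity homology holds
and every aligned interaction is conserved (ISC of any alignment on such
instances is 1).  A connected planted module (default 8 genes) receives
per-network log2 offsets from a base expression of 8.0: one network at
+δ/2, one at −δ/2 (δ = 2 by default), the rest uniform in between;
Gaussian noise (sd 0.05 in log2 space) is added and then re-clamped so
the planted pairwise MaxLogFold ≥ δ is guaranteed, not merely likely.
Background genes get offsets clipped to ±`background_fold_max`/2
(default 0.15), bounding their column folds by 0.3.  Edge weights are
uniform in [0.5, 1].  Because the guarantees are enforced by
construction, recovery experiments are deterministic at the generator
level and never flaky.

What the generator does **not** emulate: probe-level microarray noise,
batch effects, missing genes (every network shares the full node set),
divergent interactomes across conditions (so ISC is uninformative on
these instances), and correlated expression between neighboring genes.
Passing recovery tests therefore demonstrate the search mechanics, not
robustness to real-data artifacts.

## Numerical choices and degenerate inputs

- Threshold comparisons are inclusive (≥) everywhere.
- Tie-breaks (removal order, ranking, candidate enumeration) are
  lexicographic on gene labels, making runs with a fixed seed
  byte-reproducible, including written report files.
- Multi-edges in uploaded TS-PPI files collapse to one edge with the
  mean weight and `;`-joined tissue labels; self-loops are dropped with
  a warning; a file left empty by these rules is an error.
- A gene appearing in records with inconsistent expression values gets
  their mean, with a warning.
- Equal-weight identical networks yield no alignment at any positive
  fold threshold: seeds of fold 0 can never be extended and size-1
  alignments are discarded.
- Single-column expression matrices pass through quantile normalization
  unchanged (with a warning); missing cells are an error.

## Known limitations

- Gene identifiers are canonicalized only by case and whitespace; alias
  resolution against external nomenclatures is out of scope.
- The tissue/tumor mutual-exclusion rule can only be enforced when the
  caller supplies condition-kind metadata; bare condition names carry no
  kind.
- The homology-file dialect requires explicit network names per node
  (5 columns); a bare 3-column pair list would be ambiguous whenever the
  same symbol appears in more than one network.
- The topology term of the similarity score (1 + conserved attachments)
  is this package's concrete surrogate for "topology and homology
  scores"; it rewards candidates that add conserved edges while keeping
  all sampling probabilities positive.
- Raw CEL-file normalization (RMA) and cross-dataset batch correction
  are external preprocessing; the package consumes already-summarized
  matrices.
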