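# Methods

## Problem and model

Mature miRNA family assignment is hard for alignment-based tools:
sequences are short (~18–25 nt), and a single precursor can yield
matures belonging to different families. `mirnaclust` treats family
discovery as unsupervised clustering of alignment-free sequence
features, scored against curated labels only *after* clustering.

## Feature extraction (GramN)

An n-gram is a length-n contiguous subsequence over {A, C, G, U};
overlapping occurrences all count, so a length-L sequence has
L − n + 1 of them. GramN concatenates per-n frequency blocks for
n = 1..N (dimension Σ 4^n: 340 for Gram4, 1364 for Gram5). Within each
block, counts are divided by their total (L − n + 1 without boosting),
making sequences of different lengths comparable; each block is then
scaled by a block weight and the weights sum to 1, so every row of the
feature matrix sums to 1 exactly.

* **Block weights.** The originating weighted-concentration scheme is
  not recoverable from first principles; the default is uniform
  (1/N per block), which preserves the only hard constraint (row sums
  1) and keeps the weighting auditable. Fully configurable.
* **Seed boosting (off by default).** n-grams lying entirely within
  1-based positions 2–8 (the conventional seed, the target-recognition
  segment) are counted twice before normalization. Empirically the
  seed is not always more conserved than the backbone at the family
  level, so this is an option, not the default.

## Dimension reduction

Feature selection is framed as unsupervised dimension reduction of the
GramN matrix to d columns:

* **LSA** — truncated SVD; returned coordinates are U_d Σ_d, so the
  captured energy equals the top-d spectrum and the residual equals
  the optimal rank-d error. If rank < d, rank columns are returned
  with a warning.
* **LLE** — per-point reconstruction weights over the k nearest
  neighbours solved from the local Gram matrix, regularized with
  ε = 1e-3·trace/k (a standard conditioning fix; the local system is
  always singular when k exceeds the intrinsic dimension). The
  embedding is the bottom d+1 eigenvectors of (I−W)ᵀ(I−W) minus the
  constant one, columns centered.
* **Isomap (default)** — symmetrized k-NN graph, all-pairs shortest
  paths (Dijkstra via scipy.sparse.csgraph), classical MDS on the
  geodesic distance matrix. A disconnected graph is repaired by
  repeatedly adding the single shortest inter-component edge, so every
  sequence stays embedded (clustering needs all rows). Negative MDS
  eigenvalues are clipped to zero.

Defaults: d = 150 for Gram4 (the best-performing dimension in the
accuracy sweep over d = 10..180; 120–160 balances time and accuracy),
140 for Gram5; k = 10 neighbours. The k-NN metric is city-block for
consistency with the clustering metric (the original choice is
unstated; configurable). Eigenvector signs are canonicalized — first
nonzero loading positive — so repeated runs are byte-identical.

## Clustering

K-means with city-block (L1) assignment; city-block consistently
separates these short-sequence profiles better than Euclidean
distance. The centroid update is the coordinate-wise **median** — the
L1-optimal centroid — with `centroid="mean"` available for strict
Lloyd parity (the historical implementation supported both; which was
active is unknowable). Details:

* Initialization: K distinct data points drawn uniformly per restart
  from one seeded generator; 20 restarts by default, lowest final
  objective wins ("best convergence" read quantitatively).
* Empty clusters are re-seeded with the point farthest (L1) from its
  current centroid, keeping K fixed as the sweep semantics require.
* Ties in nearest-centroid assignment go to the lowest cluster index.
* Stop on unchanged assignments, relative objective change < 1e-6, or
  300 iterations. The recorded objective history is non-increasing
  within every restart (assignment and median update each minimize).

**Cluster-number sweep.** With N known families, K takes the 6 values
N + round(i·N/5), i = 0..5 — uniformly spaced over [N, 2N] up to
integer rounding (N = 300 → 300, 360, 420, 480, 540, 600). Small N can
collapse values after rounding; duplicates are dropped with a warning.
The K with the best vote accuracy is reported (ties → smaller K).
Label-free runs require an explicit K list (the unclassified-miRNA
experiment used manually chosen 800/1200).

## Evaluation

* **Vote strategy.** Clusters with fewer than `min_cluster_size`
  members (5 by default; 4 for new-family experiments where real
  families of size 4 exist) are discarded as bad quality; their
  members count as incorrect but stay in the denominator — accuracy is
  n_correct over *all* labeled sequences, the conservative reading.
  Each kept cluster credits its largest known family; families tied
  for largest are all credited (near-identical families co-cluster
  frequently, and penalizing one arbitrarily would be noise). The
  runner-up count is credited iff strictly greater than 1/3 of the
  largest ("exceeds" read as strict); third-largest and beyond are
  never credited. Unclassified sequences never vote and are never
  correct. A family is **dead** when credited in no kept cluster.
* **Weighted F-measure.** For family i and cluster j,
  F_ij = 2·p·r/(p + r) with p = n_ij/|cluster j| (full cluster size,
  unclassified members included) and r = n_ij/|family i|;
  F_i = max_j F_ij; the report value is Σ_i (|family i|/total)·F_i.
* **Cluster typing** for novel-family discovery, per kept cluster:
  *novel* if unclassified members are a strict majority; *mixed* if
  the unclassified group and the largest known family are both present
  with min(group) > 1/3·max(group); *existing* if a known family
  dominates and the unclassified minority is at or below the 1/3
  ratio; everything else — including all members of discarded small
  clusters — tallies as *failed*. The four member tallies partition
  the unclassified sequences exactly. The strict-majority reading of
  "mainly novel" is a documented choice and configurable via the vote
  fraction.

## Synthetic data

The generator emulates a curated family architecture: each family has
a random ancestor (uniform over {A,C,G,U}^L, L uniform in 18–25 nt),
and members are i.i.d. per-site substituted copies (default rate 0.05,
substitution to a uniformly chosen different base). Family sizes come
from a truncated geometric (p = 0.15) on [4, 200], reproducing the
real skew toward small families; fixed sizes are available for
controlled experiments. Ancestors are resampled until no equal-length
pair is within Hamming distance 3, guaranteeing separability at low
rates. Unlabeled families carry the UNCLASSIFIED sentinel in records
while the truth table retains their identity for recovery scoring.
Indels default to 0 (mature-family variation at this scale is mostly
substitution, and indels would blur the planted truth); an
`indel_rate` exists for stress tests.

What a green recovery test does **not** establish: real miRNA families
vary by indels, arm switching, and shared seeds between families;
real family sizes and sequence composition are far from uniform; and
the generator's families are phylogenetically star-shaped. Synthetic
recovery validates the machinery, not database-scale accuracy claims.

## Numerical and design notes

* One top-level seed drives everything; per-K k-means seeds are
  derived as seed + K so sweep arms are independent but reproducible.
* Gram5 is 1364-dimensional (Σ 4^n, n = 1..5); a historical mention of
  1346 is inconsistent with the per-n block sizes and treated as a
  typo.
* Duplicate mature sequences shared by paralogous genes are kept as
  distinct records by id.
* Records containing ambiguity codes (N, R, Y, …) are dropped whole
  under the default input policy rather than skipping individual
  n-grams: a 20-nt sequence with one N would lose a large fraction of
  its n-grams and bias the vector.
* Reports are JSON with sorted keys; assignments are fixed-column TSV;
  both are byte-stable given identical inputs and seeds.

## Known limitations

* Dense all-pairs distance matrices limit Isomap/LLE to datasets of a
  few thousand sequences on one machine.
* The vote strategy needs labels; fully label-free runs report only
  cluster typing against the unclassified sentinel.
* No gapped or positional k-mers and no secondary-structure features;
  n-grams discard position information entirely (larger N partially
  compensates).
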