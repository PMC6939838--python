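# Methods

`eccomp` compresses a collection of n genomic sequences (FASTA records —
chromosomes or whole assemblies) losslessly by choosing, for every
sequence, a *similar* reference from inside the collection itself, instead
of compressing everything against one fixed reference. Reference-based
codecs degrade sharply when target and reference diverge, so reference
choice — not the codec — often dominates the compression ratio of a
database. The pipeline has four stages.

## 1. Sketch distances

Each sequence is reduced to its set of canonical k-mers: every length-k
window consisting only of A/C/G/T after uppercasing, replaced by the
lexicographic minimum of the window and its reverse complement
(canonicalization makes the distance strand-insensitive; windows touching
any other IUPAC code are skipped). K-mers are hashed to 64 bits and the q
smallest distinct values form the bottom-q MinHash sketch. For hash sets
A, B the Jaccard similarity J = |A∩B|/|A∪B| is estimated from sketches as

    J' = |Sk(A∪B, q) ∩ Sk(A, q) ∩ Sk(B, q)| / |Sk(A∪B, q)|

(with the true merged-sketch size as denominator when the union holds
fewer than q values), and converted to a Mash-type distance

    d = −(1/k) · ln( 2J' / (1 + J') ).

The transform diverges as J'→0, so d is capped at d_max = 1.0 and disjoint
sketches are assigned the cap directly; at k = 21 the uncapped value
already approaches 1 for tiny J', so the cap loses nothing that matters to
clustering. Identical sketches return exactly 0 (the j=1 branch returns
the constant, avoiding `log` round-off).

Defaults k = 21, q = 1000 (standard sketching practice for genome-scale
inputs; both configurable). Hashing is a splitmix64 finalizer applied to
the 2-bit packing of the canonical k-mer XOR a seed-derived salt. The
finalizer is a bijection on 64-bit words, so same-length k-mers cannot
collide for k ≤ 31; k > 31 falls back to keyed blake2b. Hash values are
set-valued: a k-mer occurring twice counts once. A sequence with no valid
k-mer gets an empty sketch plus a warning; a pair of empty sketches is
placed at the distance cap by the matrix builder (nothing is known about
either), while the pairwise estimator itself treats that comparison as an
error.

Distances are assembled into the symmetric n×n matrix M (upper triangle
computed, mirrored; diagonal exactly zero). Symmetry and the zero diagonal
are exact by construction, never up to tolerance.

## 2. Cluster-count selection (subtractive clustering)

K is unknown a priori. Subtractive clustering (the mountain method over
the distance matrix) scores each sequence with

    Mt(S_i) = Σ_j exp(−M_ij)

— the self term contributes exp(0) = 1, a constant shift that cannot
change any argmax. The highest-mountain sequence joins the centroid set;
every remaining sequence's mountain is damped by the kernel exp(−M_io) of
the selected centroid o; selection repeats until the best remaining
mountain drops below ε·Mt_max (Mt_max being the round-1 maximum, the
stable reading of the stopping rule) or the centroid count reaches √n.
Hence 1 ≤ K ≤ ⌈√n⌉ always. Already-selected indices are excluded from
later rounds; argmax ties break to the lowest index.

**Choosing ε.** The damping subtracts the *bare* kernel, at most 1 per
round. For g balanced clusters of m members each, once one centroid per
cluster is selected the best remaining mountain is

    Mt_max − w − (g−1)·b  ≈  ((m−1)/m) · Mt_max

(w ≈ 1 the within-cluster kernel, b the between-cluster kernel), a ratio
that is essentially independent of how well separated the clusters are.
Stopping at K = g therefore requires ε > (m−1)/m, while ε must stay below
≈ 1 − (g−1)·b/Mt_max so selection does not stop before every cluster owns
a centroid. The default ε = 0.8 sits in that window for the small-family
regime this package targets (m ≈ 4; window ≈ (0.75, 0.85)); collections
with larger expected cluster sizes need a larger ε. The √n cap also bounds
what is reachable: K = g is only attainable when g ≤ ⌈√n⌉.

## 3. K-medoids refinement and the reference plan

The subtractive centroids seed K-medoids over the same matrix (seeding
deterministically from density peaks avoids the poor local minima of
random initialization). Each iteration (a) assigns every sequence to its
nearest centroid — distance ties to the lowest centroid index, and a
centroid always assigns to itself, so clusters can never empty — then (b)
re-picks each cluster's medoid as the member minimizing the within-cluster
distance sum, ties to the lowest index. The loop stops at a fixed point or
after `max_iter` (default 100) rounds. The cost

    λ = Σ_clusters Σ_members d(member, medoid)

is recorded after every half-step; both half-steps are per-cluster argmins,
so the trace is non-increasing, and the stored cost is computed with the
same per-cluster summation order as the public `clustering_cost`
recomputation, making the self-consistency check exact rather than
approximate. The whole stage is deterministic: identical inputs give
identical partitions.

The same stage is exposed as a scikit-learn-style estimator
(`SubtractiveKMedoids`, `fit`/`fit_predict` on a precomputed distance
matrix, with `labels_`, `medoid_indices_`, `n_clusters_`, `inertia_`), so
it composes with sklearn tooling; the functional API and the estimator
share one implementation.

Each cluster's medoid becomes the reference for its members. A final root
reference R is the medoid of the medoids — argmin over centroids of the
summed distance to the other centroids (zero self-term included; ties to
the lowest index) — and the remaining centroids are compressed against R.
The result is a reference tree of depth ≤ 2 rooted at R with exactly n−1
edges; singleton clusters need no special casing (their medoid simply
points at R). Decompression follows levels: R, then centroids, then
members. Exactly one sequence per archive is stored without a reference,
so the clustered scheme compresses the same number of sequences as a
fixed-reference scheme and comparisons are apples-to-apples.

## 4. Codec and archive

The built-in reference-based codec is a greedy LZ-style parser emitting
MATCH(position, length) and LITERAL tokens — the classic "102 72"
position/length encoding. A hash index of the reference's `index_k`-mers
(default 16, ≤ 64 positions kept per anchor) is probed at each target
position; every candidate is extended maximally forward and backward
(backward extension may consume pending literal characters), the longest
extension wins (ties to the smallest reference position), and a MATCH is
emitted when it reaches `min_match` (default 24) — otherwise the position
joins the pending literal. Adjacent literals cannot occur by construction.
Matching is byte-exact on the raw residues, so case, N runs and any other
characters round-trip; positions are absolute and 0-based. Tokens are
serialized with LEB128 varints and the stream — including the record's
layout metadata and a 16-byte digest of the reference residues — is passed
through a general-purpose byte compressor (stdlib bz2, a block-sorting
codec, by default; zlib selectable). The root sequence is stored through
the same entropy backend without tokenization. The codec claims
losslessness and reasonable behavior, not parity with specialized genome
compressors; for those, `external_backend_export` writes per-cluster
reference/target FASTAs plus a `manifest.tsv` so any external
reference-based tool can follow the same plan.

The `.ecc` archive is a single little-endian file: magic `ECC1`, version,
a bz2-compressed JSON header (parameters, reference plan, per-sequence
digests of the serialized records, payload index) and the concatenated
payloads. Truncation, trailing bytes, version mismatches and payload
corruption are all detected; decompression re-verifies every record
digest and aborts naming the offending sequence. Compression is
deterministic: one configuration and input gives a bit-identical archive.

## Evaluation metric

Compression ratios are "folds": raw input FASTA bytes over archive file
bytes, with the root's payload included in the denominator in both modes.
The gain of the clustered plan over a fixed single reference r is

    G = (1 − C_S / C_E) × 100 %,

reported half-up at 2 decimals, negative if clustering underperforms. The
worst fixed reference (maximum distance-row sum) and best (minimum) are
built in; `evaluate` can also sweep all references.

## Synthetic data

The generator emulates the one property the pipeline depends on: families
of highly similar sequences separated by large between-family distances.
Each family is an i.i.d. uniform A/C/G/T ancestor (independent 10 kb
ancestors share essentially no 21-mers, so between-family distances sit at
the cap) mutated independently per member: per-base substitutions always
changing the base (default rate 0.002), single-base insertions and
deletions (default 5×10⁻⁴ each) that exercise match-breaking in the codec.
Defaults: 3 families × 4 members × 10 kb. Every draw comes from a stream
keyed by (seed, operation, indices), so regenerating one member never
perturbs another and outputs are byte-reproducible.

What the generator does *not* model: repeats, rearrangements, block
indels, rate heterogeneity, N runs, or realistic genome length. Passing
tests therefore demonstrate the algorithmic contracts (recovery of planted
family structure, losslessness, plan superiority over a worst reference)
at desk scale, not field performance on real genome databases, whose
published ratios depend on specialized external codecs and multi-hundred-GB
inputs. Test and acceptance problem sizes (10 kb ancestors, n ≤ 20,
20 replicate seeds) were chosen as the smallest scale at which
between/within distance separation is decisive and runs stay comfortably
interactive.

## Numerical and degenerate-input choices

- All ties anywhere break to the lowest sequence index; no randomness
  exists outside the synthetic generator.
- d(j=0) = d_max = 1.0; d(j=1) = 0 exactly.
- n = 1 skips clustering entirely (the only sequence is the root).
- Sequences shorter than k, or all-ambiguous, produce empty sketches
  (warned); an all-empty pair sits at the distance cap so the pipeline
  still runs and stays lossless.
- Empty residue strings, empty targets and empty references are all legal
  codec inputs.
- Gain reporting rounds half-up to 2 decimals; ratios are reported
  unrounded internally.

## Known limitations

- The greedy parser with a capped-occurrence anchor index can miss optimal
  parses in highly repetitive references.
- ε must be matched to the expected cluster size (see above); there is no
  auto-tuning.
- Only LF-terminated FASTA is supported for byte-exact round-trips.
- Archives provide no random access to individual sequences.
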