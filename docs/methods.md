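# Methods

## The prediction model

`itsfunc` predicts the functional gene content of a fungus from its ITS
amplicon alone. The model rests on one biological assumption: the
functional repertoire of a fungus correlates strongly with that of its
close relatives, and ITS sequence similarity is a usable proxy for
relatedness. Prediction is therefore imputation, not inference: a query's
profile is the average of the profiles of its nearest reference sequences.

Formally, each sequence *s* is mapped to a dense k-mer relative-abundance
vector **v**(s) of length 4^k (default k = 5, so 1024 components): a window
of width k slides over the uppercased sequence with step 1, each
all-ACGT window increments its k-mer's count, and counts are divided by
the number of valid windows. Windows containing any other character
(N, IUPAC ambiguity codes, gaps) are skipped and excluded from the
denominator, so the vector remains a distribution over the informative
windows. The distance between a query and a reference amplicon variant
(RAV) is the cosine distance

    d(u, w) = 1 − (u · w) / (‖u‖‖w‖)

which lies in [0, 1] because k-mer frequencies are non-negative.

Each reference genome *i* carries a gene-content profile
F_i = (f_1^i, …, f_L^i), a vector of function fractions summing to 1
(the published database uses L = 430 third-level KEGG orthology groups;
the package treats L as a property of the supplied table). Neighbor
selection distinguishes five cases:

1. any RAV at distance ≤ 1e-12 → use **all** zero-distance RAVs and only
   them (exact-sequence override), regardless of K and ε;
2. otherwise collect S = {RAVs with d ≤ ε}; if |S| < K use all of S;
3. if |S| = K use S;
4. if |S| > K keep the K closest, breaking distance ties by ascending
   genome ID so output is deterministic and order-independent;
5. if S is empty, emit no prediction (the query is reported as an NA
   column; raising ε is the remedy, at a known cost in quality).

The predicted profile is the unweighted componentwise mean of the chosen
neighbors' profiles; a mean of unit-sum vectors again sums to 1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 5 | k-mer window; fixed per database, query/database mismatch is an error |
| K | 10 | maximum neighbors used |
| ε | 0.5 | cosine-distance search radius (inclusive) |
| zero tolerance | 1e-12 | distances below this count as exact matches |

ε is inclusive and must lie in (0, 1]; ε ≤ 0 is rejected rather than
interpreted. The ε boundary choice matters only on a measure-zero set of
inputs; inclusivity keeps small-ε behavior predictable. Averaging is
unweighted — the defining equation is a plain mean, and distance
weighting would change the estimator.

## Validation machinery

Quality is measured per test sample as the coefficient of determination
R² = 1 − SS_res/SS_tot between the genome's real profile and the predicted
one (SS_tot about the real profile's own mean; R² can be negative and is
undefined for a constant profile). An epoch of shuffle-split
cross-validation draws floor(0.2·N) test genomes without replacement,
predicts each against the remaining training RAVs only, and reports the
*median* R² over predicted samples plus the percentage predicted; ten
epochs by default, all driven by one seed so runs are bit-reproducible.
Unpredicted samples are excluded from the median and accounted for in the
percentage — quality and coverage are deliberately separate numbers,
because they trade off through ε. The ε sweep reuses the same seed at
every grid point so all radii see identical splits.

Highly variable functions are selected by the coefficient of variation
sd/mean across genomes, with the sample (n−1) standard deviation, using
the threshold CV > 10. That threshold, taken as printed, is extreme on the
ratio scale: it essentially selects functions present in a small fraction
of genomes (a function present in 1 of n genomes has CV = √n, so n > 100
is needed). Zero-mean functions have undefined CV and are carried as
non-variable.

The Rand index — the fraction of item pairs on which two partitions agree
(co-clustered in both or separated in both) — is provided as the plain,
unadjusted index computed from the pairwise definition, for comparing any
two labelings a user supplies (e.g. profile clusters vs taxonomy).
Embeddings and clustering algorithms themselves are out of scope.

`groupwise_accuracy` runs leave-one-out prediction over the whole
database (each genome's own RAV removed from the search space) and
reports median R² per user-supplied group, the mechanism for spotting
poorly represented clades.

## The synthetic world

`simulate_reference` builds the smallest world in which the method's
assumption is true by construction. A uniform-random root sequence
(500 bp, ITS-like) and a symmetric-Dirichlet root profile (L = 50,
concentration 1) are evolved down a balanced binary tree: each branch
substitutes every site independently with probability 0.02 (to a
uniformly chosen different base) and multiplies the profile componentwise
by exp(0.1·N(0,1)) before renormalizing. Leaves are the RAVs. Sequence
distance and profile distance then both grow with tree distance, which is
exactly the correlation KNN imputation exploits; at the defaults a
64-leaf database builds in well under a second and leave-one-out
validation yields median R² ≈ 0.96 with 100% of leaves predicted.

Defaults were chosen once as a realistic positive control: 2%
substitutions per site per branch keeps cousins within a cosine radius of
0.5 at k = 5, and 0.1 log-normal jitter keeps relatives' profiles similar
without making them identical. `simulate_queries` mutates copies of
database leaves at a chosen divergence rate and returns the source
profiles as ground truth, optionally with the source leaf removed
(leave-one-out), which emulates predicting consensus ITS sequences from a
mock community.

What the simulator does *not* emulate: indels and the conserved-5.8S /
variable-spacer structure of real ITS regions, realistic KEGG function
frequency distributions, database imbalance across families, and
community abundance structure. A green test on synthetic data therefore
establishes that the algorithm is implemented correctly and behaves as
designed where its assumption holds — not that real mycobiome predictions
reach any particular accuracy, which depends entirely on the reference
database used.

## Numerical choices and degenerate inputs

- Cosine distances are clipped to [0, 1] to remove float noise; the
  zero-distance override uses tolerance 1e-12 because dot products of
  identical frequency vectors need not be exactly 1 in floating point.
- Profiles are renormalized at load when their sum deviates from 1 by
  more than 1e-6, so raw count tables are accepted; all-zero or negative
  rows are errors. Saved profiles carry 17 significant digits so a
  save/load round trip is exact to 1e-12.
- A sequence shorter than k, an all-ambiguous reference sequence, an
  empty database, K < 1, and ε outside (0, 1] are all distinct, typed
  errors; a query with no neighbor inside ε is *not* an error but an NA
  column plus a warning.
- Medians over an even count use the midpoint convention. R² medians are
  reported both per epoch and pooled across epochs.

## Known limitations

- No reverse-complement canonicalization: mixed-orientation inputs will
  not match the database.
- Plain dense k-mer vectors; no minimizers, sketches or spaced seeds —
  adequate at the intended database scale (thousands of references).
- Single-threaded; a full leave-one-out over a database of ~6000
  references is O(N²) distance computations.
- Whether the original tool breaks truncation ties deterministically is
  unknowable; this implementation's ascending-ID rule is a documented
  convention, not a reproduction.
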