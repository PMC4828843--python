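# Methods

## Problem and model

De-duplication treats a table of person records as a noisy rendering of an
unknown entity partition. The pipeline has three stages: *indexing* proposes
candidate pairs cheaply, *comparison* scores each candidate over a set of
linking fields, and *classification* thresholds the aggregate score. All
record values are normalized at load (lowercase, outer whitespace stripped,
internal runs collapsed); missing cells are empty strings.

### Indexing

An inverted index maps each encoded blocking-key value to the list of
records carrying it. Two encodings are provided:

* **soundex** — American soundex (initial letter + 3 digits). The variant
  implemented treats `h`/`w` as transparent (they do not separate two
  consonants with the same digit) while vowels do separate them; this is the
  most widely documented convention. Non-alphabetic characters are stripped
  before encoding; fully non-alphabetic values yield an empty code.
* **substring** — the first `k` characters of the raw normalized value
  (default k = 4), the least restrictive encoding; digits in fields such as
  postcode survive.

Composite keys encode each constituent field separately and concatenate the
codes (an optional separator guards against concatenation collisions; it is
off by default because soundex codes have fixed length and same-spec prefix
keys have bounded length). A record whose constituent fields are *all* empty
gets no key and is excluded from that pass's index; pooling such records
into a shared bucket is available behind the `empty_key_bucket` flag but
distorts comparison counts when missingness is non-trivial.

Blocking compares records within a bucket. Windowing (sorted-neighborhood)
sorts buckets by key value ascending and compares all records within `w`
consecutive buckets; the window slides over *buckets*, not individual
records, so no tie-break inside a bucket is needed. Equivalently, two
records are candidates iff their bucket indices differ by less than `w`;
`w = 1` degenerates to blocking. Multipass variants union the candidate
pairs of several single-key passes.

### Average-case comparison counts

Under the uniform assumption (b blocks of n/b records each):

* blocking: `b · C(n/b, 2)`
* single-key blocking, key with `i` distinct values: `i · C(n/i, 2)`
* composite-key blocking on keys with `i` and `j` distinct values: the
  average block count is modeled as `i·j/2` with block size `2n/(i·j)`
  (a modeling assumption, not a derivation — the true count lies between
  `i` and `i·j`), giving `(i·j/2) · C(2n/(i·j), 2)`
* two-pass multipass blocking: the sum of the two single-key costs
* windowing: `C(wn/b, 2) + (b−w)·[C(n/b, 2) + (w−1)·n²/b²]` — the first
  window in full, then each slide adds one new bucket's internal pairs plus
  its cross pairs against the `w−1` retained buckets.

These return reals (expectations), never rounded. On indexes whose blocks
really are uniform they coincide exactly with enumeration, which the test
suite exploits as an oracle.

### Comparison and classification

Default linking fields and comparators: postcode and soc_sec_id by
normalized Levenshtein similarity `1 − d(a,b)/max(|a|,|b|)` (via edlib);
address_1 by bigram overlap `|common q-grams| / mean q-gram count` (q = 2,
no padding); given_name and surname by exact agreement of their encoding,
mirroring the run's indexing encoder (soundex agreement under soundex keys,
k-prefix agreement under substring keys). If either side of a field is
empty its similarity is 0; the `missing_ignore` flag instead drops the field
from the aggregate. The aggregate F is the weighted arithmetic mean (unit
weights by default), keeping F in [0, 1] so thresholds are scale-free.

Thresholds default to (T_L, T_U) = (0.5, 0.75): with five unit-weight
fields, one fully disagreeing field (F = 0.8) still matches, two do not.
(1.0, 1.0) recovers the deterministic exact-agreement rule. The upper
boundary is inclusive (F ≥ T_U ⇒ Match).

The F-score used in evaluation is the plain harmonic mean 2·PC·RR/(PC+RR).
A published rendering of this formula carries a leading "1 −", but every
printed F value it accompanies is consistent with the plain harmonic mean
and inconsistent with the inverted form; we treat the "1 −" as a
typographical inversion. PC is computed against the gold standard's exhaustive
within-entity pair set; the matching-pair count of a profile can also be
estimated as DR·(n/d)·[d + d(d−1)/2].

### The three-phase framework

CKB → MPB (two passes) → MPW (two passes, small window, default w = 3).
Cross-phase accounting uses two mechanisms, both on by default and
independently switchable, because the published phase counts are below the
standalone costs of the same configurations and the exact mechanism is not
stated:

* a global compared-pair cache — a pair generated by a later phase that was
  already scored is not scored again;
* removal of resolved duplicates before windowing — the match pairs found in
  the blocking phases are closed transitively (networkx connected
  components); in each cluster only the representative (lexicographically
  smallest rec_id) survives into the windowing phase, which re-sorts the
  reduced dataset.

Per-phase reports carry pairs generated, pairs newly compared, and matches
newly found; "matches found" counts pairs newly classified Match in that
phase, and possible matches are reported separately, never folded in.

## Synthetic data generator

The generator emulates a DBGen-style corruption process so every stage is
testable without external data. Originals draw from built-in pools: ~100
given names, ~95 surnames, 30 street names, 40 suburbs, 8 state codes, plus
numeric generators for street_number, postcode (2000–7999), date_of_birth,
age, phone_number and soc_sec_id. Duplicates copy an original and apply
1..`max_mods_per_duplicate` single-character edits (insert, delete,
substitute, transpose, field clear), the attribute chosen uniformly among
those still under `max_mods_per_attribute`, the operator uniformly among the
applicable enabled ones; every edit is guaranteed to change the value, and a
duplicate that ends up identical to its original (edits canceling) is
redrawn. Corrupted values are re-normalized, so a deletion adjacent to a
space can shift a value by two characters. Duplicate counts per original are
uniform on {1..max}, truncated to hit the requested total exactly. Output
order is shuffled; identical config + seed reproduces byte-identical output.

Two profiles fix the study conditions:

* **A** (dirty): 500 originals + 500 duplicates, 1 duplicate/original,
  exactly 1 modification, ≤ 1 per attribute → exactly 500 true pairs.
* **C** (massively dirty): 600 originals + 400 duplicates, ≤ 9
  duplicates/original, ≤ 10 modifications/duplicate, ≤ 3 per attribute; the
  true-pair count follows from the realized allocation (clusters contribute
  duplicate–duplicate pairs).

What the generator does *not* emulate: Febrl's empirical name/address
frequency tables (the built-in pools are smaller and uniform, so blocks are
somewhat larger and absolute comparison counts run higher than runs on
DBGen's own output), phonetic/OCR-specific error models, correlated errors
across fields, and household structure. Passing tests therefore demonstrate
the pipeline's behaviour under a realistic but simplified corruption model,
not performance on any particular external dataset.

## Numerical and design choices

* Pair canonicalization: unordered pairs stored as (min, max)
  lexicographically; self-pairs are errors.
* Bucket order for windowing: ascending lexicographic on the encoded key.
* Estimators are exact reals; comparisons of estimator vs enumeration in
  tests use exact equality, which holds because all quantities involved are
  integer-valued at the tested sizes.
* Metric edge cases: any zero denominator yields that metric as 0 with a
  warning; F-score is 0 when PC + RR = 0.
* Cluster representative: smallest rec_id — deterministic and independent of
  input order.
* Problem sizes in the test suite and acceptance script: n = 1000 for both
  synthetic profiles (matching the profiles themselves), n ≤ 200 for
  estimator/enumeration sweeps and n ≤ 50 for randomized brute-force
  equivalence, sizes at which exhaustive oracles are exact and fast.

## Known limitations

* Thresholds are global constants, not field-frequency (value-specific)
  weights; no Fellegi–Sunter weight estimation.
* No merging/survivorship: the pipeline reports match pairs and clusters,
  not canonical merged records.
* The windowing phase inherits blocking's sensitivity to errors in the first
  characters of key fields; a corrupted leading character can move a record
  far away in sort order.
* Absolute match counts depend on the unstated thresholds of any published
  run being compared against; only threshold-free quantities (counts of
  candidates, metric identities, monotonicities) are asserted exactly.
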