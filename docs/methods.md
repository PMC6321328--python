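# Methods

## The landscape model

The package analyzes the activity landscape of a compound set through
systematic pairwise comparison.  For compounds *i*, *j* with per-target
activities `A_i`, `A_j` (pIC50, i.e. −log10 of the molar IC50) and a
structural similarity `sim(i,j)` (Tanimoto coefficient over binary
fingerprints), every unordered pair is a point in one of two spaces:

- **SAS space** (one target): `(sim(i,j), |A_i − A_j|)`.
- **DAD space** (two targets X, Y): `(|A_i − A_j|_X, |A_i − A_j|_Y)`, with
  signed differences `A_i − A_j` (fixed i-before-j table orientation)
  retained for the quadrant reading of selectivity inversions.

Cliff severity is the structure–activity landscape index
`SALI(i,j) = |A_i − A_j| / (1 − sim(i,j))`.  At `sim = 1` the index is
undefined; the implementation returns 0 when the activities agree and an
infinity sentinel otherwise.  The sentinel is excluded from plot color-scale
normalization (it would saturate the scale) but the pair keeps its region
label, so duplicate structures flow through the pipeline rather than
crashing it.

## Thresholds and region classification

Two thresholds cut SAS space into four regions.  The activity threshold
`t_act` defaults to 1 log unit — a ten-fold potency change, the
conventional floor for calling a pair an activity cliff.  The similarity
threshold `t_sim` defaults, per fingerprint scheme, to the dataset's mean
pairwise similarity under that scheme.  The default is per-scheme rather
than global because Tanimoto scales are not comparable across fingerprints:
a MACCS value of 0.6 is unremarkable while an ECFP4 value of 0.6 is high,
and one shared cutoff would make the per-scheme region counts
incommensurable.  A global override is available for users who want a fixed
cutoff.

**Boundary convention.**  "High" means strictly greater than the threshold
on both axes, so a pair sitting exactly on a boundary falls on the low
side.  This makes the classification a total, unambiguous function and
gives the threshold-monotonicity property tested in the suite: raising
`t_act` can only move pairs from the large-ΔA regions into the small-ΔA
regions, never the reverse.

**Consensus.**  Region counts are computed per fingerprint and averaged
across schemes, rounding each region's mean to the nearest integer (half
away from zero).  Because the four regions round independently, the
consensus row can miss the pair total: errors are multiples of 1/k for k
schemes, so the drift is at most 1 for three schemes and at most 2 in the
worst (two-scheme) case.  Per-scheme counts are authoritative; the
consensus is a summary, and percentages are always recomputed from counts
at report time.

**Cliff generators.**  Each compound's generator frequency is its number of
activity-cliff pair memberships divided by the total memberships (twice the
number of cliff pairs).  This normalization is self-normalizing (sums to 1)
and rank-preserving; other normalizations (per-compound pair counts, raw
counts) reorder nothing but change the printed percentages.  A cross-scheme
consensus ranking uses mean rank, with absent compounds ranked below all
present ones.

## Fingerprints

- **MACCS**: RDKit's implementation of the 166 public MACCS keys.  The
  declared length is 167 because RDKit numbers the keys 1–166 and leaves
  bit 0 unused.
- **ECFP4**: Morgan circular fingerprint of radius 2 (diameter 4), hashed
  and folded to 2048 bits by default.  2048 is the de facto standard;
  folding length shifts Tanimoto values slightly, so it is configurable.
- **PUBCHEM**: an 881-bit PubChem-style structural key set reimplemented in
  `cliffscape.pubchem_keys` (version `cliffscape-pubchem-1`): hierarchic
  element counts, ring-size/aromaticity descriptors, bonded element pairs,
  and a curated SMARTS section, each at a fixed index of the 881-bit
  layout.  It is **not** bit-compatible with PubChem's own CACTVS keys —
  no Python toolkit in the stack provides those — so Tanimoto values under
  this scheme are internally consistent but not comparable to values from
  PubChem itself.  The provider contract isolates this: any callable
  producing a `BitFingerprint` can stand behind a scheme name.

Tanimoto is computed on the package's own on-bit set representation
(`|A∩B| / |A∪B|`); the test suite cross-checks it against RDKit's
independent implementation.  Conventions for pathological inputs: two empty
fingerprints compare as 1.0 (with a logged warning — the molecules are
indistinguishable to the scheme), empty vs non-empty as 0.0.  This keeps
the similarity matrix total.

## Input handling

Tables are CSV with `compound_id`, `smiles`, and `pIC50_<target>` columns
(structures may come from a separate `.smi` file).  Validation rejects
duplicate ids, unparseable SMILES (naming the compound), missing per-target
activities (never imputed — the landscape is defined only on complete
pairs), and pIC50 values outside [0, 14], which in practice are IC50s
entered in the wrong unit.  IC50 inputs are supported via an explicit
unit flag (M/uM/nM) and converted with `pIC50 = −log10(IC50 [M])`.
Multi-fragment SMILES (salts) are reduced to the largest covalent fragment,
with no neutralization or tautomer canonicalization — minimal, reproducible
intervention, logged when it fires.

## The synthetic series

The generator emulates a two-target lead-optimization campaign: a common
scaffold (default: 4-aminoquinoline, decorated at the exocyclic amine R1
and an aromatic ring position R3) with full R-group enumeration (capped at
200 products), additive per-(position, substituent, target) pIC50
contributions, and i.i.d. Gaussian assay noise per (compound, target),
default SD 0.1 log units — the order of inter-assay reproducibility.
Attachment is by single bonds at map-numbered dummy atoms; every product is
sanitized, so invalid assemblies fail loudly naming the fragment.

Cliffs and switches are injected by overriding the additive model: after
noise, a designated compound's activity on one target is set to its
partner's value minus the forced gap, making the realized gap exact.
Designating one compound as the overridden member of several injections
plants an activity-cliff *generator* — a single outlier cliffing against
each of its structural analogs, which is the construction the
generator-ranking statistic is designed to detect.  When one compound is
overridden by several injections on the same target, the last one defines
its activity and earlier designated gaps are approximate (off by the
activity spread among the partners).

Two reference specs ship with the package:

- `default_series_spec` — 50 compounds (5 R1 × 10 R3), a rough first-target
  landscape (contributions spanning ~2 log units plus five injected
  2.8-log-unit cliffs sharing compound 12), a smooth second-target
  landscape (contributions ≤ 0.5), one injected selectivity switch and one
  injected dual pair.  Activity ranges land near 4.8–9.0 and 3.5–7.0.
- `recovery_series_spec` — same chemistry, but every contribution is below
  half the cliff threshold (maximum modeled pairwise gap 0.9 log units), so
  with zero noise and no injections the landscape contains no cliff at all.
  Against this flat background the five generator cliffs and the switch are
  the only cliffs, making recovery rate, generator rank, and switch
  labeling exact correctness measures rather than statistical ones.

What the generator does *not* emulate: correlated assay errors, activity
censoring ("IC50 > 10 µM"), non-additive R-group interactions (the injected
cliffs are the only epistasis), scaffold diversity, and stereochemistry.
Passing recovery tests therefore demonstrates that the pipeline's
classification, ranking, and labeling logic is correct under the stated
noise model — not that any particular real dataset has a recoverable
landscape.

## Numerical and testing choices

- All pair enumeration is over `itertools.combinations` in table order, so
  outputs are deterministic and byte-identical across runs for a fixed
  input and seed.
- Expected-label predictions (`expected_landscape`) are guaranteed only
  when `noise_sd ≤ t_act/5` (a >5σ margin per comparison); otherwise a
  warning marks them unreliable.  Smooth-SAR expectations additionally
  require the modeled gap plus a 5σ√2 noise margin to stay below `t_act`.
- The recovery experiment in the acceptance script uses 100 replicates of
  the 50-compound recovery series with MACCS fingerprints — about ten
  seconds of compute — chosen as the smallest design that makes a 95%
  recovery bound meaningful at 5 injected cliffs per replicate.
- Ties in generator rankings break by compound id for determinism.

## Known limitations

- The PubChem-style scheme approximates a fingerprint family whose
  canonical implementation is unavailable in this stack; per-scheme region
  counts under it will differ from publications that used CACTVS keys.
- Consensus counts inherit the off-by-one (or two) rounding drift described
  above.
- The DAD analysis is limited to two targets; no multi-target
  generalization is attempted.
- No matched-molecular-pair formalism or cliff-network representation:
  pairs are treated independently, so a "cliff generator" is a frequency
  statement, not a causal attribution to a specific substructure change.
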