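# Methods

## The measurement problem

Pooled phage-display libraries compete during amplification: every clone's
representation in the sequencing output depends jointly on its initial copy
number and its propagation capacity. The pipeline quantifies that
competition from single-end amplicon reads taken at successive time points
of one co-culture. Because each library format has a distinctive insert
architecture (leading alanine, randomized stretch, optional flanking
cysteines, constant GGGS linker, then mature pIII), reads can be assigned
to their library of origin purely from the translated insert region, with
no barcode.

## Read model and classification

A read is `5'-flank | insert | 3'-flank`, where the 3' end of the 5' flank
is a constant ≥10 nt *anchor* motif and the 3' flank encodes the mature
pIII N-terminus (`AETVESCLAKSH…`). Classification takes the 51 nt after
the unique anchor occurrence (absent/duplicated anchor or a truncated
window ⇒ `REMOVED`), translates them with the standard code (stops ⇒ `*`,
any codon containing a non-ACGT character ⇒ `X`), drops the constant
leading residue, and applies the precedence rules C7C → 12 → 7 → REMOVED
listed in the README. Design choices worth recording:

- **Coordinate convention.** Window positions are 1-based and exclude the
  leading alanine, so "GGGS at 8–11" refers to the heptapeptide linker and
  "GGGS at 13–16" to the dodecapeptide linker. For the cyclic library the
  leading alanine is likewise excluded, making position 1 the first
  cysteine.
- **Single-pass precedence** replaces post-hoc deduplication between
  per-library cleaned/removed pools. The orders are equivalent: the C7C
  rule cannot co-fire with the linear rules (it requires `C` at position 9
  where they require `G`), and the only true overlap — a dodecapeptide
  carrying `GGGS` at positions 8–11 as well as 13–16 — is resolved to
  PhD12, the only self-consistent reading.
- **Stop/ambiguity policy.** `*` and `X` disqualify a read only when they
  fall inside the randomized region used by the matched rule; residues
  downstream of the linker are unconstrained. `X` (ambiguous translation)
  is treated like `*` as a conservative choice.
- **WT detection.** Insertless clones have no peptide or linker, so their
  window begins directly with mature pIII. A removed read is counted as WT
  when the first 12 residues of the full translated window are within
  Hamming distance 1 of `AETVESCLAKSH`; the one-mismatch tolerance absorbs
  single sequencing errors, at any position. WT reads stay in the removed
  pool and never enter fold-change, diversity or EF statistics.
- No quality filtering or trimming is performed; the classifier is
  deliberately sequence-only.

## Population statistics

- **WT shares**: `wt / total` and `wt / removed` per time point.
- **Fold change** per library: cleaned read count at `t` over the count at
  `t = 0`; a `normalize_depth` option uses within-time-point proportions
  instead (the default is raw counts; per-time-point depths are reported
  alongside so either reading is reproducible).
- **Diversity**: the pool at a time point is split into *distinct* reads
  (one representative per unique peptide, keyed per library) and *repeated*
  reads (the surplus copies), expressed as percentages of cleaned reads —
  the two always sum to 100. An alternative `singleton` mode counts only
  peptides seen exactly once as distinct; the representative-copy reading
  is the default because only it makes the distinct/repeated split a
  partition.
- **Titers** (non-competitive assay): `titer = plaques × dilution /
  volume`, averaged over replicate plates; SEM is `sd/√n` (reported as 0
  for a single replicate, where the sd is undefined); fold change is
  against the library's `t = 0` mean titer.

## Enrichment factors

Relative frequency is `f = count / total cleaned reads across libraries`
(an `all` mode divides by all reads instead; cleaned is the default since
EF is defined over peptide-bearing sequences). For peptides with nonzero
counts at both ends of an interval, `EF = f_later / f_earlier`. No
pseudocounts are used: peptides appearing or disappearing between samples
are simply absent from the EF table. Enriched-sequence shares use the
strict inequality `EF > 1`; reported shares are rounded to one decimal,
half-up. EF composes exactly across intervals
(`EF(0→270) = EF(0→150)·EF(150→270)`), which the tests assert to 1e-9.

## The simulator

The generator emulates the statistical structure of the competitive assay:

| parameter | default | meaning |
|---|---|---|
| `timepoints` | 0, 150, 270 min | sampling times of the co-culture |
| `depth` | 10^5 reads | sequencing depth per time point |
| `n_clones` | 1000 per library | pool complexity (scaled down from ~10^9) |
| `rate_means` | 0.026 / 0.024 / 0.022 min⁻¹ | PhD7 / PhD12 / PhDC7C growth-rate means (~27 min doubling) |
| `rate_sds` | 0.2 × mean | clone-to-clone growth heterogeneity |
| `wt_fraction_0` | 0.125 | WT share of the pool at t = 0 |
| `r_wt` | 0.024 min⁻¹ | WT growth rate |
| `error_rate` | 0.001 | iid per-base substitution probability |
| `amber_rate` | 0 | TAG injection probability per randomized codon |

Growth is deterministic exponential per clone, `N_i(t) = N_i(0)e^{r_i t}`
— the simplest model that produces competitive displacement; resource
limitation and infection kinetics are deliberately out of scope. Each
library starts with equal total input (10^9 copies split evenly across its
clones). Randomized residues are drawn uniformly from the 20 canonical
amino acids and back-translated with uniformly chosen NNK codons
(constant positions use fixed NNK-member codons), so every insert codon
belongs to the 32-codon NNK set. Inserts that would create a second anchor
occurrence in the read are redrawn, keeping window location unambiguous.

Reads at time `t` are a multinomial sample of size `D_t` with
probabilities ∝ `N_i(t)` (WT compartment included), built from per-clone
templates with iid substitutions. In `exact_mode`, counts are the
largest-remainder rounding of `D_t·p_i` and the error rate is forced to 0;
this mode exists for closed-form tests (neutral pools give every EF = 1
exactly). All randomness flows from one master seed through named
substreams (clone composition, codon choice, amber injection, sampling,
errors), and FASTQ output is byte-identical across reruns of the same
configuration.

Amber biology: with `amber_suppression` on (supE-like host) a TAG codon
displays Q, but in-silico translation of the sequenced DNA still yields
`*`, so amber-bearing reads are removed by the classifier either way —
matching how stop-bearing reads behave in a real analysis.

### What the simulation does and does not show

The simulator reproduces competitive displacement, diversity loss, a WT
background, sequencing error and stop-codon reads. It does **not** model
PCR amplification bias, chimeras, indels, quality-score structure,
host/infection kinetics, or true library-scale complexity: with 10^3
clones per library against 10^5 reads, nearly every peptide is sampled
many times, so absolute distinct-sequence percentages are far below those
of a real ~10^9-complexity library, where nearly every read is unique.
Tests on simulated data therefore validate the *estimators and their
qualitative recoveries* (orderings, trends, conservation, algebra), not
the numerical values a particular wet-lab run would produce.

### Verification conditions

Three recovery properties are checked over 100 seeded replicate
simulations each:

- **Fold-change ordering** (rate means ordered PhD7 > PhD12 > PhDC7C,
  defaults above): classified fold changes over 0→270 min recover the
  ordering in ≥95 runs. Only the interval endpoints are classified, since
  the statistic does not involve the mid-point sample.
- **WT balance**: when WT growth matches the pool's per-capita growth, the
  WT read fraction is constant in expectation and later values should sit
  within 3 binomial standard errors of the t = 0 value (SE of a difference
  of two estimated proportions, `√(2p(1−p)/D)`, depth 10^4). This is run
  with all clone rates equal to `r_wt`: under heterogeneous rates a pool's
  per-capita growth is time-varying (log-mean ≈ `r̄t + σ²t²/2`) and
  exceeds any fixed WT rate, so drift — not sampling error — would
  dominate; the matched-rate design isolates what the property actually
  tests, the unbiasedness of the sampling and classification chain.
- **Diversity decline**: in exact mode with heterogeneous rates and
  constant depth (2×10^4), the distinct-read percentage is non-increasing
  across 0/150/270 min in all 100 runs.

## Numerical choices and degenerate inputs

Largest-remainder rounding breaks ties by index order (stable argsort).
Exponents `r·t > 700` raise a simulation error naming the clone, except
for empty compartments, which stay empty at any rate. Empty cleaned pools,
zero denominators and missing `t = 0` baselines raise typed errors; an
empty EF-overlap or an interval with no enriched sequence is a warning
plus an empty/None result, not an error. Classification is memoized per
unique read sequence (pure function of the sequence), which makes
simulated pools with repeated templates cheap to process.

## Known limitations

- Anchor-based window location assumes the anchor survives sequencing; a
  substitution inside the anchor removes the read (at default error rates
  this is a ~1.6% uniform loss, which cancels in ratios).
- Peptides are keyed per library; identical 7-mers arising independently
  in PhD7 and PhDC7C are counted separately (they are distinct clones).
- Fold changes on raw counts conflate depth differences between time
  points when depths differ; use `normalize_depth` in that case.
- The EF table is conditioned on presence at both time points, which
  biases against rare, fast-enriching clones at low depth — a property of
  the estimator itself, shared with the analysis it implements.
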