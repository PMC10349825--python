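# Methods

## The classification model

`vusact` operationalizes a curation-team rule set for variants of unknown
significance (VUS) in therapeutically actionable genes. The model's core
assumption is spatial clustering of function: oncogenic, druggable
alterations concentrate in specific protein regions, so an uncharacterized
variant located in such a region — or simply close to a characterized
actionable alteration in linear sequence — is more likely to be functional
than one located elsewhere. The scheme is deliberately knowledge-driven: it
uses no conservation scores, no 3D structure, no mutation frequency.
Recurrence alone never upgrades a variant; some recurrent variants are
benign polymorphisms, so the rules require that *other* alterations at the
position or in the region are demonstrably tumor-promoting.

The decision cascade (first match wins):

1. **Gene gate.** A variant in a gene not classified therapeutically
   actionable is `No`. Gene actionability is an input (the registry), not
   something the package infers.
2. **Curated match.** An exact match on (gene, normalized change) returns
   the curated aggregate value. Positional overlap with a curated record is
   *not* a match. A placeholder record — functional significance unknown
   and no assertion beyond `Unknown` — does not short-circuit; such a
   variant flows through the computational rules like any uncurated VUS.
   (The stricter reading, "any curated record matches", would make the
   rules unreachable for exactly the cohort they were designed for.)
3. **Truncating gate.** Nonsense and frameshift variants return `Unknown`
   with `rule_fired=truncating_manual_review`. Their impact depends on the
   lost region, which is literature work, not proximity arithmetic; the
   package surfaces the manual step rather than automating it away.
4. **Domain rule.** `Potentially` if the variant's span overlaps a
   functional, non-disordered feature that also contains (overlaps) at
   least one proximity-eligible Yes-actionable record other than the
   variant itself.
5. **Proximity rule.** `Potentially` if the nearest proximity-eligible
   Yes-actionable record is within `proximity_threshold` amino acids.
6. Otherwise `Unknown`.

The domain rule is checked before proximity only to make the audit trail
deterministic; both yield `Potentially`, so the order never changes a
value. Every result carries the rule fired and its evidence (feature name,
or neighbor + distance).

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `proximity_threshold` | 5 aa | "within five amino acids", inclusive: distance 5 fires, 6 does not. |
| `distance_fallback` | `start` | convention for non-nested span pairs (below). |
| `full_containment` | `False` | domain rule uses span overlap; strict containment available for in-frame events straddling a boundary. |
| `strict` | `False` | lenient mode logs and skips unparseable rows / unregistered genes instead of aborting a cohort run. |

### The distance metric

Distances are computed on 1-based inclusive codon spans; an insertion
between flanking residues spans both of them (`D770_N771insGF` →
[770, 771], which is what makes its distance to `N771_P772insH` equal 1
under the start-difference rule). The four defined cases (single/single
difference; containment in either direction; nested or identical spans)
are unambiguous. For a single-codon variant *outside* a multi-codon span
the rule set only defines the containment branch, so the package extends
it with the same most-N-terminal-difference fallback used for non-nested
multi-codon pairs — the only convention consistent with the one printed
non-zero example. The alternative nearest-boundary convention
(`fallback="boundary"`, e.g. K385M vs Y375_K380del = 5 instead of 10) is
implemented for sensitivity analyses; it is never the default.

Proximity eligibility is exactly {missense, in-frame deletion, in-frame
insertion, duplication, deletion–insertion}: truncating events neither
serve as neighbors nor are scored as queries.

### The parser

One-letter protein HGVS plus two curation dialects seen in real
knowledgebase exports: an extra underscore before `delins`
(`H64_Y65_delinsQS`) and the `>` shorthand (`P551_M552 > L` ≡
`P551_M552delinsL`). Matching is case-insensitive with whitespace and a
`p.` prefix tolerated; normalized output uses uppercase residues and
lowercase event keywords and is idempotent. Three-letter codes and
cDNA/genomic HGVS are out of scope. In lenient mode an unrecognized string
becomes `subtype=other` with a best-effort span from the digits present
(it can then never satisfy a rule, but it does not abort a 700-row cohort
file either).

## Assay interpretation

Viability effects arrive categorical (`increased` / `no_change` /
`decreased` vs matched wildtype, per cell line); the thresholding of raw
viability curves belongs to the upstream assay platform and is
intentionally not re-invented here. Gating precedes calling:

- a (gene, line) context is informative only if the wildtype or ≥1 variant
  of the gene promoted viability there (otherwise the gene's oncogenic
  potential is unobservable in that cell background), and
- the wildtype must not contradict the gene's role — an oncogene whose
  wildtype suppresses viability, or a tumor suppressor whose wildtype
  promotes it, cannot be scored. This generalizes the known per-gene
  exceptions (an FGF6-like oncogene suppressing growth, a PTCH1-like tumor
  suppressor promoting it, an ARAF-like line-specific case) into one rule;
  genes of role `both`/`unknown` skip the contradiction check.

Calls over informative lines only: increase in ≥1 line with no decrease
elsewhere → `oncogenic`; increase and decrease across lines →
`conflicting`; otherwise `not_oncogenic`; no informative line →
`non_informative`. Integration into the knowledgebase defers to curated
literature: existing Yes/No values stand, contradictions are flagged
`Unclear`, and only unopposed assay verdicts create new Yes/No assertions
with basis `functional_genomics`.

## Validation statistics

The 2×2 table crosses Potentially/Unknown with oncogenic/not-oncogenic
after excluding conflicting and non-informative calls. `fisher_exact_2x2`
reports the two-sided exact p (sum of hypergeometric point probabilities ≤
the observed, margins fixed) and the **conditional-MLE odds ratio** — the
ψ maximizing the noncentral hypergeometric likelihood. The distinction
matters: on [[76, 128], [30, 200]] the sample OR is 3.958 while the
conditional MLE is 3.945, and the scheme's published validation uses the
latter convention. Both are exposed (`odds_ratio`, `sample_odds_ratio`).
Computation is delegated to scipy (`fisher_exact`,
`contingency.odds_ratio(kind="conditional")`); the test suite checks the p
against an exhaustive enumeration oracle over all tables with margins ≤ 8
and the OR against an independent scalar maximization of the
hand-written conditional log-likelihood, so the convention is pinned by
tests rather than by trust in any one library. Boundary tables (a zero
diagonal cell) return OR 0 or +∞; zero-margin tables are rejected. No
confidence intervals or multiple-testing corrections are produced — each
validation is a single planned comparison.

Proximity distributions bin each oncogenic VUS by nearest-actionable
distance into {0, 1–2, 3–5, >5} by default (configurable); the bin edges
are an interpretation of the narrative categories ("same position or
span", "within at least 2 amino acids") since no exact edges are
published. Variants on genes with no eligible actionable record are
reported as `unreached` and excluded from fractions.

## Synthetic data

`generate_knowledgebase` / `generate_cohort` emulate the structure the
validation assumes: actionable genes with non-overlapping features (one in
three disordered), Yes-actionable missense anchors inside the
non-disordered features, a cohort placed either within the proximity
threshold of an anchor (or inside its domain) or in an empty C-terminal
stretch, and assay effects drawn class-conditionally. Defaults are the
validation-cohort conditions: 20 actionable genes, 438 VUS with ~47%
satisfying a Potentially rule, P(oncogenic | Potentially) = 0.37,
P(oncogenic | Unknown) = 0.13, conflicting rate 4/438. All draws come from
one `numpy` generator seeded explicitly, so outputs are byte-identical
across runs.

What the generator does *not* emulate: real gene identities or domain
boundaries, mutation spectra, inter-gene variation in oncogenicity rates,
and any correlation between distance-to-anchor and oncogenic probability
beyond the two-class split. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not the real-world
enrichment, which depends on the content of a curated knowledgebase
snapshot. For the same reason the published nearest-neighbor distribution
(52% at distance 0, another 23% within 2) is not reproducible from
synthetic placements and is exercised only as binning arithmetic.

Two deterministic fixture cohorts reproduce the published count flows
end-to-end through classifier → assay → contingency: the 438-variant
curated cohort (206/232 split; 106/328/4 assay calls; table
[[76, 128], [30, 200]] after the four conflicting variants are excluded,
with the 4 split 2/2 across classes — the only split consistent with
204 = 206 − 2 and 230 = 232 − 2) and the 777-variant computationally
classified cohort (659/118; [[290, 369], [9, 109]]). Gene symbols
(`FIX001`…, `CMP001`…) and positions are synthetic placeholders.

## Numerical and degenerate-input choices

- Exact-p tie handling: tables whose point probability is within relative
  1e-7 of the observed count as ties (the common implementation choice);
  the enumeration oracle in the tests uses the same tolerance.
- Nearest-neighbor ties break by smaller span start, then lexicographic
  normalized string; a variant never counts as its own neighbor.
- Empty proximity distributions report NaN fractions rather than raising.
- `aggregate_actionability` of an empty list, zero-margin tables, and
  distance across different genes are errors, not silent defaults.

## Known limitations

- Strictly linear-sequence proximity; no 3D contact-based hotspot logic.
- Gene actionability and protein features are inputs; the package performs
  no literature curation and no therapy matching.
- The assay layer consumes categorical effects; dose–response, time-series
  and batch normalization are out of scope.
- The parser accepts one-letter protein notation only.
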