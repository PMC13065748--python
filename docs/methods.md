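# Methods

This note records what each component computes, the parameters that
matter, and the choices made where the procedure admitted more than one
reasonable definition.

## 1. Code algebra

**Numeration.** Identifiers are positive integers rendered in bijective
base-35: digit values 1..35 over the alphabet A–Z (1–26) then 1–9
(27–35), least-significant digit `((n−1) mod 35) + 1`. Bijective
numeration — not standard positional base-35 — is forced by the absence
of a zero symbol: with digits 0..34 the string `RSC` could not decompose
22718 as 18·35² + 19·35 + 3 with R = 18, S = 19, C = 3. Consequences:
identifier 1 is `A`, 36 is `AA` (not `A` followed by a zero digit), and
code length steps exactly at 36, 1261 = 35² + 35 + 1, 35³ + 35² + 35 + 1, …
No maximum identifier is imposed; Python integers make length a
non-issue.

**Check digit.** `v = 26 − (n mod 26)` with v in 1..26 mapped to the
v-th uppercase letter; n divisible by 26 gives v = 26 → `Z`. The check
letter is a pure detection device (any single substitution of the check
letter is caught; it is not an error-*correcting* code). It is computed
from the identifier only: extension suffixes and the check letter itself
never enter the computation.

**Published-code inconsistency.** Two published four-character sample
codes (`AX8D`, `A6IG`) do not satisfy this rule — their cores decode to
2099 and 2354, demanding check letters `G` and `L` — while the worked
example `RSCF` and all published five-character codes (`AYAXU`, `AINXD`,
`AOSUV`, `ASSZE`, `ATSSI`, `AROEM`) do. The toolkit applies the rule as
stated and *flags* these rows as checksum-inconsistent rather than
inferring an undocumented alternative rule; batch validation reports
such failures in-band and never hides them.

**Grammar.** Codes are uppercased on input and always emitted uppercase.
The extension suffix is one dot plus a base-10 integer ≥ 1 with no
leading zeros; nested suffixes (`X.1.2`) are rejected because the
extension mechanism is explicitly single-level. The digits 1–9 are legal
core symbols *and* legal suffix digits; the dot removes any ambiguity.
Construction functions are strict (raise on bad input); `validate_code`
is total and reports all failures in-band, because validators feed batch
reports.

## 2. Registry semantics

A registry row binds identifier, code, optional source reference
(`<prefix>-<source code>`, split on the *first* hyphen so LOINC-style
codes with internal hyphens survive), one of twelve domain acronyms
(PROC, EVAL, MED, PROT, CONS, TRANS, LOG, LAB, IMG, RXT, PHY, MENT;
`TRAN` is accepted as an input alias of TRANS), labels in up to four
languages (at least one required — a toolkit must accept partial
drafts), a parent code for extensions, and an operational flag.

Design choices that were genuinely open:

- **Extensions and identifiers.** Extension rows draw from the same
  sequential identifier counter as every other row (so the identifier
  set is exactly 1..N), but their *code* is parent-derived
  (`parent + "." + k`, suffixes dense from 1); the row's own identifier
  is bookkeeping and is never encoded. This keeps "one sequential
  identifier per service" while matching the published extension code
  forms.
- **Operational codes** allocate ordinary identifiers/codes but carry no
  source reference, since they have no international equivalent.
- **Audit.** A single routine checks every invariant — unique
  identifiers and codes, valid checksums, codes encoding their
  identifiers, classification/domain compatibility, dense suffixes,
  single-level hierarchy — and file loading runs it before returning, so
  a registry read from disk is sound by construction. Malformed rows are
  rejected with their line number.

Persistence is header-checked TSV (default) or CSV plus a JSON export
with the same fields; write∘read is the identity on canonical
registries. Real classification content is never shipped or validated
against: only each system's prefix and domain role is modeled, and
fixtures use mock codes that imitate the surface shape (e.g.
7-character alphanumerics for the ICD-10-PCS mock).

## 3. Consistency assessment

Items are aligned across facilities into clusters by normalized label —
uppercase, NFKD accent stripping, punctuation collapsed to single
spaces — with an optional explicit concept key that always wins where
supplied (the reproducible default, expert-correctable). The four
statistics, each reported with its denominator because no standard
definition exists:

1. **Consistent nomenclature across facilities** — of the clusters
   present in *every* facility, the share whose raw labels agree
   verbatim everywhere.
2. **Duplicate codes in the same facility** — the share of *items* that
   are duplicate entries of the same service within one facility (same
   cluster, shared local code). Restricting to the same cluster keeps
   this criterion disjoint from criterion 4: a code shared across two
   *different* services is reuse, not duplication, and counting it in
   both would make the two rates arithmetically inseparable.
3. **Multiple codes across different facilities** — of the clusters
   present in ≥ 2 facilities, the share realized with ≥ 2 distinct
   (code, label) pairs. A cluster can be label-consistent yet
   multi-coded, which is why 33% consistency can coexist with 100%
   multi-coding.
4. **Same code for different services** — of the distinct
   (facility, local code) pairs, the share attached to ≥ 2 clusters.

All reports are invariant under permutation of facility or item order.
Percentages are rounded half-up to one decimal.

## 4. Coverage analysis

Each item of a catalog is classified against a validated registry as
`direct` (exact concept match via hint or normalized-label equality),
`extension_required` (matches a parent concept but needs a new suffix),
`header_mapped` (absorbed by a more generic code), `operational_only`
(no international equivalent), or `unmatched`. Expert hints override
label matching; hint codes must pass their checksum. A fuzzy matcher
(difflib similarity ratio against registry labels) exists but is **off
by default** and flags its matches distinctly — the conservative default
for a procedure that is manual review in practice.

Per-domain and overall rows report, as percentages of all items in the
row: international coverage (direct), national extension
(extension_required + header_mapped), operational-only, unmatched, and
**overall coverage = direct + extension_required + header_mapped**, with
operational-only excluded from the numerator. All five shares are
reported so any alternative roll-up can be recomputed; the published
per-domain rows are internally inconsistent in places and are not
individually reproduced.

## 5. Synthetic fixtures

The generator emulates the study inputs — multi-facility billing
catalogs with controlled disharmony and a mock registry — because both
the real hospital rate lists and the licensed terminologies are
unavailable by design. Defaults mirror the study conditions: 5
facilities, disharmony rates 33% consistent / 11% duplicates / 100%
multi-coded / 9% reuse, coverage split 91% direct / 6.7% extension /
2.3% operational-only. The default of 100 cross-facility services keeps
the closed-loop tests fast; the counts scale linearly and the planting
logic is size-independent.

Planting works by exact integer counts, not sampling:

- `round((1 − rate_multi_coded)·K)` clusters get one (code, label)
  realization everywhere; such clusters are necessarily
  label-consistent, so `rate_consistent < 1 − rate_multi_coded` is
  rejected as infeasible. Further consistent clusters share labels but
  receive per-facility codes; the remainder get a deterministically
  corrupted label (synonym swap, word shuffle, or abbreviation) in one
  facility.
- Code reuse is planted by merging the codes of m disjoint pairs of
  multi-coded clusters within a facility, with m chosen so that
  m/(K·F − m) best approximates the requested rate (exact when the
  counts divide evenly, otherwise within one item).
- Duplicates are planted as extra copies of items in unmerged clusters,
  with the copy count solving 2a/(K·F + a) ≈ rate the same way.
- The coverage split is apportioned over the final item count by the
  largest-remainder method, so planted counts always sum exactly.

Cluster labels come from a synthetic local-billing vocabulary that is
checked against the registry's label index, so coverage status is fully
controlled by the emitted hints; statuses are assigned over a
cluster-major item order, keeping almost every cluster status-
homogeneous. The ground truth (concept key, per-item hints, domains,
intended statuses, and the exactly-achieved rates) is emitted alongside
the catalogs, and the closed-loop property — assessment output equals
the achieved rates, and sits within one item's rounding of the request —
is tested for both analyses. Everything derives from one seed; the same
seed yields byte-identical files.

What the fixtures do **not** emulate: realistic price distributions,
multilingual label drift, domain-correlated disharmony, or the manual
validation workshop. Passing closed-loop tests therefore demonstrates
that the *measurement machinery* is correct and self-consistent, not
that any particular real-world catalog has these rates.

## 6. Numerical and interface conventions

- Percentages: decimal half-up rounding to one decimal, computed in
  exact rational arithmetic before rounding; empty denominators report
  0.0 rather than dividing.
- Determinism: all generator randomness flows from the config seed;
  clustering and reports are order-invariant; ties in the
  largest-remainder apportionment break on class name.
- CLI: exit 0 on success, 1 on validation failures found in inputs, 2 on
  usage errors; batch validation reports every failure (no fail-fast);
  errors go to stderr as diagnostics, never stack traces.
- Limitations: the check digit detects but cannot correct; label
  alignment is exact-match by design (fuzzy off by default); no
  terminology-server protocol, versioning, or real classification
  content.
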