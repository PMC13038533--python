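# Methods

## The model

`pvsignal` treats a spontaneous-report database as a set of cleaned cases,
each carrying a boolean target-drug flag and a set of MedDRA preferred
terms (PTs). For an event term *t* the data reduce to a 2×2 table over
unique (case, term) pairs:

|                 | term *t* | other terms |
|-----------------|----------|-------------|
| target drug     | a        | b           |
| all other drugs | c        | d           |

The counting unit is the (case, term) pair: a case contributes a term at
most once per level (PT or SOC), so within-case repetition of a reaction
never inflates counts, and `a+b+c+d` is the same for every term at a fixed
level. Spontaneous-report counts have no exposure denominator, so both
statistics are *disproportionality* measures, not risks:

* **Classical ROR** `ad/bc` with the Woolf interval using z = 1.96. Any
  zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
  cells); the result is flagged `zero_cell_corrected` rather than failing,
  because rare-event scans hit zero cells routinely.
* **Shrinkage O/E ratio and IC.** `N_exp = N_drug·N_event/N_total` is the
  pair count expected under independence; the ratio
  `(N_obs+0.5)/(N_exp+0.5)` is stabilized for rare events, and the
  information component is its log2 — the identity
  `IC = log2(ror_shrunk)` holds exactly by construction and is asserted in
  tests. The credible bounds use the closed-form approximations
  `IC ∓ {3.3, −2.4}·(N_obs+0.5)^−1/2 − {2, 0.5}·(N_obs+0.5)^−3/2`,
  whose width depends only on `N_obs` and is strictly decreasing in it.

A term is flagged as a signal when `ROR025 > 1` **or** `IC025 > 0` with at
least three observed reports. The disjunction is the default because it is
the more conservative screening reading; in practice strong signals
satisfy both, and a `rule="both"` configuration is provided for analysts
who prefer the conjunction. Results carry both the classical ROR and the
shrunk ratio in separate columns: they answer different questions (odds
ratio against the comparator vs stabilized observed/expected), and
published tables commonly print the classical ROR while methods sections
define the shrunk one.

## Cleaning rules

Deduplication is exact-key matching in two passes: per PRIMARYID keep the
latest FDA_DT (ties: largest CASEID, then CASEVERSION, then last in file
order — the file-order tie-break makes output deterministic); per CASEID
keep only the most recent version. Dates are YYYYMMDD integers; only their
ordering is used. The operation is idempotent and never grows a table.

Target-drug identification searches normalized generic and brand names
(uppercase, punctuation stripped, whitespace collapsed) as substrings of
DRUGNAME and PROD_AI — substring rather than exact-token matching because
free-text names carry salts and strengths ("ATROPINE SULFATE 1%"); an
exact-token mode exists by configuration. A report qualifies only if the
matching record has a suspect role (PS/SS) *and* an accepted route. The
default accepted-route vocabulary {OPHTHALMIC, OCULAR, INTRAOCULAR,
TOPICAL OCULAR} is a package decision — route coding in real extracts is
heterogeneous and the set is configurable. Records with missing routes
never qualify: confirmed-route analysis trades sensitivity for
specificity.

Ages are converted to years (months /12, days /365.25), floored to
completed years, and binned into ≤3 / 4–18 / 19–64 / ≥65; unknown units
become missing. All missing demographics are explicit "Missing or
unknown" categories in the descriptive tables, whose percentages are
rounded to two decimals against the target-case denominator.

## The priority rubric

Five dimensions, 0–2 points each: report count (>50 / 10–50 / <10), ROR
(>5 / 2–5 / 1–2), mortality proportion (>50% / 25–50% / <25%), EMA
event-list designation (DME / IME / none, DME taking precedence when a PT
is on both lists), and an expert evidence grade (++ / + / −) supplied as
an annotation table, never computed. Totals map to weak (0–4), moderate
(5–7), strong (8–10).

Two decisions deserve note. First, printed rubric ranges are open at the
boundaries; the package closes them downward (exactly 50 reports, ROR
exactly 5 or 2, mortality exactly 25%/50% all score the middle bin),
which is the closure consistent with the bundled reference panel. Second,
the ROR dimension bins the **point estimate** by default: recomputing the
reference panel is consistent only with that choice (e.g. bradycardia,
ROR 2.96 with lower bound 1.11, scores 1 only from the point estimate),
although the accompanying text of such scales sometimes names the lower
bound. `ror_mode="lower"` provides the alternative. The mortality
denominator is the term's case count — the simplest reading where none is
defined. Under the default configuration 82 of the 83 bundled reference
rows reproduce their published score and tier exactly; the remaining row
("Toxicity to various agents", published as moderate with 5 points) sums
to 3 from its own printed inputs under every reading of the scale and is
asserted as discordant rather than reproduced.

## Synthetic data

The generator emits one demo row per report, 1–4 drug rows, 1–3 reaction
rows, optional outcome and indication rows, in the same canonical schema
the reader produces. Defaults (chosen once as a realistic mid-sized
quarter): 5,000 reports, 20% carrying the target drug, role mix PS 0.60 /
SS 0.15 / C 0.20 / I 0.05, route present 85% of the time and ocular for
75% of present routes, 10% injected near-duplicates (same CASEID,
version +1, later FDA_DT), sex missing 15%, age missing 25%. The
24-term event vocabulary spans eight organ classes with the planted
default pair ("Mydriasis") at a 4% baseline weight — large enough that at
the default size its null expected pair count exceeds 20.

A planted effect multiplies the event-selection probability for cleaned
target reports by RR and renormalizes. Under that design the reporting
*odds* of the planted term are exactly RR times the comparator odds, so
the classical ROR is the consistent estimator of the planted multiplier;
the shrunk O/E ratio is attenuated because target reports contribute to
its expected-count denominator. `recovery_experiment` therefore measures
bias as mean log2(ROR) − log2(RR), reports the mean log2 shrunk ratio
descriptively, and uses IC025 > 0 for detection.

What passing synthetic tests shows — and what it does not: the pipeline's
rules, determinism, ledger accounting and estimator behaviour are
verified under known ground truth; the generator does not emulate drug
co-reporting correlations, secular reporting trends, coding noise or
true-signal masking, so synthetic recovery says nothing about those
real-data phenomena.

## Numerical and design choices

* z = 1.96 literal (not the exact normal quantile); the tests'
  independent statsmodels cross-check agrees to <0.1% on the interval.
* Scan ordering: lower ROR bound descending, then term name ascending —
  reproducible tables under ties.
* Degenerate inputs: empty tables round-trip; a term absent from the data
  yields a valid table with a = c = 0; an all-missing demographic column
  collapses to a single 100% missing row; an empty drug dictionary or
  event vocabulary is a hard error.
* Simulation sizes in the test and acceptance suites (5,000 reports × 20
  replicates for detection and null calibration; 500–8,000 ladders for
  consistency) were chosen as the smallest sizes at which the planted
  pair's null expected count is comfortably ≥20 and replicate noise is
  negligible.
* Pre-registered synthetic bands: RR = 20 detection rate ≥ 0.95; null
  mean fraction of terms with IC025 > 0 ≤ 0.05 (the closed-form IC bound
  is conservative at small counts, so the observed null rate sits well
  below the nominal 2.5%).

## Known limitations

Disproportionality is association screening: no causality, no incidence.
The exact-key deduplication cannot catch re-entered cases with new
identifiers (probabilistic linkage is out of scope). PT→SOC mapping ships
only as a toy fixture covering the bundled panel — a licensed MedDRA
mapping must be supplied for real analyses, as must current EMA IME/DME
lists and the expert evidence grades. SOC-level scans inherit whatever
multiplicity the PT mapping induces; no multiple-testing adjustment is
applied, matching standard signal-screening practice.
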