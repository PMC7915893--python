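# Methods

## Permethylated benzyl glycoside masses

CORA-style O-glycomics reads out secreted *benzyl* O-glycosides that are
permethylated before LC-MS. The neutral monoisotopic mass of a composition
with residue counts `c` over the classes {Hex, HexNAc, dHex, NeuAc} is

    M = Σ c_i · m_i + 18.010565 + 90.046950 + n · 14.015650
    n = Σ c_i · s_i − (R − 1)

where `m_i` are the dehydrated residue masses (Hex 162.052824,
HexNAc 203.079373, dHex 146.057909, NeuAc 291.095417 Da), `s_i` the free
methylation sites per residue (Hex 4, HexNAc 4, dHex 3, NeuAc 6 — the
NeuAc count includes the N-methyl and the carboxyl methyl ester formed
during permethylation), `R` the residue total, 18.010565 the terminal
water, 90.046950 the C7H6 benzyl replacing the anomeric hydroxyl hydrogen,
and 14.015650 the CH2 added per methylation. Each glycosidic bond consumes
one hydroxyl, hence the `−(R−1)`; branch topology therefore never affects
the mass, which is why the model is composition- not structure-level.

Peaks are interpreted as singly protonated [M+H]+ by default
(proton 1.007276 Da). This adduct convention, together with the
6-site NeuAc bookkeeping, is what reproduces the canonical ion series
(T 572.31, sialyl-T 933.48, STn 729.4, core 3 613.33, core 2 1021.53 …);
a sodiated convention does not. A free-reducing-end mode (`benzyl=False`,
anomeric position methylated instead) exists for non-CORA samples but is
not exercised by the acceptance checks.

Composition assignment enumerates all compositions within per-class bounds
(default ≤6) and keeps those whose theoretical m/z falls within a window of
the observed peak (default 0.05 Da; no tolerance is standard for this kind
of profiling, so it is exposed as a parameter). Ties sort by absolute
error, then fewer residues, then canonical class order — deterministic by
construction. Relative abundance is each peak's intensity over the summed
intensity of the profile, so abundances are scale-invariant and sum to 1.

## Identification selection

The selection funnel mirrors a membrane-focused re-analysis of a
two-fractionation proteomics experiment: per method (RPS/SCX), restrict to
accessions in a plasma-membrane registry, deduplicate to the best record
per accession, sort by PEP ascending and keep the top N (default 250),
then intersect the methods. PEP is treated with its standard semantics
(posterior probability the match is wrong; smaller is better). Ties break
by PSM count descending then accession, purely so output is reproducible.
Isoform suffixes ("-2") are stripped before registry lookup because GO
registries are keyed on canonical accessions; this is switchable. The
order is fixed as filter → rank → top: membrane restriction conceptually
happens at the database level, before confidence ranking.

## Target Score

The score is a linear combination of the evidence channels a targetability
triage cares about:

    score = w_m·[membrane] + w_t·tumor_level + w_p·[poor prognosis]
            − agg_tissues( w_h · mult(system) · level )

with levels on the 4-step IHC ordinal scale (not detected/low/medium/high
= 0–3) and `mult = system_penalty_multiplier` for reproductive, immune and
nervous tissues (systems where off-target engagement is least tolerable),
1 otherwise. Defaults: w_m = 3, w_t = 1 per level, w_p = 2, w_h = 1 per
level, multiplier 2, penalty aggregated as the *mean* over profiled
tissues. The qualitative structure (which channels reward, which penalize,
which systems are extra-penalized) is fixed; the exact weights are a
design choice of this package — the mean aggregation keeps the penalty on
the same 0–6 scale regardless of how many tissues an atlas profiles, and
the defaults make one reward channel unable to overwhelm the other two.
All weights live in `ScoreWeights`, so a different published weighting can
be dropped in without code changes. Missing tissue levels are read as "not
detected" and logged. Ranks are dense and ties break by accession.

## STn glycopeptide search

Digestion is tryptic: cleavage C-terminal to K/R except before P, up to 2
missed cleavages, 1-based inclusive protein coordinates. Peptide masses
are standard monoisotopic residue sums (pyteomics table) plus water plus
modification deltas: fixed carbamidomethyl-Cys (+57.02146), variable Met
oxidation (+15.9949, ≤2 per peptide) and STn (+494.1748 on Ser/Thr, ≤3 per
peptide — a combinatorial cap, not a biological claim). 494.1748 is
exactly the HexNAc + NeuAc residue-mass sum.

Spectra must pass an oxonium prefilter before any STn interpretation is
considered: a HexNAc oxonium (204.0867) AND a NeuAc oxonium (292.1027 or
its water loss 274.0921), each within the fragment tolerance. Candidates
are peptides whose theoretical (M + z·1.007276)/z lies within 10 ppm of
the precursor (the first-search stage uses 0.02 Da fragments; the glyco
stage 0.01 Da — both exposed as parameters). Scoring is a transparent
count of matched singly charged b/y ions; proprietary search-engine scores
are deliberately not imitated. Because HCD frequently strips O-glycans,
every STn-carrying fragment is matched in both its intact and fully
deglycosylated form. Ties break by fewer modifications, then peptide
lexicographic order. Spectra without a charge state are tried at z = 2 and
3 with a warning; charge-0 spectra are skipped.

Localization compares all ways of placing the matched number of STn groups
on the peptide's Ser/Thr sites and counts matched *site-determining* ions
(fragments whose m/z differs between placements; shared m/z values, e.g.
the glycan-stripped backbone series, are excluded). A unique, non-zero
argmax localizes the site(s); otherwise all tied sites are reported with
`localized = False`. A peptide with a single candidate site is localized
by necessity.

## Clinical statistics

Cross-tabulations use the uncorrected Pearson chi-square
(Σ(O−E)²/E, df = (r−1)(c−1), upper-tail p): on 2×2 tables this equals the
classical n(ad−bc)²/marginals form, and it is the variant that reproduces
the published cross-tabulation p-values (0.026 for GLUT1 × distant
recurrence, 0.414 for STn × stage); Yates' correction does not. Zero
marginal rows/columns are rejected. A 2×2 Fisher-exact mode exists for
exploration; several published table p-values match neither variant on the
printed counts, so no expectation is attached to them. Survival uses the
Kaplan-Meier product-limit estimator and the two-group log-rank test via
lifelines; the per-patient survival times behind the published survival
figures are not available, so the log-rank implementation is validated by
simulation (planted hazard ratios, type-I error under the null) rather
than against printed p-values. p-values are conventionally reported at 3
decimals to match clinical tables.

## Synthetic data

Every generator is a pure function of a `FixtureConfig` (seed included);
repeated calls are byte-identical, which the suite asserts.

- **Identifications**: a pool of accessions split into two method lists
  with a planted overlap of known size; PEP ~ Beta(1, 20) (most
  identifications confident, a thin tail of poor ones); membrane
  membership assigned to a configurable fraction (default 0.4).
- **Annotations**: decoys are broadly expressed (healthy levels drawn
  uniformly from low/medium/high — the "well-behaved housekeeping surface
  protein" case) with random membrane/tumor/prognosis flags; the planted
  target has the ideal profile (membrane, tumor-high, poor prognosis, one
  low-level healthy tissue), which outranks every decoy under the default
  weights by construction.
- **Spectra**: tryptic S/T-containing peptides (length 6–30) sampled from
  a bundled synthetic FASTA (3 invented Ser/Thr-rich, membrane-protein-like
  sequences of 247–428 aa; no real protein sequence ships with the
  package), one STn placement per spectrum, complete singly charged b/y
  series in intact and glycan-stripped form, the three diagnostic oxonium
  peaks, precursor at the true z = 2 m/z. Optional uniform peak dropout
  (oxonium peaks exempt, so the filter gate stays testable separately) and
  uniform decoy peaks. No chromatography, isotope envelopes or intensity
  model — so passing recovery tests demonstrates correctness of the
  matching/localization logic, not robustness to real instrument noise.
- **Cohorts**: exponential event times (baseline hazard 0.05/month,
  group B multiplied by the hazard ratio) with independent exponential
  censoring tuned so the reference group's expected censored fraction
  equals `censoring_rate` (default 0.2).

Problem sizes used by the test suite — 1000-protein selection fixtures,
100-protein score panels, 50 noiseless spectra, 1000 null cohorts of
2×50 for the log-rank type-I check — were chosen as the smallest scales at
which the respective properties are non-trivial.

## Known limitations

- Glycan masses are composition-level; isomers, linkages and adducts other
  than [M+H]+ are out of scope.
- The Target Score weights are package defaults, not a published
  calibration; results should be read as orderings under a stated weight
  choice.
- The glycopeptide search scores by fragment count without an error model
  or decoy-based FDR (a reversed-decoy option is not implemented); it is
  designed for clean, targeted re-analysis rather than large open searches.
- Fragment ions are singly charged b/y only; c/z ions (ETD) and multiply
  charged fragments are not modeled.
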