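# Methods

## Scope and coordinate model

`splicepanel` interprets targeted RNA-panel evidence for splice-variant
classification. Everything is computed in transcript space: each gene is laid
out 5′→3′ on a single 1-based "unspliced axis" (exons and introns in
transcript orientation), and genomic coordinates and strand are not modelled.
This removes an entire class of strand-convention bugs and loses nothing,
because every quantity the workflow needs — junction positions, r./c.
coordinates, reading frame, RT-PCR product sizes — is defined on the
transcript. HGVS support is deliberately minimal (substitutions, del, dup,
ins, delins, intron offsets, negative 5′UTR bases, and the uncertainty
notations `r.?`/`r.=`); anything else raises a parse error rather than
guessing.

## Junction quantification

Every gap in every gapped read contributes one count to its
(donor, acceptor) junction. The relative expression of a junction *j* is
`c(j) / (c(j) + r(j))`, where `r(j)` is the mean count of the natural
junctions sharing *j*'s donor or acceptor (both flanking naturals, averaged,
for an exon-skip junction; the gene's other natural junctions when *j* is
itself natural; all natural junctions when neither end is shared). No public
formula exists for "relative expression over natural junctions" in
junction-matrix tools of this kind, so this concretization was chosen to
satisfy two anchoring observations: a fully penetrant heterozygous event
under balanced expression reads out at 0.5, and a 0.21 junction fraction
converts to 42% of the variant-carrying allele.

Event typing: both junction ends on natural exon boundaries with ≥1 exon
omitted → exon skip; exactly one novel end → cryptic donor/acceptor; both
novel → complex; acceptor at or 5′ of the donor → back-junction (tandem
duplication). Intron retention is evidenced not by a junction but by gapless
reads crossing an exon–intron boundary with at least 8 matched bases on each
side (the anchor guards against ragged read ends); it is quantified as
`B / (B + c_natural)` where `B` is the mean of the donor-side and
acceptor-side boundary coverages — the mean, because one retained-intron
molecule crosses two boundaries while contributing only one junction-read
equivalent of support.

Default calling thresholds are `min_reads = 10` and `min_fraction = 0.05`:
small enough to catch minor isoforms in the 0–25% range, large enough that
event-free simulations at depth 10⁴ produce no calls (a tested property).
For a forward junction whose ends are both exonic, the implied RNA change is
the deletion of the exonic bases strictly between donor and acceptor,
reported in c.-anchored r. numbering; junctions with an intronic end,
back-junctions and complex events are reported as `r.?`.

## Allele-level conversion and NMD

`percent_of_variant_allele = 100 × fraction / allele_balance`, capped at 100.
The default `allele_balance = 0.5` (balanced biallelic expression) is the
assumption that underlies both the "equal depths ⇒ total effect" reading and
the 42%-of-allele arithmetic; it is stated here prominently because it is an
assumption, not a measurement, unless a heterozygous exonic marker is
available. A marker is accepted as heterozygous when both base classes reach
10 reads and the minor fraction reaches 0.05, and counted as *balanced*
within [0.3, 0.7] — the published workflow gives no numeric criterion for
"heterozygous variant in RNA", so these are configurable defaults. An effect
is graded *total* at ≥90% of the variant allele, separating total calls from
partial ones while tolerating sampling noise.

NMD exclusion: a total observed effect needs no exclusion; a balanced marker
excludes silent allele dropout; a skewed marker, or no marker with a normal
result or a partial frameshift product, leaves decay possible
(`not_excluded`); a partial in-frame product is not an NMD substrate
(`not_applicable`). Under decay with survival *s* and balanced alleles, the
expected marker ratio is *s*/(1+*s*), a closed form the simulator-estimator
pair reproduces within three standard errors in the test suite.

## Prediction triage and concordance

Predictor scores are inputs; neither tool is executed. Percentage-scale
predictions bucket as high (>50), moderate (20–50, both boundaries
inclusive) and negative (<20); delta-scale predictions are mapped by ×100
after taking the maximum of the four deltas. In the concordance cross-tab
the textual label "NTR" (nothing to report) is a negative call regardless of
its residual percentage, matching the published table layout. One fixture
row carries a negative current-version label alongside a positive
previous-version annotation; the previous-version call is stored as the
effective prediction for that row (the verbatim text is retained), which is
the only reading under which the published marginals (19/17/14/3) are
reproducible.

The high-confidence positive predictive value counts high-bucket variants
whose RNA outcome is a demonstrated total or partial splice event, divided
by all high-bucket variants, rounded half-up. A "complex" RNA outcome (one
fixture row: multiple alterations, mechanism unresolved) counts as a
transcript modification in cohort summaries and outcome marginals, but is
not credited to a predictor as a validated splice effect in the PPV — the
predictor made a site-specific claim that the complex result neither
confirms nor refutes. The published whole-dataset sensitivity/specificity
pairs cannot be reconciled with the underlying per-variant table under any
definition tested, and are therefore not computed by this package.

## ACMG combination

Codes carry an effective strength (suffixes `_S`, `_M`, `_P`, `_NA`);
`_NA` codes are recorded but contribute nothing. The combining rules are the
standard ACMG-AMP patterns (see the `acmg_engine` module docstring).
Strength-modifier semantics were validated against the packaged 53-variant
table, which the engine reproduces row-for-row. Two deliberate choices:

* Strong benign evidence (e.g. `BP7_S` from a demonstrated-normal transcript
  with decay excluded) overrides isolated moderate/supporting pathogenic
  context codes, yielding likely benign rather than VUS. If the pathogenic
  codes would reach class 4/5 on their own, the evidence genuinely conflicts
  and the variant stays a VUS; benign evidence alongside strong-or-better
  pathogenic evidence raises an error.
* `derive_rna_codes` maps a total frameshift event to full-strength `PVS1`,
  a total in-frame event to `PVS1_M`, and a partial event to `PVS1_NA`
  unless a monoallelic assay showed the effect is total on the variant
  allele (`PVS1_S`). This is conservative: a clinician may justifiably
  assign full `PVS1` to an in-frame deletion of a critical domain, but that
  is prior biological knowledge, so it enters through the criteria list
  (PM2, PS3, PP1, … are always external inputs), never by inference here.

Large duplications: chimeric back-junction reads prove the tandem
arrangement; with a frame-disrupting length the variant is pathogenic,
without chimeric proof (or with a frame-preserving length) it remains a VUS.

## The simulator: what it emulates and what it does not

Reads are drawn per molecule: category (allele of origin; aberrant or not;
for frameshift products, NMD survival) and then a uniform start position on
that isoform. Category weights include a factor of
(isoform length − read length + 1), the fragmentation length bias of
short-read library preparation; with it, per-base coverage is proportional
to molecule abundance, so junction fractions and marker ratios are unbiased
estimators of the configured molecule fractions. NMD is a uniform survival
probability applied only to frameshift isoforms (published workflows never
quantify decay, so survival is a free parameter; 1.0 means no decay and 0.3
is a reasonable enabled default). Back-junction reads carry a signed gap
internally and are written to SAM as primary + supplementary split-read
pairs, since an `N` CIGAR operation cannot run backwards.

The simulator does **not** model sequencing error, base qualities, capture
efficiency, positional coverage bias, multi-isoform physiological
alternative splicing, or pseudogene ambiguity. Passing tests therefore show
that the estimators recover the configured truth under clean sampling noise
— they do not show robustness to alignment artefacts or to genes with
processed pseudogenes, both of which real panels must handle upstream.

## Packaged transcript models and problem sizes

The packaged transcript models are synthetic approximations built for the
worked examples: exon boundaries that carry published c. coordinates are
exact (PTEN exon 3 = c.165–209; MLH1 exon 3 ending c.306 and exon 10 =
c.791–884; MSH2 exon 7 = c.1077–1276; the BRCA2 window's exon 2 = c.68–316),
while the remaining exon lengths and all intron lengths are invented. The
BRCA2 entry models only a five-exon capture window around its exon 3, with a
100-nt 5′UTR segment on the first window exon so that every junction has a
full read-length window on both sides (a first exon shorter than the read
length would truncate junction windows and bias the shared-site reference
mean). Low expression of a gene in blood is emulated purely through the
depth parameter.

Simulations in the tests and the acceptance script use depths of 10,000–
20,000 reads per gene and 100-nt reads — large enough that three binomial
standard errors separate the scenarios of interest, small enough that the
whole suite runs in seconds. Stochastic assertions are made at three
standard errors with the standard error computed from the realized
informative read count, never from a hard-coded width.

## Known limitations

* Phasing of the splice variant to the marker is not performed; the
  simulator provides truth tags, and real-data phasing is out of scope.
* `combine` covers the code families appearing in splice-variant
  classification practice; gene-specific VCEP rule sets are not modelled.
* Protein-level HGVS (e.g. frameshift termination positions) is not
  generated, as it requires real sequence.
* The replicate-to-replicate spread reported for low-expression genes
  (e.g. 42–82% of the variant allele across libraries) is surfaced by
  running replicates with different seeds; the package does not attempt to
  reconcile such spreads into a single estimate.
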