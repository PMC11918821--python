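# splicepanel

Junction-level interpretation of targeted blood-RNA panel sequencing for the
classification of putative splice variants in hereditary-cancer genes.

Clinical gene-panel sequencing produces many variants of unknown significance
(VUS), a large share of which are *predicted* to disturb splicing. Sequencing
the transcripts of the same genes from a blood sample answers the question
directly: an exon-skipping, cryptic-site or intron-retention isoform either
appears at the expected abundance or it does not, and a tandem exon
duplication betrays itself through chimeric "back" junctions. `splicepanel`
implements that interpretive workflow as a tested library for people building
or evaluating RNA-based variant-classification pipelines: it quantifies
splice junctions from gapped alignments against a transcript model, types
aberrant events, converts junction fractions into allele-level effect
estimates with nonsense-mediated-decay (NMD) caveats, triages variants by
splice-prediction scores, and combines the evidence into the familiar
ACMG-AMP five-tier classes. A ground-truth read simulator generates every
scenario the workflow must recognise, and the package ships a 53-variant
evidence table and a 4-duplication table as reference fixtures.

## The quantities at the core

For a junction *j* with read count *c(j)*, relative expression is

```
rel(j) = c(j) / (c(j) + r(j))
```

where *r(j)* is the mean count of the natural (reference-transcript)
junctions sharing *j*'s donor or acceptor site. A heterozygous total event
under balanced biallelic expression therefore reads out at 0.5 — the
"equal depths of full-length and exon-skipped transcripts" situation. The
allele-level effect is

```
percent_of_variant_allele = 100 × rel(j) / allele_balance   (capped at 100)
```

with `allele_balance = 0.5` unless a heterozygous exonic marker says
otherwise. An observed fraction of 0.21 thus means 42% of the
variant-carrying allele's transcripts are aberrant. Intron retention is
quantified from gapless reads crossing the exon–intron boundary rather than
from a junction, and a junction whose acceptor lies at or 5′ of its donor is
a back-junction: direct transcript-level proof that a duplicated exon sits in
tandem. ACMG evidence codes (`PVS1`, `BP7`, … with `_S`/`_M`/`_NA` strength
modifiers) are combined by the standard rules, with strong benign evidence
overriding isolated rarity/in-silico codes.

## Worked example

Simulate a heterozygous variant that causes total skipping of PTEN exon 3
(45 nt, in frame), quantify it, and interpret the result:

```python
from splicepanel import *
from splicepanel.junction_quant import calls_to_frame

pten = load_transcript_models()["PTEN"]
cfg = ScenarioConfig(transcript=pten, depth=10_000, seed=2024,
                     event="exon_skip", event_params={"exons": 3},
                     allele_balance=0.5, per_allele_event_fraction=1.0)
reads = simulate_reads(cfg)
matrix = count_junctions(reads, pten)
calls = detect_events(matrix, pten)
print(calls_to_frame(calls).to_string(index=False))
```

```
gene event_type  donor  acceptor  relative_expression  supporting_reads affected_exons   rna_change
PTEN  exon_skip    464      1160             0.484174               413            3-3 r.165_209del
```

One aberrant junction is called: an exon-3 skip supported by 413 reads at a
relative expression of 0.48 — indistinguishable from the 0.5 a fully
penetrant heterozygous event produces. Converting to the allele level and
deriving evidence codes:

```python
pct = percent_variant_allele(calls[0].relative_expression, allele_balance=0.5)
# 96.8 -> grade "total"
codes = derive_rna_codes(AlleleEffect(pct, "total", "not_applicable"),
                         frame=frame_effect(parse_hgvs_r("r.165_209del")))
# ['PVS1_M']  (total but in-frame -> moderate strength)
combine(["PM2", "PVS1_M"])   # -> 3
predict_rtpcr_size(370, parse_hgvs_r("r.165_209del"))  # -> 325 (bp)
codons_overlapped(165, 209)                            # -> 16 codons lost
```

The skip removes 16 codons and predicts a 325 bp RT-PCR product from a
370 bp reference amplicon. Note the conservative default: a *total but
in-frame* event earns only moderate-strength loss-of-function evidence, which
with rarity alone leaves a VUS; upgrading such calls (e.g. when the deleted
codons are known to be functionally critical) is a clinical-context decision
supplied through the criteria list, not inferred by the engine.

The same stages are available from a thin CLI
(`splicepanel simulate | quantify | classify | report`); `classify` and
`report` run against the packaged 53-variant evidence table by default.

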