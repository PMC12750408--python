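Benchmark fixture tables
========================

Hand-transcribed prediction/truth rows from the printed result tables of
the originating study, used by dyespy.metrics.score_fixture_table to
re-derive the published summary statistics under the study's scoring
conventions.  Row labels (hD#/D#) and cell text (support percentages,
"IC", "No Match", "no color match") are kept as printed.

table5.tsv  - nonoxidative mixture identification on dyed hair
              (14 rows; parenthesized codes such as "(LL)" mark pigments
              outside the modeled label space).
table7.tsv  - oxidative mixture identification on dyed hair under the
              20-80 train/test partition (42 rows incl. the nanorod
              negative control hNRs).
table9.tsv  - cross-study validation rows, external data set A
              (21 samples, all three phases).
table10.tsv - cross-study validation rows, external data set B
              (photodegradation series: 3 dyes x 8 weeks).
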