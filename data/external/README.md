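# External empirical inputs

The re-analysis of the curated empirical dataset needs four files that are
distributed as supplementary material / external resources and are not
bundled here:

- `timetree_189_species.nwk` — the 189-species time-calibrated tree
  (TimeTree export, branch lengths in My, polytomies resolved).
- `presence_absence_matrix.tsv` — species x candidate-gene matrix of
  {0,1,?} (first column `species`, one column per gene).
- `prdm9_states.tsv` — two-column TSV `species<TAB>{0,1,?}` of PRDM9 status.
- `zcwpw1_states.tsv` — same format, curated ZCWPW1 status calls.

Place them in this directory to enable the empirical reproduction test in
`tests/test_acceptance.py`.
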