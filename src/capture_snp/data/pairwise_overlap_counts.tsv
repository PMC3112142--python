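# Published pairwise SNP-set partition counts for the four samples
# (two patients x leukocyte/tumor) and the published overlap percentages.
sample_1	sample_2	only_in_sample_1	only_in_sample_2	in_both	overlap_percent
patientA-leuko	patientA-tumor	1924	1517	829	19.4
patientB-leuko	patientB-tumor	729	1558	798	25.9
patientA-leuko	patientB-leuko	2086	860	667	18.5
patientA-tumor	patientB-tumor	1654	1664	692	17.3
patientA-leuko	patientB-tumor	2044	1647	709	16.1
patientB-leuko	patientA-tumor	920	1739	607	18.6
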