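# Headline counts and percentages of the published reference screen.
# false_positive_pct is the recomputed 25/(1055-12) value.
name	value
total_scores	12187
distinct_clones	8100
n_assays	52
max_assay_hits	3124
n_both_nucleotide_assays	42
n_ambiguous_clones	2
selection_criterion_a	467
selected_clones	738
selected_pct	9.1
unambiguous_clones	7228
both_nucleotide_clones	7230
unambiguous_pct	99.97
conflicting_clones	60
multi_marker_clones	1586
conflict_pct	3.8
confirmed_clones_a	114
confirmed_clones_c	83
confirmed_clone_scores	1055
unverified_scores	37
untestable_scores	12
false_positive_scores	25
false_positive_pct	2.4
false_negative_scores	114
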