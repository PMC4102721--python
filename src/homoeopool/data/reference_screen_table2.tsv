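# Published reference screen: multiplicity histogram — number of
# putative clones identified by exactly k assays, over all assays
# and excluding the promiscuous assay with >3000 hits.
n_assays	n_clones_all	n_clones_excl
1	6051	3875
2	1106	912
3	387	348
4	280	220
5	122	127
6	96	71
7	25	24
8	20	16
9	8	7
10	5	2
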