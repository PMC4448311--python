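# Published ranking of eleven B. subtilis riboswitches within a 157-nt
# non-overlapping window scan of intergenic regions (28340 windows total,
# regions longer than 150 nt), under the {L, MFE, GC, RND} classifier.
# overlap_pct: percentage overlap of the best-ranked window with the riboswitch.
# probability: classifier riboswitch probability of that window.
riboswitch	overlap_pct	rank	total	probability
TPP	82.9	347	28340	0.76
Guanine	90.1	535	28340	0.735
ATP	85.6	1159	28340	0.676
Lysine	83.5	2278	28340	0.612
Adenine	100	2459	28340	0.604
FMN	51.7	3880	28340	0.547
preQ1	80	4051	28340	0.541
Magnesium	62.3	4212	28340	0.536
Glycine	91.7	5200	28340	0.508
Tryptophan	100	6074	28340	0.484
SAM-I	68.8	12330	28340	0.356
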