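row	library	reads	unique
sequences of 18-30 nt	0HAI	22265577	6596317
sequences of 18-30 nt	12HAI	27075645	10712075
sequences of 18-30 nt	24HAI	21236500	9420781
mapping to genome	0HAI	19203513	4856925
mapping to genome	12HAI	22332607	7892704
mapping to genome	24HAI	17359816	7115379
CDS matched	0HAI	600910	211949
CDS matched	12HAI	1570839	338298
CDS matched	24HAI	1322306	243265
non-coding total	0HAI	17642144	NA
non-coding total	12HAI	19201655	NA
non-coding total	24HAI	14737124	NA
known miRNA	0HAI	400047	1724
known miRNA	12HAI	873690	2506
known miRNA	24HAI	781907	2314
rRNA	0HAI	2289143	24748
rRNA	12HAI	1388914	23099
rRNA	24HAI	747877	19579
tRNA	0HAI	277627	8121
tRNA	12HAI	274039	7349
tRNA	24HAI	421275	6878
snoRNA	0HAI	40642	8790
snoRNA	12HAI	44927	6001
snoRNA	24HAI	28636	4755
snRNA	0HAI	5956	1679
snRNA	12HAI	6005	1390
snRNA	24HAI	3623	1079
others	0HAI	14628729	4345729
others	12HAI	16614080	7138503
others	24HAI	12753806	6489573
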