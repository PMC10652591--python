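alias	canonical
tss1500	TSS1500
tss200	TSS200
1stexon	FirstExon
firstexon	FirstExon
first_exon	FirstExon
1st_exon	FirstExon
5'utr	UTR5
5utr	UTR5
utr5	UTR5
5_utr	UTR5
body	Body
gene_body	Body
3'utr	UTR3
3utr	UTR3
utr3	UTR3
3_utr	UTR3
other	Other
intergenic	Other
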