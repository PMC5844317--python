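region,balancer,genes_sequenced,single_allele_genes,single_allele_identified,two_allele_genes,two_allele_identified,total_identified
chrIII_mid,sDp3,43,37,21,6,6,27
chrV_left,eT1,46,6,5,40,30,35
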