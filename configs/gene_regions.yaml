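# Drug-target gene spans (editable; approximate Ensembl gene boundaries).
# Flanks follow the study design: SLC5A1 ± 500 kb, SLC5A2 ± 1000 kb.
GRCh37:
  SLC5A1:
    gene: SLC5A1
    chrom: "22"
    start: 32439248
    end: 32509016
    flank_kb: 500
    genome_build: GRCh37
  SLC5A2:
    gene: SLC5A2
    chrom: "16"
    start: 31494323
    end: 31502089
    flank_kb: 1000
    genome_build: GRCh37
GRCh38:
  SLC5A1:
    gene: SLC5A1
    chrom: "22"
    start: 32043260
    end: 32113029
    flank_kb: 500
    genome_build: GRCh38
  SLC5A2:
    gene: SLC5A2
    chrom: "16"
    start: 31483002
    end: 31490768
    flank_kb: 1000
    genome_build: GRCh38
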