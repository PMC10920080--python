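# Minimal transcript models for the four driver genes targeted by the panel.
#
# Format: blank-line-separated blocks of TAB-separated key/value lines.
#   gene          gene symbol (starts a new block)
#   chrom         chromosome name
#   strand        + or -
#   codon_offset  codon number of the first modelled codon (1 = CDS start)
#   segment       1-based inclusive genomic interval of a coding segment
#                 (listed in genomic order; transcription order is derived
#                 from the strand)
#   target        1-based inclusive genomic interval covered by the assay
#                 (amplicon territory; used for gene assignment). The extra
#                 CDKN2A target covers the intron-1 alternative-transcript
#                 region.
#   sequence      coding-strand CDS sequence; multiple lines are concatenated
#
# KRAS codons 1-37 carry the reference first coding exon at its GRCh37
# location (so e.g. chr12:25398284 C>A encodes G12V); remaining sequence is
# synthetic but internally consistent (no premature stops, canonical hotspot
# codons: KRAS Q61 CAA, TP53 P72 CCC / R175 CGC, CDKN2A L117 CTG,
# SMAD4 D493 GAC / W509 TGG).

gene	KRAS
chrom	chr12
strand	-
codon_offset	1
segment	25398208	25398318
segment	25380167	25380346
target	25398158	25398368
target	25380117	25380396
sequence	ATGACTGAATATAAACTTGTGGTAGTTGGAGCTGGTGGCGTAGGCAAGAGTGCCTTGACGATACAGCTAATTCAGAATCA
sequence	TTTTGTGGACGAATATGATCCAACAATAGAGAGTGTGAGACGTAAGACCCCGGCAGTGCAGACTCAAATGGGATTGTGGC
sequence	ACCGGTGTGAAGTTCGTGGGCAAGGTGAAAGGTGCCATTTGACGCTTACATGTCTCGGGTATGCCCACTTAAGCAGGGGT
sequence	AAACCAGGTAGCGTGTACATATGCGTAAAATTGAGATCCGCCGTAGATCGG

gene	CDKN2A
chrom	chr9
strand	-
codon_offset	1
segment	21970901	21971050
segment	21968101	21968418
target	21970851	21971100
target	21968051	21968468
target	21970650	21970850
sequence	ATGGTACCGAGGTTCGTGTCCGAAGTAGCCTTCACCGCACGCCCTCTTTGGTACGCTAGTAACTATCCACTATTTGGACT
sequence	TTGCAGACTCTCCGAACCGGGTCACATGTGTCGGAGCATACCTATCGAAACTTTTCTCGGATCCGTCTTGGTCCCGCCCC
sequence	GCGAAACAGAATTACGCGGTCTCTCTCTGATCAATGTGCTAATCCCCATATCGGGTTGTGTTAGAGCCGCCAAGCTTGGA
sequence	TATCACCAGGCCCGGGTAAGGTATATGTATTTACTACCCCTATTGATTCTAGACGTCCCCAGAAAGGATTCGGTACGGCG
sequence	GACTATGAAAGTTTATCAGATGTGCCAGCTGCATGAGTATTGGAGAGACAATCTAGGATATCCGGTGCCTCATATAACGT
sequence	GCAGCACTAGTAGTATATTCATCCCTTTCTATCGCGAATCCAATCTTTTTTGGCCTGACAAATATACC

gene	TP53
chrom	chr17
strand	+
codon_offset	1
segment	7570001	7571179
target	7569951	7571229
sequence	ATGCGTCGCGACGTGTACATTCGCGACAGAGATCACAGGAAAAAAAGCCGCCTGGCTAGTCGCGTGGAGCGTCAGGTGAT
sequence	GGCACCCTTGGCGCTACCTGAGTCCCCCACCTGCGATCTCAGTATCCCCCGCCACTTTGGTGACGCTCAAATCGCGAAAG
sequence	TGGCTCTTTCGCCTATCCCTTCCGTTTCGTTCTTCGGCGGCCCTACCACAGACCCCGGCGGTCATTCGGCGAGATATACC
sequence	GCCGCGCGGTGTCATGCAGGGCAAGTGGGGTCCAACTGCAAGATGAGCTTAAAGCAGTCCCGAACCCTTGCTGACCTCAC
sequence	CTTTAGAATTCCATGCTACTGGAATCCATTCCTTCGCGACATCACGTATAGTATCTGTCATACAACGGCACTATCTGGCT
sequence	TATGGCCCCTCACCGGTGCATTTGACCCCCTTGCCCCAGAGTTGATCCGTACCACGGTTTTTTTAAATCGATTATGCACA
sequence	AGTCATTGCGCTTGTGATAGTCTCTTACTGCTTCGGGTGTACCGCAACGACTCTAAGGCCCTAGGAGTTGGAGTCCATAG
sequence	CTTGAAAGTGGCTCCTTATATATTTGCTCTCCCAGAACAAGGTGTGTATGTCATGCGTGATGTATTCACCCACACTACCT
sequence	CAACTTCGCATGTGTGGCTGCGCAGGATCGTGCCAGCCGGTCACGCCAAAGATAATGACACGGAAGTCAAGAGCCCCAAG
sequence	GCCACCCAGGCACGAACGAGGGAGGGAAGTGAGTGGATTAAGATGGTAAAAGAAGAAGTAGACGATTGGCCCTCCGTGAC
sequence	TGGAAGAATCAATTACGCAAGGGATATACTCCTGACGAAACGAGGACGGAGCCTATACACGAACTCGTCTTCAATACCTC
sequence	TCACGGCAGGCGATTTCCGGTCGCATTCAAGCCGGCGATCCAGTAAGCTGCCGGAATCGGCGACGACCGAGGTTCGCGTC
sequence	TATATGCTTAAAGAAGAAACTATCGTAACGTGCATAGCCACTATTCGCACTCAGATGTCCGAGTCAGATTTTCCTTCGTT
sequence	TAAGATAGGCGACCTTAATAGCTGTTGTGGTCAGATATATCTGCATAGACTAATACTCTCCTCATGCATGAGGCCTGTGG
sequence	ATACCAACCATGAATGCACCATGAACATTATATCGCGGCAGTGTCCGTCAGAGGTACCT

gene	SMAD4
chrom	chr18
strand	+
codon_offset	1
segment	48575001	48576656
target	48574951	48576706
sequence	ATGACTGTAAGCGCCAGGATCAGATGCATCCACATGGACTCTCTGCTCGTCACTCGATTAACGCATCGGCTCAGCCGACA
sequence	CTTTTCGCTACCCAGTCTTAGTGTAAAGAACCCAAAGGTGAGCATACGAACCGGCCCTTCACAAGCTATGTGTTCTCGAC
sequence	GGCACACACTCTACAACGACACTGGTAACTACAGCCAACACCTCGAAGCGGGCACAATGTGGAATCTATGGATATCCATG
sequence	GCTAAAAGACCCCTGCTAGTTTGTTCTATAGGCAATAGAATTGGCAGGACCAACTCCACACGAGCTACCACAGCATCCCG
sequence	AGCAAGTGCCCGGAACCCTTATGGCCATTCGTTAATAATGGAGGAAGAACTAGGCATGTTTTGTTCGGGGAACATGTCGG
sequence	CGGTAAATGCTGTGACTACGCCCCCTCTACATCGATTAATACACGTCTCCACTAGTACATCCTCATGCCAGCTATGCCAG
sequence	ATTATTCACGTGGAGGCGGTCATCGTTCTGTACACTTGTTTGCCCAGAAAGAGCAAGGTCGCACCAATGATTGGACCGGA
sequence	CCGCTGCCCCGTACCTTACTCAATGAGCCACAAACTTTTGGTCGCTGGCCGAGAGGGTGGTACATGTCCATGCGAACGTG
sequence	GGATACACAGTGCATCTTGTCCAAAAACGTGGCCGCTCTGTACCGTTGCGAAAAGCCCAACTTCCATGAACTTACTCCGG
sequence	TTTACTAAGAAAGCGGGCGTTGCCGTGGGCTCCCGTCATGAATCTATTAGGAGCGGGTCGTGCGTTCCGTGGTCCCTGGC
sequence	ACGGTATGGAAAGGGTACCACATTCTTTGTGCGTAGAAGCAAGCTCACAGTATCTTCTTTAATTGTTTGCCACGATTTCA
sequence	TCATTTGTCAACACGGTGGCCTTACTGTAACTAGTTGCCGTCCAAGAGCCCAGGGAATTTCCAAAGTCTCAAACAAGAGA
sequence	AAAGTGGGAGACGATATTCGCGAAGACTACCGGAGTAGGTCTAACCAGCGCGTAAATCAGCGTGGGCTGACCCAGCTAGC
sequence	GCGTGAGGATGACTGGCTAGGGAAATGTTGGACTCGTACTAAACTGGCTCTTGAAATGGCAGTCCCAGATTCGGTGGGTG
sequence	TACGACGAGGGAGTAACAATAATGCATCGGGAGGCCGGTCAAAGTCCATTTTCGTTTCCCGTAAAACATTATCTCGTTTC
sequence	GCCCGTGGTATGTTCAGGGGGTATTCCTCCCAACGCCCACGGATAAACGTACGGGTAGGAGGAGGACAGCGTAAGTTTGG
sequence	GCGTGTGGCAGGTCGCACCGGGTTAAACGGGAGATGTTGCGTGACCGCGCCAGCAAGTTCACGGAGTGTTGAGTACCCGG
sequence	TAACACCGACGAGCCAGCCTGGAAGTGCGCGCCGGGTGCGTTCCGCGTCCGTGCTAGGCGGCGCCCCACTTGGTTCTAGA
sequence	TTCGCGATTAGTTGGCCGGTATTTATCCGAAAGAACGACTCCATCCACGTGTCCCTAATCAACCACGAGGCTATGGCTAT
sequence	GTCCTGGAACCCTTCAAGTGTGGGGTATGCGGCTGCGCCCCTACTCTACGGACGTTGGCTCACCGTATTTGCGGAGCGGG
sequence	CGTCACCTCCACCCGCACCTAGGCCGCGTACTGCCATGATAACGACGGCATCCCCA
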