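# Predefined overlap fragments for common fusion-PCR applications.
# name	sequence_5p_to_3p
GFP	ACAGCTCCTCGCCCTTGCTCACCAT
GFP_Celegans	AGTCGACCTGCAGGCATGCAAGCT
mCherry	TATCTTCTTCACCCTTTGAGACCAT
RFP	TATCTTCTTCACCCTTTGAGACCAT
YFP	ACAGCTCCTCGCCCTTGCTCACCAT
tdTomato	TGACCTCCTCGCCCTTGCTCACCAT
Illumina paired end adapter 1	ACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina paired end adapter 2	CTCGGCATTCCTGCTGAACCGCTCTTCCGATCT
Illumina paired PCR primer 1	AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina paired PCR primer 2	CAAGCAGAAGACGGCATACGAGATCGGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT
Illumina paired sequencing primer 1	ACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina paired sequencing primer 2	CGGTCTCGGCATTCCTACTGAACCGCTCTTCCGATCT
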