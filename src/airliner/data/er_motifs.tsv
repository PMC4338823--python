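# Significant motifs discovered in non-repetitive edited regions (47 training ERs),
# after E-value < 0.05 and ultraconserved-sequence filtering and permutation testing
# (p < 0.01). Columns: id, consensus (best possible match), type, E-value.
id	consensus	type	evalue
1	CCAGGCTGGAGTGCAGTGGCGCAATCTCA	non-palindromic	1e-126
2	GGATTACAGGCGTGAGCCACCGCGCCTGG	non-palindromic	3.60e-123
3	GAGGTGCTGGGATTATAGGGG	non-palindromic	8.50e-35
4	CCTGACCTCATGAGA	non-palindromic	4.10e-22
5	AGACATGGAACCAACCTAAATGCCCACCA	non-palindromic	9.40e-17
6	AGGAGGCAAAGGAAG	non-palindromic	7.00e-11
7	TGGGATTGCAGGCAT	non-palindromic	1.20e-06
8	TTTCATGGCTGCATAGTATTCTATTGTGT	non-palindromic	1.00e-05
9	TGTAAATTAGTACAGCCTTTATGGAAAAC	non-palindromic	2.90e-12
10	AGTCCCAGCTTCTCGAGAAGCTGGGACT	palindromic	2.7e-97
11	TGCACCCCAGGCTGGGGTGCA	palindromic	8.4e-50
12	CTTGTACTCCCAACATGTTGGGAGTACAAG	palindromic	5.2e-72
13	CTTGAACCTCGGAGGTTCAAG	palindromic	3.9e-28
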