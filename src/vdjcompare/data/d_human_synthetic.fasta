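>TOY00001|IGHD1-1*01|synthetic human-like|F|synthetic toy germline
CCGATAATACACTATG
>TOY00002|IGHD2-2*01|synthetic human-like|F|synthetic toy germline
TCGAGGCAAGACGACGAGCTT
>TOY00003|IGHD3-3*01|synthetic human-like|F|synthetic toy germline
CTGCAGTGGATGTCTTTCTTTAGGAGAAGTC
>TOY00004|IGHD3-10*01|synthetic human-like|F|synthetic toy germline
AAAGAAGCCATGAGTTGTGTTTTTAGCACTT
>TOY00005|IGHD3-22*01|synthetic human-like|F|synthetic toy germline
TATTTGCATCCCCGGGCAGTTGTGAAGA
>TOY00006|IGHD4-17*01|synthetic human-like|F|synthetic toy germline
CTTCATCCCCTAAACGC
>TOY00007|IGHD5-12*01|synthetic human-like|F|synthetic toy germline
ACGAAGTAGGGGCTCAAG
>TOY00008|IGHD6-19*01|synthetic human-like|F|synthetic toy germline
TTGGGTCGGTCTGATTCGATTGT
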