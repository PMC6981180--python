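>TOY00001|IGHD1-1*01|synthetic rat-like|F|synthetic toy germline
GACGATGGGA
>TOY00002|IGHD1-12*01|synthetic rat-like|F|synthetic toy germline
GCTCTAGATAC
>TOY00003|IGHD2-3*01|synthetic rat-like|F|synthetic toy germline
TGAGCGGTCATCA
>TOY00004|IGHD2-14*01|synthetic rat-like|F|synthetic toy germline
GACACCAATTCCTC
>TOY00005|IGHD3-1*01|synthetic rat-like|F|synthetic toy germline
CAGGGGTAGTGG
>TOY00006|IGHD3-2*01|synthetic rat-like|F|synthetic toy germline
GTGGTAGCTATTATAG
>TOY00007|IGHD4-1*01|synthetic rat-like|F|synthetic toy germline
AGCACTGCGTC
>TOY00008|IGHD5-1*01|synthetic rat-like|F|synthetic toy germline
ATTTGTCACCAA
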