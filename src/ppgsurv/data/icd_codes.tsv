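# Cardiovascular outcome code lists, version 1.
# category	icd_version	codes (comma-separated prefixes; ranges with '-')
CVD	9	3361, 36231, 36232, 39-44
CVD	10	I00-I78, G951, H431, H432, O10, S066, Z951, Z955
CHD	9	410, 412, 414
CHD	10	I21-25, Z951, Z955
MI	9	410, 412
MI	10	I21-I23, I252
HF	9	428
HF	10	I110, I130, I132, I50
hypertension	9	401-405
hypertension	10	I10-I13, I15, O10
stroke	9	3361, 36231, 36232, 430, 431, 4329, 43301, 43311, 43331, 43381, 43391, 434, 436
stroke	10	I60, I61, I629, I63, I64, I678, I690, I693, G951, H341, H342, S066
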