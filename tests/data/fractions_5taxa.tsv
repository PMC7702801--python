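taxon_0	taxon_1	taxon_2	taxon_3	taxon_4
0.1820759970	0.2467942026	0.1599149521	0.1431902497	0.2680245986
0.1622667839	0.2171121500	0.2026270268	0.2848006968	0.1331933425
0.3524837720	0.1088954643	0.2277700706	0.2097213044	0.1011293887
0.3119219920	0.1831628539	0.0976939105	0.3392129504	0.0680082932
0.0892535099	0.1717697430	0.2888572269	0.2551016510	0.1950178693
0.1023434023	0.2859557683	0.3380555021	0.1973914404	0.0762538868
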