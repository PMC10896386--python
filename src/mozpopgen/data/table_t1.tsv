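# Sampling locations in Kenya and the number of samples successfully
# sequenced, grouped by taxon. Verbatim transcription of the published
# sampling table. Note: the accompanying text describes the earliest
# Turkana cohort as month 2 of 2009, while this table lists year 2006;
# the table is transcribed as printed.
location	latitude	longitude	year	month	arabiensis	coluzzii	gambiae	quadriannulatus
Kwale	-4.572	39.257	2019	7	7	0	0	2
Mwea	-0.717	37.382	2007	6	18	0	0	0
Mwea	-0.717	37.382	2014	9	15	0	0	0
Mwea	-0.717	37.382	2020	2	46	0	0	0
Mwea	-0.717	37.382	2020	12	26	0	0	0
Mwea	-0.717	37.382	2021	1	29	0	0	1
Mwea	-0.717	37.382	2021	2	16	0	0	0
Teso	0.626	34.236	2013	8	24	0	4	0
Teso	0.626	34.236	2019	7	17	0	14	0
Teso	0.626	34.236	2019	12	43	0	17	0
Thika	-1.061	37.181	2019	7	45	0	1	0
Thika	-1.061	37.181	2019	8	19	0	0	0
Turkana	3.717	34.857	2006	2	19	5	1	0
Turkana	3.717	34.857	2019	1	51	13	0	0
Turkana	3.717	34.857	2019	9	123	8	0	0
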