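sample_id	stage	histology
WT01	I	FH
WT02	I	FH
WT03	I	FH
WT04	I	FH
WT05	III	FH
WT06	III	NA
WT07	IV	NA
WT08	NA	NA
WT09	I	FH
WT10	I	FH
WT11	I	FH
WT12	I	NA
WT13	V	NA
WT14	I	FH
WT15	II	FH
WT16	III	FH
WT17	III	NA
WT18	III	NA
WT19	III	NA
WT20	IV	NA
WT21	IV	NA
WT22	V	NA
WT23	I	FH
WT24	NA	FH
WT25	NA	FH
WT26	NA	FH
WT27	III	UH
WT28	III	FH
WT29	IV	NA
WT30	V	FH
WT31	III	NA
WT32	IV	NA
WT33	NA	NA
WT34	I	UH
WT35	III	FH
WT36	III	NA
WT37	III	NA
WT38	III	FH
WT39	IV	FH
WT40	IV	NA
WT41	V	NA
WT42	NA	NA
WT43	NA	NA
WT44	NA	UH
WT45	NA	NA
WT46	I	UH
WT47	III	UH
WT48	IV	FH
WT49	V	NA
WT50	NA	NA
WT51	NA	NA
WT52	III	UH
WT53	III	FH
WT54	IV	NA
WT55	IV	NA
WT56	V	NA
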