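sample_id	chromosome	start	end	event_type	artifact_flag
WT09	chr11	2000000	32500000	CNN_LOH	0
WT10	chr11	2000000	32500000	CNN_LOH	0
WT11	chr11	2000000	32500000	CNN_LOH	0
WT12	chr11	2000000	32500000	CNN_LOH	0
WT13	chr11	2000000	32500000	CNN_LOH	0
WT14	chr1	142000000	247249719	CNA_gain	0
WT14	chr11	2000000	32500000	CNN_LOH	0
WT15	chr1	142000000	247249719	CNA_gain	0
WT15	chr11	2000000	32500000	CNN_LOH	0
WT16	chr1	142000000	247249719	CNA_gain	0
WT16	chr11	2000000	32500000	CNN_LOH	0
WT17	chr1	142000000	247249719	CNA_gain	0
WT17	chr11	2000000	32500000	CNN_LOH	0
WT18	chr1	142000000	247249719	CNA_gain	0
WT18	chr11	2000000	32500000	CNN_LOH	0
WT19	chr1	142000000	247249719	CNA_gain	0
WT19	chr11	2000000	32500000	CNN_LOH	0
WT20	chr1	142000000	247249719	CNA_gain	0
WT20	chr11	2000000	32500000	CNN_LOH	0
WT21	chr1	142000000	247249719	CNA_gain	0
WT21	chr11	2000000	32500000	CNN_LOH	0
WT22	chr1	142000000	247249719	CNA_gain	0
WT22	chr11	2000000	32500000	CNN_LOH	0
WT23	chr11	2000000	32500000	CNN_LOH	0
WT23	chr18	1	76117153	WCG	0
WT24	chr11	2000000	32500000	CNN_LOH	0
WT24	chr18	1	76117153	WCG	0
WT25	chr11	2000000	32500000	CNN_LOH	0
WT25	chr18	1	76117153	WCG	0
WT26	chr11	2000000	32500000	CNN_LOH	0
WT26	chr18	1	76117153	WCG	0
WT27	chr1	142000000	247249719	CNA_gain	0
WT27	chr11	1	134452384	WCL_LOH	0
WT28	chr1	142000000	247249719	CNA_gain	0
WT28	chr11	1	134452384	WCL_LOH	0
WT29	chr1	142000000	247249719	CNA_gain	0
WT29	chr11	1	134452384	WCL_LOH	0
WT30	chr11	1	134452384	WCL_LOH	0
WT31	chr11	1	134452384	WCL	0
WT32	chr11	1	134452384	WCL	0
WT33	chr11	1	134452384	WCL	0
WT34	chr1	142000000	247249719	CNA_gain	0
WT34	chr11	102077451	134452384	CNA_loss_LOH	0
WT35	chr1	142000000	247249719	CNA_gain	0
WT35	chr11	1	17449758	CNA_loss_LOH	0
WT36	chr1	142000000	247249719	CNA_gain	0
WT36	chr11	102077451	134452384	CNA_loss_LOH	0
WT37	chr1	142000000	247249719	CNA_gain	0
WT37	chr11	1	17449758	CNA_loss_LOH	0
WT38	chr11	102077451	134452384	CNA_loss_LOH	0
WT39	chr11	1	17449758	CNA_loss_LOH	0
WT40	chr11	102077451	134452384	CNA_loss_LOH	0
WT41	chr11	1	17449758	CNA_loss_LOH	0
WT42	chr11	102077451	134452384	CNA_loss_LOH	0
WT43	chr11	1	17449758	CNA_loss_LOH	0
WT44	chr11	102077451	134452384	CNA_loss	0
WT45	chr11	1	17449758	CNA_loss	0
WT46	chr1	142000000	247249719	CNA_gain	0
WT47	chr1	142000000	247249719	CNA_gain	0
WT48	chr1	142000000	247249719	CNA_gain	0
WT49	chr1	142000000	247249719	CNA_gain	0
WT50	chr1	142000000	247249719	CNA_gain	0
WT51	chr1	142000000	247249719	CNA_gain	0
WT52	chr16	45000000	88827254	CNA_loss	0
WT53	chr12	1	132349534	WCG	0
WT54	chr7	1	46805718	CNA_loss	0
WT55	chr14	1	106368585	WCL	0
WT56	chr22	40456765	49691432	CNA_loss	0
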