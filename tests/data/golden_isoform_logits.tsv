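query_id	T000	T001	T002
G00000.1	3.5214472948587803	-4.995319351900283	
G00000.2	-1.6734280645726753	-4.995319351900283	
G00001.1	3.5214472948587803	-5.044012387675324	
G00001.2	3.5214472948587803	-5.044012387675324	
G00002.1	3.5214472948587803	-4.767306972866168	
G00002.2	3.5214472948587803	-4.767306972866168	
G00003.1	3.4119248101318957	-4.767306972866168	
G00003.2	3.4119248101318957	-4.767306972866168	
G00004.1	3.4085551654451685	-5.060458100990957	
G00004.2	3.4085551654451685	-5.060458100990957	
G00005.1	3.5178034012881767	-5.060458100990957	
G00005.2	3.5178034012881767	-5.060458100990957	
G00006.1	-5.052875455208572	3.5637199988872346	
G00007.1	-4.765280726350124	3.5637199988872346	
G00008.1	-4.418232341659568	3.5637199988872346	
G00009.1	-3.900815157282472	3.5637199988872346	
G00010.1	-4.684092410411744	3.5637199988872346	
G00012.1	-2.36304834107987	-5.018111943002763	
G00013.1	-3.667837309105087	-4.791796771641625	
G00015.1	-3.667837309105087	-3.7887769848617916	
G00017.1	-5.5912594665352975	-3.207449788608535	
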