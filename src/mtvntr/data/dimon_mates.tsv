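strain	di_types	mon_types	mate_types	VNTR7	VNTR13	VNTR18	VNTR20	VNTR23	VNTR25
IUM3182	A9/A11	A1	A1/A11	Mon	Mon	Mon	Mon*	Mon	Mon
IUM3179	A11/A19	A1	A1/A19	Mon	Mon	Mon	Mon	Mon	Mon
KFRI3010	A47/A54	A1	A1/A54	Mon	ND	ND	ND	Mon	Mon
IUM3178	A14/A18	A1	A1/A14	Mon	ND	ND	ND	Mon	Mon
KFRI665	A38/A61	A1	A1/A38	UP	ND	Mon	ND	Mon	Mon
KFRI956	A41/A65	A1	A1/A65	Mon	Mon	Mon	ND	Mon	Mon
KFRI39	A33/A57	A1	A1/A33	Mon	Mon	Mon	ND	Mon	UP
KFRI664	A37/A60	A1	A1/A37	Mon	Mon	Mon	Mon	Mon	Mon
KFRI1520	A43/A52	A1	A1/A52	Mon	Mon	Mon	Mon	Mon	Mon
KFRI2521	A46/A53	A1	A1/A46	Mon	Mon	Mon	Mon	ND	Mon
IUM5054	A12/A13	A1	A1/A12	Mon	Mon	Mon	Mon	ND	Mon
NAAS6640	A12/A49	A1	A1/A12	UP	Mon	Mon	Mon	Mon	Mon
NAAS4255	A19/A63	A1	A1/A63	Mon	Mon	Mon	Mon	Mon	UP
NAAS5735	A27/A48	A1	A1/A48	ND	Mon	ND	Mon	Mon	ND
NAAS6833	A50/A55	A1	A1/A50	Mon	ND	Mon	ND	Mon	ND
KFRI57	A34/A58	A1	A1/A34	Mon	Mon	Mon	ND	Mon	ND
KFRI411	A36/A59	A1	A1/A59	Mon	Mon	Mon	Mon	Mon	Mon
KFRI674	A44/A64	A1	A1/A64	ND	Mon	Mon	Mon*	Mon	Mon
IUM4848	A10/A17	A1	A1/A17	Mon	Mon	Mon	ND	Mon	Mon
KFRI666	A39/A62	A1	A1/A39	ND	Mon	Mon	ND	Mon	Mon
KFRI58	A17/A35	A1	A1/A35	Mon	Mon	ND	Mon	Mon	Mon
IUM4841	A1/A16	A1	A1/A16	Mon	Mon	ND	Mon	Mon	Mon
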