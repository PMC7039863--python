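site_id	environment	dmsp_mean	dmsp_sd	unit
H12	YS-sediment	62.5	4.8	nmol/g
HS5	YS-sediment	72.2	8.6	nmol/g
H25	YS-sediment	25.2	9.3	nmol/g
B41	BS-sediment	26.9	4.8	nmol/g
B45	BS-sediment	9.5	1.4	nmol/g
B47	BS-sediment	13.6	1.0	nmol/g
B50	BS-sediment	35.4	2.5	nmol/g
TVG5-3	OT-sediment	6.2	0.3	nmol/g
TVG5-3-PS	OT-polymetallic-sulfide	6.5	0.6	nmol/g
TVG11-2	OT-sediment	6.4	2.6	nmol/g
TVG11-2-PS	OT-polymetallic-sulfide	6.6	2.8	nmol/g
T1	OT-sediment	6.8	2.3	nmol/g
F8	seawater	22.6	0.0	nmol/L
G1	seawater	43.2	0.0	nmol/L
F3	seawater	35.0	0.0	nmol/L
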