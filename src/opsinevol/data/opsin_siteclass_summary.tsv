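gene	omega_avian	selection_avian	omega_mammal	selection_mammal	e_p
RH1	0.061	positive	0.064	negative	0.411
RH2	0.080	neutral
OPN1sw1	0.041	negative	0.178	positive	0.261
OPN1sw2	0.050	negative
OPN1lw	0.024	negative	0.135	neutral	0.215
TMT	0.220	negative
TMT2	0.118	neutral
OPN3	0.101	negative	0.310	positive	0.210
PIN	0.230	positive
VA	0.265	positive
RGR	0.148	positive	0.193	neutral	0.316
RRH	0.155	positive	0.273	positive	0.333
OPN5	0.112	neutral	0.089	neutral	0.497
OPN4x	0.171	positive
OPN4m	0.203	neutral	0.239	positive	0.470
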