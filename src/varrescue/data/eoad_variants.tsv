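gene	protein_change	external_af	called_by_default
APP	p.V717F	0	1
APP	p.I716T	0	0
APP	p.A673T	0.0003632	0
PSEN1	p.A79V	0.00002369	1
PSEN1	p.G206A	0	1
PSEN1	p.H214Y	0.000008952	0
PSEN1	p.P218L	0.0000179	1
PSEN1	p.L262F	0	1
PSEN1	p.R269H	0	1
PSEN1	p.A396T	0	1
PSEN2	p.A85V	0.000008955	1
PSEN2	p.L238P	0.00002687	1
PSEN2	p.R284G	0.000008952	0
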