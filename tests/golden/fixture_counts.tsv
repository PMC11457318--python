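rga_class	A	F
TNL	3	3
RNL	2	2
CNL	3	3
RLK	4	4
RLP	3	3
LYSM	2	2
PARTIAL	2	2
UNCLASSIFIED	0	0
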