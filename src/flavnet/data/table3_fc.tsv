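# Published fragility-coefficient row (2-decimal rounding) for the 12
# candidate reactions of the cut-set table.
reaction	fc
N-3-D-RXN	0.50
LEUCPEL-RXN	0.43
D-4-R-RXN	0.43
RXN-525	0.33
APIGNAR-RXN	1
RXN-600	0.50
RXN-602	0.50
RXN-7652	0.38
PELUDP-RXN	0.43
RXN1F-775	0.50
RXN-7775	0.38
N-C-S-RXN	1
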