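# Curated position/nucleotide preference rules for effective siRNAs,
# transcribed best-effort from the published design-rule literature
# (Reynolds, Ui-Tei, Amarzguioui, Shabalina, Hsieh, Jagla, Takasaki,
# Elbashir, Khvorova, Holen, Matveeva, Chalk).  Positions are 1-based,
# 5'->3' on the SENSE strand; verdict +1 marks a nucleotide preferred in
# high-efficacy siRNAs at that position, -1 a disfavored one.
# This default table is editable data, not code: pass your own file of the
# same shape to use a different rule collection.
rule_set	position	nucleotide	verdict
Reynolds	3	A	1
Reynolds	10	U	1
Reynolds	19	A	1
Reynolds	13	G	-1
Reynolds	19	G	-1
Reynolds	19	C	-1
Ui-Tei	1	G	1
Ui-Tei	1	C	1
Ui-Tei	19	A	1
Ui-Tei	19	U	1
Ui-Tei	1	A	-1
Ui-Tei	1	U	-1
Ui-Tei	19	G	-1
Ui-Tei	19	C	-1
Amarzguioui	1	G	1
Amarzguioui	1	C	1
Amarzguioui	6	A	1
Amarzguioui	19	A	1
Amarzguioui	19	U	1
Amarzguioui	1	U	-1
Amarzguioui	19	G	-1
Shabalina	1	G	1
Shabalina	1	C	1
Shabalina	19	A	1
Shabalina	19	U	1
Shabalina	19	C	-1
Shabalina	19	G	-1
Hsieh	19	U	1
Hsieh	11	G	-1
Hsieh	16	G	-1
Jagla	1	G	1
Jagla	1	C	1
Jagla	10	A	1
Jagla	10	U	1
Jagla	19	A	1
Jagla	19	U	1
Takasaki	3	C	1
Takasaki	10	U	1
Takasaki	13	A	1
Takasaki	19	A	1
Elbashir	19	A	1
Elbashir	19	U	1
Khvorova	1	G	1
Khvorova	1	C	1
Khvorova	19	A	1
Khvorova	19	U	1
Holen	10	A	1
Holen	10	G	-1
Matveeva	10	U	1
Matveeva	19	A	1
Matveeva	13	G	-1
Matveeva	19	C	-1
Chalk	1	G	1
Chalk	1	C	1
Chalk	19	A	1
Chalk	19	U	1
Chalk	13	G	-1
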