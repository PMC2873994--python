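# allele alias map: <allele> TAB <group/synonym label>
Cw*0210	Cw*0202
Cw*0401	Cw*0401G
Cw*0501	Cw*0501G
Cw*0701	Cw*0701G
Cw*0704	Cw*0704G
Cw*1701	Cw*1701G
Cw*1801	Cw*1801G
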