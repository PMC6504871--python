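# Gene membership and facilitatory/inhibitory role per functional module (FM)
# of neuronal migration.  Roles drive the migration-readout rule of each
# per-FM regulatory network: readout = AND(facilitatory) & AND(!inhibitory).
fm	gene	role
FM1	PCM1	facilitatory
FM1	BBS4	facilitatory
FM1	DISC1	facilitatory
FM2	PAFAH1B1	facilitatory
FM2	ZNF365	facilitatory
FM2	NDEL1	facilitatory
FM2	DISC1	facilitatory
FM2	GSK3B	inhibitory
FM3	CDK5	facilitatory
FM3	NDEL1	facilitatory
FM3	DIXDC1	facilitatory
FM3	DISC1	facilitatory
FM4	APP	facilitatory
FM4	NDEL1	facilitatory
FM4	DAB1	facilitatory
FM4	PAFAH1B1	facilitatory
FM4	DISC1	facilitatory
FM5	CCDC141	facilitatory
FM5	MYH2	facilitatory
FM5	DISC1	facilitatory
FM6	AKT1	facilitatory
FM6	ACTB	facilitatory
FM6	CCDC88A	facilitatory
FM6	DISC1	facilitatory
FM7	DISC1	facilitatory
FM7	SOX10	inhibitory
FM7	FOXD3	inhibitory
FM8	DISC1	facilitatory
FM8	RHEB	inhibitory
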