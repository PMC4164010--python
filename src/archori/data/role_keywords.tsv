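# default replication-gene keyword table: role<TAB>keyword
orc1_cdc6	cdc6
orc1_cdc6	orc1
orc1_cdc6	cell division control protein 6
orc1_cdc6	orc 
whip	whip
whip	winged-helix initiator
primase	primase
other_replication	minichromosome maintenance
other_replication	mcm
other_replication	replication factor
other_replication	replication protein
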