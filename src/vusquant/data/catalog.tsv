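code	polarity	strength	type
BA1	benign	stand_alone	population
BS1	benign	strong	population
BS2	benign	strong	population
PS4	pathogenic	strong	population
PM2	pathogenic	moderate	population
BS3	benign	strong	functional_allelic
BP2	benign	supporting	functional_allelic
PS3	pathogenic	strong	functional_allelic
PM3	pathogenic	moderate	functional_allelic
BS4	benign	strong	clinical
BP5	benign	supporting	clinical
PP1	pathogenic	supporting	clinical
PP4	pathogenic	supporting	clinical
PS2	pathogenic	strong	clinical
PM6	pathogenic	moderate	clinical
PPC	pathogenic	supporting	clinical
BP4	benign	supporting	computational
PP3	pathogenic	supporting	computational
BP7	benign	supporting	molecular_impact
BP3	benign	supporting	molecular_impact
BP1	benign	supporting	molecular_impact
PVS1	pathogenic	very_strong	molecular_impact
PS1	pathogenic	strong	molecular_impact
PM4	pathogenic	moderate	molecular_impact
PM1	pathogenic	moderate	molecular_impact
PM5	pathogenic	moderate	molecular_impact
PP2	pathogenic	supporting	molecular_impact
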