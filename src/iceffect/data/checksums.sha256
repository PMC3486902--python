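207783af7caf4e75f0ad1dae14d9cb1b8560ed1a9132daec0b615168b3863011  table1_patients.tsv
75ee8767d4d4f164a29fde35770637fbb3418b1904b259765f3ea24436d356a4  table2_cases.tsv
ca50593912f983f14778dd35d3d8febcbe5ee1a89923730da89b0e4bba013ded  table3_controls.tsv
715251f716984ff6703b6f01f43a29cb22ab12d962f02b645f68cff98300c34e  table5_weighted.tsv
0bf16b628997000717901972bb5ebdb05d76f57b77e2ccd17423f9f2351a85ea  embryo_level_robertsonian.json
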