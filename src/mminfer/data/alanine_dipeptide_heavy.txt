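# Alanine dipeptide (Ace-Ala-NMe), heavy atoms only.
# Methyl carbons are listed as CH3 united labels; hydrogens omitted.
# Format: "atom <index> <label>" and "bond <i> <j>".
atom 0 CH3   # acetyl methyl carbon
atom 1 C     # acetyl carbonyl carbon
atom 2 O     # acetyl carbonyl oxygen
atom 3 N     # amide nitrogen
atom 4 CA    # alpha carbon
atom 5 CB    # alanine side-chain methyl carbon
atom 6 C     # alanine carbonyl carbon
atom 7 O     # alanine carbonyl oxygen
atom 8 N     # N-methyl amide nitrogen
atom 9 CH3   # N-methyl carbon
bond 0 1
bond 1 2
bond 1 3
bond 3 4
bond 4 5
bond 4 6
bond 6 7
bond 6 8
bond 8 9
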