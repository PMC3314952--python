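>im7_wt E colicin immunity protein Im7, 87 residues, wild-type numbering from 1
MELKNSISDYTEAEFVQLLKEIEKENVAATDDVLDVLLEHFVKITEHPDGTDLIYYPSDN
RDDSPEGIVKEIKEWRAANGKPGFKQG
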