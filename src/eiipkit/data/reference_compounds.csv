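id,formula,smiles
boscalid,C18H12Cl2N2O,Clc1ccc(cc1)-c1ccccc1NC(=O)c1cccnc1Cl
abamectin_B1A,C48H72O14,
abamectin_B1B,C47H70O14,
chlorantraniliprole,C18H14BrCl2N5O2,
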