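id,family,smiles,steps
A1,arene-A,,1
A2,arene-A,,1
A3,arene-A,,1
A4,arene-A,,1
A5,arene-A,,1
A6,arene-A,,1
A7,arene-A,,1
A8,arene-A,,1
A9,arene-A,,1
A10,arene-A,,2
A11,arene-A,,1
A12,arene-A,,1
A13,arene-A,,1
A14,arene-A,,2
A15,arene-A,,3
A16,arene-A,,1
C1B1,linker-BC,,1
C2B1,linker-BC,,1
C3B1,linker-BC,,2
C1B2,linker-BC,,1
C2B2,linker-BC,,1
C3B2,linker-BC,,2
C1B3,linker-BC,,1
C2B3,linker-BC,,1
C3B3,linker-BC,,1
C1B4,linker-BC,,1
C2B4,linker-BC,,2
C3B4,linker-BC,,2
C1B5,linker-BC,,3
C2B5,linker-BC,,1
C3B5,linker-BC,,2
C1B6,linker-BC,,3
C2B6,linker-BC,,1
C3B6,linker-BC,,3
C1B7,linker-BC,,1
C2B7,linker-BC,,2
C3B7,linker-BC,,3
C1B8,linker-BC,,1
C2B8,linker-BC,,2
C3B8,linker-BC,,1
C1B9,linker-BC,,3
C2B9,linker-BC,,1
C3B9,linker-BC,,3
C1B10,linker-BC,,2
C2B10,linker-BC,,2
C3B10,linker-BC,,2
C1B11,linker-BC,,2
C2B11,linker-BC,,2
C3B11,linker-BC,,2
C1B12,linker-BC,,3
C2B12,linker-BC,,3
C3B12,linker-BC,,3
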