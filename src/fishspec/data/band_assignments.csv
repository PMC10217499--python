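wavenumber,biomarker_for,molecular_bond,assignment
1002,D7,"Phe, Tyr","aromatic compound, protein"
1024,D0,CO,"polysaccharides, glycogen"
1176,D0,"CC of DNA, PO2 stretch","DNA, PO2, nucleic acids, carbohydrates"
1186,D7,amide III,amide III
1205,D7,amide III,"amide III, collagen"
1247,D0,PO2-,nucleic acids (RNA)
1363,D0,"CH2, CC",polysaccharides
1469,D0,CH2 bending of lipids,saturated lipids
1490,D7,"CC, CH","amide I, fatty acids"
1553,D0,amide II,predominantly alpha-helix of amide II
1635,D0,beta-sheet structures of amide I,"beta-sheets, shoulder peak of amide I"
1670,D7,"v(CC) trans, antiparallel beta-sheet structures of amide I","antiparallel beta-sheets (shoulder of amide I), fatty acids"
1712,D0,CO,"glycogen, lipid oxidation, unsaturated fatty acids (PUFA)"
1760,D0,"CO, COO-R","glycogen, lipids"
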