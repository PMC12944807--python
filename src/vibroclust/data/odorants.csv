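# Aroma-active compounds of three Orchidaceae (D. lindenii, M. tenuifolia,
# C. arietinum) and three Apocynaceae (H. keniensis, P. cubiformis,
# O. variegata) species: literature odor descriptor and relative content (%)
# in each species' floral volatile profile (blank = not detected).
number,name,odor_descriptor,D_lin,M_ten,C_ari,H_ken,P_cub,O_var
1,"(E,E)-α-farnesene",fruit,70.7,,24.3,,,
2,(E)-β-ocimene,wood,9.1,,,,,
3,Methyl salicylate,sweet,7.8,,,,,
4,Linalool,flower,4.7,,,,,
5,(-)-β-Caryophyllene,spices,,69.0,,,,
6,(-)-α-Copaene,wood,,10.3,,,,
7,Caryophylladienol II,spices,,7.4,,,,
8,(Z)-Methyl-p-methoxycinnamate,spices,,,18.6,,,
9,β-Bisabolene,wood,,,10.9,,,
10,(E)-α-Bergamotene,fruit,,,10.4,,,
11,6-Methylhept-5-en-2-one,fruit,,,4.5,,,
12,(E)-Methyl-p-methoxycinnamate,spices,,,3.9,,,
13,(E)-Geranyl geraniol,flower,,,3.3,,,
14,Eucalyptol,spices,,,3.2,,,
15,Dimethyl disulfide,garlic,,,,22.7,10.8,
16,Benzoic acid,sweet,,,,22.3,,17.4
17,Octanal,decayed,,,,11.4,15.7,9.2
18,Acetophenone,sweet,,,,6.9,,11.2
19,3-Methyl-2-pentanone,sweet,,,,6.2,,4.2
20,Dimethyl trisulfide,garlic,,,,6.0,53.7,26.3
21,Heptanal,decayed,,,,4.8,,
22,Decanoic acid,decayed,,,,3.5,,8.0
23,Benzaldehyde,sweet,,,,,9.3,
24,d-Limonene,fruit,,,,,3.5,
25,Indole,decayed,,,,,,5.7
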