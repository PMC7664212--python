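# cilffa packaged standards library (SYNTHETIC FIXTURE).
# Names and neutral formulas are real compounds; reference retention indices
# are synthetic values derived from a chain-length/unsaturation heuristic
# (RI = 100 x carbons for straight-chain saturated acids, roughly -55 RI per
# C=C double bond, made-up but ordered values for the non-FA acids), since no
# measured in-house library is publicly deposited.
name,formula,reference_ri,class
valeric acid,C5H10O2,500,saturated FA
caproic acid,C6H12O2,600,saturated FA
enanthic acid,C7H14O2,700,saturated FA
caprylic acid,C8H16O2,800,saturated FA
pelargonic acid,C9H18O2,900,saturated FA
capric acid,C10H20O2,1000,saturated FA
undecanoic acid,C11H22O2,1100,saturated FA
lauric acid,C12H24O2,1200,saturated FA
tridecanoic acid,C13H26O2,1300,saturated FA
myristic acid,C14H28O2,1400,saturated FA
pentadecanoic acid,C15H30O2,1500,saturated FA
palmitic acid,C16H32O2,1600,saturated FA
margaric acid,C17H34O2,1700,saturated FA
stearic acid,C18H36O2,1800,saturated FA
nonadecanoic acid,C19H38O2,1900,saturated FA
arachidic acid,C20H40O2,2000,saturated FA
heneicosanoic acid,C21H42O2,2100,saturated FA
behenic acid,C22H44O2,2200,saturated FA
tricosanoic acid,C23H46O2,2300,saturated FA
lignoceric acid,C24H48O2,2400,saturated FA
myristoleic acid,C14H26O2,1345,monounsaturated FA
palmitoleic acid,C16H30O2,1545,monounsaturated FA
oleic acid,C18H34O2,1745,monounsaturated FA
cis-11-eicosenoic acid,C20H38O2,1945,monounsaturated FA
erucic acid,C22H42O2,2145,monounsaturated FA
nervonic acid,C24H46O2,2345,monounsaturated FA
linoleic acid,C18H32O2,1690,polyunsaturated FA
alpha-linolenic acid,C18H30O2,1635,polyunsaturated FA
gamma-linolenic acid,C18H30O2,1620,polyunsaturated FA
cis-11 14-eicosadienoic acid,C20H36O2,1890,polyunsaturated FA
dihomo-gamma-linolenic acid,C20H34O2,1835,polyunsaturated FA
arachidonic acid,C20H32O2,1780,polyunsaturated FA
eicosapentaenoic acid,C20H30O2,1725,polyunsaturated FA
docosatetraenoic acid,C22H36O2,1980,polyunsaturated FA
docosapentaenoic acid,C22H34O2,1925,polyunsaturated FA
docosahexaenoic acid,C22H32O2,1870,polyunsaturated FA
cholic acid,C24H40O5,2510,bile acid
chenodeoxycholic acid,C24H40O4,2560,bile acid
deoxycholic acid,C24H40O4,2585,bile acid
lithocholic acid,C24H40O3,2620,bile acid
4-methyl-2-oxovaleric acid,C6H10O3,585,other
pyruvic acid,C3H4O3,310,other
lactic acid,C3H6O3,330,other
2-hydroxybutyric acid,C4H8O3,415,other
3-hydroxybutyric acid,C4H8O3,440,other
2-hydroxyisovaleric acid,C5H10O3,525,other
levulinic acid,C5H8O3,520,other
succinic acid,C4H6O4,460,other
glutaric acid,C5H8O4,555,other
adipic acid,C6H10O4,640,other
azelaic acid,C9H16O4,930,other
sebacic acid,C10H18O4,1030,other
benzoic acid,C7H6O2,735,other
phenylacetic acid,C8H8O2,830,other
hippuric acid,C9H9NO3,955,other
2-oxoglutaric acid,C5H6O5,540,other
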